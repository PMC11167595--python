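#!/usr/bin/env python
"""Combine computed binding energies with fitted Ka into the library report.

Joins results/05_binding.csv (theory) and results/06_fits.csv (synthetic
experiment) on sequence id, computes the pairwise trend concordance
(fraction of sequence pairs where the more negative dG_bind goes with the
larger Ka), and ranks the library both ways.

Writes results/07_report.csv and results/07_summary.md.
"""

import pandas as pd

from common import RESULTS
from urethanefold.titration import trend_concordance


def main() -> None:
    binding_path = RESULTS / "05_binding.csv"
    fits_path = RESULTS / "06_fits.csv"
    for p in (binding_path, fits_path):
        if not p.exists():
            raise SystemExit(f"missing {p}; run the earlier analysis scripts first")
    binding = pd.read_csv(binding_path)
    fits = pd.read_csv(fits_path)
    table = binding.merge(fits[["sequence_id", "fitted_Kd_mM", "Ka_per_M"]],
                          on="sequence_id", how="left")
    table["has_experiment"] = table.Ka_per_M.notna()
    table.to_csv(RESULTS / "07_report.csv", index=False)

    both = table[table.has_experiment]
    lines = ["# Library report", ""]
    if len(both) >= 2:
        dg = dict(zip(both.sequence_id, both.dG_bind))
        ka = dict(zip(both.sequence_id, both.Ka_per_M))
        conc = trend_concordance(dg, ka)
        lines.append(f"Trend concordance (pairwise, theory vs synthetic experiment): "
                     f"**{conc:.2f}**")
        print(f"trend concordance: {conc:.2f} over {len(both)} sequences")
    theory_rank = table.sort_values("dG_bind").sequence_id.tolist()
    lines.append(f"\nRanking by dG_bind (strongest first): {' > '.join(theory_rank)}")
    if len(both) >= 2:
        exp_rank = both.sort_values("Ka_per_M", ascending=False).sequence_id.tolist()
        lines.append(f"\nRanking by Ka (strongest first): {' > '.join(exp_rank)}")
    lines.append("\n" + table.to_string(index=False))
    (RESULTS / "07_summary.md").write_text("\n".join(lines) + "\n")
    print("wrote results/07_report.csv and 07_summary.md")


if __name__ == "__main__":
    main()
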