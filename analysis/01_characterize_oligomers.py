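#!/usr/bin/env python
"""Molecular formulas and LC-MS adduct m/z for the oligourethane library.

All pentamers share the 2-benzyl + 3-methyl composition, so every sequence
gives the same formula (C36H53N5O11) and the same three ion signals: the
stereo-sequence is invisible to mass spectrometry, which is exactly why the
conformational analysis in the later scripts is needed.

Writes results/01_adducts.csv.
"""

import pandas as pd

from common import LIBRARY, RESULTS, topologies
from urethanefold.molecules import adduct_mz, molecular_formula

ADDUCTS = ("[M+H]+", "[M+Na]+", "[M-Boc+H]+")


def main() -> None:
    rows = []
    for seq_id, topo in topologies(LIBRARY).items():
        stereo, synthetic = LIBRARY[seq_id]
        formula = molecular_formula(topo)
        row = {
            "sequence_id": seq_id,
            "stereo": stereo,
            "synthetic_standin": synthetic,
            "formula": formula.hill_formula(),
        }
        for ad in ADDUCTS:
            row[ad] = adduct_mz(formula, ad)
        rows.append(row)
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "01_adducts.csv"
    df.to_csv(out, index=False)
    print(df.to_string(index=False))
    print(f"\nAll {len(df)} diastereomers share one formula "
          f"({df.formula.nunique()} unique) - mass spectrometry cannot "
          "distinguish stereo-sequences.")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
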