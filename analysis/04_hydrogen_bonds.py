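#!/usr/bin/env python
"""Hydrogen-bond statistics: intramolecular folding vs BPA coupling.

Counts geometric hydrogen bonds (D...A <= 3.5 A, D-H...A >= 135 deg) per
frame and partitions them into oligomer-internal (intra) and oligomer-BPA
(inter) classes, per ensemble and per cluster.

Writes results/04_hbonds.csv and results/04_hbonds_by_cluster.csv.
"""

import argparse

import pandas as pd

from common import DEFAULT_SAMPLED, LIBRARY, RESULTS, complex_for, load_ensemble, topologies
from urethanefold.conformers import cluster_ensemble
from urethanefold.hbonds import hbond_statistics


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--all", action="store_true")
    args = ap.parse_args()
    ids = list(LIBRARY) if args.all else DEFAULT_SAMPLED

    rows, cluster_rows = [], []
    for seq_id, topo in topologies(ids).items():
        cx, _ = complex_for(topo)
        frames = load_ensemble(seq_id, cx)
        asg = cluster_ensemble(frames, cutoff=2.0)
        stats = hbond_statistics(frames, asg)
        rows.append(
            {
                "sequence_id": seq_id,
                "mean_intra": round(stats.mean_intra, 3),
                "mean_inter": round(stats.mean_inter, 3),
                "n_frames": len(frames),
            }
        )
        for c in range(asg.n_clusters):
            cluster_rows.append(
                {
                    "sequence_id": seq_id,
                    "cluster": c,
                    "population": float(asg.populations[c]),
                    "mean_intra": float(stats.cluster_mean_intra[c]),
                    "mean_inter": float(stats.cluster_mean_inter[c]),
                }
            )
        print(f"{seq_id}: intra {stats.mean_intra:.2f}, inter {stats.mean_inter:.2f} "
              "H-bonds per frame")
    pd.DataFrame(rows).to_csv(RESULTS / "04_hbonds.csv", index=False)
    pd.DataFrame(cluster_rows).to_csv(RESULTS / "04_hbonds_by_cluster.csv", index=False)
    print("wrote results/04_hbonds.csv and 04_hbonds_by_cluster.csv")


if __name__ == "__main__":
    main()
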