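"""Shared definitions for the numbered analysis scripts.

The sequence library: five stereo-sequences with zero or one stereocenter
mutation (OU1-OU4) plus the two-mutation OU6; OU5 and OU7 are synthetic
stand-in sequences (their published identities are only available as
supplementary figures), marked as such in the table below.
"""

from __future__ import annotations

from pathlib import Path

from urethanefold.forcefield import default_params
from urethanefold.io import read_xyz
from urethanefold.molecules import bpa_structure, merge_topologies, oligourethane_topology

_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results"
# raw ensembles are bulky regenerable intermediates; keep them out of results
ENSEMBLE_DIR = _ROOT / "scratch" / "ensembles"

# id -> (stereo sequence, is synthetic stand-in)
LIBRARY = {
    "OU1": ("SSSSS", False),
    "OU2": ("SRSSS", False),
    "OU3": ("SSRSS", False),
    "OU4": ("SSSRS", False),
    "OU5": ("SRSSR", True),  # synthetic stand-in (two mutations)
    "OU6": ("SRSRS", False),
    "OU7": ("SSRRS", True),  # synthetic stand-in (two mutations)
}

# sequences sampled by default in 02-05 (full library with --all)
DEFAULT_SAMPLED = ["OU1", "OU3", "OU4"]

PARAMS = default_params()


def topologies(ids):
    out = {}
    for seq_id in ids:
        stereo, _synthetic = LIBRARY[seq_id]
        out[seq_id] = oligourethane_topology(stereo, name=seq_id)
    return out


def complex_for(topo):
    bpa = bpa_structure()
    return merge_topologies(topo, bpa.topology), bpa


def load_ensemble(seq_id, complex_topo):
    path = ENSEMBLE_DIR / f"{seq_id}.xyz"
    if not path.exists():
        raise SystemExit(
            f"missing {path}; run analysis/02_sample_ensembles.py first"
        )
    return read_xyz(path, complex_topo)
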