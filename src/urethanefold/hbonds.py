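"""Geometric hydrogen-bond detection and intra/intermolecular statistics.

A hydrogen bond is a donor-hydrogen...acceptor contact with heavy-atom
donor-acceptor distance <= `dmax` (default 3.5 A) and D-H...A angle >=
`theta_min` (default 135 deg).  Each donor contributes at most one bond per
frame (the best-angle candidate wins), which keeps counts free of bifurcated
double counting.  Bonds are classed intramolecular (both partners on the
oligomer) or intermolecular (exactly one partner on the BPA ligand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .conformers import ClusterAssignment
from .geometry import bond_angle
from .molecules import Conformation

__all__ = ["HBond", "HBondStats", "detect_hbonds", "partition_hbonds", "hbond_statistics"]

DEFAULT_DMAX = 3.5
DEFAULT_THETA_MIN = 135.0


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # heavy-atom D...A, Angstrom
    angle: float  # D-H...A, degrees
    hb_class: str  # intra | inter


def _graph_distances(topology, sources, cutoff=2):
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_atoms))
    g.add_edges_from(topology.bonds)
    out = {}
    for s in sources:
        out[s] = nx.single_source_shortest_path_length(g, s, cutoff=cutoff)
    return out


def detect_hbonds(
    conf: Conformation,
    dmax: float = DEFAULT_DMAX,
    theta_min: float = DEFAULT_THETA_MIN,
) -> list[HBond]:
    """All donor-acceptor contacts meeting both geometric criteria.

    Donor-acceptor pairs closer than 3 bonds on the molecular graph are not
    counted (they cannot form a meaningful hydrogen bond in these scaffolds).
    """
    topo = conf.topology
    mol = topo.molecule_of()
    near = _graph_distances(topo, [d for d, _h in topo.hb_donors], cutoff=2)
    bonds: list[HBond] = []
    for donor, hydrogen in topo.hb_donors:
        best: HBond | None = None
        for acceptor in topo.hb_acceptors:
            if acceptor == donor or acceptor in near[donor]:
                continue
            d = float(np.linalg.norm(conf.coords[donor] - conf.coords[acceptor]))
            if d > dmax:
                continue
            ang = bond_angle(conf.coords[donor], conf.coords[hydrogen], conf.coords[acceptor])
            if ang < theta_min:
                continue
            if mol[donor] == 0 and mol[acceptor] == 0:
                cls = "intra"
            elif mol[donor] != mol[acceptor]:
                cls = "inter"
            else:
                cls = "intra"  # ligand-internal; flagged in partition_hbonds
            cand = HBond(donor, hydrogen, acceptor, d, ang, cls)
            if best is None or cand.angle > best.angle:
                best = cand
        if best is not None:
            bonds.append(best)
    return bonds


def partition_hbonds(
    hbonds: list[HBond], topology
) -> tuple[list[HBond], list[HBond]]:
    """Split detected bonds into (intra, inter) lists; a bond with both
    partners on the ligand is physically unexpected in a 1:1 complex and is
    kept in the intra list with a warning."""
    mol = topology.molecule_of()
    intra, inter = [], []
    for hb in hbonds:
        if mol[hb.donor] == 1 and mol[hb.acceptor] == 1:
            warnings.warn("hydrogen bond with both partners on the ligand", stacklevel=2)
            intra.append(hb)
        elif hb.hb_class == "inter":
            inter.append(hb)
        else:
            intra.append(hb)
    return intra, inter


@dataclass
class HBondStats:
    per_frame_intra: np.ndarray
    per_frame_inter: np.ndarray
    mean_intra: float
    mean_inter: float
    cluster_mean_intra: np.ndarray | None = None
    cluster_mean_inter: np.ndarray | None = None


def hbond_statistics(
    frames: list[Conformation],
    assignment: ClusterAssignment | None = None,
    dmax: float = DEFAULT_DMAX,
    theta_min: float = DEFAULT_THETA_MIN,
) -> HBondStats:
    """Per-frame intra/inter hydrogen-bond counts with ensemble means and,
    when a cluster assignment is given, per-cluster means.  The ensemble
    mean equals the population-weighted cluster means by construction."""
    if not frames:
        raise ValueError("empty ensemble")
    topo = frames[0].topology
    intra = np.empty(len(frames))
    inter = np.empty(len(frames))
    for i, conf in enumerate(frames):
        hi, he = partition_hbonds(detect_hbonds(conf, dmax, theta_min), topo)
        intra[i] = len(hi)
        inter[i] = len(he)
    stats = HBondStats(
        per_frame_intra=intra,
        per_frame_inter=inter,
        mean_intra=float(intra.mean()),
        mean_inter=float(inter.mean()),
    )
    if assignment is not None:
        if len(assignment.labels) != len(frames):
            raise ValueError("assignment does not match frame count")
        k = assignment.n_clusters
        stats.cluster_mean_intra = np.array(
            [intra[assignment.labels == c].mean() for c in range(k)]
        )
        stats.cluster_mean_inter = np.array(
            [inter[assignment.labels == c].mean() for c in range(k)]
        )
    return stats
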