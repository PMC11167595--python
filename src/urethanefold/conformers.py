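"""Structural analysis of conformer ensembles.

Pairwise Kabsch RMSD, deterministic average-linkage clustering with
population statistics, urethane backbone torsion measurement with circular
statistics, the stereochemistry sign rule (S at Cgamma -> phi < 0), and
heuristic helix regularity / handedness metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import dihedral_angle, wrap_angle
from .molecules import Conformation

__all__ = [
    "ClusterAssignment",
    "TorsionSet",
    "HelixMetrics",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rmsd_after_fit",
    "pairwise_rmsd",
    "cluster_ensemble",
    "top_clusters",
    "measure_torsions",
    "torsion_mode",
    "circular_variance",
    "stereo_sign_statistics",
    "helix_metrics",
]


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (SVD construction) aligning centered `mobile`
    onto centered `target`."""
    h = mobile.T @ target
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_rmsd(
    conf_a: Conformation | np.ndarray,
    conf_b: Conformation | np.ndarray,
    selection: np.ndarray | None = None,
) -> float:
    """Minimal RMSD over rigid superposition of the selected atoms."""
    a = conf_a.coords if isinstance(conf_a, Conformation) else np.asarray(conf_a, float)
    b = conf_b.coords if isinstance(conf_b, Conformation) else np.asarray(conf_b, float)
    if selection is not None:
        a = a[selection]
        b = b[selection]
    if a.shape != b.shape:
        raise ValueError("selection size mismatch")
    if len(a) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot = kabsch_rotation(a, b)
    diff = a @ rot.T - b
    return float(np.sqrt((diff**2).sum() / len(a)))


def rmsd_after_fit(
    conf_a: Conformation | np.ndarray,
    conf_b: Conformation | np.ndarray,
    fit_selection: np.ndarray,
    rmsd_selection: np.ndarray,
) -> float:
    """RMSD over `rmsd_selection` after superposing on `fit_selection`
    (e.g. fit on the oligomer backbone, measure the whole complex)."""
    a = conf_a.coords if isinstance(conf_a, Conformation) else np.asarray(conf_a, float)
    b = conf_b.coords if isinstance(conf_b, Conformation) else np.asarray(conf_b, float)
    ca = a[fit_selection].mean(axis=0)
    cb = b[fit_selection].mean(axis=0)
    rot = kabsch_rotation(a[fit_selection] - ca, b[fit_selection] - cb)
    moved = (a - ca) @ rot.T + cb
    diff = moved[rmsd_selection] - b[rmsd_selection]
    return float(np.sqrt((diff**2).sum() / len(rmsd_selection)))


def pairwise_rmsd(
    frames: list[Conformation],
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix."""
    n = len(frames)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fit_selection is not None and selection is not None:
                r = rmsd_after_fit(frames[i], frames[j], fit_selection, selection)
            else:
                r = kabsch_rmsd(frames[i], frames[j], selection)
            mat[i, j] = mat[j, i] = r
    return mat


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Frame -> cluster labels with populations and medoid representatives.

    Labels are dense from 0 and ordered by first-occurring frame; the medoid
    is the member frame minimizing summed RMSD to its clustermates (ties go
    to the lowest frame index)."""

    labels: np.ndarray
    populations: np.ndarray
    medoids: list[int]
    cutoff: float
    rmsd_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if abs(self.populations.sum() - 1.0) > 1e-12:
            raise ValueError("cluster populations must sum to 1")
        for c, m in enumerate(self.medoids):
            if self.labels[m] != c:
                raise ValueError("medoid not a member of its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, label: int) -> np.ndarray:
        return np.where(self.labels == label)[0]


def _default_selections(frames: list[Conformation]):
    topo = frames[0].topology
    heavy = topo.heavy_atoms()
    if topo.components is not None:
        fit = topo.backbone_atoms(mol=0)
    else:
        fit = topo.backbone_atoms() if len(topo.backbone_atoms()) >= 3 else heavy
    return heavy, fit


def cluster_ensemble(
    ensemble,
    selection: np.ndarray | None = None,
    cutoff: float = 2.0,
    fit_selection: np.ndarray | None = None,
    skip_fraction: float = 0.1,
) -> ClusterAssignment:
    """Average-linkage agglomerative clustering on the pairwise RMSD matrix.

    `ensemble` is a sampler Ensemble or a list of Conformations.  By default
    frames are superposed on the oligomer backbone and compared on all heavy
    atoms.  The dendrogram is cut at `cutoff` (Angstrom); all tie-breaking is
    deterministic.
    """
    frames = ensemble if isinstance(ensemble, list) else ensemble.frames(skip_fraction)
    if not frames:
        raise ValueError("empty ensemble")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if selection is None:
        selection, default_fit = _default_selections(frames)
        if fit_selection is None:
            fit_selection = default_fit
    mat = pairwise_rmsd(frames, selection, fit_selection)
    n = len(frames)
    if n == 1:
        raw = np.zeros(1, dtype=int)
    else:
        z = linkage(squareform(mat, checks=False), method="average")
        raw = fcluster(z, t=cutoff, criterion="distance") - 1
    # relabel densely in order of first appearance
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    k = len(order)
    populations = np.array([(labels == c).sum() for c in range(k)], dtype=float) / n
    medoids = []
    for c in range(k):
        members = np.where(labels == c)[0]
        sums = mat[np.ix_(members, members)].sum(axis=1)
        medoids.append(int(members[np.argmin(sums)]))  # argmin takes first on ties
    return ClusterAssignment(
        labels=labels,
        populations=populations,
        medoids=medoids,
        cutoff=cutoff,
        rmsd_matrix=mat,
    )


def top_clusters(assignment: ClusterAssignment, k: int = 5):
    """The k most populated clusters (ties broken by label) plus the fraction
    of the ensemble they jointly cover."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        range(assignment.n_clusters), key=lambda c: (-assignment.populations[c], c)
    )[:k]
    summaries = [
        {
            "label": c,
            "population": float(assignment.populations[c]),
            "medoid": assignment.medoids[c],
            "size": int(len(assignment.members(c))),
        }
        for c in order
    ]
    coverage = float(sum(s["population"] for s in summaries))
    return summaries, coverage


# ---------------------------------------------------------------------------
# Torsion analysis
# ---------------------------------------------------------------------------

@dataclass
class TorsionSet:
    """Measured (phi, xi, chi) per residue, with the resonance-locked psi and
    omega reported at their fixed value of 180 degrees."""

    phi: np.ndarray
    xi: np.ndarray
    chi: np.ndarray
    psi: np.ndarray = field(default=None)  # type: ignore[assignment]
    omega: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.phi)
        if self.psi is None:
            self.psi = np.full(n, 180.0)
        if self.omega is None:
            self.omega = np.full(n, 180.0)
        for arr in (self.phi, self.xi, self.chi):
            if len(arr) != n:
                raise ValueError("one entry per residue required")
            if np.any((arr <= -180.0) | (arr > 180.0)):
                raise ValueError("torsion outside (-180, 180]")

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.phi, self.xi, self.chi])


def measure_torsions(conf: Conformation) -> TorsionSet:
    """Signed dihedrals (IUPAC convention, cis = 0) for every defined
    rotatable torsion of the conformation's topology."""
    topo = conf.topology
    n = len(topo.residues)
    vals = {"phi": np.full(n, np.nan), "xi": np.full(n, np.nan), "chi": np.full(n, np.nan)}
    for name, res, quad in topo.rotatable_torsions:
        kind = name.split("_")[0]
        try:
            pts = [conf.coords[q] for q in quad]
        except IndexError as exc:
            raise ValueError(f"torsion {name}: atom index out of range") from exc
        vals[kind][res] = wrap_angle(dihedral_angle(*pts))  # -180 reported as +180
    return TorsionSet(phi=vals["phi"], xi=vals["xi"], chi=vals["chi"])


def torsion_mode(values: np.ndarray, bin_width: float = 10.0) -> float:
    """Most probable angle: center of the most populated circular bin.

    Bins are centered on -180 + k*bin_width and wrap at +/-180; ties break
    toward the smaller absolute angle.  Returned on (-180, 180] (the wrap
    bin is reported as +180)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value set")
    nbins = int(round(360.0 / bin_width))
    idx = np.floor((values + 180.0 + bin_width / 2.0) / bin_width).astype(int) % nbins
    counts = np.bincount(idx, minlength=nbins)
    centers = wrap_angle(-180.0 + bin_width * np.arange(nbins))
    best = max(range(nbins), key=lambda b: (counts[b], -abs(centers[b]), centers[b]))
    return float(centers[best])


def circular_variance(values_deg: np.ndarray) -> float:
    """1 - mean resultant length of the angles; 0 for identical angles."""
    t = np.radians(np.asarray(values_deg, dtype=float))
    return float(1.0 - np.hypot(np.sin(t).mean(), np.cos(t).mean()))


def stereo_sign_statistics(frames: list[Conformation]) -> dict:
    """Per-residue fraction of frames obeying the stereochemical sign rule
    (S configuration -> phi < 0, R -> phi > 0), plus the ensemble mean."""
    if not frames:
        raise ValueError("empty frame set")
    topo = frames[0].topology
    residues = topo.residues
    n = len(residues)
    match = np.zeros(n)
    for conf in frames:
        phi = measure_torsions(conf).phi
        for i, res in enumerate(residues):
            ok = phi[i] < 0 if res.stereo == "S" else phi[i] > 0
            match[i] += ok
    frac = match / len(frames)
    return {"per_residue": frac, "mean": float(frac.mean()), "n_frames": len(frames)}


@dataclass
class HelixMetrics:
    regularity: float
    handedness: str  # right | left | none
    per_torsion_variance: dict[str, float]


def helix_metrics(conf: Conformation, threshold: float = 0.7) -> HelixMetrics:
    """Heuristic helix regularity and handedness of one conformation.

    Regularity is 1 minus the mean circular variance of phi, xi and chi
    across residues (1 = perfectly repeating torsions).  Handedness comes
    from the sign of the circular-mean virtual dihedral over consecutive
    Cgamma quadruples (positive = right-handed) and is reported only when
    regularity reaches `threshold`."""
    topo = conf.topology
    if len(topo.residues) < 4:
        raise ValueError("need at least 4 residues for helix metrics")
    ts = measure_torsions(conf)
    variances = {
        "phi": circular_variance(ts.phi),
        "xi": circular_variance(ts.xi),
        "chi": circular_variance(ts.chi),
    }
    regularity = 1.0 - float(np.mean(list(variances.values())))
    cg = topo.cgamma_atoms()
    virt = [
        dihedral_angle(*[conf.coords[cg[i + k]] for k in range(4)])
        for i in range(len(cg) - 3)
    ]
    t = np.radians(virt)
    mean_virtual = np.degrees(np.arctan2(np.sin(t).mean(), np.cos(t).mean()))
    if regularity < threshold:
        handedness = "none"
    else:
        handedness = "right" if mean_virtual > 0 else "left"
    return HelixMetrics(
        regularity=regularity,
        handedness=handedness,
        per_torsion_variance=variances,
    )
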