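"""Simplified molecular-mechanics energy model with implicit-chloroform solvation.

Terms: Lennard-Jones, Coulomb, a small periodic torsion potential on the
rotatable backbone torsions, generalized-Born polar solvation (HCT-style
pairwise descreening with the Still cross term) and a SASA-proportional
nonpolar term.  Chloroform is represented only through its dielectric
constant (4.81).  Bond stretches and angle bends are absent by construction:
internal geometry is idealized and fixed, so those terms would be constant.

The parameter set (LJ well depths, the partial-charge rule table, GB radii,
surface coefficients) is this package's own documented, reproducible choice,
shipped as ``data/forcefield_default.json``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .geometry import dihedral_angle
from .molecules import Conformation, Topology

__all__ = [
    "ForceFieldParams",
    "EnergyBreakdown",
    "default_params",
    "atom_type",
    "assign_parameters",
    "lj_energy",
    "coulomb_energy",
    "gb_polar",
    "born_radii",
    "sasa",
    "nonpolar_solvation",
    "torsion_energy",
    "total_potential",
]

COULOMB_CONSTANT = 332.06  # kcal*A/(mol*e^2)
GB_PREFACTOR = -166.03  # -COULOMB_CONSTANT / 2

_AROMATIC_NAME = re.compile(r"^C[AB]?[1-6]$")


@dataclass
class ForceFieldParams:
    lj: dict[str, tuple[float, float]]  # type -> (sigma A, eps kcal/mol)
    charges_by_type: dict[str, float]
    charges_by_name: dict[str, float]
    gb_radii: dict[str, float]
    solvent_dielectric: float = 4.81
    interior_dielectric: float = 1.0
    probe_radius: float = 1.4
    sasa_points: int = 960
    gamma_nonpolar: float = 0.005  # kcal/(mol*A^2)
    beta_nonpolar: float = 0.0
    scale_14: float = 0.5
    gb_offset: float = 0.09
    gb_scale: float = 0.8
    torsion_barrier: float = 0.3
    torsion_periodicity: int = 3
    torsion_phase: float = 0.0
    version: int = 1

    def __post_init__(self) -> None:
        for t, (s, e) in self.lj.items():
            if s <= 0 or e <= 0:
                raise ValueError(f"non-positive LJ parameter for type {t}")
        if self.solvent_dielectric <= 1.0:
            raise ValueError("solvent dielectric must exceed 1")
        if any(r <= 0 for r in self.gb_radii.values()):
            raise ValueError("GB radii must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        d = dict(d)
        d.pop("comment", None)
        d["lj"] = {k: (v["sigma"], v["eps"]) for k, v in d["lj"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "ForceFieldParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        d = {
            k: getattr(self, k)
            for k in (
                "version",
                "solvent_dielectric",
                "interior_dielectric",
                "probe_radius",
                "sasa_points",
                "gamma_nonpolar",
                "beta_nonpolar",
                "scale_14",
                "gb_offset",
                "gb_scale",
                "torsion_barrier",
                "torsion_periodicity",
                "torsion_phase",
            )
        }
        d["lj"] = {k: {"sigma": s, "eps": e} for k, (s, e) in self.lj.items()}
        d["charges_by_type"] = self.charges_by_type
        d["charges_by_name"] = self.charges_by_name
        d["gb_radii"] = self.gb_radii
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def default_params() -> ForceFieldParams:
    """The versioned default parameter set shipped with the package."""
    with resources.files("urethanefold.data").joinpath("forcefield_default.json").open() as fh:
        return ForceFieldParams.from_dict(json.load(fh))


def atom_type(topology: Topology, i: int) -> str:
    a = topology.atoms[i]
    if a.element == "H":
        return "H_polar"
    if a.element == "N":
        return "N_amide"
    if a.element == "O":
        if a.name.startswith("OS"):
            return "O_ester"
        if a.name == "O":
            return "O_carbonyl"
        return "O_hydroxyl"  # OT, OA, OB
    if a.name == "C":
        return "C_carbonyl"
    if _AROMATIC_NAME.match(a.name):
        return "C_aromatic"
    return "C_sp3"


@dataclass
class AtomParameters:
    """Per-atom parameter arrays for one topology."""

    sigma: np.ndarray
    eps: np.ndarray
    charge: np.ndarray
    gb_radius: np.ndarray
    types: list[str] = field(default_factory=list)


def assign_parameters(topology: Topology, params: ForceFieldParams) -> AtomParameters:
    """Assign LJ, charge and GB radius per atom.

    Charges come from the type table with per-name overrides, then are shifted
    uniformly within each molecule so every molecule carries exactly its
    formal charge (zero here).
    """
    n = topology.n_atoms
    sigma = np.empty(n)
    eps = np.empty(n)
    charge = np.empty(n)
    radius = np.empty(n)
    types = []
    for i, a in enumerate(topology.atoms):
        t = atom_type(topology, i)
        types.append(t)
        sigma[i], eps[i] = params.lj[t]
        charge[i] = params.charges_by_name.get(a.name, params.charges_by_type[t])
        radius[i] = params.gb_radii[a.element]
    mol = topology.molecule_of()
    for m in np.unique(mol):
        sel = mol == m
        charge[sel] -= charge[sel].sum() / sel.sum()
    return AtomParameters(sigma=sigma, eps=eps, charge=charge, gb_radius=radius, types=types)


def _get_tables(conf: Conformation, params: ForceFieldParams) -> AtomParameters:
    cache = getattr(conf.topology, "_ff_tables", None)
    if cache is None or cache[0] is not params:
        cache = (params, assign_parameters(conf.topology, params))
        conf.topology._ff_tables = cache
    return cache[1]


def _pair_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


class ClashError(ValueError):
    """Interatomic distance below the model's validity limit."""


def _checked_distances(conf: Conformation, scale: np.ndarray) -> np.ndarray:
    r = _pair_distances(conf.coords)
    mask = scale > 0
    if np.any(r[mask] < 0.1):
        raise ClashError("pair distance below 0.1 A")
    return r


def lj_energy(
    conf: Conformation,
    params: ForceFieldParams,
    exclusions: np.ndarray | None = None,
) -> float:
    """Sum of 4*eps*[(sigma/r)^12 - (sigma/r)^6] over non-excluded pairs.

    Lorentz-Berthelot combining; 1-2/1-3 pairs excluded and 1-4 pairs scaled
    by ``params.scale_14`` (or pass an explicit pair-scale matrix)."""
    t = _get_tables(conf, params)
    scale = exclusions if exclusions is not None else conf.topology.nonbonded_scale(params.scale_14)
    r = _checked_distances(conf, scale)
    sig = 0.5 * (t.sigma[:, None] + t.sigma[None, :])
    eps = np.sqrt(t.eps[:, None] * t.eps[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = (sig / np.where(r > 0, r, np.inf)) ** 6
    e = 4.0 * eps * (sr6**2 - sr6) * scale
    return float(np.triu(e, k=1).sum())


def coulomb_energy(
    conf: Conformation,
    params: ForceFieldParams,
    eps_r: float | None = None,
    charges: np.ndarray | None = None,
    exclusions: np.ndarray | None = None,
) -> float:
    """Screened Coulomb sum 332.06*qi*qj/(eps_r*rij) over non-excluded pairs."""
    t = _get_tables(conf, params)
    q = t.charge if charges is None else np.asarray(charges, dtype=float)
    er = params.interior_dielectric if eps_r is None else eps_r
    scale = exclusions if exclusions is not None else conf.topology.nonbonded_scale(params.scale_14)
    r = _checked_distances(conf, scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = COULOMB_CONSTANT * np.outer(q, q) / (er * np.where(r > 0, r, np.inf)) * scale
    return float(np.triu(e, k=1).sum())


def born_radii(conf: Conformation, params: ForceFieldParams) -> np.ndarray:
    """Effective Born radii by HCT pairwise descreening.

    Intrinsic radii are the GB radii minus ``gb_offset``; each neighbour j
    descreens with a scaled radius ``gb_scale * rho_j``.  An isolated atom's
    Born radius equals its intrinsic radius exactly."""
    t = _get_tables(conf, params)
    rho = t.gb_radius - params.gb_offset
    r = _pair_distances(conf.coords)
    sr = params.gb_scale * rho[None, :]  # descreening radius of j
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.maximum(np.abs(r - sr), rho[:, None])
        U = r + sr
        H = 0.5 * (
            1.0 / L
            - 1.0 / U
            + r / 4.0 * (1.0 / U**2 - 1.0 / L**2)
            + 1.0 / (2.0 * np.where(r > 0, r, np.inf)) * np.log(L / U)
            + sr**2 / (4.0 * np.where(r > 0, r, np.inf)) * (1.0 / L**2 - 1.0 / U**2)
        )
    np.fill_diagonal(H, 0.0)
    # atoms fully engulfing the descreening sphere contribute nothing
    H[rho[:, None] >= U] = 0.0
    inv_a = 1.0 / rho - H.sum(axis=1)
    if np.any(inv_a <= 0):
        raise ValueError("non-positive Born radius; geometry outside model validity")
    return 1.0 / inv_a


def gb_polar(
    conf: Conformation,
    params: ForceFieldParams,
    charges: np.ndarray | None = None,
) -> float:
    """Generalized-Born polar solvation energy (Still cross term), kcal/mol.

    -166*(1/eps_in - 1/eps_solv)*sum_ij qi*qj/f_GB with the full double sum
    (self terms i == j included)."""
    t = _get_tables(conf, params)
    q = t.charge if charges is None else np.asarray(charges, dtype=float)
    a = born_radii(conf, params)
    r2 = _pair_distances(conf.coords) ** 2
    aa = np.outer(a, a)
    f = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    dielectric_factor = 1.0 / params.interior_dielectric - 1.0 / params.solvent_dielectric
    e = GB_PREFACTOR * dielectric_factor * np.outer(q, q) / f
    return float(e.sum())


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _unit_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    if n not in _SPHERE_CACHE:
        k = np.arange(n) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n)
        theta = np.pi * (1.0 + 5.0**0.5) * k
        _SPHERE_CACHE[n] = np.column_stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
    return _SPHERE_CACHE[n]


def _canonical_rotation(coords: np.ndarray) -> np.ndarray:
    """Orthogonal matrix mapping `coords` into a molecule-fixed frame.

    Principal axes with a deterministic sign convention, so the frame
    co-rotates exactly with the molecule under rigid motions."""
    c = coords - coords.mean(axis=0)
    if len(c) < 3:
        return np.eye(3)
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    x = c @ vt.T
    signs = np.ones(3)
    for k in range(3):
        col = x[:, k]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            signs[k] = -1.0
    return signs[:, None] * vt


def sasa(
    conf: Conformation,
    params: ForceFieldParams,
    radii: np.ndarray | None = None,
    probe: float | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2), Shrake-Rupley style.

    Deterministic fixed point set (``params.sasa_points`` per atom) oriented
    in each molecule's canonical frame, so results are bit-reproducible,
    rotation-invariant, and exactly additive for well-separated molecules."""
    t = _get_tables(conf, params)
    rad = (t.gb_radius if radii is None else np.asarray(radii, dtype=float)) + (
        params.probe_radius if probe is None else probe
    )
    pts = _unit_sphere(params.sasa_points)
    coords = conf.coords
    n = conf.topology.n_atoms
    mol = conf.topology.molecule_of()
    directions = {m: pts @ _canonical_rotation(coords[mol == m]) for m in np.unique(mol)}
    areas = np.empty(n)
    d = _pair_distances(coords)
    for i in range(n):
        neigh = np.where((d[i] < rad[i] + rad) & (np.arange(n) != i))[0]
        if neigh.size:
            surface = coords[i] + rad[i] * directions[mol[i]]
            dd = surface[:, None, :] - coords[neigh][None, :, :]
            buried = (dd**2).sum(-1) < (rad[neigh] ** 2)[None, :]
            frac = 1.0 - buried.any(axis=1).mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * rad[i] ** 2 * frac
    return areas


def nonpolar_solvation(total_sasa: float, gamma: float, beta: float = 0.0) -> float:
    """Linear surface-area nonpolar solvation term gamma*SASA + beta."""
    if total_sasa < 0:
        raise ValueError("negative SASA")
    return gamma * total_sasa + beta


def torsion_energy(conf: Conformation, params: ForceFieldParams) -> float:
    """Periodic potential k*(1 + cos(n*theta - phase)) on rotatable torsions."""
    e = 0.0
    for _name, _res, quad in conf.topology.rotatable_torsions:
        theta = np.radians(dihedral_angle(*[conf.coords[q] for q in quad]))
        e += params.torsion_barrier * (
            1.0 + np.cos(params.torsion_periodicity * theta - np.radians(params.torsion_phase))
        )
    return float(e)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components in kcal/mol; E_total is their exact sum."""

    E_vdW: float
    E_el: float
    E_torsion: float
    G_solv_polar: float
    G_solv_nonpolar: float

    @property
    def E_total(self) -> float:
        return self.E_vdW + self.E_el + self.E_torsion + self.G_solv_polar + self.G_solv_nonpolar

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.E_vdW - other.E_vdW,
            self.E_el - other.E_el,
            self.E_torsion - other.E_torsion,
            self.G_solv_polar - other.G_solv_polar,
            self.G_solv_nonpolar - other.G_solv_nonpolar,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "E_vdW": self.E_vdW,
            "E_el": self.E_el,
            "E_torsion": self.E_torsion,
            "G_solv_polar": self.G_solv_polar,
            "G_solv_nonpolar": self.G_solv_nonpolar,
            "E_total": self.E_total,
        }


def total_potential(
    conf: Conformation,
    params: ForceFieldParams,
    solvation: bool = True,
    eps_r: float | None = None,
) -> EnergyBreakdown:
    """All energy components for one conformation.

    With ``solvation=False`` the GB and SASA terms are zero and ``eps_r``
    (default: the solvent dielectric) screens the Coulomb term instead - the
    fast potential used during Monte Carlo sampling."""
    e_vdw = lj_energy(conf, params)
    if solvation:
        e_el = coulomb_energy(conf, params)
        g_pol = gb_polar(conf, params)
        g_np = nonpolar_solvation(
            float(sasa(conf, params).sum()), params.gamma_nonpolar, params.beta_nonpolar
        )
    else:
        e_el = coulomb_energy(conf, params, eps_r=eps_r or params.solvent_dielectric)
        g_pol = 0.0
        g_np = 0.0
    return EnergyBreakdown(
        E_vdW=e_vdw,
        E_el=e_el,
        E_torsion=torsion_energy(conf, params),
        G_solv_polar=g_pol,
        G_solv_nonpolar=g_np,
    )
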