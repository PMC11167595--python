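"""Molecular graphs and 3D builders for sequence-defined oligourethanes and BPA.

The oligomers are Boc-capped chains of carbamate-linked amino-alcohol units
(gamma-peptide relatives).  Two monomer types are supported:

* ``P`` — benzyl side chain (phenylalaninol-derived, aromatic)
* ``M`` — methyl side chain (alaninol-derived, aliphatic)

each carrying an ``S`` or ``R`` stereocenter at the backbone C-gamma.
All heavy atoms are explicit; polar hydrogens (urethane N-H, hydroxyls) are
explicit because hydrogen-bond geometry needs them; aliphatic and aromatic
hydrogens are implicit (united atoms) but counted in molecular formulas.

Backbone torsion nomenclature follows the generalized-Ramachandran scheme for
urethanes: rotatable phi (N-Cgamma), xi (Cgamma-Cbeta) and chi (Cbeta-O);
resonance-locked psi (C-O) and omega (C-N) are held planar-trans at 180 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .geometry import place_atom

__all__ = [
    "MonomerSpec",
    "Atom",
    "Topology",
    "Conformation",
    "ElementCounts",
    "parse_sequence",
    "oligourethane_topology",
    "bpa_topology",
    "merge_topologies",
    "molecular_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "build_structure",
    "bpa_structure",
    "assign_stereo",
    "signed_volume",
    "DEFAULT_PENTAMER_PATTERN",
]

# Monoisotopic atomic masses, Da (CODATA/IUPAC values, >=6 decimals).
MONOISOTOPIC_MASS = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "Na": 22.98976928,
}
PROTON_MASS = 1.00727646

# Default composition pattern for the pentamer library: 2 benzyl (P) + 3
# methyl (M) units, P at positions 1 and 4.  Formula and mass results are
# invariant to the arrangement at fixed composition.
DEFAULT_PENTAMER_PATTERN = "PMMPM"

# Idealized internal coordinates (Angstrom / degrees).
_B = {
    "C-C": 1.53,
    "C-Car": 1.51,
    "Car-Car": 1.39,
    "N-C": 1.45,  # N-Cgamma
    "C(=O)-N": 1.35,
    "C=O": 1.22,
    "C(=O)-O": 1.34,  # carbonyl-ester oxygen
    "C-O": 1.43,  # sp3 C - ester/hydroxyl oxygen
    "O-H": 0.96,
    "N-H": 1.01,
}


class SequenceError(ValueError):
    """Invalid stereo/composition specification."""


@dataclass(frozen=True)
class MonomerSpec:
    """One carbamate-linked unit: side-chain type and Cgamma configuration."""

    code: str  # "P" (benzyl) or "M" (methyl)
    stereo: str  # "S" or "R"

    def __post_init__(self) -> None:
        if self.code not in ("P", "M"):
            raise SequenceError(f"monomer code must be P or M, got {self.code!r}")
        if self.stereo not in ("S", "R"):
            raise SequenceError(f"stereo flag must be S or R, got {self.stereo!r}")


@dataclass
class Atom:
    element: str
    name: str
    residue: int  # -1 for the Boc cap
    role: str  # backbone | sidechain | cap
    implicit_h: int = 0
    mol: int = 0  # 0 = oligomer/host, 1 = ligand


@dataclass
class ZEntry:
    """Internal-coordinate record: place atom `l` from references i-j-k."""

    l: int
    k: int
    j: int
    i: int
    bond: float
    angle: float
    dihedral: float  # offset added to the named variable (or absolute if None)
    variable: str | None = None


@dataclass
class Topology:
    """Molecular graph plus the internal-coordinate recipe to build it in 3D."""

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    residues: list[MonomerSpec] = field(default_factory=list)
    zmatrix: list[ZEntry] = field(default_factory=list)
    rotatable_torsions: list[tuple[str, int, tuple[int, int, int, int]]] = field(default_factory=list)
    fixed_torsions: list[tuple[str, int, tuple[int, int, int, int]]] = field(default_factory=list)
    hb_donors: list[tuple[int, int]] = field(default_factory=list)  # (heavy donor, polar H)
    hb_acceptors: list[int] = field(default_factory=list)
    n_cap: str | None = None
    c_terminus: str | None = None
    components: list["Topology"] | None = None  # set for merged complexes
    component_slices: list[slice] | None = None

    def __post_init__(self) -> None:
        self._index: dict[tuple[int, str], int] = {}
        for i, a in enumerate(self.atoms):
            self._index[(a.residue, a.name)] = i
        self._nb_scale: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, residue: int, name: str) -> int:
        return self._index[(residue, name)]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def heavy_atoms(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.element != "H"], dtype=int)

    def backbone_atoms(self, mol: int | None = None) -> np.ndarray:
        return np.array(
            [
                i
                for i, a in enumerate(self.atoms)
                if a.role == "backbone"
                and a.element != "H"
                and (mol is None or a.mol == mol)
            ],
            dtype=int,
        )

    def cgamma_atoms(self) -> np.ndarray:
        return np.array(
            [self.atom_index(i, "CG") for i in range(len(self.residues))], dtype=int
        )

    def molecule_of(self) -> np.ndarray:
        return np.array([a.mol for a in self.atoms], dtype=int)

    def nonbonded_scale(self, scale_14: float = 0.5) -> np.ndarray:
        """Pairwise scaling matrix: 0 for 1-2/1-3 pairs, `scale_14` for 1-4,
        1 otherwise (including intermolecular pairs)."""
        if self._nb_scale is None:
            n = self.n_atoms
            scale = np.ones((n, n))
            np.fill_diagonal(scale, 0.0)
            g = self.graph()
            for i, dists in nx.all_pairs_shortest_path_length(g, cutoff=3):
                for j, d in dists.items():
                    if i == j:
                        continue
                    if d <= 2:
                        scale[i, j] = 0.0
                    elif d == 3:
                        scale[i, j] = scale_14
            self._nb_scale = scale
        return self._nb_scale

    def validate(self) -> None:
        g = self.graph()
        if self.n_atoms and not nx.is_connected(g) and self.components is None:
            raise ValueError("bond graph is not connected")
        for name, _res, quad in self.rotatable_torsions:
            for a, b in zip(quad[:-1], quad[1:]):
                if not g.has_edge(a, b):
                    raise ValueError(f"torsion {name}: atoms {a}-{b} not bonded")
        for d, h in self.hb_donors:
            if self.atoms[d].element not in ("N", "O") or self.atoms[h].element != "H":
                raise ValueError("donor must be N/O with an explicit polar hydrogen")


@dataclass
class Conformation:
    """Cartesian coordinates (Angstrom) for one topology."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def check_bonds(self, lo: float = 0.8, hi: float = 2.0) -> None:
        for a, b in self.topology.bonds:
            d = float(np.linalg.norm(self.coords[a] - self.coords[b]))
            if not lo <= d <= hi:
                raise ValueError(f"bond {a}-{b} length {d:.3f} A outside [{lo}, {hi}]")

    def copy(self) -> "Conformation":
        return Conformation(self.topology, self.coords.copy(), dict(self.provenance))


class ElementCounts(dict):
    """Element symbol -> count mapping with Hill-order formatting."""

    def __init__(self, counts: Mapping[str, int] | None = None):
        super().__init__()
        if counts:
            for k, v in counts.items():
                self.add(k, v)

    def add(self, element: str, count: int = 1) -> None:
        if count < 0:
            raise ValueError("negative element count")
        self[element] = self.get(element, 0) + count

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        out = ElementCounts(self)
        for k, v in other.items():
            out.add(k, v)
        return out

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        out = ElementCounts(self)
        for k, v in other.items():
            out[k] = out.get(k, 0) - v
            if out[k] < 0:
                raise ValueError(f"negative count for {k}")
            if out[k] == 0:
                del out[k]
        return out

    def hill_formula(self) -> str:
        parts = []
        for el in ["C", "H"] + sorted(k for k in self if k not in ("C", "H")):
            n = self.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)


def parse_sequence(stereo: str, composition: str | None = None) -> list[MonomerSpec]:
    """Parse a stereo string (S/R per position) and a composition pattern (P/M).

    ``composition=None`` selects the default pentamer pattern
    ``PMMPM`` and is only valid for length-5 sequences.
    """
    if composition is None:
        if len(stereo) != len(DEFAULT_PENTAMER_PATTERN):
            raise SequenceError(
                "composition pattern required for non-pentamer sequences"
            )
        composition = DEFAULT_PENTAMER_PATTERN
    if len(stereo) != len(composition):
        raise SequenceError(
            f"stereo length {len(stereo)} != composition length {len(composition)}"
        )
    if not stereo:
        raise SequenceError("empty sequence")
    residues = []
    for pos, (s, c) in enumerate(zip(stereo, composition), start=1):
        if s not in ("S", "R"):
            raise SequenceError(f"illegal stereo character {s!r} at position {pos}")
        if c not in ("P", "M"):
            raise SequenceError(f"illegal composition character {c!r} at position {pos}")
        residues.append(MonomerSpec(code=c, stereo=s))
    return residues


# ---------------------------------------------------------------------------
# Topology builders
# ---------------------------------------------------------------------------

# Side-chain placement: the first side-chain carbon is placed at
# dihedral(phi) + offset about the N-Cgamma bond.  With the backbone built
# N -> CG -> CB, an offset of -120 deg puts the substituents in the order
# that makes det[v_N, v_SC, v_CB] negative, i.e. the S convention used here;
# verified by the chirality round-trip tests.
_STEREO_OFFSET = {"S": -120.0, "R": 120.0}


def oligourethane_topology(
    residues: Sequence[MonomerSpec] | str,
    composition: str | None = None,
    name: str | None = None,
) -> Topology:
    """Build the molecular graph + z-matrix of a Boc-capped oligourethane.

    `residues` may be a list of :class:`MonomerSpec` or a stereo string
    (with `composition` as for :func:`parse_sequence`).
    """
    if isinstance(residues, str):
        seq_str = residues
        residues = parse_sequence(residues, composition)
    else:
        seq_str = "".join(r.stereo for r in residues)
    if not residues:
        raise SequenceError("empty residue list")
    n = len(residues)

    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    zm: list[ZEntry] = []
    rot: list[tuple[str, int, tuple[int, int, int, int]]] = []
    fixed: list[tuple[str, int, tuple[int, int, int, int]]] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []

    def add(atom: Atom, bond_to: int | None = None) -> int:
        atoms.append(atom)
        idx = len(atoms) - 1
        if bond_to is not None:
            bonds.append((bond_to, idx))
        return idx

    # --- Boc cap: (CH3)3C-O-C(=O)-  (residue index -1)
    ct = add(Atom("C", "CT", -1, "cap"))
    osb = add(Atom("O", "OS", -1, "cap"), ct)
    cb_ = add(Atom("C", "C", -1, "cap"), osb)
    ob = add(Atom("O", "O", -1, "cap"), cb_)
    zm.append(ZEntry(ob, cb_, osb, ct, _B["C=O"], 123.0, 0.0))
    for mi, dih in zip((1, 2, 3), (60.0, 180.0, -60.0)):
        cm = add(Atom("C", f"CM{mi}", -1, "cap", implicit_h=3), ct)
        zm.append(ZEntry(cm, ct, osb, cb_, _B["C-C"], 109.5, dih))
    acceptors += [osb, ob]

    prev_c = cb_  # carbonyl carbon bonded to the next N
    prev_os = osb  # ester oxygen of the preceding carbamate
    prev_anchor = ct  # atom defining psi of the preceding unit

    for i, res in enumerate(residues):
        terminal = i == n - 1
        ni = add(Atom("N", "N", i, "backbone"), prev_c)
        zm.append(ZEntry(ni, prev_c, prev_os, prev_anchor, _B["C(=O)-N"], 114.0, 180.0))
        fixed.append((f"psi_{i - 1}", i - 1, (prev_anchor, prev_os, prev_c, ni)))
        cg = add(Atom("C", "CG", i, "backbone", implicit_h=1), ni)
        zm.append(ZEntry(cg, ni, prev_c, prev_os, _B["N-C"], 122.0, 180.0))
        fixed.append((f"omega_{i - 1}", i - 1, (prev_os, prev_c, ni, cg)))
        hn = add(Atom("H", "H", i, "backbone"), ni)
        zm.append(ZEntry(hn, ni, prev_c, prev_os, _B["N-H"], 119.0, 0.0))
        donors.append((ni, hn))

        cb = add(Atom("C", "CB", i, "backbone", implicit_h=2), cg)
        zm.append(ZEntry(cb, cg, ni, prev_c, _B["C-C"], 110.0, 0.0, variable=f"phi_{i}"))
        rot.append((f"phi_{i}", i, (prev_c, ni, cg, cb)))

        # side chain, placed with the stereo-dependent offset about N-CG
        off = _STEREO_OFFSET[res.stereo]
        if res.code == "M":
            sc = add(Atom("C", "CM", i, "sidechain", implicit_h=3), cg)
            zm.append(ZEntry(sc, cg, ni, prev_c, _B["C-C"], 110.0, off, variable=f"phi_{i}"))
        else:  # P: benzyl = CD(H2) + phenyl ring
            cd = add(Atom("C", "CD", i, "sidechain", implicit_h=2), cg)
            zm.append(ZEntry(cd, cg, ni, prev_c, _B["C-C"], 110.0, off, variable=f"phi_{i}"))
            c1 = add(Atom("C", "C1", i, "sidechain"), cd)
            zm.append(ZEntry(c1, cd, cg, ni, _B["C-Car"], 113.0, 180.0))
            ring = [c1]
            # planar phenyl: first ring torsion sets the rotamer, the rest are
            # in-plane (anti to the exocyclic atom, then ring torsions 0)
            ring_dihedrals = [90.0, 180.0, 0.0, 0.0, 0.0]
            for ri, dih in zip(range(2, 7), ring_dihedrals):
                cri = add(Atom("C", f"C{ri}", i, "sidechain", implicit_h=1), ring[-1])
                if len(ring) == 1:
                    zm.append(ZEntry(cri, c1, cd, cg, _B["Car-Car"], 120.0, dih))
                elif len(ring) == 2:
                    zm.append(ZEntry(cri, ring[-1], ring[-2], cd, _B["Car-Car"], 120.0, dih))
                else:
                    zm.append(ZEntry(cri, ring[-1], ring[-2], ring[-3], _B["Car-Car"], 120.0, dih))
                ring.append(cri)
            bonds.append((ring[-1], c1))  # ring closure

        if not terminal:
            osi = add(Atom("O", "OS", i, "backbone"), cb)
            zm.append(ZEntry(osi, cb, cg, ni, _B["C-O"], 109.0, 0.0, variable=f"xi_{i}"))
            rot.append((f"xi_{i}", i, (ni, cg, cb, osi)))
            ci = add(Atom("C", "C", i, "backbone"), osi)
            zm.append(ZEntry(ci, osi, cb, cg, _B["C(=O)-O"], 117.0, 0.0, variable=f"chi_{i}"))
            rot.append((f"chi_{i}", i, (cg, cb, osi, ci)))
            oi = add(Atom("O", "O", i, "backbone"), ci)
            zm.append(ZEntry(oi, ci, osi, cb, _B["C=O"], 123.0, 0.0))
            acceptors += [osi, oi]
            prev_c, prev_os, prev_anchor = ci, osi, cb
        else:
            ot = add(Atom("O", "OT", i, "backbone"), cb)
            zm.append(ZEntry(ot, cb, cg, ni, _B["C-O"], 109.0, 0.0, variable=f"xi_{i}"))
            rot.append((f"xi_{i}", i, (ni, cg, cb, ot)))
            ho = add(Atom("H", "HO", i, "backbone"), ot)
            zm.append(ZEntry(ho, ot, cb, cg, _B["O-H"], 108.0, 0.0, variable=f"chi_{i}"))
            rot.append((f"chi_{i}", i, (cg, cb, ot, ho)))
            donors.append((ot, ho))
            acceptors.append(ot)

    topo = Topology(
        name=name or f"OU-{seq_str}",
        atoms=atoms,
        bonds=bonds,
        residues=list(residues),
        zmatrix=zm,
        rotatable_torsions=rot,
        fixed_torsions=[t for t in fixed if t[1] >= 0],
        hb_donors=donors,
        hb_acceptors=acceptors,
        n_cap="Boc",
        c_terminus="OH",
    )
    topo.validate()
    return topo


def bpa_topology() -> Topology:
    """Bisphenol A: two para-phenol rings on a gem-dimethyl quaternary carbon."""
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    zm: list[ZEntry] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []

    def add(atom: Atom, bond_to: int | None = None) -> int:
        atoms.append(atom)
        idx = len(atoms) - 1
        if bond_to is not None:
            bonds.append((bond_to, idx))
        return idx

    # seed chain CM1-CT-CM2 so the generic 3-seed placement applies
    cm1 = add(Atom("C", "CM1", 0, "sidechain", implicit_h=3))
    ct = add(Atom("C", "CT", 0, "backbone"), cm1)
    cm2 = add(Atom("C", "CM2", 0, "sidechain", implicit_h=3), ct)
    for ring, sign in (("A", 1.0), ("B", -1.0)):
        ipso = add(Atom("C", f"C{ring}1", 0, "backbone"), ct)
        zm.append(ZEntry(ipso, ct, cm1, cm2, _B["C-Car"], 109.5, sign * 120.0))
        r2 = add(Atom("C", f"C{ring}2", 0, "backbone", implicit_h=1), ipso)
        zm.append(ZEntry(r2, ipso, ct, cm1, _B["Car-Car"], 120.0, sign * 45.0))
        ringatoms = [ipso, r2]
        for ri, dih in zip(range(3, 7), (180.0, 0.0, 0.0, 0.0)):
            impl = 1 if ri != 4 else 0  # C4 is para, carries the hydroxyl
            cri = add(Atom("C", f"C{ring}{ri}", 0, "backbone", implicit_h=impl), ringatoms[-1])
            if len(ringatoms) == 2:
                zm.append(ZEntry(cri, r2, ipso, ct, _B["Car-Car"], 120.0, dih))
            else:
                zm.append(
                    ZEntry(cri, ringatoms[-1], ringatoms[-2], ringatoms[-3],
                           _B["Car-Car"], 120.0, dih)
                )
            ringatoms.append(cri)
        bonds.append((ringatoms[-1], ipso))
        c4 = ringatoms[3]  # para position
        oh = add(Atom("O", f"O{ring}", 0, "backbone"), c4)
        zm.append(ZEntry(oh, c4, ringatoms[2], ringatoms[1], 1.36, 120.0, 180.0))
        hh = add(Atom("H", f"HO{ring}", 0, "backbone"), oh)
        zm.append(ZEntry(hh, oh, c4, ringatoms[2], _B["O-H"], 109.0, 0.0))
        donors.append((oh, hh))
        acceptors.append(oh)

    topo = Topology(
        name="BPA",
        atoms=atoms,
        bonds=bonds,
        zmatrix=zm,
        hb_donors=donors,
        hb_acceptors=acceptors,
    )
    topo.validate()
    return topo


def merge_topologies(host: Topology, ligand: Topology, name: str | None = None) -> Topology:
    """Concatenate two molecules into a complex topology (host mol=0, ligand mol=1).

    Rotatable torsions are carried over from the host only; complex
    coordinates are assembled from per-component conformations.
    """
    off = host.n_atoms
    atoms = [Atom(a.element, a.name, a.residue, a.role, a.implicit_h, 0) for a in host.atoms]
    atoms += [Atom(a.element, a.name, a.residue + 1000, a.role, a.implicit_h, 1) for a in ligand.atoms]
    bonds = list(host.bonds) + [(a + off, b + off) for a, b in ligand.bonds]
    topo = Topology(
        name=name or f"{host.name}:{ligand.name}",
        atoms=atoms,
        bonds=bonds,
        residues=list(host.residues),
        rotatable_torsions=list(host.rotatable_torsions),
        fixed_torsions=list(host.fixed_torsions),
        hb_donors=list(host.hb_donors) + [(d + off, h + off) for d, h in ligand.hb_donors],
        hb_acceptors=list(host.hb_acceptors) + [a + off for a in ligand.hb_acceptors],
        n_cap=host.n_cap,
        c_terminus=host.c_terminus,
        components=[host, ligand],
        component_slices=[slice(0, off), slice(off, off + ligand.n_atoms)],
    )
    return topo


# ---------------------------------------------------------------------------
# Formula / mass arithmetic
# ---------------------------------------------------------------------------

def molecular_formula(topology: Topology) -> ElementCounts:
    """Element counts including implicit hydrogens."""
    if topology.n_atoms == 0:
        raise ValueError("empty topology")
    counts = ElementCounts()
    for a in topology.atoms:
        counts.add(a.element)
        if a.implicit_h:
            counts.add("H", a.implicit_h)
    return counts


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Sum of count x monoisotopic atomic mass, in Da."""
    if not formula:
        raise ValueError("empty formula")
    total = 0.0
    for el, count in formula.items():
        if el not in MONOISOTOPIC_MASS:
            raise KeyError(f"no monoisotopic mass for element {el!r}")
        total += count * MONOISOTOPIC_MASS[el]
    return total


_BOC_LOSS = ElementCounts({"C": 5, "H": 8, "O": 2})  # C4H8 + CO2


def adduct_mz(
    formula: Mapping[str, int], adduct: str, has_boc: bool = True, rounded: bool = True
) -> float:
    """Singly-charged monoisotopic m/z for the supported LC-MS adducts.

    Supported adducts: ``[M+H]+``, ``[M+Na]+`` and the in-source Boc-loss
    fragment ``[M-Boc+H]+`` (loss of isobutylene + CO2).  By default values
    are rounded half-even to 2 decimals, the precision of routine LC-MS
    readout; pass ``rounded=False`` for the full-precision value.
    """
    m = monoisotopic_mass(formula)
    if adduct == "[M+H]+":
        mz = m + PROTON_MASS
    elif adduct == "[M+Na]+":
        mz = m + MONOISOTOPIC_MASS["Na"] - MONOISOTOPIC_MASS["H"] + PROTON_MASS
    elif adduct == "[M-Boc+H]+":
        if not has_boc:
            raise ValueError("Boc-loss adduct requires a Boc-capped topology")
        mz = m - monoisotopic_mass(_BOC_LOSS) + PROTON_MASS
    else:
        raise ValueError(f"unsupported adduct {adduct!r}")
    return float(np.round(mz, 2)) if rounded else float(mz)


# ---------------------------------------------------------------------------
# 3D construction
# ---------------------------------------------------------------------------

def _build_from_zmatrix(topology: Topology, variables: Mapping[str, float]) -> np.ndarray:
    zm = topology.zmatrix
    n = topology.n_atoms
    coords = np.zeros((n, 3))
    placed = {e.l for e in zm}
    seeds = [i for i in range(n) if i not in placed]
    # Seed atoms: the first three non-zmatrix atoms define the frame.
    if len(seeds) < 3:
        raise ValueError("z-matrix must leave at least 3 seed atoms")
    s0, s1, s2 = seeds[:3]
    # seed geometry: s0 at origin, s1 on x, s2 in the xy-plane
    coords[s0] = [0.0, 0.0, 0.0]
    coords[s1] = [_seed_bond(topology, s0, s1), 0.0, 0.0]
    r12 = _seed_bond(topology, s1, s2)
    ang = np.radians(_seed_angle(topology, s0, s1, s2))
    coords[s2] = coords[s1] + [-r12 * np.cos(ang), r12 * np.sin(ang), 0.0]
    for e in zm:
        dih = e.dihedral
        if e.variable is not None:
            dih = variables[e.variable] + e.dihedral
        coords[e.l] = place_atom(coords[e.i], coords[e.j], coords[e.k], e.bond, e.angle, dih)
    return coords


def _seed_bond(topology: Topology, a: int, b: int) -> float:
    ea, eb = topology.atoms[a].element, topology.atoms[b].element
    pair = frozenset((ea, eb))
    if pair == frozenset(("C", "O")):
        return _B["C-O"]
    if pair == frozenset(("C",)):
        return _B["C-C"]
    return 1.45


def _seed_angle(topology: Topology, a: int, b: int, c: int) -> float:
    if topology.atoms[b].element == "O":
        return 117.0
    return 111.0


def build_structure(
    topology: Topology,
    torsions: np.ndarray | Mapping[str, float],
    provenance: dict | None = None,
) -> Conformation:
    """Construct Cartesian coordinates from per-residue (phi, xi, chi) torsions.

    `torsions` is an (n_residues, 3) array in degrees on (-180, 180], or a
    mapping from torsion names (``phi_i``/``xi_i``/``chi_i``) to angles.
    Bond lengths/angles are idealized; urethane psi and omega are exactly 180.
    """
    if isinstance(torsions, Mapping):
        variables = dict(torsions)
    else:
        arr = np.asarray(torsions, dtype=float)
        nres = len(topology.residues)
        if arr.shape != (nres, 3):
            raise ValueError(f"expected torsion array of shape ({nres}, 3), got {arr.shape}")
        variables = {}
        for i in range(nres):
            variables[f"phi_{i}"] = arr[i, 0]
            variables[f"xi_{i}"] = arr[i, 1]
            variables[f"chi_{i}"] = arr[i, 2]
    for k, v in variables.items():
        if not -180.0 < v <= 180.0:
            raise ValueError(f"torsion {k} = {v} outside (-180, 180]")
    missing = {e.variable for e in topology.zmatrix if e.variable} - set(variables)
    if missing:
        raise ValueError(f"missing torsion values: {sorted(missing)}")
    coords = _build_from_zmatrix(topology, variables)
    return Conformation(topology, coords, provenance or {})


def bpa_structure() -> Conformation:
    """Fixed 3D model of BPA (rings in a ~45 deg propeller)."""
    topo = bpa_topology()
    coords = _build_from_zmatrix(topo, {})
    return Conformation(topo, coords, {"molecule": "BPA"})


# ---------------------------------------------------------------------------
# Chirality
# ---------------------------------------------------------------------------

def signed_volume(conf: Conformation, residue: int) -> float:
    """Signed volume det[v_N, v_SC, v_CB] of the substituent vectors about
    Cgamma.  Negative corresponds to the S flag under this package's
    convention."""
    topo = conf.topology
    cg = conf.coords[topo.atom_index(residue, "CG")]
    vn = conf.coords[topo.atom_index(residue, "N")] - cg
    sc_name = "CM" if topo.residues[residue].code == "M" else "CD"
    vsc = conf.coords[topo.atom_index(residue, sc_name)] - cg
    vcb = conf.coords[topo.atom_index(residue, "CB")] - cg
    return float(np.linalg.det(np.stack([vn, vsc, vcb])))


def assign_stereo(conf: Conformation) -> list[str]:
    """Apparent configuration of every residue from the signed-volume rule."""
    return [
        "S" if signed_volume(conf, i) < 0 else "R"
        for i in range(len(conf.topology.residues))
    ]
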