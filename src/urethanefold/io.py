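"""Reading and writing conformer ensembles (multi-model PDB via biotite, XYZ)."""

from __future__ import annotations

from pathlib import Path

import biotite.structure as struc
import numpy as np
from biotite.structure.io.pdb import PDBFile

from .molecules import Conformation, Topology

__all__ = ["write_pdb", "read_pdb_coords", "write_xyz", "read_xyz"]


def _atom_array(topology: Topology) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    res_names = []
    res_ids = []
    chains = []
    for a in topology.atoms:
        if a.mol == 1:
            res_names.append("BPA")
            res_ids.append(1)
            chains.append("B")
        elif a.residue < 0:
            res_names.append("BOC")
            res_ids.append(1)
            chains.append("A")
        else:
            res = topology.residues[a.residue]
            res_names.append(f"{res.code}{res.stereo}")
            res_ids.append(a.residue + 2)
            chains.append("A")
    arr.atom_name = np.array([a.name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.res_name = np.array(res_names)
    arr.res_id = np.array(res_ids)
    arr.chain_id = np.array(chains)
    arr.hetero = np.full(n, True)
    return arr


def write_pdb(frames: Conformation | list[Conformation], path: str | Path) -> None:
    """Write one conformation (single MODEL) or an ensemble (multi-model)."""
    if isinstance(frames, Conformation):
        frames = [frames]
    if not frames:
        raise ValueError("no frames to write")
    template = _atom_array(frames[0].topology)
    arrays = []
    for conf in frames:
        arr = template.copy()
        arr.coord = np.asarray(conf.coords, dtype=np.float32)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb_coords(path: str | Path, topology: Topology) -> list[Conformation]:
    """Read a (multi-model) PDB written by this package back into
    conformations over a known topology."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if stack.array_length() != topology.n_atoms:
        raise ValueError(
            f"PDB atom count {stack.array_length()} != topology {topology.n_atoms}"
        )
    return [
        Conformation(topology, np.asarray(stack.coord[m], dtype=float), {"source": str(path)})
        for m in range(stack.stack_depth())
    ]


def write_xyz(frames: Conformation | list[Conformation], path: str | Path) -> None:
    """Concatenated-frame XYZ (element x y z; one block per frame)."""
    if isinstance(frames, Conformation):
        frames = [frames]
    if not frames:
        raise ValueError("no frames to write")
    with open(path, "w") as fh:
        for k, conf in enumerate(frames):
            fh.write(f"{conf.topology.n_atoms}\n")
            fh.write(f"{conf.topology.name} frame {k}\n")
            for a, xyz in zip(conf.topology.atoms, conf.coords):
                fh.write(f"{a.element:2s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}\n")


def read_xyz(path: str | Path, topology: Topology | None = None):
    """Read concatenated XYZ; with a topology, return Conformations
    (elements are checked), otherwise (elements, coords) tuples."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        elements = []
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            elements.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        if topology is not None:
            expect = [a.element for a in topology.atoms]
            if elements != expect:
                raise ValueError("XYZ elements do not match topology")
            frames.append(Conformation(topology, coords, {"source": str(path)}))
        else:
            frames.append((elements, coords))
        i += 2 + n
    return frames
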