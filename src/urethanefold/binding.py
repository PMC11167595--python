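"""MM-GBSA-style binding free-energy decomposition for oligomer-BPA complexes.

Single-trajectory approximation: the oligomer and the ligand are evaluated
at their in-complex geometries, so all internal (torsional) terms cancel
exactly in the difference and the decomposition reduces to

    dG_bind = dE_vdW + dE_el + dG_solv_polar + dG_solv_nonpolar

with each delta = component(complex) - component(oligomer) - component(BPA).
No entropy estimate is included.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conformers import ClusterAssignment
from .forcefield import ForceFieldParams, total_potential
from .molecules import Conformation

__all__ = [
    "BindingDecomposition",
    "single_point_decomposition",
    "ensemble_binding",
    "rank_oligomers",
]


@dataclass(frozen=True)
class BindingDecomposition:
    """Binding energy components, kcal/mol."""

    dE_vdW: float
    dE_el: float
    dG_solv_polar: float
    dG_solv_nonpolar: float

    @property
    def dG_solv(self) -> float:
        return self.dG_solv_polar + self.dG_solv_nonpolar

    @property
    def dG_bind(self) -> float:
        return self.dE_vdW + self.dE_el + self.dG_solv_polar + self.dG_solv_nonpolar

    def as_dict(self) -> dict[str, float]:
        return {
            "dE_vdW": self.dE_vdW,
            "dE_el": self.dE_el,
            "dG_solv_polar": self.dG_solv_polar,
            "dG_solv_nonpolar": self.dG_solv_nonpolar,
            "dG_solv": self.dG_solv,
            "dG_bind": self.dG_bind,
        }


def single_point_decomposition(
    conf: Conformation, params: ForceFieldParams
) -> BindingDecomposition:
    """Decompose one complex frame into binding energy components."""
    topo = conf.topology
    if topo.components is None or len(topo.components) != 2:
        raise ValueError("conformation must belong to a two-molecule complex topology")
    complex_e = total_potential(conf, params, solvation=True)
    parts = []
    for comp_topo, sl in zip(topo.components, topo.component_slices):
        parts.append(
            total_potential(Conformation(comp_topo, conf.coords[sl]), params, solvation=True)
        )
    delta = complex_e - parts[0] - parts[1]
    if abs(delta.E_torsion) > 1e-9:
        raise AssertionError("torsional term failed to cancel in single-trajectory delta")
    return BindingDecomposition(
        dE_vdW=delta.E_vdW,
        dE_el=delta.E_el,
        dG_solv_polar=delta.G_solv_polar,
        dG_solv_nonpolar=delta.G_solv_nonpolar,
    )


_COMPONENT_COLS = ["dE_vdW", "dE_el", "dG_solv_polar", "dG_solv_nonpolar", "dG_solv", "dG_bind"]


def ensemble_binding(
    frames: list[Conformation],
    params: ForceFieldParams,
    assignment: ClusterAssignment | None = None,
) -> dict:
    """Per-frame decompositions plus cluster and ensemble statistics.

    Returns a dict with the per-frame DataFrame, ensemble means/SD and
    5-95 percentile bars per component, and per-cluster means when an
    assignment is given.  The ensemble mean equals the population-weighted
    cluster means by the law of total expectation."""
    if not frames:
        raise ValueError("empty ensemble")
    rows = [single_point_decomposition(f, params).as_dict() for f in frames]
    df = pd.DataFrame(rows, columns=_COMPONENT_COLS)
    summary = {
        "per_frame": df,
        "mean": df.mean().to_dict(),
        "sd": df.std(ddof=0).to_dict(),
        "p5": df.quantile(0.05).to_dict(),
        "p95": df.quantile(0.95).to_dict(),
        "n_frames": len(frames),
    }
    if assignment is not None:
        if len(assignment.labels) != len(frames):
            raise ValueError("assignment does not match frame count")
        summary["cluster_mean"] = {
            c: df[assignment.labels == c].mean().to_dict()
            for c in range(assignment.n_clusters)
        }
    return summary


def rank_oligomers(mean_dg_bind: dict[str, float]) -> list[str]:
    """Sequences ordered from strongest (most negative mean dG_bind) to
    weakest binder; exact ties break lexicographically."""
    if len(mean_dg_bind) < 2:
        raise ValueError("need at least 2 sequences to rank")
    return sorted(mean_dg_bind, key=lambda s: (mean_dg_bind[s], s))
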