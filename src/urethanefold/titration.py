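"""Stern-Volmer analysis of fluorescence quenching titrations.

The linear Stern-Volmer model F0/F = 1 + Q/Kd relates the quenching ratio
to the quencher (BPA) concentration; the slope of (F0/F - 1) against Q,
fitted through the origin, is the Stern-Volmer constant K_SV = 1/Kd, and
the association constant is Ka = 1/Kd.  Trend concordance between computed
binding energies and measured Ka is a Kendall-type pairwise statistic:
a sequence pair is concordant when the more negative dG_bind goes with the
larger Ka.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TitrationCurve",
    "SternVolmerFit",
    "QuenchingError",
    "stern_volmer_fit",
    "trend_concordance",
    "library_report",
    "read_titration_csv",
    "write_titration_csv",
]


class QuenchingError(ValueError):
    """No detectable quenching (non-positive fitted slope)."""


@dataclass
class TitrationCurve:
    """(Q, F) fluorescence titration points with the unquenched intensity F0."""

    Q: np.ndarray  # quencher concentration, molar, increasing
    F: np.ndarray  # fluorescence intensity, arbitrary units
    F0: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.Q.shape != self.F.shape:
            raise ValueError("Q and F must have equal length")
        if np.any(self.Q < 0):
            raise ValueError("negative quencher concentration")
        if np.any(np.diff(self.Q) <= 0):
            raise ValueError("Q must be strictly increasing")
        if np.any(self.F <= 0) or self.F0 <= 0:
            raise ValueError("fluorescence intensities must be positive")


@dataclass
class SternVolmerFit:
    Kd: float  # molar
    Ka: float  # 1/molar, == 1/Kd
    slope_se: float
    r_squared: float
    residuals: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        if self.Kd <= 0:
            raise ValueError("Kd must be positive")
        if abs(self.Ka * self.Kd - 1.0) > 1e-12:
            raise ValueError("Ka must equal 1/Kd")


def stern_volmer_fit(curve: TitrationCurve) -> SternVolmerFit:
    """Ordinary least squares of (F0/F - 1) on Q through the origin.

    The slope is K_SV = 1/Kd = Ka.  Requires at least 3 points with Q > 0;
    a non-positive slope raises :class:`QuenchingError`."""
    mask = curve.Q > 0
    q = curve.Q[mask]
    y = curve.F0 / curve.F[mask] - 1.0
    if len(q) < 3:
        raise ValueError("need at least 3 titration points with Q > 0")
    sqq = float(np.dot(q, q))
    slope = float(np.dot(q, y)) / sqq
    if slope <= 0:
        raise QuenchingError("fitted Stern-Volmer slope is not positive")
    residuals = y - slope * q
    dof = max(len(q) - 1, 1)
    slope_se = float(np.sqrt((residuals**2).sum() / dof / sqq))
    ss_tot = float((y**2).sum())  # through-origin total sum of squares
    r2 = 1.0 - float((residuals**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    kd = 1.0 / slope
    return SternVolmerFit(
        Kd=kd,
        Ka=slope,
        slope_se=slope_se,
        r_squared=r2,
        residuals=residuals,
        n_points=int(len(q)),
    )


def trend_concordance(dg_bind: dict[str, float], ka: dict[str, float]) -> float:
    """Fraction of sequence pairs ordered consistently by theory and
    experiment: more negative dG_bind should pair with larger Ka.  Exact
    ties in either quantity count one half."""
    if set(dg_bind) != set(ka):
        raise ValueError("sequence sets differ between dG_bind and Ka inputs")
    seqs = sorted(dg_bind)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    score = 0.0
    n_pairs = 0
    for a_i in range(len(seqs)):
        for b_i in range(a_i + 1, len(seqs)):
            a, b = seqs[a_i], seqs[b_i]
            sg = np.sign(dg_bind[a] - dg_bind[b])
            sk = np.sign(ka[a] - ka[b])
            n_pairs += 1
            if sg == 0 or sk == 0:
                score += 0.5
            elif sg == -sk:
                score += 1.0
    return score / n_pairs


def library_report(
    fits: dict[str, SternVolmerFit | None],
    binding_summaries: dict[str, dict],
) -> tuple[pd.DataFrame, dict]:
    """Combined per-sequence table of computed binding energies and fitted
    experimental constants.  Sequences without experimental data are kept in
    the table (marked) but excluded from the concordance statistic."""
    if not binding_summaries:
        raise ValueError("empty input")
    rows = []
    for seq in sorted(binding_summaries):
        b = binding_summaries[seq]
        fit = fits.get(seq)
        rows.append(
            {
                "sequence": seq,
                "dG_bind_mean": b["mean"]["dG_bind"],
                "dG_bind_sd": b["sd"]["dG_bind"],
                "dG_bind_p5": b["p5"]["dG_bind"],
                "dG_bind_p95": b["p95"]["dG_bind"],
                "Kd_molar": fit.Kd if fit else np.nan,
                "Ka_per_molar": fit.Ka if fit else np.nan,
                "has_experiment": fit is not None,
            }
        )
    table = pd.DataFrame(rows)
    with_exp = table[table.has_experiment]
    summary: dict = {"n_sequences": len(table), "n_with_experiment": int(with_exp.shape[0])}
    if with_exp.shape[0] >= 2:
        dg = dict(zip(with_exp.sequence, with_exp.dG_bind_mean))
        ka = dict(zip(with_exp.sequence, with_exp.Ka_per_molar))
        summary["concordance"] = trend_concordance(dg, ka)
    ranked = table.sort_values(["dG_bind_mean", "sequence"]).sequence.tolist()
    summary["ranking"] = ranked
    return table, summary


def read_titration_csv(path: str | Path) -> dict[str, TitrationCurve]:
    """Read titration curves from a CSV with columns
    sequence_id, Q_molar, F.  The F at the Q = 0 row defines F0."""
    df = pd.read_csv(path, comment="#")
    required = {"sequence_id", "Q_molar", "F"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration CSV must have columns {sorted(required)}")
    curves = {}
    for seq, grp in df.groupby("sequence_id"):
        grp = grp.sort_values("Q_molar")
        zero = grp[grp.Q_molar == 0]
        if zero.empty:
            raise ValueError(f"sequence {seq}: missing required Q = 0 row")
        f0 = float(zero.F.iloc[0])
        curves[str(seq)] = TitrationCurve(
            Q=grp.Q_molar.to_numpy(),
            F=grp.F.to_numpy(),
            F0=f0,
            metadata={"sequence_id": str(seq)},
        )
    return curves


def write_titration_csv(curves: dict[str, TitrationCurve], path: str | Path) -> None:
    rows = []
    for seq, c in sorted(curves.items()):
        for q, f in zip(c.Q, c.F):
            rows.append({"sequence_id": seq, "Q_molar": q, "F": f})
    pd.DataFrame(rows).to_csv(path, index=False)
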