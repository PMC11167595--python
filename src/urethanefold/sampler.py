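"""Torsional-space Monte Carlo sampling of oligourethane-BPA complexes.

Desk-scale analog of a multiple-simulated-annealing protocol: each repeat
starts from random torsions and a random ligand pose, is annealed
(heat 298 -> 500 K, equilibrate, cool to 0 K) to a local minimum, and then
seeds a constant-temperature Metropolis production run at 298 K.  Repeats
use independent, reproducible streams derived from one master seed.

The sampler operates on any object implementing the small ``System``
protocol (``energy``, ``propose``, ``initial_state``), which keeps the
Metropolis machinery testable on analytic toy systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

from .forcefield import ClashError, ForceFieldParams, total_potential
from .geometry import random_rotation_matrix, rotation_about_axis, wrap_angle
from .molecules import Conformation, Topology, build_structure

__all__ = [
    "BOLTZMANN_KCAL",
    "AnnealingSchedule",
    "Trajectory",
    "Ensemble",
    "ComplexSystem",
    "metropolis_step",
    "simulated_anneal",
    "production_sample",
    "msa_ensemble",
    "repeat_rng",
]

BOLTZMANN_KCAL = 0.0019872041  # kcal/(mol*K)


@dataclass
class AnnealingSchedule:
    """Heat / equilibrate / cool temperature program, linear in T."""

    T_start: float = 298.0
    T_peak: float = 500.0
    T_end: float = 0.0
    sweeps_heat: int = 150
    sweeps_equil: int = 100
    sweeps_cool: int = 250

    def __post_init__(self) -> None:
        if not (self.T_peak >= self.T_start >= self.T_end >= 0.0):
            raise ValueError("require T_peak >= T_start >= T_end >= 0")
        if min(self.sweeps_heat, self.sweeps_equil, self.sweeps_cool) < 1:
            raise ValueError("sweep counts must be >= 1")

    @property
    def total_sweeps(self) -> int:
        return self.sweeps_heat + self.sweeps_equil + self.sweeps_cool

    def temperatures(self) -> Iterator[tuple[str, float]]:
        for k in range(self.sweeps_heat):
            f = k / max(self.sweeps_heat - 1, 1)
            yield "heat", self.T_start + f * (self.T_peak - self.T_start)
        for _ in range(self.sweeps_equil):
            yield "equil", self.T_peak
        for k in range(self.sweeps_cool):
            f = (k + 1) / self.sweeps_cool
            yield "cool", self.T_peak + f * (self.T_end - self.T_peak)


@dataclass
class Trajectory:
    """Frames recorded every `stride` sweeps of a fixed-temperature run."""

    frames: list[Any]
    energies: np.ndarray
    temperature: float
    stride: int
    seed: Any
    repeat_id: int = 0
    acceptance_rate: float = float("nan")

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.frames) != len(self.energies):
            raise ValueError("frame/energy length mismatch")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite frame energy")


@dataclass
class Ensemble:
    """Pooled production trajectories over one topology."""

    trajectories: list[Trajectory]
    topology: Topology | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.repeat_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("repeat ids must be unique")

    def frames(self, skip_fraction: float = 0.1) -> list[Any]:
        """All production frames, excluding the first `skip_fraction` of each
        trajectory as equilibration."""
        out = []
        for t in self.trajectories:
            start = int(np.floor(skip_fraction * len(t.frames)))
            out.extend(t.frames[start:])
        return out

    def frame_repeats(self, skip_fraction: float = 0.1) -> np.ndarray:
        out = []
        for t in self.trajectories:
            start = int(np.floor(skip_fraction * len(t.frames)))
            out.extend([t.repeat_id] * (len(t.frames) - start))
        return np.array(out, dtype=int)


def metropolis_step(
    system: Any,
    state: Any,
    energy: float,
    T: float,
    rng: np.random.Generator,
) -> tuple[Any, float, bool]:
    """One Metropolis trial: accept with min(1, exp(-dE/kBT)); at T = 0 only
    downhill (dE <= 0) moves are accepted."""
    if T < 0:
        raise ValueError("negative temperature")
    new_state = system.propose(state, rng)
    new_energy = system.energy(new_state)
    d_e = new_energy - energy
    if d_e <= 0:
        return new_state, new_energy, True
    if T == 0.0 or not np.isfinite(new_energy):
        return state, energy, False
    if rng.random() < np.exp(-d_e / (BOLTZMANN_KCAL * T)):
        return new_state, new_energy, True
    return state, energy, False


def _sweep(system, state, energy, T, rng) -> tuple[Any, float, int]:
    n_moves = getattr(system, "moves_per_sweep", 1)
    accepted = 0
    for _ in range(n_moves):
        state, energy, acc = metropolis_step(system, state, energy, T, rng)
        accepted += acc
    return state, energy, accepted


def simulated_anneal(
    system: Any,
    schedule: AnnealingSchedule,
    rng: np.random.Generator | int,
    state: Any | None = None,
) -> tuple[Any, float]:
    """Run one heat/equilibrate/cool cycle; returns the final (state, energy)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if state is None:
        state = system.initial_state(rng)
    if hasattr(system, "set_stage"):
        system.set_stage("anneal")
    energy = system.energy(state)
    if not np.isfinite(energy):
        raise ValueError("non-finite energy at annealing start")
    for _stage, T in schedule.temperatures():
        state, energy, _ = _sweep(system, state, energy, T, rng)
    return state, energy


def production_sample(
    system: Any,
    state: Any,
    T: float = 298.0,
    sweeps: int = 2000,
    stride: int = 10,
    rng: np.random.Generator | int = 0,
    repeat_id: int = 0,
) -> Trajectory:
    """Fixed-temperature Metropolis chain; a frame is recorded every `stride`
    sweeps, giving floor(sweeps/stride) frames."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if hasattr(system, "set_stage"):
        system.set_stage("production")
    energy = system.energy(state)
    frames: list[Any] = []
    energies: list[float] = []
    accepted = 0
    n_moves = getattr(system, "moves_per_sweep", 1)
    for sweep in range(1, sweeps + 1):
        state, energy, acc = _sweep(system, state, energy, T, rng)
        accepted += acc
        if sweep % stride == 0:
            frames.append(system.snapshot(state) if hasattr(system, "snapshot") else state)
            energies.append(energy)
    return Trajectory(
        frames=frames,
        energies=np.array(energies),
        temperature=T,
        stride=stride,
        seed=None,
        repeat_id=repeat_id,
        acceptance_rate=accepted / max(sweeps * n_moves, 1),
    )


def repeat_rng(master_seed: int, repeat: int) -> np.random.Generator:
    """Per-repeat generator from a documented counter-based rule: the stream
    is seeded with the entropy pair (master_seed, repeat)."""
    return np.random.default_rng([int(master_seed), int(repeat)])


def msa_ensemble(
    system: Any,
    n_repeats: int,
    schedule: AnnealingSchedule | None = None,
    production_sweeps: int = 2000,
    production_T: float = 298.0,
    stride: int = 10,
    master_seed: int = 0,
) -> Ensemble:
    """Repeat (random init -> anneal -> production) `n_repeats` times and pool
    the production trajectories."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    schedule = schedule or AnnealingSchedule()
    trajectories = []
    for rep in range(n_repeats):
        rng = repeat_rng(master_seed, rep)
        try:
            state, _ = simulated_anneal(system, schedule, rng)
            traj = production_sample(
                system,
                state,
                T=production_T,
                sweeps=production_sweeps,
                stride=stride,
                rng=rng,
                repeat_id=rep,
            )
        except Exception as exc:  # noqa: BLE001 - annotate with repeat id
            raise RuntimeError(f"sampling repeat {rep} failed: {exc}") from exc
        traj.seed = (master_seed, rep)
        trajectories.append(traj)
    topo = getattr(system, "topology", None)
    return Ensemble(
        trajectories=trajectories,
        topology=topo,
        metadata={
            "master_seed": master_seed,
            "n_repeats": n_repeats,
            "schedule": vars(schedule),
            "production_sweeps": production_sweeps,
            "production_T": production_T,
            "stride": stride,
        },
    )


@dataclass
class TorsionPoseState:
    """Sampler state: oligomer torsions + rigid-body ligand pose."""

    torsions: np.ndarray  # (n_res, 3) degrees
    lig_translation: np.ndarray | None = None  # (3,)
    lig_rotation: np.ndarray | None = None  # (3, 3)

    def copy(self) -> "TorsionPoseState":
        return TorsionPoseState(
            self.torsions.copy(),
            None if self.lig_translation is None else self.lig_translation.copy(),
            None if self.lig_rotation is None else self.lig_rotation.copy(),
        )


class ComplexSystem:
    """Oligomer(-BPA) system sampled in torsion/pose space.

    Energies use the fast screened potential by default (LJ + Coulomb at the
    solvent dielectric + torsion terms); GB/SASA rescoring happens at
    analysis time.  Steric clashes return +inf, so such moves are rejected.
    """

    def __init__(
        self,
        topology: Topology,
        params: ForceFieldParams,
        ligand_template: np.ndarray | None = None,
        solvation: bool = False,
        delta_torsion_anneal: float = 30.0,
        delta_torsion_production: float = 10.0,
        delta_translation: float = 0.5,
        delta_rotation: float = 10.0,
        init_separation: tuple[float, float] = (4.0, 8.0),
    ):
        self.topology = topology
        self.params = params
        self.host = topology.components[0] if topology.components else topology
        self.ligand_template = None
        if ligand_template is not None:
            self.ligand_template = ligand_template - ligand_template.mean(axis=0)
        self.solvation = solvation
        self.delta_torsion_anneal = delta_torsion_anneal
        self.delta_torsion_production = delta_torsion_production
        self.delta_translation = delta_translation
        self.delta_rotation = delta_rotation
        self.init_separation = init_separation
        self._delta_torsion = delta_torsion_anneal
        self.n_res = len(self.host.residues)
        self.n_torsions = 3 * self.n_res

    @property
    def moves_per_sweep(self) -> int:
        return self.n_torsions + (2 if self.ligand_template is not None else 0)

    def set_stage(self, stage: str) -> None:
        self._delta_torsion = (
            self.delta_torsion_anneal if stage == "anneal" else self.delta_torsion_production
        )

    def build(self, state: TorsionPoseState) -> Conformation:
        host_conf = build_structure(self.host, state.torsions)
        if self.ligand_template is None:
            if self.topology is self.host:
                return host_conf
            return Conformation(self.topology, host_conf.coords)
        lig = self.ligand_template @ state.lig_rotation.T + state.lig_translation
        return Conformation(self.topology, np.vstack([host_conf.coords, lig]))

    def snapshot(self, state: TorsionPoseState) -> Conformation:
        conf = self.build(state)
        conf.provenance["torsions"] = state.torsions.copy()
        return conf

    def energy(self, state: TorsionPoseState) -> float:
        try:
            return total_potential(self.build(state), self.params, solvation=self.solvation).E_total
        except ClashError:
            return float("inf")

    def propose(self, state: TorsionPoseState, rng: np.random.Generator) -> TorsionPoseState:
        new = state.copy()
        n_kinds = self.moves_per_sweep
        pick = int(rng.integers(n_kinds))
        if pick < self.n_torsions:
            i, j = divmod(pick, 3)
            new.torsions[i, j] = wrap_angle(
                new.torsions[i, j] + rng.normal(0.0, self._delta_torsion)
            )
        elif pick == self.n_torsions:
            new.lig_translation = new.lig_translation + rng.normal(
                0.0, self.delta_translation, size=3
            )
        else:
            axis = rng.normal(size=3)
            angle = rng.normal(0.0, self.delta_rotation)
            new.lig_rotation = rotation_about_axis(axis, angle) @ new.lig_rotation
        return new

    def initial_state(self, rng: np.random.Generator) -> TorsionPoseState:
        for _attempt in range(200):
            torsions = wrap_angle(rng.uniform(-180.0, 180.0, size=(self.n_res, 3)))
            torsions = np.where(torsions == -180.0, 180.0, torsions)
            if self.ligand_template is None:
                state = TorsionPoseState(torsions)
            else:
                host_conf = build_structure(self.host, torsions)
                center = host_conf.coords.mean(axis=0)
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                dist = rng.uniform(*self.init_separation)
                state = TorsionPoseState(
                    torsions,
                    lig_translation=center + dist * direction,
                    lig_rotation=random_rotation_matrix(rng),
                )
            if np.isfinite(self.energy(state)):
                return state
        raise RuntimeError("could not generate a clash-free initial state")
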