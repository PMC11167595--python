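"""Metropolis machinery: acceptance law, Boltzmann sampling, annealing."""

import numpy as np
import pytest

from urethanefold import molecules as mol
from urethanefold import sampler as smp
from urethanefold.geometry import wrap_angle

KT298 = smp.BOLTZMANN_KCAL * 298.0


class ConstantStepSystem:
    """Every proposal raises the energy by a fixed amount."""

    def __init__(self, step):
        self.step = step

    def energy(self, state):
        return state

    def propose(self, state, rng):
        return state + self.step


class TorsionToy:
    """1-D system on the torsion circle with an arbitrary energy function."""

    moves_per_sweep = 1

    def __init__(self, energy_fn, width=60.0):
        self.energy_fn = energy_fn
        self.width = width

    def energy(self, state):
        return self.energy_fn(state)

    def propose(self, state, rng):
        return wrap_angle(state + rng.normal(0.0, self.width))

    def initial_state(self, rng):
        return wrap_angle(rng.uniform(-180.0, 180.0))


class ThreeStateSystem:
    """Enumerable 3-state chain with symmetric uniform proposals."""

    moves_per_sweep = 1

    def __init__(self, energies):
        self.energies = list(energies)

    def energy(self, state):
        return self.energies[state]

    def propose(self, state, rng):
        return int((state + rng.integers(1, 3)) % 3)

    def initial_state(self, rng):
        return int(rng.integers(3))


def block_se(x, n_blocks=20):
    """Standard error of a correlated series by block averaging."""
    x = np.asarray(x, dtype=float)
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return means.std(ddof=1) / np.sqrt(n_blocks)


class TestMetropolisStep:
    def test_downhill_always_accepted(self):
        system = ConstantStepSystem(-1.0)
        rng = np.random.default_rng(0)
        for T in (0.0, 100.0, 500.0):
            _s, _e, acc = smp.metropolis_step(system, 0.0, 0.0, T, rng)
            assert acc

    def test_uphill_rejected_at_zero_temperature(self):
        system = ConstantStepSystem(0.1)
        rng = np.random.default_rng(0)
        state, energy, acc = smp.metropolis_step(system, 0.0, 0.0, 0.0, rng)
        assert not acc and state == 0.0 and energy == 0.0

    def test_acceptance_probability_at_kt_ln2(self):
        """dE = kBT ln 2 must be accepted with probability one half."""
        system = ConstantStepSystem(KT298 * np.log(2.0))
        rng = np.random.default_rng(1234)
        n = 10_000
        accepted = sum(
            smp.metropolis_step(system, 0.0, 0.0, 298.0, rng)[2] for _ in range(n)
        )
        assert accepted / n == pytest.approx(0.5, abs=0.02)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            smp.metropolis_step(ConstantStepSystem(0.0), 0.0, 0.0, -1.0, np.random.default_rng(0))


class TestAnnealing:
    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            smp.AnnealingSchedule(T_start=100.0, T_peak=50.0)
        with pytest.raises(ValueError):
            smp.AnnealingSchedule(sweeps_heat=0)

    def test_schedule_covers_all_phases(self):
        sched = smp.AnnealingSchedule(sweeps_heat=3, sweeps_equil=2, sweeps_cool=4)
        temps = list(sched.temperatures())
        assert len(temps) == sched.total_sweeps
        assert temps[0] == ("heat", 298.0)
        assert temps[2] == ("heat", 500.0)
        assert temps[3] == ("equil", 500.0)
        assert temps[-1] == ("cool", 0.0)

    def test_single_basin_toy_finds_the_minimum(self):
        """A slow anneal on a quadratic-like 1-torsion well lands within 5 deg
        of the true minimum (located by scanning the energy profile)."""
        energy = lambda x: 0.002 * wrap_angle(x - 40.0) ** 2
        grid = np.arange(-180.0, 180.0, 0.1)
        true_min = grid[np.argmin([energy(g) for g in grid])]
        system = TorsionToy(energy, width=20.0)
        sched = smp.AnnealingSchedule(sweeps_heat=200, sweeps_equil=200, sweeps_cool=2000)
        state, _e = smp.simulated_anneal(system, sched, rng=7)
        assert abs(wrap_angle(state - true_min)) < 5.0

    def test_identical_seeds_identical_results(self):
        system = TorsionToy(lambda x: 0.01 * abs(wrap_angle(x)), width=30.0)
        sched = smp.AnnealingSchedule(sweeps_heat=20, sweeps_equil=20, sweeps_cool=50)
        s1, e1 = smp.simulated_anneal(system, sched, rng=99)
        s2, e2 = smp.simulated_anneal(system, sched, rng=99)
        assert s1 == s2 and e1 == e2

    def test_double_well_reaches_both_basins(self):
        """Across 50 seeds a symmetric double well ends in both basins."""
        energy = lambda x: 0.001 * (abs(wrap_angle(x)) - 90.0) ** 2
        system = TorsionToy(energy, width=40.0)
        sched = smp.AnnealingSchedule(sweeps_heat=30, sweeps_equil=30, sweeps_cool=100)
        signs = set()
        for seed in range(50):
            state, _ = smp.simulated_anneal(system, sched, rng=seed)
            signs.add(np.sign(state))
        assert signs == {-1.0, 1.0}

    def test_cooling_phase_accepted_moves_go_downhill_on_average(self):
        energy = lambda x: 0.002 * wrap_angle(x - 10.0) ** 2
        system = TorsionToy(energy, width=30.0)
        rng = np.random.default_rng(5)
        state = system.initial_state(rng)
        e = system.energy(state)
        for _ in range(200):  # equilibrate hot
            state, e, _ = smp.metropolis_step(system, state, e, 500.0, rng)
        deltas = []
        for T in np.linspace(500.0, 0.0, 400):
            new_state, new_e, acc = smp.metropolis_step(system, state, e, T, rng)
            if acc:
                deltas.append(new_e - e)
            state, e = new_state, new_e
        assert np.mean(deltas) <= 0.0


class TestProductionSampling:
    def test_frame_count_bookkeeping(self):
        system = TorsionToy(lambda x: 0.0)
        traj = smp.production_sample(system, 0.0, sweeps=105, stride=10, rng=0)
        assert len(traj.frames) == 10
        assert len(traj.energies) == 10

    def test_two_state_boltzmann_occupancy(self):
        """Occupancy ratio of two equal-width torsion wells with known dE
        matches exp(-dE/kBT) within 3 block-averaged standard errors."""
        d_e = 0.5
        energy = lambda x: 0.0 if x <= 0 else d_e
        system = TorsionToy(energy, width=60.0)
        traj = smp.production_sample(system, -90.0, T=298.0, sweeps=100_000, stride=1, rng=2024)
        in_high = np.array([f > 0 for f in traj.frames], dtype=float)
        p = in_high.mean()
        se = block_se(in_high)
        expected = np.exp(-d_e / KT298)
        p_expected = expected / (1.0 + expected)
        assert abs(p - p_expected) < 3 * se

    def test_three_state_detailed_balance(self):
        energies = [0.0, 0.4, 0.9]
        system = ThreeStateSystem(energies)
        traj = smp.production_sample(system, 0, T=298.0, sweeps=100_000, stride=1, rng=31)
        states = np.array(traj.frames)
        w = np.exp(-np.array(energies) / KT298)
        w /= w.sum()
        for s in range(3):
            ind = (states == s).astype(float)
            assert abs(ind.mean() - w[s]) < 3 * block_se(ind)

    def test_same_seed_identical_trajectory(self):
        system = TorsionToy(lambda x: 0.001 * x**2)
        t1 = smp.production_sample(system, 10.0, sweeps=500, stride=10, rng=4)
        t2 = smp.production_sample(system, 10.0, sweeps=500, stride=10, rng=4)
        assert t1.frames == t2.frames
        assert np.array_equal(t1.energies, t2.energies)


class TestMSAEnsemble:
    def test_repeat_ids_and_reproducibility(self):
        system = TorsionToy(lambda x: 0.001 * (abs(wrap_angle(x)) - 90.0) ** 2)
        kwargs = dict(
            n_repeats=3,
            schedule=smp.AnnealingSchedule(sweeps_heat=5, sweeps_equil=5, sweeps_cool=10),
            production_sweeps=20,
            stride=5,
            master_seed=12,
        )
        ens1 = smp.msa_ensemble(system, **kwargs)
        ens2 = smp.msa_ensemble(system, **kwargs)
        assert [t.repeat_id for t in ens1.trajectories] == [0, 1, 2]
        for a, b in zip(ens1.trajectories, ens2.trajectories):
            assert a.frames == b.frames

    def test_double_well_coverage_across_repeats(self):
        system = TorsionToy(
            lambda x: 0.002 * (abs(wrap_angle(x)) - 90.0) ** 2, width=30.0
        )
        ens = smp.msa_ensemble(
            system,
            n_repeats=20,
            schedule=smp.AnnealingSchedule(sweeps_heat=10, sweeps_equil=10, sweeps_cool=40),
            production_sweeps=20,
            stride=20,
            master_seed=3,
        )
        basins = {np.sign(t.frames[-1]) for t in ens.trajectories}
        assert len(basins) >= 2

    def test_invalid_repeat_count(self):
        with pytest.raises(ValueError):
            smp.msa_ensemble(TorsionToy(lambda x: 0.0), n_repeats=0)


class TestComplexSampling:
    def test_ensemble_is_deterministic_and_chirality_preserving(
        self, tiny_ensemble, complex_frames
    ):
        assert [t.repeat_id for t in tiny_ensemble.trajectories] == [0, 1]
        for frame in complex_frames:
            assert mol.assign_stereo(frame) == ["S", "S", "R", "S", "S"]

    def test_frames_respect_bond_geometry(self, complex_frames):
        for frame in complex_frames[:3]:
            frame.check_bonds()

    def test_equilibration_skipping(self, tiny_ensemble):
        all_frames = tiny_ensemble.frames(0.0)
        kept = tiny_ensemble.frames(0.4)
        assert 0 < len(kept) < len(all_frames)
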