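"""Energy terms: closed forms, brute-force pair oracles, invariances."""

import numpy as np
import pytest

from urethanefold import forcefield as ff
from urethanefold import molecules as mol
from urethanefold.geometry import random_rotation_matrix

ENERGY_KEYS = ("E_vdW", "E_el", "E_torsion", "G_solv_polar", "G_solv_nonpolar")


def toy_topology(n, elements=None, bonds=()):
    """Bare n-atom topology (C_sp3 types unless elements given)."""
    elements = elements or ["C"] * n
    atoms = [mol.Atom(e, f"X{i}", 0, "backbone") for i, e in enumerate(elements)]
    for a in atoms:
        a.name = "XX"  # avoid the charge-by-name table
    return mol.Topology(name="toy", atoms=atoms, bonds=list(bonds))


def conf_at(topology, coords):
    return mol.Conformation(topology, np.asarray(coords, dtype=float))


class TestLennardJones:
    def test_zero_at_sigma_and_minimum(self, params):
        sigma, eps = params.lj["C_sp3"]
        topo = toy_topology(2)
        at_sigma = conf_at(topo, [[0, 0, 0], [sigma, 0, 0]])
        assert ff.lj_energy(at_sigma, params) == pytest.approx(0.0, abs=1e-12)
        at_min = conf_at(topo, [[0, 0, 0], [2 ** (1 / 6) * sigma, 0, 0]])
        assert ff.lj_energy(at_min, params) == pytest.approx(-eps, abs=1e-12)

    def test_clash_raises(self, params):
        topo = toy_topology(2)
        with pytest.raises(ff.ClashError):
            ff.lj_energy(conf_at(topo, [[0, 0, 0], [0.05, 0, 0]]), params)

    def test_pair_sum_oracle_with_exclusions(self, params):
        """LJ and Coulomb equal an explicit double loop with 1-2/1-3 excluded
        and 1-4 scaled, on random bonded 10-atom chains."""
        import networkx as nx

        rng = np.random.default_rng(3)
        for _trial in range(5):
            n = 10
            bonds = [(i, i + 1) for i in range(n - 1)]
            topo = toy_topology(n, bonds=bonds)
            coords = rng.uniform(0, 6, size=(n, 3))
            coords += np.arange(n)[:, None] * [1.6, 0, 0]  # keep a chain-like spread
            conf = conf_at(topo, coords)
            tables = ff.assign_parameters(topo, params)
            g = nx.Graph(bonds)
            expected_lj = 0.0
            expected_coul = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    d = nx.shortest_path_length(g, i, j)
                    w = 0.0 if d <= 2 else (params.scale_14 if d == 3 else 1.0)
                    r = np.linalg.norm(coords[i] - coords[j])
                    sig = 0.5 * (tables.sigma[i] + tables.sigma[j])
                    eps = np.sqrt(tables.eps[i] * tables.eps[j])
                    expected_lj += w * 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                    expected_coul += (
                        w * ff.COULOMB_CONSTANT * tables.charge[i] * tables.charge[j] / r
                    )
            assert ff.lj_energy(conf, params) == pytest.approx(expected_lj, abs=1e-10)
            assert ff.coulomb_energy(conf, params) == pytest.approx(expected_coul, abs=1e-10)


class TestCoulomb:
    def test_closed_form_pair(self, params):
        topo = toy_topology(2)
        conf = conf_at(topo, [[0, 0, 0], [3.3206, 0, 0]])
        q = np.array([0.5, -0.5])
        e1 = ff.coulomb_energy(conf, params, eps_r=1.0, charges=q)
        assert e1 == pytest.approx(-25.00, abs=5e-3)
        e_scr = ff.coulomb_energy(conf, params, eps_r=4.81, charges=q)
        assert e_scr == pytest.approx(e1 / 4.81, rel=1e-12)

    def test_zero_charges(self, params):
        topo = toy_topology(3)
        conf = conf_at(topo, np.eye(3) * 3.0)
        assert ff.coulomb_energy(conf, params, charges=np.zeros(3)) == 0.0


class TestGeneralizedBorn:
    def test_single_ion_born_equation(self, params):
        topo = toy_topology(1, elements=["O"])
        conf = conf_at(topo, [[0.0, 0.0, 0.0]])
        a = ff.born_radii(conf, params)[0]
        assert a == pytest.approx(params.gb_radii["O"] - params.gb_offset)
        e = ff.gb_polar(conf, params, charges=np.array([1.0]))
        expected = ff.GB_PREFACTOR * (1 - 1 / params.solvent_dielectric) / a
        assert e == pytest.approx(expected, rel=1e-12)

    def test_zero_charges_zero_energy(self, params):
        topo = toy_topology(4)
        rng = np.random.default_rng(0)
        conf = conf_at(topo, rng.uniform(0, 5, (4, 3)))
        assert ff.gb_polar(conf, params, charges=np.zeros(4)) == 0.0

    def test_distant_ions_additive(self, params):
        topo2 = toy_topology(2, elements=["O", "O"])
        pair = conf_at(topo2, [[0, 0, 0], [100.0, 0, 0]])
        e_pair = ff.gb_polar(pair, params, charges=np.array([1.0, 1.0]))
        topo1 = toy_topology(1, elements=["O"])
        single = conf_at(topo1, [[0.0, 0.0, 0.0]])
        e_single = ff.gb_polar(single, params, charges=np.array([1.0]))
        # two isolated Born terms plus the screened 1/r cross term
        cross = (
            2
            * ff.GB_PREFACTOR
            * (1 - 1 / params.solvent_dielectric)
            / 100.0
        )
        assert e_pair == pytest.approx(2 * e_single + cross, abs=0.01)

    def test_gb_vanishes_as_dielectric_approaches_one(self, params, complex_frames):
        import dataclasses

        vac = dataclasses.replace(params, solvent_dielectric=1.0 + 1e-9)
        conf = complex_frames[0]
        conf.topology._ff_tables = None  # drop cache keyed on params identity
        assert abs(ff.gb_polar(conf, vac)) < 1e-5
        conf.topology._ff_tables = None


class TestSASA:
    def test_isolated_atom_is_a_sphere(self, params):
        topo = toy_topology(1, elements=["N"])
        conf = conf_at(topo, [[1.0, 2.0, 3.0]])
        area = ff.sasa(conf, params)[0]
        expected = 4 * np.pi * (params.gb_radii["N"] + params.probe_radius) ** 2
        assert area == pytest.approx(expected, rel=0.02)

    def test_caged_atom_fully_buried(self, params):
        directions = []
        for v in np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]]):
            directions += [v, -v]
        corners = np.array(list(np.ndindex(2, 2, 2))) * 2 - 1
        directions += list(corners / np.sqrt(3))
        cage = np.array(directions) * 1.5
        topo = toy_topology(1 + len(cage))
        conf = conf_at(topo, np.vstack([[0, 0, 0], cage]))
        assert ff.sasa(conf, params)[0] == 0.0

    def test_two_sphere_analytic_overlap(self, params):
        r1 = params.gb_radii["C"] + params.probe_radius
        r2 = params.gb_radii["O"] + params.probe_radius
        d = 2.0
        topo = toy_topology(2, elements=["C", "O"])
        conf = conf_at(topo, [[0, 0, 0], [d, 0, 0]])
        areas = ff.sasa(conf, params)
        h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
        h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
        exp1 = 4 * np.pi * r1**2 - 2 * np.pi * r1 * h1
        exp2 = 4 * np.pi * r2**2 - 2 * np.pi * r2 * h2
        assert areas[0] == pytest.approx(exp1, rel=0.02)
        assert areas[1] == pytest.approx(exp2, rel=0.02)

    def test_nonpolar_term(self):
        assert ff.nonpolar_solvation(0.0, 0.005) == 0.0
        assert ff.nonpolar_solvation(1000.0, 0.005) == pytest.approx(5.0)
        base = ff.nonpolar_solvation(300.0, 0.007, beta=1.0)
        doubled = ff.nonpolar_solvation(600.0, 0.007, beta=1.0)
        assert doubled - 1.0 == pytest.approx(2 * (base - 1.0))
        with pytest.raises(ValueError):
            ff.nonpolar_solvation(-1.0, 0.005)


class TestTotalPotential:
    def test_components_sum_exactly(self, params, complex_frames):
        eb = ff.total_potential(complex_frames[0], params)
        assert eb.E_total == pytest.approx(
            sum(getattr(eb, k) for k in ENERGY_KEYS), abs=1e-12
        )

    def test_three_atom_manual_sum(self, params):
        """Unbonded 3-atom toy equals hand-summed LJ + Coulomb pair terms."""
        topo = toy_topology(3, elements=["C", "O", "N"])
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [0, 5.0, 0]])
        conf = conf_at(topo, coords)
        t = ff.assign_parameters(topo, params)
        lj = coul = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.linalg.norm(coords[i] - coords[j])
                sig = 0.5 * (t.sigma[i] + t.sigma[j])
                eps = np.sqrt(t.eps[i] * t.eps[j])
                lj += 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
                coul += ff.COULOMB_CONSTANT * t.charge[i] * t.charge[j] / r
        eb = ff.total_potential(conf, params, solvation=False)
        assert eb.E_vdW == pytest.approx(lj, abs=1e-10)
        assert eb.E_el == pytest.approx(coul / params.solvent_dielectric, abs=1e-10)

    def test_rigid_motion_invariance_every_term(self, params, complex_frames):
        conf = complex_frames[0]
        reference = ff.total_potential(conf, params)
        rng = np.random.default_rng(11)
        for _ in range(3):
            rot = random_rotation_matrix(rng)
            shift = rng.uniform(-20, 20, 3)
            moved = mol.Conformation(conf.topology, conf.coords @ rot.T + shift)
            eb = ff.total_potential(moved, params)
            for k in ENERGY_KEYS:
                assert getattr(eb, k) == pytest.approx(getattr(reference, k), abs=1e-8)


class TestParams:
    def test_charges_neutral_per_molecule(self, complex_topo, params):
        tables = ff.assign_parameters(complex_topo, params)
        m = complex_topo.molecule_of()
        assert tables.charge[m == 0].sum() == pytest.approx(0.0, abs=1e-12)
        assert tables.charge[m == 1].sum() == pytest.approx(0.0, abs=1e-12)

    def test_json_round_trip(self, params, tmp_path):
        path = tmp_path / "ff.json"
        params.to_json(path)
        again = ff.ForceFieldParams.from_json(path)
        assert again == params

    def test_invalid_params_rejected(self, params):
        import dataclasses

        with pytest.raises(ValueError):
            dataclasses.replace(params, solvent_dielectric=0.9)
        with pytest.raises(ValueError):
            dataclasses.replace(params, gb_radii={"C": -1.0})
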