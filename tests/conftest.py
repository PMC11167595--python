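"""Shared fixtures: topologies, parameters and a small sampled ensemble."""

import numpy as np
import pytest

from urethanefold import forcefield as ff
from urethanefold import molecules as mol
from urethanefold import sampler as smp
from urethanefold import synthetic as syn


@pytest.fixture(scope="session")
def params():
    return ff.default_params()


@pytest.fixture(scope="session")
def pentamer_topo():
    return mol.oligourethane_topology("SSRSS")


@pytest.fixture(scope="session")
def bpa_conf():
    return mol.bpa_structure()


@pytest.fixture(scope="session")
def complex_topo(pentamer_topo, bpa_conf):
    return mol.merge_topologies(pentamer_topo, bpa_conf.topology)


@pytest.fixture(scope="session")
def tiny_ensemble(complex_topo, bpa_conf, params):
    """Small but real sampled ensemble of the SSRSS-BPA complex."""
    system = smp.ComplexSystem(complex_topo, params, ligand_template=bpa_conf.coords)
    return smp.msa_ensemble(
        system,
        n_repeats=2,
        schedule=smp.AnnealingSchedule(sweeps_heat=5, sweeps_equil=5, sweeps_cool=10),
        production_sweeps=30,
        stride=5,
        master_seed=42,
    )


@pytest.fixture(scope="session")
def complex_frames(tiny_ensemble):
    return tiny_ensemble.frames(0.0)


@pytest.fixture(scope="session")
def planted(pentamer_topo):
    """Planted 3-cluster ensemble with ground-truth labels."""
    templates = syn.make_cluster_templates(pentamer_topo, 3, np.random.default_rng(5))
    spec = syn.PlantedEnsembleSpec(templates, frames_per_cluster=10, noise_sd=5.0, seed=17)
    ens, labels = syn.make_planted_ensemble(spec, pentamer_topo)
    return ens, labels
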