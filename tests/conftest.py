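import numpy as np
import pytest

from tandemapa.simulate import SimulationConfig, simulate_probe_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Six-tandem paired cohort with a planted shortening in one subtype."""
    effects = np.zeros((6, 2))
    effects[:3, 0] = -1.0  # first three tandems shortened in subtype 1
    cfg = SimulationConfig(
        n_tandems=6,
        probes_per_segment=(4, 4),
        n_normals=8,
        subtype_sizes=(6, 6),
        baseline_long_fraction=0.8,
        subtype_effects=effects,
        abundance_sd=0.3,
        probe_affinity_sd=0.3,
        noise_sd=0.1,
        seed=11,
    )
    return cfg, simulate_probe_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Deterministic dataset: no noise, no affinity, no abundance spread."""
    effects = np.zeros((4, 2))
    effects[:2, 0] = -1.0
    cfg = SimulationConfig(
        n_tandems=4,
        probes_per_segment=(4, 4),
        n_normals=4,
        subtype_sizes=(3, 3),
        baseline_long_fraction=0.8,
        subtype_effects=effects,
        abundance_sd=0.0,
        probe_affinity_sd=0.0,
        noise_sd=0.0,
        seed=5,
    )
    return cfg, simulate_probe_dataset(cfg)
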