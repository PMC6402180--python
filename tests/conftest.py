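import numpy as np
import pytest

from rohscape.simulate import SimConfig, simulate_population


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_panel():
    """A small structured panel with planted tracts and an island."""
    cfg = SimConfig(
        samples_per_subpop=(20, 12, 10, 8),
        chromosomes=(("1", 30_000_000), ("2", 20_000_000)),
        snp_spacing=5000,
        target_fst=0.05,
        per_individual_froh_target=0.13,
        island_spec=("2", 8_000_000, 8_800_000, 0.7),
        seed=7,
    )
    g, truth = simulate_population(cfg)
    return g, truth, cfg
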