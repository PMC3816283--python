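import pytest

from btbkin.pipeline import SimConfig, simulate_run


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Compact study configuration for fast end-to-end runs."""
    return SimConfig(
        shape=(192, 192),
        n_lesions=2,
        n_vessels_bbb=10,
        n_vessels_btb=5,
        calib_replicates=2,
    )


@pytest.fixture(scope="session")
def simulated_run(tmp_path_factory, small_config):
    """One simulated animal's full input directory (seed 7)."""
    out = tmp_path_factory.mktemp("run")
    simulate_run(small_config, out, seed=7)
    return out
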