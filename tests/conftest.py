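import numpy as np
import pytest

from degracall.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One simulated study at the default conditions, shared read-only."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast study for end-to-end plumbing tests."""
    cfg = SimConfig(
        seed=11,
        n_transcripts=12,
        transcript_length_range=(400, 900),
        n_mirna_families=4,
        sites_per_mirna=2,
        n_dual_duplexes=2,
        n_self_target_hairpins=2,
        single_read_sites=2,
        n_ncrna=2,
    )
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
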