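import pytest

from wmbrainage import synth


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate default cohort shared by read-only metadata tests."""
    cfg = synth.SynthConfig(n_participants=2000, seed=7)
    records, truth = synth.simulate_cohort(cfg)
    return cfg, records, truth
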