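import pytest

from hsckinetics import synthetic


@pytest.fixture(scope="session")
def default_tracks():
    """One default-design division-tracking experiment (576 wells, seed 0)."""
    return synthetic.generate_division_tracks(synthetic.TimingConfig(seed=0))


@pytest.fixture(scope="session")
def default_brdu():
    return synthetic.generate_brdu_series(synthetic.BrdUConfig(seed=0))
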