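import pytest

from pipertdm import BAND_ORDER, BandDistribution, DosingPolicy


@pytest.fixture
def policy():
    return DosingPolicy()


@pytest.fixture
def reported_band_counts():
    """Published per-patient band counts after software-guided empiric
    dosing in a 179-patient cohort: {<16: 1, 16-32: 18, 32-64: 72,
    64-96: 66, >96: 22}."""
    return BandDistribution.from_counts(
        dict(zip(BAND_ORDER, [1, 18, 72, 66, 22]))
    )
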