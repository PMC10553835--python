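import pytest
from hypothesis import settings

from fuccikit.synthetic_data import ImagingConfig, PhaseDurations, ReporterConfig

settings.register_profile("fuccikit", deadline=None, derandomize=True)
settings.load_profile("fuccikit")


@pytest.fixture
def wt_durations() -> PhaseDurations:
    """Wild-type layer-1 phase durations (minutes): G1 81, S 318, G2 527, M 17."""
    return PhaseDurations(g1_min=81, s_min=318, g2_min=527, m_min=17)


@pytest.fixture
def reporters() -> ReporterConfig:
    return ReporterConfig()


@pytest.fixture
def imaging() -> ImagingConfig:
    return ImagingConfig(window_min=150.0, frame_interval_min=20.0, seed=7)
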