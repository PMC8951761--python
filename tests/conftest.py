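import pytest
from hypothesis import HealthCheck, settings

from xciskew.allele_call import repeats_to_size
from xciskew.peak_io import Assay, Channel, Peak, SampleRun, default_config_a, default_config_b

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def cfg_a():
    return default_config_a()


@pytest.fixture
def cfg_b():
    return default_config_b()


def run_from_signals(
    cfg,
    undigested: dict[int, float],
    digested: dict[int, float],
    sample_id: str = "S1",
    assay: Assay = Assay.B,
    replicate: int = 1,
) -> SampleRun:
    """Build a SampleRun from repeat-count -> signal maps.

    Height and area are set equal so the run behaves identically under
    area- and height-based quantification.
    """
    peaks = []
    for channel, signals in ((Channel.UNDIGESTED, undigested), (Channel.DIGESTED, digested)):
        for k, q in signals.items():
            peaks.append(
                Peak(channel=channel, size_bp=repeats_to_size(k, cfg), height=q, area=q)
            )
    return SampleRun(sample_id=sample_id, assay=assay, replicate=replicate, peaks=tuple(peaks))


@pytest.fixture
def build_run():
    return run_from_signals
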