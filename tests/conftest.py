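import numpy as np
import pytest

from isoweb import IsotopeMeasurement, SourceSummary, TDFSpec


@pytest.fixture
def zero_tdf():
    return TDFSpec("zero", 0.0, 0.0, 0.0, 0.0)


@pytest.fixture
def three_sources():
    """Well-separated sources spanning a broad two-tracer triangle."""
    return [
        SourceSummary("A", "pelagic", -10.0, 0.5, 0.0, 0.5, 5),
        SourceSummary("B", "pelagic", -20.0, 0.5, 5.0, 0.5, 5),
        SourceSummary("C", "littoral", -15.0, 0.5, 12.0, 0.5, 5),
    ]


def make_consumer(sample_id, d13C, d15N, zone="pelagic", lake="L", group="g"):
    return IsotopeMeasurement(
        sample_id=sample_id, lake=lake, zone=zone, taxon="t", group=group,
        d13C=d13C, d15N=d15N,
    )


@pytest.fixture
def make_consumer_factory():
    return make_consumer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
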