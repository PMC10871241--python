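from io import BytesIO

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bbikit import ChromSizes, open_bbi, write_bigbed, write_bigwig
from bbikit.fixtures import FeatureSpec, TrackSpec, gen_features, gen_signal_track
from bbikit.write import WriteOptions


@pytest.fixture
def small_genome() -> ChromSizes:
    return ChromSizes([("chr1", 5000), ("chr2", 3000), ("chrM", 800)])


@pytest.fixture
def track(small_genome):
    """A seeded signal track with its per-base oracle map."""
    spec = TrackSpec(seed=11, chroms=small_genome, interval_count=300,
                     length_range=(1, 40), gap_probability=0.3)
    return gen_signal_track(spec)


@pytest.fixture
def features(small_genome):
    spec = FeatureSpec(seed=23, chroms=small_genome, record_count=200, bed_n=6)
    return gen_features(spec)


def write_track(intervals, chroms, opts: WriteOptions = WriteOptions()):
    """Write a BigWig into memory and reopen it."""
    buf = BytesIO()
    write_bigwig(iter(intervals), chroms, buf, opts)
    return open_bbi(buf)


def write_feats(records, chroms, opts: WriteOptions = WriteOptions(), **kw):
    buf = BytesIO()
    write_bigbed(iter(records), chroms, buf, opts, **kw)
    return open_bbi(buf)


@pytest.fixture
def bigwig(track, small_genome):
    intervals, _ = track
    return write_track(intervals, small_genome)


@pytest.fixture
def bigbed(features, small_genome):
    return write_feats(features, small_genome)
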