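import numpy as np
import pytest

from regspot.io import Interval, ScoreTrack, VariantRecord


def make_variant(pos1, donor="D1", chrom="chr1", ref="G", alt="A", **kw):
    return VariantRecord(donor_id=donor, chrom=chrom, pos1=pos1, ref=ref, alt=alt, **kw)


@pytest.fixture
def mkvar():
    return make_variant


@pytest.fixture
def worked_example_variants():
    """The Fig-style worked example: 10 records at 4 positions (3,1,2,4)
    within chained 25 bp gaps."""
    variants = []
    donor = 0
    for pos, count in zip([1000, 1020, 1040, 1060], [3, 1, 2, 4]):
        for _ in range(count):
            variants.append(make_variant(pos, donor=f"D{donor}"))
            donor += 1
    return variants


@pytest.fixture
def flat_track():
    """Uniform score 1.5 across chr1:0-1,000,000."""
    return ScoreTrack([(Interval("chr1", 0, 1_000_000), 1.5)])


def random_variants(rng, n, chrom_len=10_000, chrom="chr1", n_donors=20):
    out = []
    for i in range(n):
        pos = int(rng.integers(1, chrom_len + 1))
        out.append(
            make_variant(pos, donor=f"D{int(rng.integers(0, n_donors))}", chrom=chrom)
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)
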