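import numpy as np
import pandas as pd
import pytest

from mycnload.genomics_io import ExpressionTable, GenomicInterval, ReadAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_read(chrom, start, end, strand):
    return ReadAlignment(GenomicInterval(chrom, start, end, strand))


def random_reads(rng, n, chrom="chr1", max_pos=5000, read_len_range=(20, 80)):
    reads = []
    for _ in range(n):
        length = int(rng.integers(*read_len_range))
        start = int(rng.integers(0, max_pos - length))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(make_read(chrom, start, start + length, strand))
    return reads


def make_expression(values: dict, conditions: dict, spikes: set | None = None):
    """values: gene -> list of per-sample numbers; sample names from conditions."""
    samples = list(conditions)
    df = pd.DataFrame(values, index=samples).T.astype(float)
    df.columns = samples
    spikes = spikes or set()
    return ExpressionTable(
        values=df,
        condition_of=dict(conditions),
        is_spike=pd.Series([g in spikes for g in df.index], index=df.index),
    )
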