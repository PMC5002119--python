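import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from poolvar.frequencies import FrequencyRecord
from poolvar.io_formats import AlleleDepth, PoolSpec, VariantSite


@pytest.fixture
def rng():
    return np.random.default_rng(20160826)


@pytest.fixture
def two_breed_manifest():
    return [
        PoolSpec("X1", "BreedX", 10),
        PoolSpec("X2", "BreedX", 10),
        PoolSpec("Y1", "BreedY", 5),
    ]


def make_record(
    key="chr1_100_A_T",
    paaf=None,
    alt_reads=None,
    dp=None,
    manifest=None,
    n_alts=1,
    weights="ploidy",
):
    """Assemble a FrequencyRecord with a consistent global frequency."""
    from poolvar.frequencies import (
        classify_frequency,
        combine_global_frequency,
        flag_fixed_alternative,
    )

    paaf = dict(paaf or {})
    dp = dict(dp if dp is not None else {p: 1000 for p in paaf})
    alt_reads = dict(
        alt_reads
        if alt_reads is not None
        else {p: int(round(f * dp[p])) for p, f in paaf.items()}
    )
    manifest = manifest or [PoolSpec(p, p, 10) for p in paaf]
    aaf, pmaf = combine_global_frequency(paaf, manifest, weights, dp)
    chrom, pos, _, _ = key.rsplit("_", 3)
    return FrequencyRecord(
        variant_key=key,
        chrom=chrom,
        pos=int(pos),
        n_alts=n_alts,
        paaf=paaf,
        alt_reads=alt_reads,
        dp=dp,
        global_aaf=aaf,
        pmaf=pmaf,
        freq_class=classify_frequency(pmaf),
        fixed_alt=flag_fixed_alternative(paaf),
    )


def make_site(chrom="chr1", pos=100, ref="A", alts=("T",), depths=None):
    return VariantSite(
        chrom,
        pos,
        ref,
        tuple(alts),
        {
            pid: d if isinstance(d, AlleleDepth) else AlleleDepth(d[0], tuple(d[1:]))
            for pid, d in (depths or {}).items()
        },
    )
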