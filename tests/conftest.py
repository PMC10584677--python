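import numpy as np
import pytest

from txroadblock import ElongationParams, FragmentSet, GeneModel


@pytest.fixture
def small_gene() -> GeneModel:
    """A 10-kb test locus: TSS at 0, single PAS at 7 kb."""
    return GeneModel(
        chrom="chrT",
        locus_start=0,
        locus_end=10_000,
        tss=0,
        pas_positions=(7_000,),
        gene_length=7_000,
    )


@pytest.fixture
def two_pas_gene() -> GeneModel:
    """A 14-kb locus with proximal (6 kb) and distal (10 kb) PAS."""
    return GeneModel(
        chrom="chrT",
        locus_start=0,
        locus_end=14_000,
        tss=0,
        pas_positions=(6_000, 10_000),
        gene_length=10_000,
    )


@pytest.fixture
def params() -> ElongationParams:
    return ElongationParams(term_hazard=5e-4, pas_commit=(1.0,))


def make_fragments(starts, ends, chrom="chrT", locus=(0, 10_000), label="test"):
    return FragmentSet(
        chrom=chrom,
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        label=label,
        locus_start=locus[0],
        locus_end=locus[1],
    )
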