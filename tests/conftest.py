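import numpy as np
import pytest

from introscan.genotype_io import HaplotypePanel, PopulationMap


def make_panel(alleles, pos=None, chrom="1", sample_ids=None):
    """Build a panel from a (2n x m) nested list / array of {0,1,-1}."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, m = alleles.shape
    assert n_hap % 2 == 0
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    pos = np.asarray(pos)
    if np.isscalar(chrom) or isinstance(chrom, str):
        chrom = np.full(m, chrom, dtype=object)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_hap // 2)]
    return HaplotypePanel(
        chrom=np.asarray(chrom, dtype=object),
        pos=pos,
        alleles=alleles,
        sample_ids=sample_ids,
        variant_ids=[f"v{j}" for j in range(m)],
    )


@pytest.fixture
def toy_panel():
    """3 samples x 5 SNPs, fully phased, no missing data."""
    return make_panel(
        [
            [0, 0, 1, 0, 1],
            [0, 1, 1, 0, 0],
            [1, 0, 0, 1, 1],
            [0, 0, 1, 1, 0],
            [1, 1, 0, 0, 1],
            [0, 1, 1, 1, 0],
        ],
        pos=[100, 2000, 5000, 12000, 30000],
    )


@pytest.fixture
def two_group_map():
    return PopulationMap({"s1": "A", "s2": "A", "s3": "B"})
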