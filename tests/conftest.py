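import numpy as np
import pytest

import gmetools as gt
from gmetools.hicmat import as_balanced


@pytest.fixture(scope="session")
def enriched_dataset():
    """Default-condition dataset with planted anchor enrichment e=3 (seed 1)."""
    genome, truth = gt.make_truth(anchor_enrichment=3.0, seed=1)
    M = gt.simulate_hic(genome, truth)
    return genome, truth, M


@pytest.fixture(scope="session")
def null_dataset():
    """Fully null dataset: e=1 and tau=1, so no planted structure (seed 7)."""
    genome, truth = gt.make_truth(anchor_enrichment=1.0, tau=1.0, seed=7)
    M = gt.simulate_hic(genome, truth)
    return genome, truth, M


@pytest.fixture(scope="session")
def enriched_oe(enriched_dataset):
    genome, truth, M = enriched_dataset
    OE, prof = gt.obs_exp(as_balanced(M))
    return genome, truth, M, OE, prof


def planted_border_bins(genome, truth):
    """Global bin ids of the junctions between planted TAD blocks."""
    out = []
    for chrom, sub in truth.tad_blocks.groupby("chrom"):
        ends = sorted(sub["end"])[:-1]
        off = genome.chrom_offset(chrom)
        out += [off + e // genome.bin_size for e in ends]
    return np.array(sorted(out))
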