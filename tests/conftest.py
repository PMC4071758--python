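import random

import pytest

from splicefate.gene_model_io import GeneModel
from splicefate.synthetic_data import SyntheticSpec, gen_gene_model, gene_from_cds, _rand_codon, _STOPS


@pytest.fixture(scope="session")
def model15() -> GeneModel:
    """A 15-exon / 14-intron plant-like gene model (SPO11-1-like shape)."""
    return gen_gene_model(SyntheticSpec(seed=7, n_exons=15, gene_id="g15"))


@pytest.fixture(scope="session")
def model11() -> GeneModel:
    """An 11-exon / 10-intron model (SPO11-2-like shape)."""
    return gen_gene_model(SyntheticSpec(seed=7, n_exons=11, gene_id="g11"))


@pytest.fixture(scope="session")
def model_noutr() -> GeneModel:
    """A model without UTRs: spliced transcript == CDS exactly."""
    return gen_gene_model(
        SyntheticSpec(seed=11, n_exons=6, gene_id="gnoutr", utr5_len=0, utr3_len=0)
    )


def make_cds(n_codons: int, seed: int = 0) -> str:
    """A clean CDS: ATG start, no internal in-frame stop, one terminal stop."""
    rng = random.Random(seed)
    body = "".join(_rand_codon(rng, 0.45) for _ in range(n_codons - 2))
    return "ATG" + body + rng.choice(_STOPS)


def make_gene_with_offsets(offsets, n_codons=80, seed=0, **kw) -> GeneModel:
    """A gene whose CDS introns sit at exactly the given coding offsets."""
    rng = random.Random(seed + 1)
    return gene_from_cds("goff", "goff_sp", make_cds(n_codons, seed), offsets, rng, **kw)
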