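import numpy as np
import pytest

from phagebin.formats_io import Bin, Contig
from phagebin.gene_calling import AnnotatedBin, GeneCall, sort_genes


def make_annotated(contig_specs, gene_specs, bin_id="b1"):
    """Build an AnnotatedBin from terse specs.

    contig_specs: list of (contig_id, length) — sequence is all-A filler —
    or (contig_id, sequence).
    gene_specs: list of (gene_id, contig_id, start, end, strand).
    """
    contigs = []
    for spec in contig_specs:
        cid, val = spec
        seq = val if isinstance(val, str) else "A" * val
        contigs.append(Contig(cid, seq))
    b = Bin(bin_id, tuple(contigs))
    genes = [GeneCall(*g) for g in gene_specs]
    return AnnotatedBin(bin=b, genes=sort_genes(genes, [c.id for c in contigs]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def phage_genome():
    from phagebin.synthetic_fixtures import PHAGE_PROFILE, generate_genome

    return generate_genome(PHAGE_PROFILE, 30_000, seed=11)


@pytest.fixture
def bacteria_genome():
    from phagebin.synthetic_fixtures import BACTERIA_PROFILE, generate_genome

    return generate_genome(BACTERIA_PROFILE, 60_000, seed=12)
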