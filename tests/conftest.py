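import numpy as np
import pytest

from dndscape.genome_io import GeneFeature, GenomeRecord, Replicon, assign_ordinals


@pytest.fixture
def toy_genome_factory():
    """Build a linear single-replicon genome with genes at given ordinals."""

    def _make(n_genes: int, genome_id: str = "G1", circular: bool = False):
        feats = [
            GeneFeature(
                gene_id=f"{genome_id}_p{i:03d}",
                replicon_id="chrom",
                start=i * 1000,
                end=i * 1000 + 900,
                strand="+",
            )
            for i in range(n_genes)
        ]
        return GenomeRecord(
            genome_id=genome_id,
            replicons=[Replicon("chrom", n_genes * 1000, circular)],
            features=assign_ordinals(feats),
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20210)
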