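import numpy as np
import pytest

from hexorient.io_formats import GenomeSeq, ParticleRecord, Pfm


def make_particle(
    h2b=(10.0, 4.0),
    h4=(6.0, 5.0),
    h2a=(5.0, 5.0),
    h3=(5.0, 5.0),
    strand="+",
    gene_index=1,
    dyad=500,
    gene_id="geneA",
) -> ParticleRecord:
    tags = {}
    for hist, (up, down) in zip(("H2A", "H2B", "H3", "H4"), (h2a, h2b, h3, h4)):
        tags[(hist, "upstream")] = float(up)
        tags[(hist, "downstream")] = float(down)
    return ParticleRecord(
        gene_id=gene_id, chrom="chrS", strand=strand,
        gene_index=gene_index, dyad=dyad, tags=tags,
    )


@pytest.fixture
def toy_genome() -> GenomeSeq:
    return GenomeSeq({"chrS": "AACGTTT"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def consensus_pfm() -> Pfm:
    """Near-deterministic ACGTAC motif."""
    probs = np.full((6, 4), 0.01)
    for i, b in enumerate([0, 1, 2, 3, 0, 1]):
        probs[i, b] = 0.97
    return Pfm("ACGTAC", probs)
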