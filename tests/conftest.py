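import numpy as np
import pytest

from cnvnet import GeneCatalog, GeneModel, GenomicInterval, SimConfig, generate_world


@pytest.fixture(scope="session")
def world():
    """The default synthetic world used across tests (seed fixed)."""
    return generate_world(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def small_world():
    """A small, fast world for pipeline/CLI smoke tests."""
    return generate_world(
        SimConfig(
            rng_seed=3,
            n_genes=300,
            n_chroms=3,
            planted_term_size=25,
            planted_module_size=12,
            n_patients=20,
            n_control_patients=10,
        )
    )


def make_gene(gene_id, chrom, transcripts, symbol=None):
    """Helper: transcripts as {tx_id: [(start, end), ...]}."""
    return GeneModel(
        gene_id,
        symbol or gene_id,
        {
            tx: tuple(GenomicInterval(chrom, s, e) for s, e in exons)
            for tx, exons in transcripts.items()
        },
    )


@pytest.fixture
def two_transcript_gene():
    # txA exons 100-200 and 400-500; txB exon 150-250
    return make_gene(
        "g1", "chr1", {"t1": [(100, 200), (400, 500)], "t2": [(150, 250)]}
    )


def random_catalog(rng: np.random.Generator, n_genes=10, n_chroms=2, coord_max=2000):
    """Small random catalogue for oracle-based property tests."""
    genes = []
    for gi in range(n_genes):
        chrom = f"c{rng.integers(1, n_chroms + 1)}"
        transcripts = {}
        for ti in range(rng.integers(1, 4)):
            exons = []
            for _ in range(rng.integers(1, 4)):
                s = int(rng.integers(1, coord_max))
                e = s + int(rng.integers(0, 50))
                exons.append((s, e))
            transcripts[f"g{gi}t{ti}"] = exons
        genes.append(make_gene(f"g{gi}", chrom, transcripts))
    return GeneCatalog(genes)
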