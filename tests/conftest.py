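import numpy as np
import pytest

import isohap as ih


@pytest.fixture(scope="session")
def default_sim():
    """One simulated study at default-ish conditions, shared across tests."""
    cfg = ih.SimulationConfig(n_fragments=2500, seed=7)
    genome, annotation, sites, library = ih.simulate(cfg)
    return cfg, genome, annotation, sites, library


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free simulation: truth and observation coincide exactly."""
    cfg = ih.SimulationConfig(n_fragments=1500, seed=5, error_rate=0.0)
    genome, annotation, sites, library = ih.simulate(cfg)
    return cfg, genome, annotation, sites, library


def _gene(gene_id, exon_sets, chrom="chr1", strand="+", biotype="protein_coding"):
    """Tiny hand-built gene: one transcript per exon tuple list."""
    txs = tuple(
        ih.Transcript(f"{gene_id}.{i + 1}", gene_id, tuple(exons))
        for i, exons in enumerate(exon_sets)
    )
    return ih.Gene(gene_id, gene_id, chrom, strand, biotype, txs)


@pytest.fixture
def make_gene():
    return _gene


@pytest.fixture
def make_annotation():
    def _make(*genes):
        ann = ih.Annotation()
        for g in genes:
            ann.add(g)
        return ann

    return _make


@pytest.fixture
def make_fragment():
    """Fragment from explicit (position, base) calls."""

    def _make(calls, junctions=(), chrom="chr1", name="frag"):
        return ih.fragment_from_positions(name, chrom, dict(calls), junctions)

    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
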