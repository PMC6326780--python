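import numpy as np
import pytest

from itr_regnet.genome_intervals import GeneModel, GenomicInterval, PipelineConfig
from itr_regnet.synthetic_data import DEFAULT_CONSENSUS, SimulationConfig, simulate_genome

BASE_COMPLEMENT = {"A": "C", "C": "G", "G": "T", "T": "A"}  # cyclic substitution


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def substitute(seq, k, rng, interior_margin=2):
    """k substitutions at distinct interior positions."""
    pos = rng.choice(np.arange(interior_margin, len(seq) - interior_margin),
                     size=k, replace=False)
    s = list(seq)
    for p in pos:
        s[p] = BASE_COMPLEMENT[s[p]]
    return "".join(s)


def substitute_spaced(seq, k):
    """k substitutions spaced >=3 apart and >=3 from either end.

    The spacing keeps every prefix/suffix of the alignment net-positive,
    so the full-length local alignment is the unique optimum and the
    identity is exactly (len-k)/len.
    """
    s = list(seq)
    for i in range(k):
        p = 3 + 3 * i
        s[p] = BASE_COMPLEMENT[s[p]]
    return "".join(s)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(genome_length=120_000, n_genes=10, n_remnants=15,
                           divergence=0.05, min_separation=800,
                           n_peaks=40, make_tracks=False)
    genome, manifest = simulate_genome(cfg, seed=7)
    return cfg, genome, manifest


@pytest.fixture
def toy_gene():
    exons = [GenomicInterval("chr1", 1000, 1200, "+", "e1"),
             GenomicInterval("chr1", 4000, 4300, "+", "e2"),
             GenomicInterval("chr1", 7800, 8000, "+", "e3")]
    return GeneModel(gene=GenomicInterval("chr1", 1000, 8000, "+", "gA"),
                     gene_id="gA", exons=exons)


CONSENSUS = DEFAULT_CONSENSUS
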