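import numpy as np
import pytest
from Bio.Seq import Seq

from itr_regnet.genome_intervals import GeneModel, GenomicInterval, PipelineConfig
from itr_regnet.itr_scanner import (
    ItrHit,
    census_report,
    classify_remnants,
    scan_consensus,
    scan_consensus_bruteforce,
)
from itr_regnet.synthetic_data import SimulationConfig, simulate_genome

from conftest import CONSENSUS, random_seq, substitute


def _hit_keys(hits):
    return [(h.locus.start, h.locus.end, h.strand, round(h.score, 6))
            for h in hits]


def _plant(rng, core, flank=1000):
    return {"chr1": random_seq(rng, flank) + core + random_seq(rng, flank)}


class TestScanConsensus:
    def test_exact_copy_found_with_full_identity(self, rng):
        hits = scan_consensus(_plant(rng, CONSENSUS), CONSENSUS)
        assert len(hits) == 1
        h = hits[0]
        assert h.identity == 1.0 and h.aligned_consensus_frac == 1.0
        assert (h.locus.start, h.locus.end, h.strand) == (1000, 1028, "+")

    def test_reverse_complement_copy_on_minus_strand(self, rng):
        rc = str(Seq(CONSENSUS).reverse_complement())
        hits = scan_consensus(_plant(rng, rc), CONSENSUS)
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].identity == 1.0

    def test_identity_filter_boundary_5_vs_6_substitutions(self, rng):
        """23/28 = 0.821 passes the 80% filter; 22/28 = 0.786 does not."""
        from conftest import substitute_spaced
        hits5 = scan_consensus(_plant(rng, substitute_spaced(CONSENSUS, 5)),
                               CONSENSUS)
        assert len(hits5) == 1
        assert hits5[0].identity == pytest.approx(23 / 28, abs=1e-6)
        hits6 = scan_consensus(_plant(rng, substitute_spaced(CONSENSUS, 6)),
                               CONSENSUS)
        assert hits6 == []

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            scan_consensus({"chr1": "ACGT" * 100}, "")
        with pytest.raises(ValueError):
            scan_consensus({}, CONSENSUS)

    def test_consensus_longer_than_genome_gives_empty(self):
        assert scan_consensus({"chr1": "ACGTACGT"}, CONSENSUS) == []

    def test_n_bases_never_match(self, rng):
        core = CONSENSUS[:10] + "N" * 18
        hits = scan_consensus(_plant(rng, core), CONSENSUS)
        assert hits == []

    def test_iupac_ambiguity_in_consensus_matches_listed_bases(self, rng):
        ambiguous = "R" + CONSENSUS[1:]  # R = A or G
        for base in "AG":
            hits = scan_consensus(_plant(rng, base + CONSENSUS[1:]), ambiguous)
            assert hits and hits[0].identity == 1.0

    def test_mirror_image_under_genome_reverse_complement(self, rng):
        cfg = SimulationConfig(genome_length=30_000, n_genes=3, n_remnants=6,
                               divergence=0.08, min_separation=400)
        genome, _ = simulate_genome(cfg, seed=5)
        fwd = scan_consensus(genome, CONSENSUS)
        L = len(genome["chr1"])
        rc_genome = {"chr1": str(Seq(genome["chr1"]).reverse_complement())}
        rev = scan_consensus(rc_genome, CONSENSUS)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted((L - h.locus.end, L - h.locus.start, flip[h.strand])
                          for h in rev)
        assert mirrored == sorted((h.locus.start, h.locus.end, h.strand)
                                  for h in fwd)

    def test_matches_bruteforce_oracle_on_random_genomes(self):
        for seed in range(3):
            cfg = SimulationConfig(genome_length=20_000, n_genes=2,
                                   n_remnants=4, divergence=0.12,
                                   min_separation=300)
            genome, _ = simulate_genome(cfg, seed=seed)
            assert _hit_keys(scan_consensus(genome, CONSENSUS)) == \
                _hit_keys(scan_consensus_bruteforce(genome, CONSENSUS))

    def test_raising_min_identity_never_adds_hits(self):
        cfg = SimulationConfig(genome_length=40_000, n_genes=4, n_remnants=8,
                               divergence=0.15, min_separation=400)
        genome, _ = simulate_genome(cfg, seed=9)
        counts = []
        for min_id in (0.70, 0.80, 0.90, 1.0):
            pc = PipelineConfig(min_identity=min_id)
            counts.append(len(scan_consensus(genome, CONSENSUS, pc)))
        assert counts == sorted(counts, reverse=True)

    def test_planted_recovery_recall(self):
        """Recall 1 at zero divergence; 0 far beyond the 80% filter.

        Near-threshold divergence can stochastically leave a copy above
        the filter (binomial tail), so the no-recovery check plants at
        50% per-site divergence where survival is negligible.
        """
        for seed in range(5):
            cfg = SimulationConfig(genome_length=30_000, n_genes=3,
                                   n_remnants=5, divergence=0.0,
                                   min_separation=400)
            genome, man = simulate_genome(cfg, seed=seed)
            hits = scan_consensus(genome, CONSENSUS)
            got = {(h.locus.start, h.locus.end) for h in hits}
            assert {(p.start, p.end) for p in man.planted_itrs} <= got

            cfg_far = SimulationConfig(genome_length=30_000, n_genes=3,
                                       n_remnants=5, divergence=0.50,
                                       min_separation=400)
            genome, man = simulate_genome(cfg_far, seed=seed)
            hits = scan_consensus(genome, CONSENSUS)
            assert hits == []


def _mk_hit(start, end, strand, chrom="chr1"):
    return ItrHit(locus=GenomicInterval(chrom, start, end, strand, "itr"),
                  identity=0.9, aligned_consensus_frac=1.0, score=20.0,
                  strand=strand)


class TestClassifyRemnants:
    def test_inverted_pair_with_6bp_spacer_is_made1(self):
        anns = classify_remnants([_mk_hit(100, 128, "+"), _mk_hit(134, 162, "-")])
        assert len(anns) == 1
        assert anns[0].remnant_class == "made1"
        assert anns[0].spacer_length == 6

    def test_single_hit_is_solo(self):
        (ann,) = classify_remnants([_mk_hit(100, 128, "+")])
        assert ann.remnant_class == "solo_itr"

    def test_greedy_left_to_right_pairing(self):
        """Middle hit could pair either way; leftmost pair wins, rest solo.

        Enumerating the pairings of (A+, B-, C+): {A,B}+C and A+{B,C} are
        both geometrically valid made1 pairs; the documented choice is the
        leftmost pair.
        """
        a, b, c = _mk_hit(100, 128, "+"), _mk_hit(134, 162, "-"), _mk_hit(168, 196, "+")
        anns = classify_remnants([a, b, c])
        assert [x.remnant_class for x in anns] == ["made1", "solo_itr"]
        assert anns[0].itrs == (a, b)

    def test_wide_inverted_pair_is_paired_remnant(self):
        anns = classify_remnants([_mk_hit(100, 128, "+"), _mk_hit(1000, 1028, "-")])
        assert [x.remnant_class for x in anns] == ["paired_itr_remnant"]

    def test_beyond_pair_span_stays_solo(self):
        anns = classify_remnants([_mk_hit(100, 128, "+"), _mk_hit(5000, 5028, "-")])
        assert [x.remnant_class for x in anns] == ["solo_itr", "solo_itr"]

    def test_same_strand_pair_not_inverted(self):
        anns = classify_remnants([_mk_hit(100, 128, "+"), _mk_hit(134, 162, "+")])
        assert [x.remnant_class for x in anns] == ["solo_itr", "solo_itr"]

    def test_every_hit_in_exactly_one_annotation(self, small_sim):
        from itr_regnet.itr_scanner import scan_consensus
        cfg, genome, _ = small_sim
        hits = scan_consensus(genome, cfg.consensus)
        anns = classify_remnants(hits)
        assert sum(len(a.itrs) for a in anns) == len(hits)


class TestCensusReport:
    def test_empty_annotations_all_zero(self):
        table = census_report([], [])
        assert table["count"].sum() == 0

    def test_planted_context_counts(self, toy_gene):
        """10 intron-planted + 5 intergenic remnants count as 10/5."""
        anns = []
        for i in range(10):  # inside the 1200..4000 intron of toy_gene
            s = 1300 + i * 250
            anns.append(classify_remnants([_mk_hit(s, s + 28, "+")])[0])
        for i in range(5):
            s = 20000 + i * 500
            anns.append(classify_remnants([_mk_hit(s, s + 28, "+")])[0])
        table = census_report(anns, [toy_gene])
        by_ctx = table.groupby("context")["count"].sum()
        assert by_ctx.get("intragenic_intron", 0) == 10
        assert by_ctx.get("intergenic", 0) == 5
        assert table["count"].sum() == 15

    def test_exonic_context_detected(self, toy_gene):
        (ann,) = classify_remnants([_mk_hit(1050, 1078, "+")])
        table = census_report([ann], [toy_gene])
        assert table.set_index("context")["count"].get("intragenic_exon") == 1

    def test_two_thirds_intragenic_design(self, small_sim):
        """Generator's intragenic share lands in the binomial CI of 2/3."""
        _, _, man = small_sim
        n = len({p.remnant_index for p in man.planted_itrs})
        n_intra = len({p.remnant_index for p in man.planted_itrs
                       if p.gene_id is not None})
        ci = 1.96 * np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(n_intra / n - 2 / 3) <= ci + 1e-9
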