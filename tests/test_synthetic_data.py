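import numpy as np
import pytest

from itr_regnet.chip_integration import assign_peaks, bound_itrs, within_bound_fraction
from itr_regnet.expression_integration import apply_de_thresholds, de_call_counts
from itr_regnet.itr_scanner import ItrHit, scan_consensus
from itr_regnet.synthetic_data import (
    SimulationConfig,
    decay_sequence,
    preset,
    simulate_chip,
    simulate_counts,
    simulate_de,
    simulate_genome,
    write_simulation,
)

from conftest import CONSENSUS


def _hits_from_manifest(manifest):
    return [ItrHit(locus=iv, identity=1.0, aligned_consensus_frac=1.0,
                   score=28.0, strand=iv.strand)
            for iv in manifest.itr_intervals()]


class TestSimulateGenome:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(genome_length=60_000, n_genes=6, n_remnants=8,
                               min_separation=500)
        g1, m1 = simulate_genome(cfg, seed=3)
        g2, m2 = simulate_genome(cfg, seed=3)
        assert g1 == g2
        assert [vars(a) for a in m1.planted_itrs] == \
            [vars(b) for b in m2.planted_itrs]
        p1 = write_simulation(tmp_path / "a", g1, m1)
        p2 = write_simulation(tmp_path / "b", g2, m2)
        assert p1["genome"].read_bytes() == p2["genome"].read_bytes()
        assert p1["manifest"].read_text().replace(str(tmp_path / "a"), "") == \
            p2["manifest"].read_text().replace(str(tmp_path / "b"), "")

    def test_different_seed_differs(self):
        cfg = SimulationConfig(genome_length=60_000, n_genes=6, n_remnants=8,
                               min_separation=500)
        g1, _ = simulate_genome(cfg, seed=3)
        g2, _ = simulate_genome(cfg, seed=4)
        assert g1 != g2

    def test_zero_divergence_scanner_recovers_every_locus(self):
        cfg = SimulationConfig(genome_length=60_000, n_genes=6, n_remnants=8,
                               divergence=0.0, min_separation=500)
        genome, man = simulate_genome(cfg, seed=1)
        hits = scan_consensus(genome, CONSENSUS)
        got = {(h.locus.start, h.locus.end): h for h in hits}
        for p in man.planted_itrs:
            assert (p.start, p.end) in got
            assert got[(p.start, p.end)].identity == 1.0

    def test_divergence_matches_binomial_expectation(self):
        """Mean scanner identity within +-0.03 of 1-d over 50 plants at d=0.1."""
        identities = []
        seed = 0
        while len(identities) < 50:
            cfg = SimulationConfig(genome_length=80_000, n_genes=6,
                                   n_remnants=12, divergence=0.10,
                                   min_separation=800)
            genome, man = simulate_genome(cfg, seed=seed)
            hits = scan_consensus(genome, CONSENSUS)
            identities.extend(h.identity for h in hits)
            seed += 1
        assert abs(np.mean(identities[:50]) - 0.90) <= 0.03

    def test_made1_structure_has_6bp_spacer(self):
        cfg = SimulationConfig(genome_length=80_000, n_genes=6, n_remnants=12,
                               made1_frac=1.0, divergence=0.0,
                               min_separation=600)
        _, man = simulate_genome(cfg, seed=2)
        by_remnant = {}
        for p in man.planted_itrs:
            by_remnant.setdefault(p.remnant_index, []).append(p)
        for pair in by_remnant.values():
            assert len(pair) == 2
            left, right = sorted(pair, key=lambda p: p.start)
            assert right.start - left.end == 6
            assert {left.strand, right.strand} == {"+", "-"}

    def test_infeasible_packing_rejected(self):
        cfg = SimulationConfig(genome_length=5000, n_genes=2, n_remnants=50)
        with pytest.raises(ValueError):
            simulate_genome(cfg, seed=0)

    def test_planted_features_within_bounds(self, small_sim):
        _, _, man = small_sim
        for p in man.planted_itrs:
            assert 0 <= p.start < p.end <= man.genome_length
        for g in man.gene_models:
            assert 0 <= g.gene.start < g.gene.end <= man.genome_length


class TestSimulateChip:
    def test_all_peaks_at_itrs_gives_full_bound_fraction(self, small_sim):
        cfg, _, man = small_sim
        chip = simulate_chip(man, n_peaks=30, frac_at_itr=1.0, seed=5,
                             config=cfg)
        asn = assign_peaks(chip["peaks"], _hits_from_manifest(man))
        assert within_bound_fraction(asn) == 1.0

    def test_bound_set_matches_ground_truth_when_unambiguous(self):
        """With d=0, solo remnants and sparse planting, the recovered
        bound-ITR set equals the generator's exactly."""
        cfg = SimulationConfig(genome_length=300_000, n_genes=10,
                               n_remnants=12, made1_frac=0.0, divergence=0.0,
                               min_separation=5000, n_peaks=10,
                               frac_at_itr=1.0, make_tracks=False)
        genome, man = simulate_genome(cfg, seed=8)
        chip = simulate_chip(man, seed=9, config=cfg)
        asn = assign_peaks(chip["peaks"], _hits_from_manifest(man))
        got = {b.locus.start for b in bound_itrs(asn)}
        want = {man.planted_itrs[i].start for i in chip["bound_itr_indices"]}
        assert got == want

    def test_track_geometry_and_determinism(self, small_sim):
        cfg, _, man = small_sim
        cfg_tracks = SimulationConfig(**{**vars(cfg), "make_tracks": True,
                                         "n_peaks": 10})
        c1 = simulate_chip(man, seed=4, config=cfg_tracks)
        c2 = simulate_chip(man, seed=4, config=cfg_tracks)
        assert c1["ip_track"].equals(c2["ip_track"])
        assert c1["input_track"]["end"].max() == man.genome_length

    def test_frac_out_of_range_rejected(self, small_sim):
        cfg, _, man = small_sim
        with pytest.raises(ValueError):
            simulate_chip(man, frac_at_itr=1.5, seed=0, config=cfg)


class TestSimulateDe:
    def test_no_de_gives_all_ns(self, small_sim):
        cfg, _, man = small_sim
        quiet = SimulationConfig(**{**vars(cfg), "n_up_a": 0, "n_down_a": 0,
                                    "n_shared": 0, "n_b_exclusive": 0,
                                    "n_de_genes": 2000})
        de_a, de_b, _ = simulate_de(man, seed=1, config=quiet)
        assert de_call_counts(apply_de_thresholds(de_a))["ns"] == 2000
        assert de_call_counts(apply_de_thresholds(de_b))["ns"] == 2000

    def test_threshold_recovery_matches_truth(self, small_sim):
        """Thresholding the emitted tables reproduces the planted calls."""
        cfg, _, man = small_sim
        sim_cfg = SimulationConfig(**{**vars(cfg), "n_de_genes": 3000,
                                      "n_up_a": 150, "n_down_a": 80,
                                      "n_shared": 40, "n_b_exclusive": 60})
        de_a, de_b, truth = simulate_de(man, seed=2, config=sim_cfg)
        recs = apply_de_thresholds(de_a)
        assert {r.gene_id: r.call for r in recs} == truth["call_a"]
        counts = de_call_counts(recs)
        assert counts["up"] == 150 and counts["down"] == 80

    def test_enrichment_truth_closure(self, small_sim):
        """(N, K, n, k) recomputed from tables equals the manifest truth."""
        cfg, _, man = small_sim
        sim_cfg = SimulationConfig(**{**vars(cfg), "n_de_genes": 3000,
                                      "n_up_a": 150, "n_down_a": 80})
        de_a, _, truth = simulate_de(man, seed=6, config=sim_cfg)
        flags = dict(zip(man.de_truth["gene_id"], man.de_truth["has_itr"]))
        recs = apply_de_thresholds(de_a)
        n = sum(r.call == "up" for r in recs)
        k = sum(r.call == "up" and flags[r.gene_id] for r in recs)
        assert man.enrichment_truth == {
            "N": len(recs), "K": int(sum(flags.values())), "n": n, "k": k}

    def test_null_odds_ratio_is_unenriched(self, small_sim):
        """itr_odds_ratio=1: the up-call rate of ITR genes is baseline."""
        cfg, _, man = small_sim
        rates = []
        for seed in range(10):
            null_cfg = SimulationConfig(**{**vars(cfg), "n_de_genes": 4000,
                                           "n_up_a": 400, "n_down_a": 0,
                                           "itr_odds_ratio": 1.0})
            _, _, truth = simulate_de(man, seed=seed, config=null_cfg)
            rates.append(truth["k"] / truth["K"])
        assert abs(np.mean(rates) - 0.1) < 0.02  # baseline 400/4000


def test_decay_sequence_statistics(rng):
    n_sub = 0
    trials = 300
    for _ in range(trials):
        _, s, _ = decay_sequence(CONSENSUS, 0.10, rng)
        n_sub += s
    rate = n_sub / (trials * len(CONSENSUS))
    assert abs(rate - 0.10) < 0.015


def test_simulate_counts_deterministic(small_sim):
    _, _, man = small_sim
    c1 = simulate_counts(man, seed=5)
    c2 = simulate_counts(man, seed=5)
    assert c1.equals(c2)
    assert set(c1["gene_id"]) == {g.gene_id for g in man.gene_models}


def test_presets_resolve():
    assert preset("small").genome_length == 200_000
    big = preset("paper-scale")
    assert big.n_peaks == 875 and big.n_de_genes == 16_776
    with pytest.raises(ValueError):
        preset("huge")
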