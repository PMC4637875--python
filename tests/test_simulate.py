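"""Tests for the synthetic-data generators: planted truth, determinism,
and statistical structure."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mirderep.quant import dominant_isoform_counts, filter_reads, match_to_hairpins
from mirderep.simulate import (
    ExprSimConfig,
    ReadSimConfig,
    ScoreDistribution,
    gen_de_table,
    gen_expression,
    gen_hairpins,
    gen_signatures,
    gen_smallrna_fastq,
    write_fastq,
)


class TestGenHairpins:
    def test_deterministic_given_seed(self):
        a = gen_hairpins(3, 60, seed=7)
        b = gen_hairpins(3, 60, seed=7)
        assert a == b
        assert all(len(s) == 60 for s in a.values())

    def test_single_record(self):
        hp = gen_hairpins(1, 40, seed=0)
        assert len(hp) == 1

    def test_pairwise_distinct_exhaustive(self):
        seqs = list(gen_hairpins(50, 80, seed=1).values())
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                hamming = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                assert hamming > 0

    def test_adapter_never_embedded(self):
        for s in gen_hairpins(30, 80, seed=5).values():
            assert "TGGAAT" not in s

    @pytest.mark.parametrize("n,length", [(0, 60), (3, 20)])
    def test_invalid_config(self, n, length):
        with pytest.raises(ValueError):
            gen_hairpins(n, length, seed=0)


class TestGenSmallRNAFastq:
    def _cfg(self, **kw):
        hp = gen_hairpins(2, 60, seed=11, names=["mirA", "mirB"])
        base = dict(n_reads=1000, composition={"mirA": 0.7, "mirB": 0.3}, seed=2)
        base.update(kw)
        return ReadSimConfig(**base), hp

    def test_planted_failure_counts_exact(self):
        cfg, hp = self._cfg(n_qc_fail=50, n_no_adapter=30, n_short_insert=40,
                            n_ambiguous=20)
        reads, truth = gen_smallrna_fastq(cfg, hp)
        assert len(reads) == 1000
        assert (truth.n_qc_fail, truth.n_no_adapter, truth.n_short_insert,
                truth.n_ambiguous, truth.n_clean) == (50, 30, 40, 20, 860)
        # the filter recovers exactly the planted partition
        clean, rep = filter_reads(reads)
        assert (rep.n_qc_fail, rep.n_no_adapter, rep.n_too_short,
                rep.n_ambiguous, rep.n_pass) == (50, 30, 40, 20, 860)

    def test_composition_within_multinomial_bound(self):
        cfg, hp = self._cfg(n_reads=10_000)
        _, truth = gen_smallrna_fastq(cfg, hp)
        frac = truth.clean_counts["mirA"] / truth.n_clean
        bound = 3 * math.sqrt(0.7 * 0.3 / 10_000)
        assert abs(frac - 0.7) <= bound

    def test_error_free_inserts_are_exact_substrings(self):
        cfg, hp = self._cfg(seq_error_rate=0.0)
        reads, _ = gen_smallrna_fastq(cfg, hp)
        clean, _ = filter_reads(reads)
        assert all(any(ins in s for s in hp.values()) for ins in clean)

    def test_fastq_bytes_reproducible(self, tmp_path):
        cfg, hp = self._cfg(n_qc_fail=10)
        for name in ("a.fastq", "b.fastq"):
            reads, _ = gen_smallrna_fastq(cfg, hp)
            write_fastq(reads, tmp_path / name)
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()

    def test_quantifier_recovers_planted_truth_exactly(self):
        cfg, hp = self._cfg(n_reads=5000, n_qc_fail=100)
        reads, truth = gen_smallrna_fastq(cfg, hp)
        clean, _ = filter_reads(reads)
        profile = dominant_isoform_counts(match_to_hairpins(clean, hp))
        assert profile.dominant_counts() == truth.dominant_counts

    def test_isomir_structure_with_wider_insert_range(self):
        cfg, hp = self._cfg(insert_len_range=(20, 24))
        reads, truth = gen_smallrna_fastq(cfg, hp)
        clean, _ = filter_reads(reads)
        profile = dominant_isoform_counts(match_to_hairpins(clean, hp))
        assert any(h.n_isoforms > 1 for h in profile.hairpins.values())
        assert profile.dominant_counts() == truth.dominant_counts
        for name, h in profile.hairpins.items():
            assert h.dominant_count <= h.total_count == truth.clean_counts[name]

    def test_overplanted_failures_rejected(self):
        with pytest.raises(ValueError):
            self._cfg(n_reads=100, n_qc_fail=60, n_no_adapter=50)

    def test_composition_must_sum_to_one(self):
        hp = gen_hairpins(2, 60, seed=0, names=["a", "b"])
        with pytest.raises(ValueError):
            ReadSimConfig(n_reads=10, composition={"a": 0.5, "b": 0.4})

    def test_unknown_composition_name_rejected(self):
        cfg, _ = self._cfg()
        with pytest.raises(ValueError):
            gen_smallrna_fastq(cfg, gen_hairpins(1, 60, seed=3))


class TestGenExpression:
    def test_zero_beta_means_zero_true_lfc(self):
        sim = gen_expression(ExprSimConfig(n_genes=500, beta=0.0, seed=1))
        assert (sim.truth["true_lfc"] == 0).all()

    def test_true_lfc_is_beta_times_abs_score(self):
        sim = gen_expression(ExprSimConfig(n_genes=2000, beta=1.0, seed=4))
        t = sim.truth[sim.truth["is_target"]]
        assert np.allclose(t["true_lfc"], np.abs(t["score"]))
        nontargets = sim.truth[~sim.truth["is_target"]]
        assert (nontargets["true_lfc"] == 0).all()

    def test_target_count_is_exact(self):
        sim = gen_expression(ExprSimConfig(n_genes=10_000, frac_targets=0.2, seed=0))
        assert int(sim.truth["is_target"].sum()) == 2000
        assert set(sim.scores.loc[sim.scores["mirna"] == "mmu-miR-150", "gene"]) == \
            set(sim.truth.loc[sim.truth["is_target"], "gene"])

    def test_mean_true_lfc_identity(self):
        """Construction identity: mean true_lfc over targets equals
        beta * mean |score|."""
        cfg = ExprSimConfig(n_genes=3000, beta=0.7, seed=9)
        sim = gen_expression(cfg)
        t = sim.truth[sim.truth["is_target"]]
        assert t["true_lfc"].mean() == pytest.approx(
            cfg.beta * np.abs(t["score"]).mean(), rel=1e-12)

    def test_deterministic_given_seed(self):
        a = gen_expression(ExprSimConfig(n_genes=300, seed=5))
        b = gen_expression(ExprSimConfig(n_genes=300, seed=5))
        assert a.expr.equals(b.expr) and a.scores.equals(b.scores)

    def test_indirect_effects_planted_on_nontargets(self):
        sim = gen_expression(ExprSimConfig(n_genes=2000, n_indirect_up=50,
                                           n_indirect_down=80, seed=2))
        down = sim.truth[sim.truth["effect"] == "indirect_down"]
        assert len(down) == 80 and (down["true_lfc"] < 0).all()
        assert not down["is_target"].any()

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ExprSimConfig(beta=-1.0)
        with pytest.raises(ValueError):
            ExprSimConfig(n_replicates_per_arm=1)
        with pytest.raises(ValueError):
            ExprSimConfig(frac_targets=1.2)


class TestGenDETable:
    def test_identical_arms_give_zero_lfc(self):
        sim = gen_expression(ExprSimConfig(n_genes=100, beta=0.0, noise_sd=0.0, seed=1))
        de = gen_de_table(sim.expr, sim.wt_samples, sim.ko_samples)
        assert de["log2fc"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_planted_effect_detected(self):
        cfg = ExprSimConfig(n_genes=400, frac_targets=0.0, frac_background=0.0,
                            n_indirect_up=1, indirect_lfc=1.0, noise_sd=0.1,
                            n_replicates_per_arm=6, seed=7)
        sim = gen_expression(cfg)
        de = gen_de_table(sim.expr, sim.wt_samples, sim.ko_samples)
        gene = sim.truth.loc[sim.truth["effect"] == "indirect_up", "gene"].iloc[0]
        assert de.loc[de["gene"] == gene, "q"].iloc[0] < 0.05

    def test_single_replicate_arm_rejected(self):
        sim = gen_expression(ExprSimConfig(n_genes=50, seed=1))
        with pytest.raises(ValueError):
            gen_de_table(sim.expr, sim.wt_samples[:1], sim.ko_samples)

    def test_q_monotone_with_p(self):
        sim = gen_expression(ExprSimConfig(n_genes=300, seed=8))
        de = gen_de_table(sim.expr, sim.wt_samples, sim.ko_samples)
        ordered = de.sort_values("p")
        assert ordered["q"].is_monotonic_increasing


class TestGenSignatures:
    UNIVERSE = [f"g{i:05d}" for i in range(10_000)]

    def test_uniform_overlap_at_enrichment_one(self, rng):
        de = set(rng.choice(self.UNIVERSE, size=300, replace=False))
        sigs = gen_signatures(self.UNIVERSE, {"s": sorted(de)}, sizes=200,
                              planted_enrichment=1.0, seed=3)
        overlap = len(sigs["s"] & de)
        # expectation 6; allow generous binomial sampling slack
        assert overlap <= 20

    def test_planted_enrichment_three_gives_expected_overlap(self, rng):
        de = set(rng.choice(self.UNIVERSE, size=300, replace=False))
        sigs = gen_signatures(self.UNIVERSE, {"s": sorted(de)}, sizes=200,
                              planted_enrichment=3.0, seed=3)
        assert len(sigs["s"] & de) == 18  # round(3 * 200*300/10000)

    def test_empty_designated_set_gives_zero_overlap(self):
        sigs = gen_signatures(self.UNIVERSE, {"s": []}, sizes=50, seed=0)
        assert len(sigs["s"]) == 50

    def test_signatures_disjoint_by_default(self, rng):
        up = sorted(rng.choice(self.UNIVERSE, size=300, replace=False))
        sigs = gen_signatures(self.UNIVERSE,
                              {"naive": up, "memory": up, "effector": []},
                              sizes=200, planted_enrichment=2.0, seed=1)
        names = list(sigs)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (sigs[a] & sigs[b])

    def test_oversized_signature_rejected(self):
        with pytest.raises(ValueError):
            gen_signatures(["a", "b", "c"], {"s": []}, sizes=10, seed=0)


def test_score_distribution_support():
    scores = ScoreDistribution(offset=0.1, scale=0.1).sample(
        np.random.default_rng(0), 5000)
    assert (scores <= -0.1).all()
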