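"""Signature derivation, t-score scoring, similarity and enrichment."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preclin import (
    ConfigError,
    ExprSimConfig,
    InputError,
    Signature,
    derive_signature,
    fisher_enrichment,
    score_sample,
    score_samples,
    signature_similarity,
    simulate_expression,
)
from preclin.signature import T_SATURATION


class TestDeriveSignature:
    def test_recovers_embedded_signature_on_panel(self):
        """Strong 50-up/50-down panel (no null background): exact recovery."""
        cfg = ExprSimConfig(
            n_genes=100, n_up=50, n_down=50, effect=2.0, noise_sd=0.25, seed=4
        )
        sim = simulate_expression(cfg)
        sig = derive_signature(sim.expr, sim.groups)
        assert sig.up_genes == sim.up_genes
        assert sig.down_genes == sim.down_genes

    def test_transcriptome_background_contains_truth_with_bh_level_leakage(self):
        """With 1,900 null genes, BH at 0.05 admits ~5 expected false
        positives (threshold ~ 0.05 k/m); truth must still be contained and
        the false count within a 3-sigma Poisson bound of that expectation."""
        cfg = ExprSimConfig(
            n_genes=2000, n_up=50, n_down=50, effect=3.0, noise_sd=0.3, seed=9
        )
        sim = simulate_expression(cfg)
        sig = derive_signature(sim.expr, sim.groups)
        assert sim.up_genes <= sig.up_genes
        assert sim.down_genes <= sig.down_genes
        false = len(sig.genes - (sim.up_genes | sim.down_genes))
        assert false <= 12  # Poisson(4.75) + 3 sd, rounded up

    def test_null_contrast_selects_nothing(self):
        sim = simulate_expression(ExprSimConfig(effect=0.0, seed=21))
        sig = derive_signature(sim.expr, sim.groups)
        assert len(sig.genes) == 0

    def test_invalid_threshold_rejected(self):
        sim = simulate_expression(ExprSimConfig(n_genes=10, n_up=2, n_down=2))
        with pytest.raises(ConfigError):
            derive_signature(sim.expr, sim.groups, fdr_threshold=0.0)

    def test_single_sample_group_rejected(self):
        sim = simulate_expression(ExprSimConfig(n_genes=10, n_up=2, n_down=2))
        groups = sim.groups.copy()
        groups.iloc[1:] = "KD"
        with pytest.raises(InputError):
            derive_signature(sim.expr, groups)


SIG = Signature(
    "toy",
    up_genes=frozenset(f"u{i}" for i in range(5)),
    down_genes=frozenset(f"d{i}" for i in range(5)),
)


class TestScoreSample:
    def test_sample_equal_to_pattern_saturates(self):
        sample = SIG.pattern().rename("s")
        score = score_sample(sample, SIG)
        assert score.saturated and score.t == T_SATURATION and score.r == 1.0

    def test_orthogonal_sample_scores_zero(self):
        pattern = SIG.pattern()
        sample = pd.Series(0.0, index=pattern.index, name="s")
        # orthogonal to the pattern: equal values on up and down genes,
        # half +1 half -1 within each, so the cross-covariance vanishes
        for half, genes in enumerate((sorted(SIG.up_genes), sorted(SIG.down_genes))):
            sample[genes[:2]] = 1.0
            sample[genes[2:4]] = -1.0
        score = score_sample(sample, SIG)
        assert score.t == pytest.approx(0.0, abs=1e-12)

    def test_shift_and_positive_scale_invariance(self, rng):
        sample = pd.Series(
            rng.normal(size=10), index=sorted(SIG.genes), name="s"
        )
        base = score_sample(sample, SIG)
        moved = score_sample(sample * 3.7 + 11.0, SIG)
        assert moved.t == pytest.approx(base.t, rel=1e-10)
        assert moved.r == pytest.approx(base.r, rel=1e-10)

    def test_insufficient_overlap_rejected(self):
        sample = pd.Series([1.0, 2.0], index=["u0", "d0"], name="s")
        with pytest.raises(InputError):
            score_sample(sample, SIG)

    def test_group_two_scores_above_group_one(self):
        """Samples from the signature-bearing group score higher against
        the true pattern than control samples."""
        sim = simulate_expression(ExprSimConfig(seed=13))
        truth = Signature("truth", sim.up_genes, sim.down_genes)
        scores = score_samples(sim.expr, truth)
        kd = scores.loc[sim.groups[sim.groups == "KD"].index, "t"]
        wt = scores.loc[sim.groups[sim.groups == "WT"].index, "t"]
        assert kd.min() > wt.max()

    def test_cohort_median_centering_changes_scale_not_ranking(self):
        sim = simulate_expression(ExprSimConfig(seed=13))
        truth = Signature("truth", sim.up_genes, sim.down_genes)
        raw = score_samples(sim.expr, truth)["t"]
        centered = score_samples(sim.expr, truth, center_genes=True)["t"]
        kd = sim.groups[sim.groups == "KD"].index
        wt = sim.groups[sim.groups == "WT"].index
        assert centered[kd].min() > centered[wt].max()
        assert not np.allclose(raw, centered)


class TestSimilarity:
    def test_pattern_with_itself_saturates(self):
        pat = SIG.pattern()
        res = signature_similarity(pat, SIG)
        assert res.saturated and res.r == 1.0

    def test_negated_pattern_anticorrelates(self):
        res = signature_similarity(-SIG.pattern(), SIG)
        assert res.r == -1.0 and res.t == -T_SATURATION

    def test_symmetry_in_arguments(self, rng):
        a = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        b = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        r1 = signature_similarity(a, b)
        r2 = signature_similarity(b, a)
        assert r1.t == pytest.approx(r2.t) and r1.n == r2.n

    def test_null_type_one_error_calibrated(self, rng):
        """Independent length-100 patterns: t ~ Student t(98), so the
        two-sided p rejects at ~5% (within 3 SE over 4,000 draws)."""
        n_draws, n = 4000, 100
        idx = [f"g{i}" for i in range(n)]
        rejections = 0
        for _ in range(n_draws):
            a = pd.Series(rng.normal(size=n), index=idx)
            b = pd.Series(rng.normal(size=n), index=idx)
            rejections += signature_similarity(a, b).p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_draws)
        assert abs(rejections / n_draws - 0.05) <= 3 * se


def exact_hypergeom_tail(k, M, K, n):
    """Brute-force upper-tail P(X >= k) by exact rational enumeration."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(M - K, n - j), comb(M, n))
    return float(total)


class TestFisherEnrichment:
    universe = {f"g{i}" for i in range(20)}

    def test_degenerate_full_overlap_has_no_signal(self):
        res = fisher_enrichment(self.universe, self.universe, self.universe)
        assert res.p_one_sided == 1.0 and res.z == 0.0

    def test_complete_overlap_matches_enumeration(self):
        q = {f"g{i}" for i in range(5)}
        res = fisher_enrichment(q, q, self.universe)
        assert res.p_one_sided == pytest.approx(
            exact_hypergeom_tail(5, 20, 5, 5), abs=1e-14
        )
        assert res.z > 0

    def test_overlap_at_expectation_gives_zero_z(self):
        # universe 20, query 10, target 10 -> expected overlap 5
        q = {f"g{i}" for i in range(10)}
        t = {f"g{i}" for i in range(5, 15)}
        res = fisher_enrichment(q, t, self.universe)
        assert res.overlap == 5 == res.expected
        assert res.z == 0.0

    def test_below_expectation_overlap_gives_negative_z(self):
        # expected overlap 5; observed 3 -> one-sided p < 1, sign negative
        q = {f"g{i}" for i in range(10)}
        t = {f"g{i}" for i in range(3)} | {f"g{i}" for i in range(10, 17)}
        res = fisher_enrichment(q, t, self.universe)
        assert res.overlap == 3 < res.expected
        assert res.z < 0

    def test_complete_depletion_saturates_p_at_one_with_zero_z(self):
        # overlap 0 with one-sided over-representation p = 1: the one-sided
        # convention carries no depletion signal, so z collapses to 0
        q = {f"g{i}" for i in range(10)}
        t = {f"g{i}" for i in range(10, 20)}
        res = fisher_enrichment(q, t, self.universe)
        assert res.overlap == 0 and res.p_one_sided == 1.0 and res.z == 0.0

    def test_non_subset_rejected(self):
        with pytest.raises(InputError):
            fisher_enrichment({"zzz"}, set(), self.universe)
        with pytest.raises(InputError):
            fisher_enrichment(set(), {"zzz"}, self.universe)

    def test_tiny_universe_rejected(self):
        with pytest.raises(InputError):
            fisher_enrichment(set(), set(), {"a", "b", "c"})

    @pytest.mark.parametrize("M", [4, 7, 12])
    def test_matches_exact_enumeration_small_universes(self, M):
        genes = [f"g{i}" for i in range(M)]
        for K, n in itertools.product(range(M + 1), repeat=2):
            target = set(genes[:K])
            for k in range(max(0, n + K - M), min(n, K) + 1):
                query = set(genes[:k]) | set(genes[K : K + n - k])
                res = fisher_enrichment(query, target, genes)
                assert res.overlap == k
                assert res.p_one_sided == pytest.approx(
                    exact_hypergeom_tail(k, M, K, n), abs=1e-12
                )
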