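"""Signature derivation, scoring, ROC, selection, FDR, AUC comparisons."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cortsig.signatures import (
    SignatureMask,
    area_weighted_mean,
    benjamini_hochberg,
    compare_aucs,
    compare_effect_domains,
    derive_candidates,
    evaluate_signatures,
    roc_auc,
    select_ideal_signature,
    signature_score,
)
from cortsig.staging import split_reference
from cortsig.surface import geodesic_disc
from cortsig.synthetic import generate_cohort

from conftest import null_config, tiny_config


def brute_force_auc(scores, labels):
    """Concordant-pair fraction with half-credit ties (the rank-free oracle)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            wins += 1.0
        elif p == n:
            wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_lower_positive(self):
        res = roc_auc(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 1, 0, 0]))
        assert res.auc == 1.0

    def test_concordant_pair_counting(self):
        # class0 {1,3}, class1 {2,4}, higher = positive: 3 of 4 pairs concordant
        res = roc_auc(
            np.array([1.0, 3.0, 2.0, 4.0]),
            np.array([0, 0, 1, 1]),
            positive_is_lower=False,
        )
        assert res.auc == 0.75

    def test_all_ties_give_half(self):
        res = roc_auc(np.ones(10), np.repeat([0, 1], 5))
        assert res.auc == 0.5

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = rng.integers(4, 21)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            if labels.min() == labels.max():
                continue
            res = roc_auc(scores, labels, positive_is_lower=False)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_curve_trapezoid_consistency(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        assert abs(res.auc - res.curve_area()) <= 1e-9

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores * 2.0) + 5.0, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.zeros(4, dtype=int))

    def test_gaussian_shift_closed_form(self):
        """Two unit-variance Gaussians separated by d have AUC = Phi(d/sqrt(2))."""
        rng = np.random.default_rng(7)
        d = 1.2
        reps = 50
        aucs = []
        for _ in range(reps):
            a = rng.normal(0.0, 1.0, 200)
            b = rng.normal(d, 1.0, 200)
            scores = np.concatenate([a, b])
            labels = np.repeat([0, 1], 200)
            aucs.append(roc_auc(scores, labels, positive_is_lower=False).auc)
        expected = stats.norm.cdf(d / np.sqrt(2.0))
        se = np.std(aucs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(aucs) - expected) <= 3 * se


class TestSignatureScore:
    def test_uniform_map_any_mask(self, tiny_cohort):
        mask = {
            h: geodesic_disc(m, 0, 30.0) for h, m in tiny_cohort.meshes.items()
        }
        sig = SignatureMask(mask, ("CS-", "IMP+"), 0.01, 0.001, 1.0)
        subject = tiny_cohort.subjects[0]
        saved = {h: subject.thickness[h] for h in mask}
        try:
            for h in mask:
                subject.thickness[h] = np.full_like(subject.thickness[h], 2.5)
            assert signature_score(subject, sig, tiny_cohort.meshes) == pytest.approx(2.5)
        finally:
            subject.thickness.update(saved)

    def test_two_vertex_weighted_mean(self):
        values = np.array([2.0, 4.0, 99.0])
        areas = np.array([1.0, 3.0, 50.0])
        mask = np.array([True, True, False])
        assert area_weighted_mean(values, areas, mask) == pytest.approx(3.5)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(2.5, 0.3, 500)
        areas = rng.uniform(0.5, 2.0, 500)
        mask = rng.random(500) < 0.3
        expected = float((areas[mask] * values[mask]).sum() / areas[mask].sum())
        assert area_weighted_mean(values, areas, mask) == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_unusable(self, tiny_cohort):
        empty = SignatureMask(
            {h: np.zeros(m.n_vertices, dtype=bool) for h, m in tiny_cohort.meshes.items()},
            ("CS-", "IMP+"),
            0.01,
            0.001,
            0.0,
        )
        with pytest.raises(ValueError, match="empty"):
            signature_score(tiny_cohort.subjects[0], empty, tiny_cohort.meshes)


class TestBenjaminiHochberg:
    def bh_oracle(self, p):
        """Step-up definition computed directly."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    @pytest.mark.parametrize(
        "pvals",
        [
            [0.01, 0.02, 0.03, 0.04],
            [0.001] * 10,
            [0.5, 0.04, 0.9, 0.002, 0.03],
            [1.0, 0.0001],
        ],
    )
    def test_matches_step_up_oracle(self, pvals):
        assert np.allclose(benjamini_hochberg(pvals), self.bh_oracle(pvals), atol=1e-12)

    def test_known_example(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.random(40)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestDeriveAndSelect:
    def test_candidates_cover_grid_and_nest(self, tiny_cohort):
        cands = derive_candidates(
            tiny_cohort,
            ("CS-", "IMP+"),
            vertex_p_grid=(0.01, 0.0005),
            cluster_p=0.05,
            n_perm=199,
            seed=0,
        )
        assert len(cands) == 2
        loose, strict = cands
        assert not loose.is_empty and not strict.is_empty
        for hemi in ("left", "right"):
            assert np.all(~strict.masks[hemi] | loose.masks[hemi])

    def test_surviving_cluster_overlaps_seeded_patch(self, tiny_cohort):
        cands = derive_candidates(
            tiny_cohort,
            ("CS-", "IMP+"),
            vertex_p_grid=(0.01,),
            cluster_p=0.05,
            n_perm=199,
            seed=1,
        )
        cand = cands[0]
        # every retained vertex lies in the seeded patch, and at this sample
        # size at least the (stronger) right-hemisphere patch is detected
        total_overlap = 0
        for hemi in ("left", "right"):
            mask = cand.masks[hemi]
            assert np.all(~mask | tiny_cohort.truth_masks[hemi])
            total_overlap += int((mask & tiny_cohort.truth_masks[hemi]).sum())
        assert total_overlap > 0

    def test_low_n_perm_warns(self, tiny_cohort):
        with pytest.warns(RuntimeWarning, match="n_perm"):
            derive_candidates(
                tiny_cohort,
                ("CS-", "IMP+"),
                vertex_p_grid=(0.01,),
                cluster_p=0.001,
                n_perm=50,
                seed=2,
            )

    def test_selection_argmax_and_tie_break(self, tiny_cohort):
        mesh = tiny_cohort.meshes
        big = {h: geodesic_disc(m, 40, 40.0) for h, m in mesh.items()}
        # a mask inside the true effect patch vs an off-effect mask
        true_like = {h: tiny_cohort.truth_masks[h].copy() for h in mesh}
        cands = [
            SignatureMask(big, ("CS-", "IMP+"), 0.05, 0.001, 500.0),
            SignatureMask(true_like, ("CS-", "IMP+"), 0.01, 0.001, 300.0),
        ]
        selected, roc = select_ideal_signature(cands, ("CS-", "IMP+"), tiny_cohort)
        assert selected is not None
        assert roc.auc >= 0.5
        # explicit tie-break: equal AUC prefers the smaller area
        dup_small = SignatureMask(true_like, ("CS-", "IMP+"), 0.005, 0.001, 100.0)
        dup_large = SignatureMask(true_like, ("CS-", "IMP+"), 0.05, 0.001, 200.0)
        chosen, _ = select_ideal_signature([dup_large, dup_small], ("CS-", "IMP+"), tiny_cohort)
        assert chosen is dup_small

    def test_all_empty_returns_no_signature(self, tiny_cohort):
        empty = SignatureMask(
            {h: np.zeros(m.n_vertices, dtype=bool) for h, m in tiny_cohort.meshes.items()},
            ("CS-", "IMP+"),
            0.01,
            0.001,
            0.0,
        )
        mask, roc = select_ideal_signature([empty], ("CS-", "IMP+"), tiny_cohort)
        assert mask is None and roc is None


class TestEvaluateSignatures:
    def test_full_cross_with_fdr(self, tiny_cohort):
        cands = derive_candidates(
            tiny_cohort,
            ("CS-", "IMP+"),
            vertex_p_grid=(0.01, 0.001),
            cluster_p=0.01,
            n_perm=199,
            seed=3,
        )
        table = evaluate_signatures(cands, tiny_cohort)
        usable = [c for c in cands if not c.is_empty]
        assert len(table) == 3 * len(usable)
        assert np.all(table["p_fdr"] >= table["p_raw"] - 1e-15)
        assert table["auc"].between(0, 1).all()
        # signatures seeded on true patches should separate CS- from IMP+
        best = table[table["comparison"] == "CS-_vs_IMP+"]["auc"].max()
        assert best > 0.8

    def test_null_cohort_fdr_control(self):
        """Random candidate masks on a no-effect cohort: essentially nothing
        survives FDR at q=0.05."""
        cohort = generate_cohort(null_config(30, 20), seed=50)
        split_reference(cohort, seed=51)
        rng = np.random.default_rng(52)
        cands = []
        for k in range(12):
            masks = {
                h: geodesic_disc(m, int(rng.integers(m.n_vertices)), 25.0)
                for h, m in cohort.meshes.items()
            }
            cands.append(SignatureMask(masks, ("CS-", "IMP+"), 0.01, 0.001, 1.0))
        table = evaluate_signatures(cands, cohort, comparisons=(("CS-", "IMP+"),))
        assert (table["p_fdr"] < 0.05).mean() <= 0.05


class TestEffectDomainComparison:
    def test_identical_lists_t_zero(self):
        out = compare_effect_domains([0.5, 0.7, 0.9], [0.5, 0.7, 0.9])
        assert out["t"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        out = compare_effect_domains([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert out["t"] == np.inf
        assert out["degenerate"] == "zero variance"
        assert out["mean_cortical"] - out["mean_subcortical"] == pytest.approx(1.0)

    def test_matches_welch_formula(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.2, 0.3, 24)
        b = rng.normal(0.8, 0.5, 14)
        out = compare_effect_domains(a, b)
        sa2, sb2 = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sa2 + sb2)
        assert out["t"] == pytest.approx(t_oracle, rel=1e-12)

    def test_singleton_means_only(self):
        out = compare_effect_domains([1.0], [0.5])
        assert out["t"] is None


class TestCompareAucs:
    def _roc_pair(self, seed, shift_a, shift_b, n=50):
        rng = np.random.default_rng(seed)
        labels = np.repeat([0, 1], n)
        base = rng.normal(size=2 * n)
        sa = base + shift_a * labels
        sb = rng.normal(size=2 * n) + shift_b * labels
        return (
            roc_auc(sa, labels, positive_is_lower=False, comparison=("CS-", "IMP+")),
            roc_auc(sb, labels, positive_is_lower=False, comparison=("CS-", "IMP+")),
        )

    def test_identical_scores_p_one(self):
        labels = np.repeat([0, 1], 20)
        scores = np.random.default_rng(9).normal(size=40)
        a = roc_auc(scores, labels, positive_is_lower=False, comparison=("CS-", "CS+"))
        b = roc_auc(scores, labels, positive_is_lower=False, comparison=("CS-", "CS+"))
        out = compare_aucs(a, b, paired=True)
        assert out["p"] == 1.0

    def test_separated_vs_null_significant(self):
        a, b = self._roc_pair(10, shift_a=3.0, shift_b=0.0)
        out = compare_aucs(a, b, paired=True)
        assert out["p"] < 0.001

    def test_mismatched_comparison_rejected(self):
        labels = np.repeat([0, 1], 10)
        rng = np.random.default_rng(11)
        a = roc_auc(rng.normal(size=20), labels, comparison=("CS-", "CS+"))
        b = roc_auc(rng.normal(size=20), labels, comparison=("CS+", "IMP+"))
        with pytest.raises(ValueError):
            compare_aucs(a, b)

    def test_bootstrap_deterministic(self):
        a, b = self._roc_pair(12, shift_a=1.0, shift_b=0.5)
        out1 = compare_aucs(a, b, paired=False, n_boot=300, seed=5)
        out2 = compare_aucs(a, b, paired=False, n_boot=300, seed=5)
        assert out1 == out2
        assert out1["method"] == "bootstrap"
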