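import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryo3d.evaluation import (ConfusionStats, confusion_stats,
                                 delong_paired_test, mann_whitney, roc_auc,
                                 subgroup_auc, two_way_anova, wald_ci,
                                 youden_cutoff)

# ---------------------------------------------------------------------------
# independent oracles


def auc_pair_counting(scores, labels):
    """Brute-force Mann-Whitney estimator: wins + half-ties over all
    positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    """Best J over every midpoint threshold, computed by explicit loops."""
    s = sorted(set(scores))
    candidates = [(a + b) / 2 for a, b in zip(s[:-1], s[1:])] + [s[0] - 1, s[-1]]
    best_j, best_t = -np.inf, None
    for t in sorted(candidates):
        tp = sum(1 for x, y in zip(scores, labels) if y == 1 and x >= t)
        fn = sum(1 for x, y in zip(scores, labels) if y == 1 and x < t)
        tn = sum(1 for x, y in zip(scores, labels) if y == 0 and x < t)
        fp = sum(1 for x, y in zip(scores, labels) if y == 0 and x >= t)
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j >= best_j - 1e-12:  # ties -> higher threshold
            best_j, best_t = max(best_j, j), t
    return best_j, best_t


# ---------------------------------------------------------------------------
# roc_auc


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0
        assert r.se == 0.0

    def test_two_pair_separation(self):
        r = roc_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_three_of_four_pairs(self):
        # positives {0.9, 0.4}, negatives {0.6, 0.2}: 3 wins of 4
        r = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(4, 201))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = rng.normal(size=n) + labels
            if rng.random() < 0.5:
                scores = np.round(scores, 1)  # force ties
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(auc_pair_counting(scores, labels),
                                          abs=1e-12)

    def test_auc_equals_trapezoid_area(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            labels = rng.integers(0, 2, size=50)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=50), 1)
            r = roc_auc(scores, labels)
            assert abs(r.auc - np.trapezoid(r.tpr, r.fpr)) < 1e-12

    def test_curve_endpoints(self):
        r = roc_auc(np.random.default_rng(0).normal(size=40),
                    np.r_[np.ones(20, int), np.zeros(20, int)])
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_ci_construction(self):
        lo, hi = wald_ci(0.774, 0.033)
        assert lo == pytest.approx(0.774 - 1.96 * 0.033)
        assert hi == pytest.approx(0.774 + 1.96 * 0.033)

    def test_se_close_to_bootstrap(self):
        rng = np.random.default_rng(3)
        n = 300
        labels = np.r_[np.ones(150, int), np.zeros(150, int)]
        scores = rng.normal(size=n) + 0.8 * labels
        r = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        boot = np.empty(2000)
        for b in range(2000):
            bp = rng.choice(pos, size=pos.size)
            bn = rng.choice(neg, size=neg.size)
            boot[b] = auc_fast(bp, bn)
        assert abs(r.se - boot.std(ddof=1)) / boot.std(ddof=1) < 0.15


def auc_fast(pos, neg):
    from scipy.stats import rankdata

    allv = np.concatenate([pos, neg])
    ranks = rankdata(allv)
    return (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size)


# ---------------------------------------------------------------------------
# DeLong paired test


class TestDeLong:
    def test_identical_models(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        s = rng.normal(size=60)
        res = delong_paired_test(s, s, labels)
        assert res.p == 1.0
        assert not res.degenerate

    def test_power_for_clear_gap(self):
        rng = np.random.default_rng(11)
        hits = 0
        n = 150
        for _ in range(200):
            labels = np.r_[np.ones(n, int), np.zeros(n, int)]
            latent = rng.normal(size=2 * n)
            a = latent + 1.25 * labels + 0.3 * rng.normal(size=2 * n)
            b = latent + 0.55 * labels + 0.3 * rng.normal(size=2 * n)
            res = delong_paired_test(a, b, labels)
            if res.p < 0.05:
                hits += 1
        assert hits >= 180  # >= 90% of replicates

    def test_type_i_error_under_permutation_null(self):
        rng = np.random.default_rng(5)
        n = 200
        base = rng.normal(size=n)
        a = base + 0.4 * rng.normal(size=n)
        b = base + 0.4 * rng.normal(size=n)
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        rejections = 0
        for _ in range(1000):
            perm = rng.permutation(n)
            res = delong_paired_test(a, b, labels[perm])
            if res.p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / 1000 <= 0.07


# ---------------------------------------------------------------------------
# Youden cut-off


class TestYouden:
    def test_perfect_separation_midpoint(self):
        r = roc_auc([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        cut = youden_cutoff(r)
        assert cut.j == pytest.approx(1.0)
        assert 0.3 < cut.threshold < 0.8
        assert cut.threshold == pytest.approx(0.55)  # midpoint convention

    def test_anti_predictive_flagged(self):
        r = roc_auc([0.9, 0.8, 0.3, 0.1], [0, 0, 1, 1])
        cut = youden_cutoff(r)
        assert cut.anti_predictive
        assert cut.j <= 0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)
            r = roc_auc(scores, labels)
            cut = youden_cutoff(r)
            best_j, _ = youden_exhaustive(list(scores), list(labels))
            assert cut.j == pytest.approx(best_j, abs=1e-12)

    def test_six_point_toy(self):
        scores = [0.9, 0.7, 0.6, 0.5, 0.3, 0.2]
        labels = [1, 1, 0, 1, 0, 0]
        r = roc_auc(scores, labels)
        cut = youden_cutoff(r)
        best_j, best_t = youden_exhaustive(scores, labels)
        assert cut.j == pytest.approx(best_j)
        assert confusion_stats(scores, labels, cut.threshold).sensitivity == \
            confusion_stats(scores, labels, best_t).sensitivity


# ---------------------------------------------------------------------------
# confusion statistics


class TestConfusion:
    def test_reference_counts(self):
        cs = ConfusionStats.from_counts(tp=72, fn=27, fp=27, tn=69)
        r = cs.rounded()
        assert r["sensitivity"] == 0.727
        assert r["specificity"] == 0.719
        assert r["ppv"] == 0.727
        assert r["npv"] == 0.719
        # the four cells sum to 195, so matrix-derived accuracy is 141/195,
        # which agrees with the independently reported 0.723
        assert r["accuracy"] == 0.723

    def test_all_ones(self):
        cs = ConfusionStats.from_counts(1, 1, 1, 1)
        assert cs.sensitivity == cs.specificity == cs.ppv == cs.npv == 0.5

    def test_threshold_above_max(self):
        cs = confusion_stats([0.2, 0.4], [1, 0], threshold=0.9)
        assert cs.sensitivity == 0.0
        assert cs.specificity == 1.0

    def test_ties_classified_positive(self):
        cs = confusion_stats([0.5, 0.5], [1, 0], threshold=0.5)
        assert cs.tp == 1 and cs.fp == 1

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=60),
           st.floats(0, 1, allow_nan=False), st.randoms())
    def test_identities_hold(self, scores, threshold, rnd):
        labels = [rnd.randint(0, 1) for _ in scores]
        cs = confusion_stats(scores, labels, threshold)
        assert cs.tp + cs.fn == sum(labels)
        assert cs.tn + cs.fp == len(labels) - sum(labels)
        if cs.tp + cs.fn:
            assert cs.sensitivity == cs.tp / (cs.tp + cs.fn)
        if cs.tn + cs.fp:
            assert cs.specificity == cs.tn / (cs.tn + cs.fp)
        if cs.total:
            assert cs.accuracy == (cs.tp + cs.tn) / cs.total


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)

    def test_fully_separated_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.p == pytest.approx(0.1)

    def test_shifted_normals(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 1.0, size=100)
        b = rng.normal(0.0, 1.0, size=100)
        assert mann_whitney(a, b).p < 1e-6

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# two-way ANOVA


class TestTwoWayAnova:
    @staticmethod
    def _grid(values_by_cell, reps):
        ys, fa, fb = [], [], []
        for (a, b), v in values_by_cell.items():
            for r in range(reps):
                ys.append(v if np.isscalar(v) else v[r])
                fa.append(a)
                fb.append(b)
        return np.array(ys), fa, fb

    def test_all_cells_equal(self):
        ys, fa, fb = self._grid({(a, b): 0.7 for a in "xy" for b in "uv"}, 3)
        res = two_way_anova(ys, fa, fb)
        assert res.p_a == 1.0 and res.p_b == 1.0

    def test_pure_additive_effect(self):
        # replicate jitter identical in every cell: factor a has exactly zero
        # effect, factor b a pure additive one
        jitter = [0.0, 1e-3, -1e-3, 5e-4]
        ys, fa, fb = [], [], []
        for a in (0, 1):
            for b in (0, 1):
                for j in jitter:
                    ys.append(0.5 + 0.2 * b + j)
                    fa.append(a)
                    fb.append(b)
        res = two_way_anova(np.array(ys), fa, fb)
        assert res.p_b < 1e-10
        assert res.p_a > 0.99

    def test_unbalanced_raises(self):
        with pytest.raises(ValueError):
            two_way_anova([1, 2, 3, 4, 5], [0, 0, 1, 1, 1], [0, 1, 0, 1, 1])

    def test_type_i_error_on_null_grid(self):
        rng = np.random.default_rng(8)
        rej_a = rej_b = 0
        n_rep = 1000
        for _ in range(n_rep):
            ys = rng.normal(size=8)
            fa = [0, 0, 0, 0, 1, 1, 1, 1]
            fb = [0, 0, 1, 1, 0, 0, 1, 1]
            res = two_way_anova(ys, fa, fb)
            rej_a += res.p_a < 0.05
            rej_b += res.p_b < 0.05
        assert 0.03 <= rej_a / n_rep <= 0.07
        assert 0.03 <= rej_b / n_rep <= 0.07


# ---------------------------------------------------------------------------
# subgroup AUC


class TestSubgroups:
    def test_single_band_equals_global(self):
        rng = np.random.default_rng(4)
        labels = np.r_[np.ones(40, int), np.zeros(40, int)]
        scores = rng.normal(size=80) + labels
        ages = np.full(80, 30.0)
        res = subgroup_auc(scores, labels, ages)
        assert res["<35"].roc.auc == roc_auc(scores, labels).auc
        assert not res["41-42"].defined

    def test_single_class_band_flagged(self):
        scores = [0.9, 0.8, 0.4, 0.2]
        labels = [1, 1, 0, 0]
        ages = [36, 36, 30, 30]  # 35-37 band holds only positives
        res = subgroup_auc(scores, labels, ages)
        assert not res["35-37"].defined
        assert res["35-37"].n_pos == 2 and res["35-37"].n_neg == 0

    def test_uniform_signal_bands_agree_with_global(self):
        rng = np.random.default_rng(12)
        n = 2000
        ages = rng.uniform(25, 46, size=n)
        labels = rng.integers(0, 2, size=n)
        scores = rng.normal(size=n) + 0.9 * labels
        glob = roc_auc(scores, labels)
        for res in subgroup_auc(scores, labels, ages).values():
            if res.defined and res.roc.se > 0:
                assert abs(res.roc.auc - glob.auc) < 3 * res.roc.se
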