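"""Statistical evaluation: ROC/AUC with DeLong variance, paired DeLong test,
Youden operating point, confusion statistics, Mann-Whitney U, balanced
two-way ANOVA and age-band subgroup AUCs.

The AUC point estimate is the Mann-Whitney pair-counting statistic (ties
counted 1/2), identical to the trapezoidal area under the empirical ROC
curve. Its standard error uses the DeLong structural components, so perfectly
separated scores get SE 0 and the paired test accounts for the correlation
between two models scored on the same cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# DeLong machinery


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components (v10, v01) and the AUC for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def _check_labels(labels: np.ndarray):
    labels = np.asarray(labels).astype(int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


@dataclass
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    curve: np.ndarray  # rows of (fpr, tpr, threshold), threshold descending

    @property
    def fpr(self):
        return self.curve[:, 0]

    @property
    def tpr(self):
        return self.curve[:, 1]

    @property
    def thresholds(self):
        return self.curve[:, 2]


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC curve over the distinct score cuts (rule: >= threshold
    is positive), from (0,0) at threshold +inf to (1,1) at the minimum score."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    thr = s[distinct]
    m, n = tps[-1], fps[-1]
    fpr = np.r_[0.0, fps / n]
    tpr = np.r_[0.0, tps / m]
    thresholds = np.r_[np.inf, thr]
    return np.column_stack([fpr, tpr, thresholds])


def roc_auc(scores, labels) -> ROCResult:
    """AUC with DeLong standard error and Wald 95% CI (auc ± 1.96·se, clipped)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    lo, hi = auc - 1.96 * se, auc + 1.96 * se
    ci = (max(0.0, lo), min(1.0, hi))
    return ROCResult(auc=float(auc), se=se, ci95=ci,
                     curve=_roc_curve(scores, labels))


def wald_ci(estimate: float, se: float, z: float = 1.96) -> tuple[float, float]:
    """The CI construction used by :func:`roc_auc`, exposed for reporting."""
    return (max(0.0, estimate - z * se), min(1.0, estimate + z * se))


class DeLongTest(NamedTuple):
    z: float
    p: float
    auc_a: float
    auc_b: float
    degenerate: bool


def delong_paired_test(scores_a, scores_b, labels) -> DeLongTest:
    """Two-sided paired DeLong test for correlated AUCs on the same cases."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("score vectors and labels must have equal length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-15:
        if abs(diff) < 1e-12:
            return DeLongTest(z=0.0, p=1.0, auc_a=float(auc_a),
                              auc_b=float(auc_b), degenerate=False)
        return DeLongTest(z=np.sign(diff) * np.inf, p=0.0, auc_a=float(auc_a),
                          auc_b=float(auc_b), degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongTest(z=float(z), p=float(p), auc_a=float(auc_a),
                      auc_b=float(auc_b), degenerate=False)


# ---------------------------------------------------------------------------
# operating point and confusion statistics


@dataclass
class CutoffResult:
    threshold: float
    j: float
    anti_predictive: bool

    def __float__(self):
        return float(self.threshold)


def youden_cutoff(roc: ROCResult) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties break toward the higher threshold. The returned value is the
    midpoint of the score interval realizing the chosen operating point, so
    for perfectly separated scores it falls between the two classes.
    """
    curve = np.asarray(roc.curve)
    if curve.shape[0] < 2:
        raise ValueError("empty ROC curve")
    j = curve[:, 1] - curve[:, 0]
    jmax = j[1:].max()
    # ties (within fp tolerance) break toward the higher threshold
    best = int(np.flatnonzero(j[1:] >= jmax - 1e-12)[0]) + 1
    thr = curve[:, 2]
    # any t in (next-lower score, chosen score] realizes this operating point
    if best + 1 < thr.size:
        threshold = 0.5 * (thr[best] + thr[best + 1])
    else:
        threshold = thr[best]
    return CutoffResult(threshold=float(threshold), j=float(j[best]),
                        anti_predictive=bool(j[best] <= 0))


@dataclass
class ConfusionStats:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "ppv": round(self.ppv, ndigits),
            "npv": round(self.npv, ndigits),
            "accuracy": round(self.accuracy, ndigits),
        }

    @classmethod
    def from_counts(cls, tp: int, fn: int, fp: int, tn: int,
                    threshold: float = float("nan")) -> "ConfusionStats":
        return cls(threshold=threshold, tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))


def confusion_stats(scores, labels, threshold: float) -> ConfusionStats:
    """Confusion matrix at a cut (score >= threshold predicts positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return ConfusionStats(threshold=float(threshold), tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# rank / variance tests


class MannWhitneyResult(NamedTuple):
    u: float
    p: float


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U: exact enumeration for small tie-free samples,
    tie-corrected normal approximation otherwise (no continuity correction,
    so identical groups give p = 1)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if max(a.size, b.size) <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return MannWhitneyResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)))


class AnovaResult(NamedTuple):
    p_a: float
    p_b: float
    f_a: float
    f_b: float


def two_way_anova(values, factor_a, factor_b) -> AnovaResult:
    """Balanced two-way fixed-effects ANOVA, main effects only.

    ``values[i]`` is one replicate observed at levels ``factor_a[i]`` and
    ``factor_b[i]``; every (a, b) cell must hold the same number (>= 2) of
    replicates. Residual pools interaction and error.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    lev_a, ia = np.unique(fa, return_inverse=True)
    lev_b, ib = np.unique(fb, return_inverse=True)
    na, nb = lev_a.size, lev_b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 levels per factor")
    counts = np.zeros((na, nb), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    if counts.min() != counts.max():
        raise ValueError("unbalanced grid: unequal cell counts")
    if counts.min() < 2:
        raise ValueError("need >= 2 replicates per cell")
    gm = y.mean()
    mean_a = np.array([y[ia == i].mean() for i in range(na)])
    mean_b = np.array([y[ib == j].mean() for j in range(nb)])
    n_per_a = y.size / na
    n_per_b = y.size / nb
    ss_a = float(n_per_a * np.sum((mean_a - gm) ** 2))
    ss_b = float(n_per_b * np.sum((mean_b - gm) ** 2))
    ss_t = float(np.sum((y - gm) ** 2))
    df_a, df_b = na - 1, nb - 1
    df_e = y.size - 1 - df_a - df_b
    ss_e = max(ss_t - ss_a - ss_b, 0.0)
    ms_e = ss_e / df_e
    if ms_e == 0.0:
        # no residual variation: zero effect -> F = 0, p = 1; else p = 0
        f_a = 0.0 if ss_a == 0 else np.inf
        f_b = 0.0 if ss_b == 0 else np.inf
        return AnovaResult(p_a=1.0 if ss_a == 0 else 0.0,
                           p_b=1.0 if ss_b == 0 else 0.0, f_a=f_a, f_b=f_b)
    f_a = (ss_a / df_a) / ms_e
    f_b = (ss_b / df_b) / ms_e
    return AnovaResult(
        p_a=float(stats.f.sf(f_a, df_a, df_e)),
        p_b=float(stats.f.sf(f_b, df_b, df_e)),
        f_a=float(f_a), f_b=float(f_b),
    )


# ---------------------------------------------------------------------------
# subgroup analysis

#: Default age bands (years): [lo, hi) half-open intervals.
SART_BANDS = (
    ("<35", 0.0, 35.0),
    ("35-37", 35.0, 38.0),
    ("38-40", 38.0, 41.0),
    ("41-42", 41.0, 43.0),
    (">=43", 43.0, float("inf")),
)


@dataclass
class SubgroupResult:
    band: str
    n_pos: int
    n_neg: int
    roc: ROCResult | None  # None when the band has a single class

    @property
    def defined(self) -> bool:
        return self.roc is not None


def subgroup_auc(scores, labels, ages, bands=SART_BANDS) -> dict[str, SubgroupResult]:
    """Per-age-band ROC results; single-class bands are flagged undefined."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    ages = np.asarray(ages, dtype=float)
    out: dict[str, SubgroupResult] = {}
    for name, lo, hi in bands:
        sel = (ages >= lo) & (ages < hi)
        n_pos = int(np.sum(labels[sel] == 1))
        n_neg = int(np.sum(labels[sel] == 0))
        roc = None
        if n_pos > 0 and n_neg > 0:
            roc = roc_auc(scores[sel], labels[sel])
        out[name] = SubgroupResult(band=name, n_pos=n_pos, n_neg=n_neg, roc=roc)
    return out
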