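"""Univariate regression encoding of the nine conventional embryo evaluation
(CEE) factors.

Each clinical factor is mapped to a probability-like scalar through a fitted
univariate function (one of four families). The package ships a default
coefficient set in ``data/regression_specs.json``; :func:`fit_regression`
re-estimates coefficients from data by weighted nonlinear least squares on
the empirical outcome-rate curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Canonical factor order; feature vectors follow it.
FACTOR_ORDER = (
    "female_age",
    "n_prev_transfers",
    "amh",
    "day3_blastomeres",
    "day3_grade",
    "cryo_day",
    "icm_grade",
    "te_grade",
    "avg_diameter",
)

FAMILIES = ("scaled_logistic", "logistic", "scaled_gaussian", "linear")


@dataclass
class CEERecord:
    """One embryo's nine clinical/morphological factors."""

    female_age: float
    n_prev_transfers: float
    amh: float
    day3_blastomeres: float
    day3_grade: float
    cryo_day: float
    icm_grade: float
    te_grade: float
    avg_diameter: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FACTOR_ORDER}


@dataclass
class RegressionSpec:
    """A univariate regression family plus fitted coefficients.

    families:
      * ``scaled_logistic`` — ``k / (1 + exp(b0 + b1*x))``
      * ``logistic``        — ``1 / (1 + exp(b0 + b1*x))``
      * ``scaled_gaussian`` — ``k / sqrt(2*pi*sigma^2) * exp(-(x-m)^2 / (2*sigma^2))``
      * ``linear``          — ``b0 + b1*x``
    """

    name: str
    family: str
    params: dict[str, float]
    se: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "scaled_gaussian" and self.params.get("sigma", 1.0) <= 0:
            raise ValueError("scaled_gaussian requires sigma > 0")
        k = self.params.get("k")
        if k is not None and k <= 0:
            raise ValueError("scale k must be positive")


def _family_fn(family: str):
    if family == "scaled_logistic":
        return lambda x, b0, b1, k: k / (1.0 + np.exp(b0 + b1 * np.asarray(x, float)))
    if family == "logistic":
        return lambda x, b0, b1: 1.0 / (1.0 + np.exp(b0 + b1 * np.asarray(x, float)))
    if family == "scaled_gaussian":
        return lambda x, sigma, m, k: (
            k / np.sqrt(2.0 * np.pi * sigma ** 2)
            * np.exp(-((np.asarray(x, float) - m) ** 2) / (2.0 * sigma ** 2))
        )
    if family == "linear":
        return lambda x, b0, b1: b0 + b1 * np.asarray(x, float)
    raise ValueError(f"unknown family {family!r}")


_PARAM_NAMES = {
    "scaled_logistic": ("b0", "b1", "k"),
    "logistic": ("b0", "b1"),
    "scaled_gaussian": ("sigma", "m", "k"),
    "linear": ("b0", "b1"),
}


def eval_regression(spec: RegressionSpec, x) -> np.ndarray | float:
    """Evaluate ``spec`` at ``x`` and clip the result to [0, 1]."""
    fn = _family_fn(spec.family)
    args = [spec.params[p] for p in _PARAM_NAMES[spec.family]]
    with np.errstate(over="ignore"):
        y = np.clip(fn(x, *args), 0.0, 1.0)
    return float(y) if np.isscalar(x) else y


def load_default_specs() -> dict[str, RegressionSpec]:
    """The coefficient set bundled with the package, keyed by factor name."""
    text = resources.files("embryo3d.data").joinpath("regression_specs.json").read_text()
    raw = json.loads(text)
    return {
        name: RegressionSpec(name=name, family=d["family"], params=d["params"], se=d["se"])
        for name, d in raw.items()
    }


def load_specs(path) -> dict[str, RegressionSpec]:
    with open(path) as fh:
        raw = json.load(fh)
    out = {}
    for name, d in raw.items():
        if d.get("family") not in FAMILIES:
            raise ValueError(f"spec {name!r}: unknown family {d.get('family')!r}")
        out[name] = RegressionSpec(name=name, family=d["family"],
                                   params=d["params"], se=d.get("se", {}))
    return out


def save_specs(specs: dict[str, RegressionSpec], path) -> None:
    raw = {s.name: {"family": s.family, "params": s.params, "se": s.se}
           for s in specs.values()}
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)


def cee_feature_vector(record, specs: dict[str, RegressionSpec]) -> np.ndarray:
    """Encode one record into the ordered 9-vector of regression outputs."""
    if isinstance(record, CEERecord):
        record = record.as_dict()
    values = []
    for name in FACTOR_ORDER:
        if name not in record or record[name] is None or (
            isinstance(record[name], float) and np.isnan(record[name])
        ):
            raise ValueError(f"missing CEE factor: {name}")
        if name not in specs:
            raise ValueError(f"missing regression spec for factor: {name}")
        values.append(eval_regression(specs[name], float(record[name])))
    return np.asarray(values, dtype=np.float64)


def cee_feature_matrix(table: pd.DataFrame, specs: dict[str, RegressionSpec]) -> np.ndarray:
    """Vectorised :func:`cee_feature_vector` over a table (n × 9)."""
    missing = [c for c in FACTOR_ORDER if c not in table.columns]
    if missing:
        raise ValueError(f"missing CEE factor: {missing[0]}")
    cols = [eval_regression(specs[name], table[name].to_numpy(float))
            for name in FACTOR_ORDER]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# fitting


def _binned_rates(xs: np.ndarray, ys: np.ndarray, max_categories: int = 12,
                  n_bins: int = 10):
    """Empirical outcome rate vs x: exact categories for ordinal x, decile
    bins for continuous x. Returns (x_centers, rates, counts)."""
    uniq = np.unique(xs)
    if uniq.size <= max_categories:
        centers = uniq.astype(float)
        rates = np.array([ys[xs == u].mean() for u in uniq])
        counts = np.array([(xs == u).sum() for u in uniq])
        return centers, rates, counts
    edges = np.unique(np.quantile(xs, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, xs, side="right") - 1, 0, len(edges) - 2)
    centers, rates, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            continue
        centers.append(xs[sel].mean())
        rates.append(ys[sel].mean())
        counts.append(int(sel.sum()))
    return np.asarray(centers), np.asarray(rates), np.asarray(counts)


def _initial_guess(family: str, xc: np.ndarray, rates: np.ndarray) -> list[float]:
    r = np.clip(rates, 1e-3, 1 - 1e-3)
    if family == "linear":
        b1, b0 = np.polyfit(xc, rates, 1)
        return [b0, b1]
    if family in ("logistic", "scaled_logistic"):
        k0 = min(1.0, float(r.max()) * 1.05) if family == "scaled_logistic" else 1.0
        z = np.log(k0 / np.clip(r, 1e-3, k0 * 0.999) - 1.0 + 1e-9)
        b1, b0 = np.polyfit(xc, z, 1)
        return [b0, b1, k0] if family == "scaled_logistic" else [b0, b1]
    if family == "scaled_gaussian":
        w = np.clip(rates, 1e-6, None)
        m0 = float(np.sum(xc * w) / np.sum(w))
        s0 = float(np.sqrt(np.sum(w * (xc - m0) ** 2) / np.sum(w))) or 1.0
        k0 = float(r.max()) * np.sqrt(2 * np.pi * s0 ** 2)
        return [max(s0, 1e-2), m0, max(k0, 1e-3)]
    raise ValueError(family)


class FitError(RuntimeError):
    """Raised when the nonlinear fit does not converge; carries diagnostics."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


def fit_regression(xs, ys, family: str, name: str = "factor",
                   p0: list[float] | None = None) -> RegressionSpec:
    """Fit one regression family to binary outcomes (or rates) against x.

    The empirical outcome rate curve (exact categories for ordinal x, decile
    bins otherwise) is fitted by count-weighted nonlinear least squares;
    standard errors come from the asymptotic covariance of the fit.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have equal length")
    if xs.size < 10:
        raise ValueError("need at least 10 points")
    xc, rates, counts = _binned_rates(xs, ys)
    fn = _family_fn(family)
    pnames = _PARAM_NAMES[family]
    if p0 is None:
        p0 = _initial_guess(family, xc, rates)
    sigma = 1.0 / np.sqrt(counts)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(fn, xc, rates, p0=p0, sigma=sigma,
                                            maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"fit for {name!r} did not converge: {exc}",
                       last_params=p0) from exc
    ses = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return RegressionSpec(
        name=name, family=family,
        params={p: float(v) for p, v in zip(pnames, popt)},
        se={p: float(s) for p, s in zip(pnames, ses)},
    )


# ---------------------------------------------------------------------------
# multicollinearity screen


def multicollinearity_screen(table: pd.DataFrame, outcome=None,
                             r_threshold: float = 0.8):
    """Greedy Spearman-correlation filter.

    For every factor pair with \\|rho\\| > ``r_threshold`` one member is dropped;
    when an outcome is supplied the factor with the smaller univariate
    Mann-Whitney p-value against the outcome is kept. Constant columns are
    excluded with a warning. Returns ``(retained_names, drop_log)``.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 candidate factors")
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique() <= 1]
    for c in constant:
        warnings.warn(f"constant column {c!r} excluded from screen")
    cols = [c for c in cols if c not in constant]

    pvals: dict[str, float] = {}
    if outcome is not None:
        y = np.asarray(outcome)
        for c in cols:
            x = table[c].to_numpy(float)
            a, b = x[y == 1], x[y == 0]
            if a.size and b.size and not (np.all(a == a[0]) and np.all(b == a[0])):
                pvals[c] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            else:
                pvals[c] = 1.0

    corr = table[cols].corr(method="spearman").abs()
    pairs = [
        (corr.iloc[i, j], cols[i], cols[j])
        for i in range(len(cols)) for j in range(i + 1, len(cols))
        if corr.iloc[i, j] > r_threshold
    ]
    pairs.sort(key=lambda t: -t[0])
    dropped: set[str] = set()
    log = []
    for r, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        if outcome is not None:
            keep, drop = (a, b) if pvals[a] <= pvals[b] else (b, a)
        else:
            keep, drop = a, b
        dropped.add(drop)
        log.append({"kept": keep, "dropped": drop, "rho": float(r)})
    retained = [c for c in cols if c not in dropped]
    return retained, log
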