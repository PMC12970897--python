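"""Time-to-onset (TTO) analysis with the Weibull shape-parameter test.

TTO is the interval, in days, from the first start of therapy with the
index drug to the onset of the adverse event within the same report. The
sample is summarised by median and interquartile range and fitted with a
two-parameter Weibull distribution

    f(t) = (β/α) (t/α)^{β-1} exp(−(t/α)^β),   t > 0,

whose shape β determines how the hazard evolves: β < 1 with the whole
95% CI below 1 means a decreasing hazard ("early failure" — the risk is
concentrated shortly after treatment start); a CI containing 1 means a
constant hazard ("random"); β > 1 with CI above 1 an increasing hazard
("wear-out").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import SRSDataset, normalize_name, select_reports

__all__ = [
    "TTOSample",
    "compute_tto",
    "WeibullTTOModel",
    "WeibullTTOResults",
    "classify_failure_type",
    "tto_histogram",
]

Z95 = 1.959963984540054


@dataclass
class TTOSample:
    """Positive onset intervals in days, with exclusion bookkeeping."""

    values: np.ndarray
    n_excluded: dict = field(default_factory=dict)
    n_imputed: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and np.any(self.values <= 0):
            raise ValueError("TTO values must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    def median_iqr(self) -> tuple[float, float, float]:
        return (
            float(np.median(self.values)),
            float(np.quantile(self.values, 0.25)),
            float(np.quantile(self.values, 0.75)),
        )


def compute_tto(
    ds: SRSDataset,
    ingredients: Iterable[str],
    event_pts: Iterable[str] | None = None,
    roles: Iterable[str] | None = None,
    exclude_imputed: bool = False,
) -> TTOSample:
    """TTO per qualifying report: event onset minus the earliest start
    date of the index drug.

    Reports lacking either date are excluded (reason ``missing_date``);
    non-positive intervals are excluded (reason ``non_positive``).
    Records whose dates were imputed from partial year/month values are
    counted in ``n_imputed`` and dropped when ``exclude_imputed``.
    """
    ings = {normalize_name(i) for i in ingredients}
    _, _, both = select_reports(ds, ingredients, roles, event_pts)
    if not both:
        raise ValueError("no reports match the drug x event query")

    d = ds.drugs
    ing = d["ingredient"].map(lambda x: normalize_name(x) if pd.notna(x) else None)
    idx_drugs = d[ing.isin(ings) & d["report_id"].isin(both)]
    starts = idx_drugs.groupby("report_id").agg(
        start=("start_date", "min"), imputed=("start_date_imputed", "any")
    )

    pts = (
        {normalize_name(p) for p in event_pts}
        if event_pts is not None
        else None
    )
    ev = ds.events[ds.events["report_id"].isin(both)]
    if pts is not None:
        ev = ev[ev["pt"].map(normalize_name).isin(pts)]
    onsets = ev.groupby("report_id").agg(
        onset=("onset_date", "min"), imputed=("onset_date_imputed", "any")
    )

    values = []
    n_missing = n_nonpos = n_imputed = n_imputed_dropped = 0
    for rid in sorted(both):
        start = starts["start"].get(rid, pd.NaT)
        onset = onsets["onset"].get(rid, pd.NaT)
        if pd.isna(start) or pd.isna(onset):
            n_missing += 1
            continue
        imputed = bool(starts["imputed"].get(rid, False)) or bool(
            onsets["imputed"].get(rid, False)
        )
        days = (onset - start).days
        if days <= 0:
            n_nonpos += 1
            continue
        if imputed:
            n_imputed += 1
            if exclude_imputed:
                n_imputed_dropped += 1
                continue
        values.append(float(days))
    excl = {"missing_date": n_missing, "non_positive": n_nonpos}
    if exclude_imputed:
        excl["imputed_date"] = n_imputed_dropped
    if not values:
        raise ValueError(f"empty TTO sample (excluded: {excl})")
    return TTOSample(np.array(values), excl, n_imputed)


def _profile_equation(beta: float, x: np.ndarray, mean_log: float) -> float:
    xb = x ** beta
    return float(np.sum(xb * np.log(x)) / np.sum(xb) - 1.0 / beta - mean_log)


def _weibull_loglik(log_alpha: float, log_beta: float, x: np.ndarray) -> float:
    alpha, beta = math.exp(log_alpha), math.exp(log_beta)
    n = x.size
    return (
        n * (log_beta - beta * log_alpha)
        + (beta - 1.0) * float(np.sum(np.log(x)))
        - float(np.sum((x / alpha) ** beta))
    )


@dataclass
class WeibullTTOResults:
    """Weibull MLE (scale α in days, dimensionless shape β) with 95% CIs,
    sample median/IQR and the hazard-profile classification."""

    alpha: float
    beta: float
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    loglik: float
    n: int
    median: float
    q25: float
    q75: float
    failure_type: str = ""

    def summary(self) -> str:
        return "\n".join(
            [
                f"Weibull time-to-onset fit (n={self.n})",
                f"  median (IQR)       {self.median:.0f} ({self.q25:.0f}-{self.q75:.0f}) days",
                f"  scale alpha (95% CI)  {self.alpha:.2f} ({self.alpha_ci[0]:.2f}-{self.alpha_ci[1]:.2f})",
                f"  shape beta  (95% CI)  {self.beta:.2f} ({self.beta_ci[0]:.2f}-{self.beta_ci[1]:.2f})",
                f"  log-likelihood     {self.loglik:.3f}",
                f"  hazard profile     {self.failure_type}",
            ]
        )

    def to_row(self) -> dict:
        return {
            "n": self.n,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "alpha": self.alpha,
            "alpha_lo": self.alpha_ci[0],
            "alpha_hi": self.alpha_ci[1],
            "beta": self.beta,
            "beta_lo": self.beta_ci[0],
            "beta_hi": self.beta_ci[1],
            "failure_type": self.failure_type,
        }


class WeibullTTOModel:
    """Maximum-likelihood Weibull fit of a time-to-onset sample.

    The shape MLE solves the one-dimensional profile equation

        Σ xᵢ^β ln xᵢ / Σ xᵢ^β − 1/β = mean(ln x)

    by bracketing and root-finding; the scale then follows in closed form
    as α = (mean x^β)^{1/β}. 95% CIs come from the observed information
    on (ln α, ln β), back-transformed.
    """

    def __init__(self, sample: TTOSample | np.ndarray):
        if not isinstance(sample, TTOSample):
            sample = TTOSample(np.asarray(sample, dtype=float))
        self.sample = sample

    def fit(self) -> WeibullTTOResults:
        x = self.sample.values
        if x.size < 3:
            raise ValueError("need at least 3 TTO values")
        if np.ptp(x) == 0:
            raise ValueError("degenerate likelihood: all TTO values identical")
        mean_log = float(np.mean(np.log(x)))

        lo, hi = 1e-3, 1.0
        while _profile_equation(hi, x, mean_log) < 0:
            hi *= 2.0
            if hi > 1e4:
                raise RuntimeError("shape profile equation has no root below 1e4")
        while _profile_equation(lo, x, mean_log) > 0:
            lo /= 2.0
            if lo < 1e-8:
                raise RuntimeError("shape profile equation has no root above 1e-8")
        beta = float(optimize.brentq(lambda b: _profile_equation(b, x, mean_log), lo, hi, xtol=1e-12))
        alpha = float(np.mean(x ** beta) ** (1.0 / beta))

        la, lb = math.log(alpha), math.log(beta)
        loglik = _weibull_loglik(la, lb, x)
        hess = _numeric_hessian(lambda p: _weibull_loglik(p[0], p[1], x), np.array([la, lb]))
        cov = np.linalg.inv(-hess)
        se_la, se_lb = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        alpha_ci = (math.exp(la - Z95 * se_la), math.exp(la + Z95 * se_la))
        beta_ci = (math.exp(lb - Z95 * se_lb), math.exp(lb + Z95 * se_lb))

        med, q25, q75 = self.sample.median_iqr()
        res = WeibullTTOResults(
            alpha=alpha,
            beta=beta,
            alpha_ci=alpha_ci,
            beta_ci=beta_ci,
            loglik=loglik,
            n=x.size,
            median=med,
            q25=q25,
            q75=q75,
        )
        res.failure_type = classify_failure_type(res)
        return res


def _numeric_hessian(f, p: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = p.size
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(p + ei + ej) - f(p + ei - ej) - f(p - ei + ej) + f(p - ei - ej)
            ) / (4 * h * h)
    return hess


def classify_failure_type(fit: WeibullTTOResults) -> str:
    """Hazard-profile rule on the shape CI.

    early: β < 1 and CI upper < 1; wear-out: β > 1 and CI lower > 1;
    otherwise (CI containing or touching 1) random.
    """
    lo, hi = fit.beta_ci
    if fit.beta < 1.0 and hi < 1.0:
        return "early failure"
    if fit.beta > 1.0 and lo > 1.0:
        return "wear-out failure"
    return "random failure"


def tto_histogram(sample: TTOSample, bin_width: float = 30.0) -> pd.DataFrame:
    """Onset-interval histogram (default monthly bins); counts sum to n."""
    edges = np.arange(0.0, sample.values.max() + bin_width, bin_width)
    if edges[-1] <= sample.values.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(sample.values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
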