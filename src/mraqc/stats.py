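"""Error-rate estimation for clustered abstraction-QC data.

The error rate is the ratio of true errors detected to fields collected,

    rate = k / n,

computed against either of two denominators: every field defined for the
QC'd cases (*all-field*, optimistic) or only the fields the primary
abstractor populated (*populated-field*, conservative).  Crude intervals use
the Wald normal approximation or the Wilson score form; cluster-adjusted
estimates come from an intercept-only binomial generalized estimating
equation (GEE) with exchangeable working correlation and a cluster-robust
sandwich variance, with the confidence interval formed on the logit scale
and back-transformed (hence asymmetric).  Rate comparisons use the pooled
two-proportion z test, and error-rate trends over successive QC events are
fitted by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.proportion import proportion_confint, proportions_ztest
import statsmodels.api as sm

from .errors import (
    BoundaryEstimateWarning,
    DegenerateIntervalWarning,
    EstimationError,
    ValidationError,
)

__all__ = [
    "ErrorRateEstimate",
    "RateDifference",
    "TrendFit",
    "ClusteredOutcomes",
    "error_rate",
    "errors_per_10k",
    "proportion_ci",
    "gee_adjusted_rate",
    "rate_difference_test",
    "trend_fit",
]


@dataclass
class ErrorRateEstimate:
    """A point estimate of an error rate with its interval.

    ``k`` errors over ``n`` fields; ``method`` records how the interval was
    obtained (``crude_wald``, ``crude_wilson``, or ``gee_adjusted``).
    """

    k: int
    n: int
    denominator_kind: str  # "all_field" | "populated_field"
    rate: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    method: str = "crude_wald"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "denominator_kind": self.denominator_kind,
            "rate": self.rate,
            "rate_percent": round(100 * self.rate, 2),
            "per_10k": round(errors_per_10k(self.k, self.n)) if self.n else 0,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "conf_level": self.conf_level,
            "method": self.method,
        }


@dataclass
class RateDifference:
    """Two-group rate comparison on the percent scale."""

    delta: float  # percentage points, rate1 - rate2
    z: float
    p: float


@dataclass
class TrendFit:
    """OLS fit of per-event error rates (percent) on event index."""

    slope: float  # percentage points per QC event
    slope_ci_low: float
    slope_ci_high: float
    p: float
    r2: float
    n_points: int
    intercept: float = float("nan")


@dataclass
class ClusteredOutcomes:
    """Per-cluster error counts: (cluster_id, k_i errors, n_i fields)."""

    clusters: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValidationError("ClusteredOutcomes needs at least one cluster")
        for cid, k, n in self.clusters:
            if not 0 <= k <= n or n <= 0:
                raise ValidationError(f"cluster {cid!r}: invalid counts k={k}, n={n}")

    @property
    def k(self) -> np.ndarray:
        return np.array([k for _, k, _ in self.clusters], dtype=float)

    @property
    def n(self) -> np.ndarray:
        return np.array([n for _, _, n in self.clusters], dtype=float)


def _check_counts(k: int, n: int) -> None:
    if n == 0:
        raise EstimationError("error rate undefined for n = 0 fields")
    if n < 0 or k < 0 or k > n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")


def error_rate(k: int, n: int) -> float:
    """Errors detected over fields collected, as a proportion."""
    _check_counts(k, n)
    return k / n


def errors_per_10k(k: int, n: int) -> float:
    """Error rate scaled to errors per 10,000 fields."""
    return 10_000 * error_rate(k, n)


def proportion_ci(
    k: int, n: int, conf: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Crude binomial confidence interval.

    ``wald``: p ± z·sqrt(p(1−p)/n), truncated to [0, 1]; degenerates to zero
    width at k ∈ {0, n}, in which case a warning recommends the Wilson score
    interval, which stays informative at the boundary.
    """
    _check_counts(k, n)
    if not 0 < conf < 1:
        raise ValidationError(f"conf must be in (0, 1), got {conf}")
    if method not in ("wald", "wilson"):
        raise ValidationError(f"method must be wald or wilson, got {method!r}")
    if method == "wald" and k in (0, n):
        warnings.warn(
            f"Wald interval is degenerate at k={k}, n={n}; consider method='wilson'",
            DegenerateIntervalWarning,
            stacklevel=2,
        )
    sm_method = "normal" if method == "wald" else "wilson"
    low, high = proportion_confint(k, n, alpha=1 - conf, method=sm_method)
    return (max(0.0, float(low)), min(1.0, float(high)))


def _gee_solve(k: np.ndarray, n: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Intercept-only binomial GEE on aggregated per-cluster counts.

    With a logit link and exchangeable working correlation, the estimating
    equation for the marginal rate mu collapses to a weighted ratio

        mu = sum_i w_i k_i / sum_i w_i n_i,   w_i = 1 / (1 + (n_i - 1) alpha),

    because the inverse of an exchangeable correlation matrix has constant
    row sums.  alpha is the usual moment estimator built from sums of
    pairwise Pearson-residual products, which are computable from (k_i, n_i)
    alone, so the fit never needs the 0/1 rows.  Returns (beta, var_beta,
    alpha, mu) with beta on the logit scale and var_beta the cluster-robust
    sandwich variance.
    """
    m = len(k)
    mu = k.sum() / n.sum()
    alpha = 0.0
    beta = _logit(mu)
    for _ in range(max_iter):
        w = 1.0 / (1.0 + (n - 1.0) * alpha)
        mu_new = float(np.sum(w * k) / np.sum(w * n))
        v = mu_new * (1.0 - mu_new)
        # moment estimator of alpha from within-cluster residual cross-products:
        # sum_{j != l} r_ij r_il = (sum_j r_ij)^2 - sum_j r_ij^2
        sum_r = (k - n * mu_new) / np.sqrt(v)
        sum_r2 = (k * (1 - mu_new) ** 2 + (n - k) * mu_new**2) / v
        pairs = np.sum(n * (n - 1.0))
        if pairs > 0:
            phi = float(np.sum(sum_r2) / max(n.sum() - 1.0, 1.0))
            alpha_new = float(np.sum(sum_r**2 - sum_r2) / (pairs * max(phi, 1e-12)))
            alpha_new = min(max(alpha_new, 0.0), 0.999)
        else:
            alpha_new = 0.0
        beta_new = _logit(mu_new)
        if abs(beta_new - beta) <= tol * max(1.0, abs(beta)):
            beta, mu, alpha = beta_new, mu_new, alpha_new
            break
        beta, mu, alpha = beta_new, mu_new, alpha_new
    else:
        raise EstimationError(
            f"GEE did not converge in {max_iter} iterations "
            f"(last beta={beta:.6g}, alpha={alpha:.4g}, m={m} clusters)"
        )
    # sandwich: B^{-1} M B^{-1} with B = v * sum w_i n_i, score_i = w_i (k_i - n_i mu)
    w = 1.0 / (1.0 + (n - 1.0) * alpha)
    v = mu * (1.0 - mu)
    bread = v * float(np.sum(w * n))
    scores = w * (k - n * mu)
    meat = float(np.sum(scores**2))
    var_beta = meat / bread**2
    return beta, var_beta, alpha, mu


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def gee_adjusted_rate(
    data: ClusteredOutcomes,
    conf: float = 0.95,
    denominator_kind: str = "populated_field",
) -> ErrorRateEstimate:
    """Cluster-adjusted marginal error rate with a robust 95% CI.

    Fits an intercept-only binomial GEE with exchangeable working correlation
    over the clusters (sites, by default, as the design's source of
    correlation), using the cluster-robust sandwich variance.  The interval
    is formed on the logit scale and back-transformed, so it is asymmetric
    around the point estimate.  When every cluster contributes a single
    observation the working correlation is irrelevant and the estimate
    reduces exactly to the crude rate k/n.

    If every outcome sits on the same boundary (no errors anywhere, or
    nothing but errors) the rate is reported at the boundary and the interval
    falls back to a continuity-offset fit (half an error added to the
    smallest cluster), with a warning.
    """
    if not 0 < conf < 1:
        raise ValidationError(f"conf must be in (0, 1), got {conf}")
    k, n = data.k, data.n
    K, N = int(k.sum()), int(n.sum())
    boundary = K == 0 or K == N
    if boundary:
        warnings.warn(
            f"all clustered outcomes at the boundary (k={K} of n={N}); "
            "interval from a continuity-offset fit",
            BoundaryEstimateWarning,
            stacklevel=2,
        )
        k_fit = k.copy()
        i = int(np.argmin(n))
        k_fit[i] = k_fit[i] + (0.5 if K == 0 else -0.5)
    else:
        k_fit = k
    beta, var_beta, _alpha, mu = _gee_solve(k_fit, n)
    z = _sps.norm.ppf(0.5 + conf / 2.0)
    se = float(np.sqrt(var_beta))
    lo = _expit(beta - z * se)
    hi = _expit(beta + z * se)
    rate = K / N if boundary else mu
    return ErrorRateEstimate(
        k=K,
        n=N,
        denominator_kind=denominator_kind,
        rate=float(rate),
        ci_low=lo,
        ci_high=hi,
        conf_level=conf,
        method="gee_adjusted",
    )


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def rate_difference_test(k1: int, n1: int, k2: int, n2: int) -> RateDifference:
    """Two-proportion z test with pooled variance; delta in percentage points."""
    _check_counts(k1, n1)
    _check_counts(k2, n2)
    delta = 100.0 * (k1 / n1 - k2 / n2)
    if k1 / n1 == k2 / n2:
        return RateDifference(delta=0.0, z=0.0, p=1.0)
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return RateDifference(delta=delta, z=float(z), p=float(p))


def trend_fit(event_rates: Sequence[tuple[float, float]], conf: float = 0.95) -> TrendFit:
    """OLS regression of per-event error rates (percent) on event index.

    ``event_rates`` is an ordered list of (event_index, rate_in_percent)
    pairs, one per QC event.  The slope is the change in error rate, in
    percentage points, per additional QC event.
    """
    if len(event_rates) < 3:
        raise EstimationError(f"trend fit needs >= 3 points, got {len(event_rates)}")
    x = np.array([e for e, _ in event_rates], dtype=float)
    y = np.array([r for _, r in event_rates], dtype=float)
    if np.ptp(x) == 0:
        raise EstimationError("trend fit: all event indices equal (singular design)")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1 - conf)
    return TrendFit(
        slope=float(res.params[1]),
        slope_ci_low=float(ci[1][0]),
        slope_ci_high=float(ci[1][1]),
        p=float(res.pvalues[1]),
        r2=float(res.rsquared) if res.centered_tss > 0 else 0.0,
        n_points=len(event_rates),
        intercept=float(res.params[0]),
    )
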