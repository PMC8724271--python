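"""Distance–area regression and the effective paracrine range.

The effective range of a secreted (paracrine) factor around an
AAV-transduced cardiomyocyte is estimated by intersecting two quantities:

* an ordinary-least-squares line relating a non-infected cell's
  cross-sectional area Y (μm²) to its distance X (μm) from the nearest
  infected cell, and
* the lower 95% confidence bound L of the mean hypertrophic cell area.

The intersection ``X* = (L − b0) / b1`` is the distance at which the
attenuation line re-enters the hypertrophic envelope — beyond X* an
uninfected neighbour is statistically indistinguishable from an untreated
hypertrophic cell, so X* is the paracrine action radius fed to the lattice
coverage model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RegressionFit",
    "AreaThreshold",
    "EffectiveRange",
    "DistanceAreaRegression",
    "fit_ols",
    "mean_lower_ci",
    "effective_range",
    "infer_sample_size",
    "bootstrap_range_ci",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS summary of the distance–area line."""

    slope: float          # b1, μm²/μm
    intercept: float      # b0, μm²
    pearson_r: float
    p_value: float        # two-sided, t with n-2 df
    n: int
    residual_sd: float    # sqrt(SSE/(n-2)), μm²

    def predict(self, distance):
        return self.intercept + self.slope * np.asarray(distance, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "n": self.n,
            "residual_sd": self.residual_sd,
        }


@dataclass(frozen=True)
class AreaThreshold:
    """Mean hypertrophic area with its symmetric t confidence interval."""

    mean: float
    lower_ci: float
    upper_ci: float
    sd: float
    n: int
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "lower_ci": self.lower_ci,
            "upper_ci": self.upper_ci,
            "sd": self.sd,
            "n": self.n,
            "level": self.level,
        }


@dataclass(frozen=True)
class EffectiveRange:
    """Intersection of the regression line with the threshold bound.

    ``crossing`` is True only when the line rises to the bound at a
    non-negative distance (positive slope, X* ≥ 0); otherwise ``distance``
    still reports the algebraic intersection but is flagged as not a
    usable paracrine range.
    """

    distance: float  # X*, μm (may be non-finite when slope == 0)
    crossing: bool

    def to_dict(self) -> dict:
        return {"distance": self.distance, "crossing": self.crossing}


def fit_ols(points) -> RegressionFit:
    """Fit ``area = b0 + b1·distance`` by ordinary least squares.

    ``points`` is any sequence/array of (distance, area) pairs or a 2-column
    array-like.  Closed-form normal equations:
    ``b1 = Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²``, ``b0 = ȳ − b1·x̄``; significance of b1
    is the exact two-sided t test with n−2 degrees of freedom.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (distance, area)")
    x, y = pts[:, 0], pts[:, 1]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points for a regression; got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("points contain non-finite values")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("degenerate design: all distances identical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    b1 = sxy / sxx
    b0 = float(y.mean() - b1 * x.mean())
    sse = max(syy - b1 * sxy, 0.0)
    residual_sd = math.sqrt(sse / (n - 2))
    if syy == 0.0:  # constant areas: flat line fits exactly, r undefined -> 0
        r = 0.0
        p = 1.0
    else:
        r = sxy / math.sqrt(sxx * syy)
        r = min(1.0, max(-1.0, r))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return RegressionFit(
        slope=b1, intercept=b0, pearson_r=r, p_value=p, n=n, residual_sd=residual_sd
    )


def mean_lower_ci(areas, level: float = 0.95) -> AreaThreshold:
    """Mean area with its symmetric t confidence interval.

    ``lower = mean − t_{(1+level)/2, n−1} · sd/√n``; the upper bound is
    symmetric.  The sample SD uses n−1.
    """
    a = np.asarray(areas, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("confidence interval needs at least 2 observations")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    mean = float(a.mean())
    sd = float(a.std(ddof=1))
    half = float(stats.t.ppf(0.5 * (1.0 + level), df=n - 1)) * sd / math.sqrt(n)
    return AreaThreshold(
        mean=mean, lower_ci=mean - half, upper_ci=mean + half, sd=sd, n=n, level=level
    )


def effective_range(fit: RegressionFit, threshold: AreaThreshold) -> EffectiveRange:
    """Distance X* at which the fitted line reaches the threshold's lower
    confidence bound.

    ``X* = (L − b0)/b1``.  A zero slope yields a no-crossing result (X*
    infinite/undefined), not an exception; a negative X* or negative slope
    is reported with ``crossing=False``.
    """
    L = threshold.lower_ci
    if fit.slope == 0.0:
        x_star = math.inf if L != fit.intercept else 0.0
        return EffectiveRange(distance=x_star, crossing=L == fit.intercept)
    x_star = (L - fit.intercept) / fit.slope
    crossing = fit.slope > 0.0 and x_star >= 0.0
    return EffectiveRange(distance=x_star, crossing=crossing)


def _p_two_sided(r: float, n: int) -> float:
    t = abs(r) * math.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(t, df=n - 2)


def infer_sample_size(r: float, p: float, n_max: int = 10**6) -> int:
    """Smallest n ≥ 3 whose two-sided correlation p-value for |r| is ≤ p.

    Inverts ``t = r·√(n−2)/√(1−r²)`` against the exact t tail; used to
    back-solve an unreported regression sample size from a printed (R, p)
    pair.
    """
    if not (0.0 < abs(r) < 1.0):
        raise ValueError("need 0 < |r| < 1")
    if not (0.0 < p < 1.0):
        raise ValueError("need 0 < p < 1")
    # p(n) decreases in n, so scan in growing vectorised chunks
    lo = 3
    chunk = 512
    while lo <= n_max:
        hi = min(lo + chunk - 1, n_max)
        ns = np.arange(lo, hi + 1)
        t = abs(r) * np.sqrt((ns - 2) / (1.0 - r * r))
        ps = 2.0 * stats.t.sf(t, df=ns - 2)
        hits = np.nonzero(ps <= p)[0]
        if hits.size:
            return int(ns[hits[0]])
        lo = hi + 1
        chunk *= 4
    raise ValueError(f"no n <= {n_max} reaches p <= {p} for r = {r}")


def bootstrap_range_ci(
    points,
    areas,
    level: float = 0.95,
    n_boot: int = 2000,
    rng=None,
) -> tuple[float, float]:
    """Optional percentile-bootstrap interval for X*.

    Resamples the regression points and the hypertrophic areas
    independently, recomputing X* each time.  Off the default pipeline
    path; the headline X* carries no uncertainty band.
    """
    pts = np.asarray(points, dtype=float)
    a = np.asarray(areas, dtype=float)
    rng = np.random.default_rng(rng)
    draws = []
    for _ in range(n_boot):
        p_idx = rng.integers(0, len(pts), len(pts))
        a_idx = rng.integers(0, len(a), len(a))
        try:
            fit = fit_ols(pts[p_idx])
        except ValueError:
            continue
        thr = mean_lower_ci(a[a_idx], level=level)
        er = effective_range(fit, thr)
        if er.crossing and math.isfinite(er.distance):
            draws.append(er.distance)
    if not draws:
        raise ValueError("no bootstrap draw produced a crossing")
    lo, hi = np.quantile(draws, [0.5 * (1 - level), 0.5 * (1 + level)])
    return float(lo), float(hi)


class DistanceAreaRegression(RegressorMixin, BaseEstimator):
    """scikit-learn-compatible wrapper around :func:`fit_ols`.

    ``fit(X, y)`` takes distances as a single-column feature matrix (or 1-D
    array) and areas as the target, exposing the fitted line through the
    usual trailing-underscore attributes so the stage composes with
    sklearn pipelines and model selection.

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients (μm²/μm and μm²).
    pearson_r_, p_value_, residual_sd_ : float
        Sample correlation, exact two-sided t significance of the slope,
        and residual standard deviation.
    n_ : int
        Number of fitted points.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("DistanceAreaRegression expects one feature")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        fit = fit_ols(np.column_stack([X, y]))
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.pearson_r_ = fit.pearson_r
        self.p_value_ = fit.p_value
        self.n_ = fit.n
        self.residual_sd_ = fit.residual_sd
        self.fit_ = fit
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        return self.intercept_ + self.slope_ * X

    def effective_range(self, threshold: AreaThreshold) -> EffectiveRange:
        """Paracrine range against a hypertrophic-area threshold."""
        return effective_range(self.fit_, threshold)
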