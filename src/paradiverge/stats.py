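"""Expression-divergence statistics: Pearson r, rescaled r′, OLS, Mann–Whitney U.

The within-pair Pearson correlation r of the two genes' expression profiles
measures expression *similarity*; the rescaled coefficient

    r′ = ln(1 + r) / (1 − r)

is its monotone transform used as the regression response, so a negative OLS
slope of r′ on Ks means expression divergence grows with sequence divergence.
An alternate Fisher z-transform reading, ln((1 + r)/(1 − r)), is selectable;
both are strictly increasing in r, so the sign of the slope — the quantity of
interest — does not depend on the choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "KsDensitySummary",
    "pearson_r",
    "rescale_r",
    "regress_rprime_on_ks",
    "mann_whitney_u",
    "ks_density_summary",
]

logger = logging.getLogger(__name__)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN signals undefined (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch ({x.size} vs {y.size})")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def rescale_r(r: float, mode: str = "printed") -> float:
    """Rescaled correlation r′.

    mode="printed": ln(1 + r) / (1 − r) (the default); mode="fisher":
    ln((1 + r) / (1 − r)). Defined on −1 < r < 1 only.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"r = {r} outside (-1, 1): r' undefined")
    if mode == "printed":
        return math.log1p(r) / (1.0 - r)
    if mode == "fisher":
        return math.log1p(r) - math.log1p(-r)
    raise ValueError(f"unknown rescale mode {mode!r}")


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of r′ on Ks: slope sign carries the directionality claim."""

    slope: float
    intercept: float
    p_slope: float
    r_squared: float
    n: int
    n_excluded: int = 0


def regress_rprime_on_ks(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> RegressionResult:
    """Ordinary least squares of r′ on Ks over (r′, Ks) pairs.

    Non-finite r′ or Ks values are excluded (count reported); the slope
    p-value is the usual two-sided t-test.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (r_prime, ks) pairs")
    keep = np.isfinite(arr).all(axis=1)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("regression: %d point(s) with undefined r' or Ks excluded", n_excluded)
    rprime, ks = arr[keep, 0], arr[keep, 1]
    if rprime.size < 3:
        raise ValueError("need at least 3 points with defined r' and Ks")
    if np.all(ks == ks[0]):
        raise ValueError("all Ks values identical: singular design")
    fit = sps.linregress(ks, rprime)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_slope=float(fit.pvalue),
        r_squared=float(fit.rvalue) ** 2,
        n=int(rprime.size),
        n_excluded=n_excluded,
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U with two-sided p.

    Exact null distribution when min(n) <= 8 and there are no ties; normal
    approximation with tie correction otherwise. Fully tied inputs give
    p = 1.0 (complete overlap).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class KsDensitySummary:
    """Histogram of Ks values in fixed-width bins plus the modal bin midpoint."""

    bin_edges: np.ndarray
    counts: np.ndarray
    modal_bin_midpoint: float
    fraction_above_1: float
    n: int


def ks_density_summary(ks_values: Sequence[float], bin_width: float = 0.1) -> KsDensitySummary:
    """Bin Ks values into [k·w, (k+1)·w) bins; report modal bin and P(Ks > 1)."""
    vals = np.asarray([v for v in np.asarray(ks_values, dtype=float) if np.isfinite(v)])
    if vals.size == 0:
        raise ValueError("no defined Ks values")
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    # half-open [lo, hi) bins: index by floor division
    idx = np.minimum((vals / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    modal = int(np.argmax(counts))
    return KsDensitySummary(
        bin_edges=edges,
        counts=counts,
        modal_bin_midpoint=float((modal + 0.5) * bin_width),
        fraction_above_1=float(np.mean(vals > 1.0)),
        n=int(vals.size),
    )
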