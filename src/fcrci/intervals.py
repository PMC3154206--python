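"""Unadjusted and FCR-adjusted confidence intervals for log fold changes.

An unadjusted (1 - alpha) interval for gene j is

    beta_hat_j  -/+  t_{1-alpha/2, f*} * se_tilde_j

with the quantile taken from the t-distribution with the augmented
degrees of freedom f* of the moderated fit (standard normal when f* is
infinite).  Adjusted intervals replace alpha by the step-up adjusted
level alpha_adj = k*alpha/m (BH) or k*alpha/(m*C(m)) (BY), the same
level for every gene, so that an adjusted interval excludes zero exactly
when the corresponding adjusted p-value is at most alpha (duality).

Intervals are built for all genes, selected or not; the FCR guarantee
concerns the selected subset only.  When the step-up rule selects no
gene (k = 0) there is no adjusted level, and `adjusted_ci` returns a
typed `NoSelection` outcome instead of intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ebayes_model import ModeratedFit
from .multiplicity import AdjustmentResult, selection

__all__ = ["GeneIntervals", "NoSelection", "unadjusted_ci", "adjusted_ci", "t_quantile"]


@dataclass(frozen=True)
class GeneIntervals:
    """Per-gene symmetric confidence intervals for the log fold change.

    level_used is the per-comparison alpha actually spent (the nominal
    alpha for unadjusted intervals, alpha_adj for adjusted ones);
    excludes_zero records the significance statement of each interval.
    A limit exactly at zero (possible only when p_raw equals alpha_adj
    exactly) is classified by the p-value side: selected genes are
    counted as excluding zero.
    """

    lower: np.ndarray
    upper: np.ndarray
    level_used: float
    method: str  # {"unadjusted", "BH", "BY"}
    excludes_zero: np.ndarray

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass(frozen=True)
class NoSelection:
    """Typed outcome when the step-up procedure selects no gene (k = 0).

    No adjusted level exists in this case; downstream consumers treat
    the FCR and CCP as zero by definition.
    """

    method: str
    alpha: float


def t_quantile(level: float, f_star: float) -> float:
    """Upper 1 - level/2 quantile of t with f_star df (normal if infinite)."""
    if np.isinf(f_star):
        return float(stats.norm.ppf(1.0 - level / 2.0))
    return float(stats.t.ppf(1.0 - level / 2.0, df=f_star))


def _build(fit: ModeratedFit, level: float, method: str, excludes_zero=None) -> GeneIntervals:
    q = t_quantile(level, fit.f_star)
    half = q * fit.se_tilde
    lower = fit.beta_hat - half
    upper = fit.beta_hat + half
    if excludes_zero is None:
        excludes_zero = (lower > 0) | (upper < 0)
    return GeneIntervals(
        lower=lower, upper=upper, level_used=level, method=method,
        excludes_zero=np.asarray(excludes_zero, dtype=bool),
    )


def unadjusted_ci(fit: ModeratedFit, alpha: float) -> GeneIntervals:
    """Per-gene unadjusted (1 - alpha) intervals."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return _build(fit, alpha, "unadjusted")


def adjusted_ci(
    fit: ModeratedFit,
    alpha: float,
    method: str = "BH",
    adjustment: AdjustmentResult | None = None,
) -> GeneIntervals | NoSelection:
    """FCR-adjusted intervals at the common level alpha_adj, all genes.

    Parameters
    ----------
    fit : moderated two-group fit.
    alpha : nominal FDR/FCR level.
    method : "BH" or "BY" step-up rule.
    adjustment : optionally a precomputed `selection(...)` result for
        the same p-values, alpha and method, to avoid recomputing it.

    Returns
    -------
    GeneIntervals whose excludes_zero flags coincide gene-for-gene with
    the step-up selection (duality), or `NoSelection` when k = 0.
    """
    if adjustment is None:
        adjustment = selection(fit.p_raw, alpha, method)
    if adjustment.k == 0:
        return NoSelection(method=adjustment.method, alpha=alpha)
    return _build(fit, adjustment.alpha_adj, adjustment.method,
                  excludes_zero=adjustment.selected)
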