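"""BH and BY step-up multiple-testing adjustment and adjusted alpha levels.

The Benjamini-Hochberg (BH) step-up procedure controls the false
discovery rate under independence and positive dependence; the
Benjamini-Yekutieli (BY) variant inflates the BH thresholds by
C(m) = sum_{i=1..m} 1/i and is valid under arbitrary dependence.

Besides adjusted p-values, the module computes the selection count k
(the largest k passing the step-up rule on the ordered raw p-values)
and the adjusted per-comparison significance level

    alpha_adj = k * alpha / m           (BH)
    alpha_adj = k * alpha / (m * C(m))  (BY)

Comparing raw p-values against alpha_adj selects exactly the genes whose
adjusted p-value is at most alpha (duality); the same alpha_adj is the
per-comparison level at which FCR-adjusted confidence intervals are
built downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AdjustmentResult", "adjust_bh", "adjust_by", "selection", "harmonic_sum"]

_METHODS = ("BH", "BY")


@dataclass(frozen=True)
class AdjustmentResult:
    """Step-up selection outcome at nominal level alpha.

    k is the number of selected genes; alpha_adj the adjusted
    per-comparison level (0 when k = 0); selected_j is True exactly when
    p_raw_j <= alpha_adj, equivalently p_adj_j <= alpha.
    """

    method: str
    p_adj: np.ndarray
    alpha: float
    k: int
    alpha_adj: float
    selected: np.ndarray


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        bad = np.argwhere(~((p >= 0) & (p <= 1)))[:, 0]
        raise ValueError(f"p-values outside [0, 1] at indices {bad[:10].tolist()}")
    return p


def harmonic_sum(m: int) -> float:
    """C(m) = sum_{i=1..m} 1/i, the BY inflation constant."""
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def adjust_bh(p_raw: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values, min_{k>=j} min(m * p_(k) / k, 1), input order."""
    p = _validate_p(p_raw)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest rank downwards (step-up)
    adj_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj_sorted
    return p_adj


def adjust_by(p_raw: np.ndarray) -> np.ndarray:
    """BY-adjusted p-values: BH inflated by C(m), capped at 1."""
    p = _validate_p(p_raw)
    return np.minimum(harmonic_sum(p.size) * adjust_bh(p), 1.0)


def selection(p_raw: np.ndarray, alpha: float, method: str = "BH") -> AdjustmentResult:
    """Step-up selection count k, adjusted level alpha_adj, selection flags.

    k is the largest k with p_(k) <= k * alpha / m (BH) or
    p_(k) <= k * alpha / (m * C(m)) (BY); comparisons use <= so a raw
    p-value exactly at the threshold is selected.  When no ordered
    p-value passes, k = 0 and alpha_adj = 0.
    """
    p = _validate_p(p_raw)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    method = method.upper()
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    m = p.size
    denom = m * harmonic_sum(m) if method == "BY" else m
    ps = np.sort(p, kind="stable")
    thresholds = alpha * np.arange(1, m + 1) / denom
    passing = np.nonzero(ps <= thresholds)[0]
    k = int(passing[-1] + 1) if passing.size else 0
    alpha_adj = k * alpha / denom if k else 0.0
    selected = p <= alpha_adj if k else np.zeros(m, dtype=bool)
    p_adj = adjust_by(p) if method == "BY" else adjust_bh(p)
    return AdjustmentResult(
        method=method, p_adj=p_adj, alpha=alpha, k=k, alpha_adj=alpha_adj, selected=selected
    )
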