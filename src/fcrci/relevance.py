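"""Biological relevance categories for significant log fold changes.

A gene whose confidence interval excludes zero is classified by the
position of that interval relative to a relevance threshold rho
(absolute log2 fold change units, e.g. rho = 1 for a two-fold change).
For an up-regulated gene (lower limit above zero):

    A  significant, not relevant:          interval entirely below rho
    B  significant, probably not relevant: estimate below rho, upper
                                           limit reaching rho
    C  significant, probably relevant:     estimate at or above rho,
                                           lower limit not yet above rho
    D  significant, relevant:              interval entirely above rho

Down-regulated genes are classified by the mirror image under negation.
Genes whose interval covers zero are labelled NS and excluded from
category profiles.  Boundary ties at rho use >= for "exceeds" on the
estimate and upper limit, and a strict > for the lower limit in D; on
continuous data ties are a measure-zero event.

The "probably" in B and C presumes a symmetric sampling distribution of
the estimate; no symmetry diagnostic is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RelevanceRecord", "categorize", "categorize_all", "category_profile"]

CATEGORIES = ("NS", "A", "B", "C", "D")


@dataclass(frozen=True)
class RelevanceRecord:
    """Relevance class of one gene at threshold rho."""

    category: str  # one of NS, A, B, C, D
    direction: str  # up, down, none
    rho: float


def categorize(
    lower: float,
    upper: float,
    beta_hat: float,
    rho: float,
    excludes_zero: bool | None = None,
) -> RelevanceRecord:
    """Classify one gene's interval relative to zero and the threshold rho.

    excludes_zero overrides the geometric zero check so the significance
    statement can follow the adjusted p-value at an exact boundary; by
    default an interval with lower > 0 or upper < 0 is significant.
    """
    if rho <= 0:
        raise ValueError(f"relevance threshold rho must be positive, got {rho}")
    if lower > upper:
        raise ValueError(f"invalid interval ({lower}, {upper})")
    if excludes_zero is None:
        excludes_zero = lower > 0 or upper < 0
    if not excludes_zero:
        return RelevanceRecord("NS", "none", rho)
    if upper < 0 or (lower <= 0 <= upper and beta_hat < 0):
        # mirror image: classify the negated, up-regulated interval
        lower, upper, beta_hat = -upper, -lower, -beta_hat
        direction = "down"
    else:
        direction = "up"
    if lower > rho:
        category = "D"
    elif beta_hat >= rho:
        category = "C"
    elif upper >= rho:
        category = "B"
    else:
        category = "A"
    return RelevanceRecord(category, direction, rho)


def categorize_all(
    lower: np.ndarray,
    upper: np.ndarray,
    beta_hat: np.ndarray,
    rho: float,
    excludes_zero: np.ndarray | None = None,
) -> list[RelevanceRecord]:
    """Vector version of `categorize`, one record per gene."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    if not (lower.shape == upper.shape == beta_hat.shape):
        raise ValueError("lower, upper and beta_hat must have equal length")
    ez = [None] * lower.size if excludes_zero is None else np.asarray(excludes_zero, bool)
    return [
        categorize(lower[j], upper[j], beta_hat[j], rho, excludes_zero=ez[j])
        for j in range(lower.size)
    ]


def default_rho_grid() -> np.ndarray:
    """Threshold grid 0.05, 0.10, ..., 2.00 in |log2 FC| units."""
    return np.round(np.arange(1, 41) * 0.05, 10)


def category_profile(
    lower: np.ndarray,
    upper: np.ndarray,
    beta_hat: np.ndarray,
    rho_grid: np.ndarray | None = None,
    excludes_zero: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percentage of significant genes per category over a grid of rho.

    Returns a DataFrame with columns rho, A, B, C, D (percentages among
    significant genes, summing to 100 per row) and n_significant.  NS
    genes are excluded from the denominator.  With no significant gene
    the result is a typed empty table with the same columns.
    """
    if rho_grid is None:
        rho_grid = default_rho_grid()
    rho_grid = np.asarray(rho_grid, dtype=float)
    if rho_grid.size and (np.any(rho_grid <= 0) or np.any(np.diff(rho_grid) < 0)):
        raise ValueError("rho_grid must be strictly positive and sorted")
    columns = ["rho", "A", "B", "C", "D", "n_significant"]
    rows = []
    for rho in rho_grid:
        records = categorize_all(lower, upper, beta_hat, rho, excludes_zero)
        letters = [r.category for r in records if r.category != "NS"]
        n_sig = len(letters)
        if n_sig == 0:
            continue
        rows.append(
            [rho] + [100.0 * letters.count(c) / n_sig for c in "ABCD"] + [n_sig]
        )
    return pd.DataFrame(rows, columns=columns)
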