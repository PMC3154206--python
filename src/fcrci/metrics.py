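"""False coverage-statement rate (FCR) and conditional coverage probability.

The FCR is the proportion of constructed confidence intervals that fail
to cover their true parameter, among the genes selected as
differentially expressed; the CCP is the covering proportion among the
same genes.  Both are defined to be zero when no gene is selected, so
FCR + CCP = 1 exactly whenever at least one gene is selected.
Containment uses closed intervals: a true value exactly at a limit
counts as covered (a measure-zero event for continuous truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoverageAssessment", "assess_coverage"]


@dataclass(frozen=True)
class CoverageAssessment:
    fcr: float
    ccp: float
    n_selected: int


def assess_coverage(
    lower: np.ndarray,
    upper: np.ndarray,
    truth: np.ndarray,
    selected: np.ndarray,
) -> CoverageAssessment:
    """FCR and CCP of the selected genes' intervals against known truth."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    truth = np.asarray(truth, dtype=float)
    selected = np.asarray(selected, dtype=bool)
    if not (lower.shape == upper.shape == truth.shape == selected.shape):
        raise ValueError("lower, upper, truth and selected must have equal length")
    if not np.all(np.isfinite(truth)):
        raise ValueError("true log fold changes must be finite")
    r = int(selected.sum())
    if r == 0:
        return CoverageAssessment(fcr=0.0, ccp=0.0, n_selected=0)
    covered = (lower[selected] <= truth[selected]) & (truth[selected] <= upper[selected])
    ccp = float(covered.mean())
    return CoverageAssessment(fcr=1.0 - ccp, ccp=ccp, n_selected=r)
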