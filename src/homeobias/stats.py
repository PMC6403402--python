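"""Chi-squared tests for homoeolog-bias patterns and BH correction.

Two questions, two Pearson tests (no continuity correction, alpha = 0.05):

* direction: among biased (HEB) transcripts, does the bias favour one
  parental genome?  Goodness of fit of (n toward P, n toward A) against an
  equal split, df = 1.
* ploidy: does the prevalence of HEB differ between diploid and triploid
  libraries?  Independence test on the 2x2 table [[HEB_2n, BHE_2n],
  [HEB_3n, BHE_3n]], df = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import DataError

ALPHA = 0.05

DIRECTION_TOWARD_P = "toward_P"
DIRECTION_TOWARD_A = "toward_A"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    direction: str = DIRECTION_NONE

    def __post_init__(self) -> None:
        if self.statistic < 0 or self.df < 1:
            raise DataError("invalid test result")


def _pearson(observed: np.ndarray, expected: np.ndarray) -> float:
    return float(((observed - expected) ** 2 / expected).sum())


def direction_test(n_heb_p: int, n_heb_a: int, alpha: float = ALPHA) -> TestResult:
    """Pearson goodness-of-fit of the HEB direction split against 1:1."""
    if n_heb_p < 0 or n_heb_a < 0 or n_heb_p + n_heb_a < 1:
        raise DataError("direction_test needs non-negative counts summing to >= 1")
    obs = np.array([n_heb_p, n_heb_a], dtype=float)
    exp = np.full(2, obs.sum() / 2)
    stat = _pearson(obs, exp)
    p = float(sps.chi2.sf(stat, df=1))
    direction = DIRECTION_NONE
    if p < alpha:
        direction = DIRECTION_TOWARD_P if n_heb_p > n_heb_a else DIRECTION_TOWARD_A
    return TestResult(statistic=stat, df=1, p_value=p, direction=direction)


def ploidy_test(table: list[list[int]] | np.ndarray) -> TestResult:
    """Pearson chi-squared independence test on a 2x2 HEB/BHE-by-ploidy table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise DataError("ploidy_test needs a non-negative 2x2 table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise DataError("ploidy_test table has a zero margin")
    exp = row @ col / obs.sum()
    stat = _pearson(obs, exp)
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(statistic=stat, df=1, p_value=p)


def benjamini_hochberg(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
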