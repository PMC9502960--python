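"""Wilcoxon signed-rank test with an exact small-sample null distribution.

Policy (fixed for reproducibility): zero differences are dropped
(Wilcoxon's original rule) and their count reported; ties among |d|
receive midranks; for n <= EXACT_N_MAX remaining pairs the two-sided
p-value is computed from the exact permutation null of the positive-rank
sum W+ (all 2^n sign assignments, evaluated by dynamic programming over
doubled ranks so midranks stay integral); above that, the normal
approximation with tie-corrected variance and a 0.5 continuity
correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError

EXACT_N_MAX = 20

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank", "EXACT_N_MAX"]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n: int  # pairs after dropping zeros
    n_zeros_dropped: int
    exact: bool


def _exact_null_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per doubled W+ value (index = 2*W+)."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test of x vs y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    d = x - y
    nonzero = d != 0
    n_dropped = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        raise DegenerateInputError(
            "all paired differences are zero; the signed-rank test is undefined"
        )
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX:
        doubled = np.round(2 * ranks).astype(int)
        counts = _exact_null_counts(doubled)
        total = counts.sum()
        idx = int(round(2 * w_plus))
        p_le = counts[: idx + 1].sum() / total
        p_ge = counts[idx:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, float(p), n, n_dropped, exact=True)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise DegenerateInputError("variance of signed-rank statistic is zero")
    delta = w_plus - mean
    cc = 0.5 * np.sign(delta)  # continuity correction toward the mean
    z = (delta - cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, n_dropped, exact=False)
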