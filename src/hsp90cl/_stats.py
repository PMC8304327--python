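"""Small statistical helpers shared across modules.

Thin wrappers around scipy/statsmodels that add the degenerate-input
conventions used throughout the pipeline (identical groups compare equal
with p = 1, NaN p-values pass through BH untouched).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "two_sample_t", "one_sample_t"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    adj = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        adj[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return adj


def _degenerate(a: np.ndarray, b: np.ndarray | None) -> tuple[float, float] | None:
    """Handle zero-variance groups: equal means -> (t=0, p=1), else p=0."""
    if b is None:
        if np.ptp(a) == 0:
            return (0.0, 1.0) if a[0] == 0 else (np.inf * np.sign(a[0]), 0.0)
        return None
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return np.inf * np.sign(a[0] - b[0]), 0.0
    return None


def two_sample_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test returning (t, p).

    ``equal_var=True`` gives the Student test, ``False`` the Welch test.
    Groups that are both constant compare with p=1 when equal, p=0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("two_sample_t requires >=2 finite values per group")
    deg = _degenerate(a - np.mean(b), b - np.mean(b))
    if deg is not None:
        return deg
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def one_sample_t(a, popmean: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of ``a`` against ``popmean``."""
    a = np.asarray(a, dtype=float)
    a = a[np.isfinite(a)]
    if a.size < 2:
        raise ValueError("one_sample_t requires >=2 finite values")
    deg = _degenerate(a - popmean, None)
    if deg is not None:
        return deg
    t, p = stats.ttest_1samp(a, popmean)
    return float(t), float(p)
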