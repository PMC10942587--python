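"""Storey q-values for FDR control across a family of p-values.

The q-value of a test is the minimum FDR at which it would be called
significant.  The proportion of true nulls pi0 is estimated by the smoother
method: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) evaluated on a grid of
lambda values, smoothed with a cubic fit and read off at the largest lambda.
With pi0 = 1 this reduces exactly to Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["storey_pi0", "qvalues", "bh_adjust"]

_LAMBDA_GRID = np.arange(0.05, 0.951, 0.05)


def bh_adjust(pvals):
    """Benjamini-Hochberg adjusted p-values; NaNs propagated."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def storey_pi0(pvals, lambdas=_LAMBDA_GRID):
    """Smoother estimate of the null proportion pi0.

    A cubic polynomial is fitted to pi0(lambda) over the grid and evaluated at
    the largest lambda; the result is clipped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    m = p.size
    if m == 0:
        return 1.0
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    coeffs = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def qvalues(pvals, min_for_storey: int = 20):
    """Convert p-values to Storey q-values.

    Fewer than `min_for_storey` finite p-values gives too little information
    to estimate pi0, so the function falls back to BH (pi0 = 1) with a
    warning.  Missing p-values propagate as missing q-values.  Output is
    monotone non-decreasing in p and clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return out
    if m < min_for_storey:
        warnings.warn(
            f"only {m} finite p-values; falling back to Benjamini-Hochberg (pi0=1)",
            stacklevel=2,
        )
        pi0 = 1.0
    else:
        pi0 = storey_pi0(p[ok])
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qq = np.empty(m)
    qq[order] = q
    out[ok] = qq
    return out
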