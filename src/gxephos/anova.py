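"""Least-squares ANOVA primitives for unbalanced factorial designs.

The designs here are small (tens to low hundreds of observations) but are
fitted tens of thousands of times across phosphopeptides, so the F statistics
are computed from residual sums of squares of nested projections rather than
through a formula interface.  For the treatment main effect in the full
strain x diet x treatment factorial, Type-II sums of squares condition on all
terms not containing treatment (strain, diet, strain:diet), which for this
design is the strain-diet "combination" cell-means model; the error term is
the residual of the saturated cell-means model over all three factors.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "rss_groups",
    "treatment_main_F",
    "oneway_F",
    "twoway_typeII",
]

_EPS = 1e-12


def rss_groups(y: np.ndarray, groups: np.ndarray) -> tuple[float, int]:
    """Residual SS and number of non-empty cells for a cell-means model."""
    rss = 0.0
    ncell = 0
    for g in np.unique(groups):
        v = y[groups == g]
        if v.size:
            ncell += 1
            rss += float(np.sum((v - v.mean()) ** 2))
    return rss, ncell


def _rss_lstsq(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual SS and rank of an arbitrary design matrix fit."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(labels, return_inverse=True)
    D = np.zeros((labels.size, levels.size))
    D[np.arange(labels.size), inv] = 1.0
    return D


def _f_pvalue(ss_num: float, df_num: int, rss_err: float, df_err: int):
    """F and p with degenerate-variance handling (noise-free data)."""
    if df_num <= 0:
        return np.nan, np.nan
    if df_err <= 0 or rss_err <= _EPS * max(1.0, ss_num):
        if ss_num <= _EPS:
            return 0.0, 1.0
        return np.inf, 0.0
    F = (ss_num / df_num) / (rss_err / df_err)
    F = max(F, 0.0)
    return F, float(stats.f.sf(F, df_num, df_err))


def treatment_main_F(
    y: np.ndarray,
    strain: np.ndarray,
    diet: np.ndarray,
    treatment: np.ndarray,
    ss: str = "II",
):
    """F-test for the treatment main effect in the full three-way factorial.

    Parameters
    ----------
    y : response values (present samples only).
    strain, diet : factor labels per sample.
    treatment : binary treatment indicator (0/1) per sample.
    ss : "II" (Type II, order-invariant; default) or "sequential"
        (strain, diet, treatment order emulating R's aov; here the
        conditioning set is the additive strain+diet model).

    Returns
    -------
    (F, p, df_num, df_err); (nan, nan, ...) when the effect is inestimable.
    """
    y = np.asarray(y, dtype=float)
    strain = np.asarray(strain).astype(str)
    diet = np.asarray(diet).astype(str)
    t = np.asarray(treatment, dtype=float)
    combo = np.char.add(np.char.add(strain, "|"), diet)
    cells = np.char.add(np.char.add(combo, "|"), t.astype(int).astype(str))
    rss_full, ncell_full = rss_groups(y, cells)
    df_err = y.size - ncell_full

    if ss == "II":
        # Condition on strain, diet and strain:diet == combo cell means;
        # add treatment by residualising it within combos and projecting.
        t_res = t.copy()
        y_res = y.copy()
        for g in np.unique(combo):
            sel = combo == g
            t_res[sel] -= t_res[sel].mean()
            y_res[sel] -= y_res[sel].mean()
        denom = float(t_res @ t_res)
        if denom <= _EPS:
            return np.nan, np.nan, 1, df_err  # treatment confounded with combos
        ss_t = float(y_res @ t_res) ** 2 / denom
    elif ss == "sequential":
        X0 = np.column_stack([_dummies(strain), _dummies(diet)])
        X1 = np.column_stack([X0, t])
        rss0, r0 = _rss_lstsq(y, X0)
        rss1, r1 = _rss_lstsq(y, X1)
        if r1 == r0:
            return np.nan, np.nan, 1, df_err
        ss_t = rss0 - rss1
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown ss type: {ss!r}")

    F, p = _f_pvalue(ss_t, 1, rss_full, df_err)
    return F, p, 1, df_err


def oneway_F(y: np.ndarray, groups: np.ndarray):
    """One-way fixed-effects ANOVA F-test from group sums of squares."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    rss1, k = rss_groups(y, groups)
    if k < 2 or y.size - k <= 0:
        return np.nan, np.nan, k - 1, y.size - k
    rss0 = float(np.sum((y - y.mean()) ** 2))
    F, p = _f_pvalue(rss0 - rss1, k - 1, rss1, y.size - k)
    return F, p, k - 1, y.size - k


def twoway_typeII(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict:
    """Type-II two-way factorial ANOVA (main effects of a and b, interaction).

    Returns a dict with F/p/df for "a", "b" and "ab".  The error term is the
    residual of the saturated cell-means model; the interaction SS compares
    the additive model against the cell means.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a).astype(str)
    b = np.asarray(b).astype(str)
    cells = np.char.add(np.char.add(a, "|"), b)
    rss_full, ncell = rss_groups(y, cells)
    df_err = y.size - ncell

    Xa = _dummies(a)
    Xb = _dummies(b)
    rss_a, rank_a = _rss_lstsq(y, Xa)
    rss_b, rank_b = _rss_lstsq(y, Xb)
    rss_ab, rank_ab = _rss_lstsq(y, np.column_stack([Xa, Xb]))

    out = {}
    # main effect of a conditioned on b, and vice versa
    F, p = _f_pvalue(rss_b - rss_ab, rank_ab - rank_b, rss_full, df_err)
    out["a"] = {"F": F, "p": p, "df": (rank_ab - rank_b, df_err)}
    F, p = _f_pvalue(rss_a - rss_ab, rank_ab - rank_a, rss_full, df_err)
    out["b"] = {"F": F, "p": p, "df": (rank_ab - rank_a, df_err)}
    df_int = ncell - rank_ab
    F, p = _f_pvalue(rss_ab - rss_full, df_int, rss_full, df_err)
    out["ab"] = {"F": F, "p": p, "df": (df_int, df_err)}
    return out
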