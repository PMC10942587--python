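"""Tracer kinetics, glucose tolerance, and phenotype association.

In vivo glucose uptake is measured with a 2-deoxyglucose tracer: blood
counts Cp(t) decay as Cp0 * exp(-Kp t) as tissues take the tracer up, and
the tissue uptake rate constant is

    Ki = Ci(t) * Kp / (Cp0 * (1 - exp(-Kp t)))

where Ci(t) is the trapped tissue count at sacrifice time t.  The glucose
tolerance curve is summarised by its baseline-subtracted trapezoidal area
(AOC).  Entity profiles (phosphopeptide intensities or responses, kinase
scores, module eigenpeptides) are associated with uptake by Pearson
correlation with a Storey-q and |r| gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .qvalue import qvalues

__all__ = [
    "TracerExperiment",
    "fit_blood_curve",
    "compute_ki",
    "compute_aoc",
    "associate_uptake",
]

log = logging.getLogger(__name__)

DEFAULT_TIMES = (1.0, 5.0, 7.5, 10.0)
R_CUT = 0.35
Q_CUT_ASSOC = 0.1


@dataclass
class TracerExperiment:
    """One animal's tracer time course and (after fitting) kinetic constants."""

    times: np.ndarray  # min
    blood: np.ndarray  # DPM/uL
    tissue_count: float = np.nan  # DPM/mg at terminal time
    terminal_time: float = 10.0  # min
    cp0: float = field(default=np.nan)
    kp: float = field(default=np.nan)
    cp1_excluded: bool = False

    @property
    def ki(self) -> float:
        return compute_ki(self.tissue_count, self.terminal_time, self.cp0, self.kp)


def _cp1_exclusion(times: np.ndarray, blood: np.ndarray) -> np.ndarray:
    """Mask dropping Cp(1) when abnormally low.

    Cp(1) is excluded iff Cp(1) < Cp(5) and
    Cp(5) - Cp(1) > 0.5 * (Cp(5) - Cp(7.5)), indicating insufficient
    diffusion of the tracer into the sampling site at the first timepoint.
    """
    keep = np.ones(times.size, dtype=bool)
    by_t = {float(t): c for t, c in zip(times, blood)}
    needed = (1.0, 5.0, 7.5)
    if not all(t in by_t for t in needed):
        return keep
    cp1, cp5, cp75 = by_t[1.0], by_t[5.0], by_t[7.5]
    if cp1 < cp5 and (cp5 - cp1) > 0.5 * (cp5 - cp75):
        log.info(
            "Cp(1)=%.3g excluded as abnormally low (Cp(5)=%.3g, Cp(7.5)=%.3g); "
            "review the blood curve if this recurs",
            cp1, cp5, cp75,
        )
        keep[np.isclose(times, 1.0)] = False
    return keep


def fit_blood_curve(
    times,
    blood,
    apply_exclusion: bool = True,
    method: str = "nls",
) -> tuple[float, float, bool]:
    """Fit the blood tracer clearance curve Cp(t) = Cp0 * exp(-Kp t).

    Nonlinear least squares initialised from the log-linear regression of
    ln Cp on t (non-positive counts are excluded from the initialisation).
    `method="loglinear"` returns the log-linear estimates directly.
    Returns (Cp0, Kp, cp1_excluded_flag).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(blood, dtype=float)
    excluded = False
    if apply_exclusion:
        keep = _cp1_exclusion(t, c)
        excluded = not keep.all()
        t, c = t[keep], c[keep]
    if t.size < 3:
        raise ValueError("need at least 3 usable timepoints to fit the blood curve")

    pos = c > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(c[pos]), 1)
        init = (float(np.exp(intercept)), float(max(-slope, 1e-6)))
    else:
        init = (float(max(c.max(), 1.0)), 0.1)
    if method == "loglinear":
        return init[0], init[1], excluded
    try:
        popt, _ = curve_fit(
            lambda tt, cp0, kp: cp0 * np.exp(-kp * tt), t, c, p0=init, maxfev=10000
        )
    except RuntimeError as err:
        resid = c - init[0] * np.exp(-init[1] * t)
        raise RuntimeError(
            f"blood-curve fit failed to converge; log-linear residuals {resid}"
        ) from err
    cp0, kp = float(popt[0]), float(popt[1])
    return cp0, kp, excluded


def compute_ki(tissue_count: float, t: float, cp0: float, kp: float) -> float:
    """Tissue uptake rate constant Ki = Ci(t) Kp / (Cp0 (1 - e^{-Kp t}))."""
    if not np.isfinite(kp) or kp <= 0:
        raise ValueError(f"Kp must be positive, got {kp}")
    return float(tissue_count * kp / (cp0 * (1.0 - np.exp(-kp * t))))


def compute_aoc(times, glucose) -> float:
    """Baseline-subtracted trapezoidal area of a glucose tolerance curve.

    AOC = sum_{i=2..n} ((G_{i-1} - G_1) + (G_i - G_1)) / 2 * (t_i - t_{i-1});
    invariant to adding a constant to all glucose values.
    """
    t = np.asarray(times, dtype=float)
    g = np.asarray(glucose, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    excess = g - g[0]
    return float(np.sum((excess[:-1] + excess[1:]) / 2.0 * np.diff(t)))


def associate_uptake(
    values: pd.DataFrame,
    uptake: pd.Series,
    mode: str = "response",
    r_cut: float = R_CUT,
    q_cut: float = Q_CUT_ASSOC,
    use_q: bool = True,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson association of entity profiles with per-sample uptake.

    `values` is entity x sample (insulin-stimulated samples), `mode` records
    whether the profiles are raw intensities or insulin responses.
    Correlations are pairwise-complete; zero-variance entities are skipped
    with a warning.  An entity passes when q < q_cut (raw p when
    `use_q=False`, as for small module families) and |r| > r_cut.
    """
    common = [c for c in values.columns if c in uptake.index]
    v = values[common]
    u = uptake.loc[common].astype(float)
    rows = []
    for ent, row in v.iterrows():
        pair = pd.concat([row.astype(float), u], axis=1).dropna()
        if len(pair) < min_pairs:
            rows.append((ent, np.nan, np.nan, len(pair)))
            continue
        x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            log.warning("zero-variance entity %s skipped", ent)
            rows.append((ent, np.nan, np.nan, len(pair)))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((ent, float(r), float(p), len(pair)))
    out = pd.DataFrame(rows, columns=["entity", "r", "p", "n"]).set_index("entity")
    out["mode"] = mode
    out["q"] = qvalues(out["p"].to_numpy())
    crit = out["q"] if use_q else out["p"]
    out["pass"] = (crit < q_cut) & ((out["r"] > r_cut) | (out["r"] < -r_cut))
    out["pass"] = out["pass"].fillna(False)
    return out
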