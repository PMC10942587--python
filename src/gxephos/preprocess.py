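"""Normalisation and quality filters for phosphopeptide intensity matrices.

Order matters and follows the processing conventions of in vivo MS
phosphoproteomics: median normalisation of log2 intensities, removal of
non-class-I peptides (localisation score <= 0.75), then removal of
implausibly low single-sample outlier values.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .data import PhosphoTable

__all__ = [
    "median_normalise",
    "filter_class_one",
    "remove_outliers",
    "preprocess",
]

log = logging.getLogger(__name__)

CLASS_I_THRESHOLD = 0.75
OUTLIER_INTENSITY = 5.0
OUTLIER_GAP = 6.0


def median_normalise(table: PhosphoTable, target: float = 0.0) -> PhosphoTable:
    """Shift each sample column so its median over present values is `target`.

    Median centring removes sample-loading differences; the choice of target
    is a global constant that cancels in every downstream within-sample
    difference.  Missing entries are untouched.
    """
    vals = table.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns handled below
        medians = np.nanmedian(vals, axis=0)
    empty = ~np.isfinite(medians)
    if empty.any():
        bad = [c for c, e in zip(table.values.columns, empty) if e]
        raise ValueError(f"samples with no present values: {bad}")
    out = table.values - (medians - target)
    return PhosphoTable(out, table.localisation.copy())


def filter_class_one(table: PhosphoTable,
                     threshold: float = CLASS_I_THRESHOLD) -> PhosphoTable:
    """Retain class-I peptides: maximum localisation score strictly > threshold."""
    loc = table.localisation
    if loc.isna().any():
        missing = list(loc.index[loc.isna()])[:5]
        raise ValueError(f"peptides without localisation score, e.g. {missing}")
    keep = loc > threshold
    log.info("class-I filter: kept %d / %d peptides", int(keep.sum()), len(keep))
    return table.subset(loc.index[keep])


def remove_outliers(table: PhosphoTable,
                    min_intensity: float = OUTLIER_INTENSITY,
                    max_gap: float = OUTLIER_GAP) -> PhosphoTable:
    """Mask single-sample low outliers.

    A value is set to missing iff it is below `min_intensity` (log2) AND more
    than `max_gap` log2 units below its peptide's median over present values.
    Retained values are never altered, so output missingness is a superset of
    input missingness.  The thresholds are on the scale of the matrix passed
    in; with median-centred data the absolute-intensity clause is permissive
    and the rule reduces to the gap clause.
    """
    vals = table.values.to_numpy(dtype=float).copy()
    with warnings.catch_warnings():
        # peptides with no present values have no median and no outliers
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(vals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        mask = (vals < min_intensity) & ((med - vals) > max_gap)
    n = int(np.nansum(mask))
    if n:
        log.info("outlier rule removed %d values", n)
    vals[mask] = np.nan
    out = table.values.copy()
    out.iloc[:, :] = vals
    return PhosphoTable(out, table.localisation.copy())


def preprocess(table: PhosphoTable,
               class_one_threshold: float = CLASS_I_THRESHOLD) -> PhosphoTable:
    """Full preprocessing: normalise, class-I filter, outlier removal."""
    return remove_outliers(filter_class_one(median_normalise(table),
                                            class_one_threshold))
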