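"""Coregulation subnetworks of insulin-regulated phosphopeptides.

Pairwise Pearson correlation of insulin-response profiles is raised to a
soft-threshold power to form an unsigned adjacency, converted to the
topological overlap measure (TOM), and clustered by average linkage on
1 - TOM.  The tree is cut at a static height (0.99 quantile of merge
heights); clusters below the minimum size dissolve to label 0 (unassigned).
Each module is summarised by its eigenpeptide (first principal component of
the standardised member profiles, sign-oriented to the module mean), and
modules with near-identical eigenpeptides are merged.  Membership scores
(kME) are correlations of each peptide with each eigenpeptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .qvalue import bh_adjust

__all__ = [
    "topological_overlap",
    "build_modules",
    "SubnetworkModel",
    "eigenpeptide_trait_correlation",
    "term_enrichment",
    "pca_fold_changes",
]

log = logging.getLogger(__name__)

DEFAULT_POWER = 3
DEFAULT_MIN_MODULE_SIZE = 15
DEFAULT_MERGE_CUT = 0.25


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    k_i = sum_u a_iu (u != i); TOM_ii = 1.  Symmetric with entries in [0, 1].
    """
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom = np.clip(np.nan_to_num(tom), 0.0, 1.0)
    tom = (tom + tom.T) / 2
    np.fill_diagonal(tom, 1.0)
    return tom


def _standardise(X: np.ndarray) -> np.ndarray:
    """Row-standardise with mean imputation of missing entries (-> 0)."""
    mu = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    return np.nan_to_num(Z)


def _eigenpeptide(Z: np.ndarray) -> np.ndarray:
    """First PC across samples of a standardised module submatrix, oriented
    to correlate positively with the module mean profile, unit variance."""
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z.T)[:, 0]
    mean_profile = Z.mean(axis=0)
    if np.std(scores) > 0:
        r = np.corrcoef(scores, mean_profile)[0, 1]
        if np.isfinite(r) and r < 0:
            scores = -scores
        scores = scores / np.std(scores)
    return scores


@dataclass
class SubnetworkModel:
    """Module assignments, eigenpeptides and membership scores."""

    labels: pd.Series  # peptide -> module id (0 = unassigned)
    eigenpeptides: pd.DataFrame  # module x sample
    kme: pd.DataFrame  # peptide x module correlation
    power: int
    min_module_size: int
    merge_cut: float

    @property
    def modules(self) -> list:
        return list(self.eigenpeptides.index)

    def members(self, module) -> pd.Index:
        return self.labels.index[self.labels == module]


def _merge_modules(
    Z: pd.DataFrame, labels: pd.Series, merge_cut: float
) -> tuple[pd.Series, pd.DataFrame]:
    """Iteratively merge module pairs whose eigenpeptides have
    dissimilarity (1 - correlation) below merge_cut; idempotent at exit."""
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        eig = {
            m: _eigenpeptide(Z.loc[labels[labels == m].index].to_numpy())
            for m in mods
        }
        if len(mods) < 2:
            break
        best = None
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                r = np.corrcoef(eig[m1], eig[m2])[0, 1]
                d = 1.0 - r
                if d < merge_cut and (best is None or d < best[0]):
                    best = (d, m1, m2)
        if best is None:
            break
        _, m1, m2 = best
        labels[labels == m2] = m1
    mods = sorted(m for m in labels.unique() if m != 0)
    eig_df = pd.DataFrame(
        {m: _eigenpeptide(Z.loc[labels[labels == m].index].to_numpy()) for m in mods},
        index=Z.columns,
    ).T
    return labels, eig_df


def build_modules(
    resp: pd.DataFrame,
    power: int = DEFAULT_POWER,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    merge_cut: float = DEFAULT_MERGE_CUT,
    signed: bool = False,
    cut_height: float | None = None,
) -> SubnetworkModel:
    """Detect coregulation modules from an insulin-response matrix.

    Correlations are pairwise-complete; constant peptide rows are excluded
    with a warning.  The unsigned adjacency |r|^power (signed variant:
    ((1+r)/2)^power) feeds TOM, average-linkage clustering of 1 - TOM, a
    static height cut, dissolution of clusters below `min_module_size`, and
    eigenpeptide-based merging.  When `cut_height` is None the tree is cut
    at the midpoint of the largest gap in merge heights — coherent modules
    merge low and join the background high, so the widest gap separates
    module formation from background agglomeration; over-splitting is
    corrected by the eigenpeptide merge step.
    """
    X = resp.to_numpy(dtype=float)
    const = np.nanstd(X, axis=1) == 0
    if const.any():
        log.warning("excluding %d constant peptide rows", int(const.sum()))
    use = resp.index[~const]
    if len(use) < 2 * min_module_size:
        raise ValueError("too few peptides for module detection")
    sub = resp.loc[use]
    corr = sub.T.corr(min_periods=3).to_numpy()
    corr = np.nan_to_num(corr)
    adj = ((1 + corr) / 2) ** power if signed else np.abs(corr) ** power
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    Zlink = linkage(squareform(dist, checks=False), method="average")
    if cut_height is None:
        heights = np.sort(Zlink[:, 2])
        if heights.size > 1:
            gaps = np.diff(heights)
            i = int(np.argmax(gaps))
            cut_height = float((heights[i] + heights[i + 1]) / 2)
        else:
            cut_height = float(heights[-1])
    raw = fcluster(Zlink, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=use)
    counts = labels.value_counts()
    labels[labels.map(counts) < min_module_size] = 0
    # relabel surviving modules 1..k in decreasing size order
    kept = [m for m in counts.index if counts[m] >= min_module_size]
    kept = sorted(kept, key=lambda m: -counts[m])
    remap = {m: i + 1 for i, m in enumerate(kept)}
    labels = labels.map(lambda m: remap.get(m, 0))
    labels = labels.reindex(resp.index, fill_value=0)

    Zstd = pd.DataFrame(_standardise(sub.to_numpy()), index=use, columns=resp.columns)
    labels_used, eig = _merge_modules(Zstd, labels.loc[use], merge_cut)
    labels.loc[use] = labels_used
    # renumber after merging
    mods = sorted(m for m in labels.unique() if m != 0)
    remap = {m: i + 1 for i, m in enumerate(mods)}
    labels = labels.map(lambda m: remap.get(m, 0))
    eig.index = [remap[m] for m in eig.index]
    eig = eig.sort_index()

    kme = pd.DataFrame(index=resp.index, columns=eig.index, dtype=float)
    Zfull = _standardise(resp.to_numpy(dtype=float))
    for m in eig.index:
        e = eig.loc[m].to_numpy()
        denom = np.linalg.norm(e) * np.linalg.norm(Zfull, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            kme[m] = (Zfull @ e) / denom
    return SubnetworkModel(
        labels=labels,
        eigenpeptides=eig,
        kme=kme,
        power=power,
        min_module_size=min_module_size,
        merge_cut=merge_cut,
    )


def eigenpeptide_trait_correlation(
    model: SubnetworkModel, trait: pd.Series
) -> pd.DataFrame:
    """Pearson r and two-sided p of each eigenpeptide with a per-sample trait."""
    rows = []
    for m in model.modules:
        e = model.eigenpeptides.loc[m]
        joined = pd.concat([e, trait], axis=1, join="inner").dropna()
        if len(joined) < 3:
            rows.append((m, np.nan, np.nan, len(joined)))
            continue
        r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
        rows.append((m, float(r), float(p), len(joined)))
    return pd.DataFrame(rows, columns=["module", "r", "p", "n"]).set_index("module")


def term_enrichment(
    foreground,
    background,
    terms: dict,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher exact tests for term sets.

    Terms overlapping the foreground in fewer than `min_overlap` members are
    not tested.  Fold enrichment is (overlap/|fg|) / (|term ∩ bg|/|bg|).
    BH adjustment is applied across the tested terms.
    """
    fg = set(foreground)
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    rows = []
    for term, members in terms.items():
        tset = set(members) & bg
        overlap = len(tset & fg)
        if overlap < min_overlap:
            continue
        table = [
            [overlap, len(fg) - overlap],
            [len(tset) - overlap, len(bg) - len(fg) - len(tset) + overlap],
        ]
        p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        fold = (overlap / len(fg)) / (len(tset) / len(bg)) if tset else np.nan
        rows.append((term, overlap, len(tset), len(fg), len(bg), fold, p))
    out = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "foreground_size",
                 "background_size", "fold_enrichment", "p"],
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def pca_fold_changes(lfc: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the combination x peptide fold-change matrix.

    Returns per-combination component scores and percent variance explained
    per component (summing to 100 over all components).
    """
    X = lfc.to_numpy(dtype=float).T  # combinations x peptides
    X = np.nan_to_num(X - np.nanmean(X, axis=0, keepdims=True))
    pca = PCA()
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=lfc.columns, columns=cols),
        pca.explained_variance_ratio_ * 100.0,
    )
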