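"""Kinase substrate enrichment analysis (KSEA) on insulin-response values.

Annotation curation keeps in-vivo-supported edges, merges kinase isoforms,
drops autophosphorylation edges and promiscuous substrates (targeted by four
or more kinases).  Per sample, peptides are ranked by insulin response and
each kinase's substrate set is scored with an unweighted GSEA-style running
sum; significance is an empirical permutation p-value obtained by permuting
substrate-set membership over the ranked list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SampleMeta, combo_label

__all__ = [
    "curate_annotations",
    "KinaseSubstrateMap",
    "running_sum_score",
    "ksea_sample",
    "ksea_matrix",
    "KSEAScores",
]

log = logging.getLogger(__name__)

MAX_KINASES_PER_SITE = 4
MIN_SUBSTRATES_PER_SAMPLE = 5
MIN_SIGNIFICANT_SAMPLES = 5


# ---------------------------------------------------------------------------
# annotation curation

@dataclass
class KinaseSubstrateMap:
    """Curated kinase -> substrate sets plus curation provenance logs."""

    substrates: dict[str, set]
    merged_isoforms: dict[str, str] = field(default_factory=dict)
    removed_autophosphorylation: list = field(default_factory=list)
    removed_promiscuous: list = field(default_factory=list)

    def __len__(self):
        return len(self.substrates)


def _resolve_aliases(alias: dict[str, str]) -> dict[str, str]:
    """Flatten an isoform alias table, rejecting cycles."""
    resolved = {}
    for start in alias:
        seen = {start}
        cur = start
        while cur in alias:
            cur = alias[cur]
            if cur in seen:
                raise ValueError(f"alias cycle involving {cur!r}")
            seen.add(cur)
        resolved[start] = cur
    return resolved


def curate_annotations(
    edges: pd.DataFrame,
    alias: dict[str, str] | None = None,
    in_vivo_only: bool = True,
    supplement: dict[str, set] | None = None,
    max_kinases_per_site: int = MAX_KINASES_PER_SITE,
) -> KinaseSubstrateMap:
    """Curate a raw kinase-substrate edge list.

    `edges` columns: kinase, substrate; optional: in_vivo (bool),
    substrate_protein (for autophosphorylation detection).  `alias` maps
    isoform labels to merged kinase labels (e.g. Akt1 -> Akt).  `supplement`
    adds extra substrate sets after curation (e.g. a putative-substrate list
    for a kinase of interest), bypassing the evidence filter but not the
    promiscuity rule.
    """
    df = edges.copy()
    if in_vivo_only and "in_vivo" in df.columns:
        df = df[df["in_vivo"].astype(bool)]
    merged = {}
    if alias:
        flat = _resolve_aliases(alias)
        merged = {k: v for k, v in flat.items() if k != v}
        df["kinase"] = df["kinase"].map(lambda k: flat.get(k, k))

    removed_auto = []
    if "substrate_protein" in df.columns:
        auto = df["substrate_protein"].astype(str) == df["kinase"].astype(str)
        removed_auto = list(df.loc[auto, "substrate"])
        df = df[~auto]

    sets: dict[str, set] = {}
    for k, grp in df.groupby("kinase"):
        sets[str(k)] = set(grp["substrate"])
    if supplement:
        for k, subs in supplement.items():
            sets.setdefault(str(k), set()).update(subs)

    counts: dict[str, int] = {}
    for subs in sets.values():
        for s in subs:
            counts[s] = counts.get(s, 0) + 1
    promiscuous = {s for s, n in counts.items() if n >= max_kinases_per_site}
    for k in list(sets):
        sets[k] = sets[k] - promiscuous
        if not sets[k]:
            del sets[k]
    if promiscuous:
        log.info("removed %d promiscuous substrates", len(promiscuous))
    return KinaseSubstrateMap(
        substrates=sets,
        merged_isoforms=merged,
        removed_autophosphorylation=removed_auto,
        removed_promiscuous=sorted(promiscuous),
    )


# ---------------------------------------------------------------------------
# running-sum statistic

def running_sum_score(positions: np.ndarray, n: int, s: int) -> np.ndarray:
    """Signed maximum deviation of the unweighted running sum.

    `positions`: (..., s) array of sorted 1-based ranks of the substrate set
    within a list of n peptides.  Increments are +1/s at substrate positions
    and -1/(n-s) elsewhere; the score is the deviation of largest magnitude
    (positive when substrates concentrate at the top of the ranking), with
    |score| <= 1 by construction.
    """
    positions = np.asarray(positions, dtype=float)
    j = np.arange(1, s + 1, dtype=float)
    misses = positions - j  # non-substrates preceding the j-th substrate
    after = j / s - misses / (n - s)
    before = (j - 1) / s - misses / (n - s)
    pos = after.max(axis=-1)
    neg = before.min(axis=-1)
    return np.where(pos >= -neg, pos, neg)


def _permutation_positions(rng, n_perm: int, n: int, s: int) -> np.ndarray:
    """n_perm uniformly random substrate placements (sorted 1-based ranks)."""
    r = rng.random((n_perm, n))
    picks = np.argpartition(r, s - 1, axis=1)[:, :s]
    return np.sort(picks, axis=1) + 1


def ksea_sample(
    values: pd.Series,
    substrates,
    n_perm: int = 1000,
    rng=None,
    method: str = "running_sum",
) -> tuple[float, float, int]:
    """Score one sample's ranked responses against one substrate set.

    Peptides are ranked by descending response, ties broken by stable
    peptide-id order.  Returns (score, empirical p, n quantified substrates);
    the permutation null permutes substrate-set membership uniformly and the
    empirical p uses the (1 + exceedances) / (n_perm + 1) estimator, so
    p >= 1/(n_perm+1).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    v = values.dropna()
    if v.empty:
        return np.nan, np.nan, 0
    order = v.sort_index().sort_values(ascending=False, kind="stable")
    n = len(order)
    member = order.index.isin(set(substrates))
    s = int(member.sum())
    if s == 0 or s == n:
        return np.nan, np.nan, s
    positions = np.flatnonzero(member) + 1

    if method == "zscore":
        # mean-rank z alternative: negative mean rank centred and scaled
        mean_rank = positions.mean()
        mu = (n + 1) / 2
        sigma = np.sqrt((n + 1) * (n - s) / (12 * s))
        obs = (mu - mean_rank) / sigma
        perm = _permutation_positions(rng, n_perm, n, s)
        perm_stat = (mu - perm.mean(axis=1)) / sigma
    elif method == "running_sum":
        obs = float(running_sum_score(positions, n, s))
        perm = _permutation_positions(rng, n_perm, n, s)
        perm_stat = running_sum_score(perm, n, s)
    else:
        raise ValueError(f"unknown method: {method!r}")

    # ties count as exceedances; the tolerance absorbs float differences
    # between arithmetic paths that yield mathematically equal scores
    p = (1.0 + np.sum(np.abs(perm_stat) >= abs(obs) - 1e-9)) / (n_perm + 1.0)
    return float(obs), float(p), s


# ---------------------------------------------------------------------------
# full matrix

@dataclass
class KSEAScores:
    """Kinase x sample enrichment scores with empirical p-values."""

    scores: pd.DataFrame
    pvalues: pd.DataFrame
    n_substrates: pd.DataFrame
    qualifying: list[str]

    def to_tsv(self, score_path, p_path):
        self.scores.to_csv(score_path, sep="\t", index_label="kinase")
        self.pvalues.to_csv(p_path, sep="\t", index_label="kinase")


def _qualifying_peptides(resp: pd.DataFrame, meta: SampleMeta) -> pd.Index:
    """Peptide universe: quantified in >=50% of samples and with >=1 insulin
    response value in every strain-diet combination."""
    frac = resp.notna().mean(axis=1)
    keep = frac >= 0.5
    for strain in meta.strains:
        for diet in meta.diets:
            cols = [
                c
                for c in meta.select(strain=strain, diet=diet, treatment="insulin")
                if c in resp.columns
            ]
            if not cols:
                log.warning("no insulin samples for %s", combo_label(strain, diet))
                continue
            keep &= resp[cols].notna().any(axis=1)
    return resp.index[keep]


def ksea_matrix(
    resp: pd.DataFrame,
    meta: SampleMeta,
    annotations: KinaseSubstrateMap,
    n_perm: int = 1000,
    seed: int = 0,
    min_substrates: int = MIN_SUBSTRATES_PER_SAMPLE,
    min_significant_samples: int = MIN_SIGNIFICANT_SAMPLES,
    p_cut: float = 0.05,
    method: str = "running_sum",
) -> KSEAScores:
    """KSEA over every (kinase, insulin-stimulated sample) cell.

    Cells with fewer than `min_substrates` quantified substrates are left
    undefined; kinases reaching empirical p < p_cut in at least
    `min_significant_samples` samples are listed as qualifying for downstream
    strain/diet testing.  Deterministic for a fixed seed.
    """
    universe = _qualifying_peptides(resp, meta)
    sub = resp.loc[universe]
    kinases = sorted(annotations.substrates)
    scores = pd.DataFrame(np.nan, index=kinases, columns=sub.columns)
    pvals = pd.DataFrame(np.nan, index=kinases, columns=sub.columns)
    nsub = pd.DataFrame(0, index=kinases, columns=sub.columns)
    root = np.random.default_rng(seed)
    # one independent child stream per kinase so kinase-level results do not
    # depend on which other kinases are present
    streams = {k: np.random.default_rng(st) for k, st in
               zip(kinases, root.spawn(len(kinases)))}
    for k in kinases:
        subs = annotations.substrates[k]
        rng = streams[k]
        for col in sub.columns:
            v = sub[col]
            quantified = v.dropna().index.isin(subs).sum()
            nsub.loc[k, col] = quantified
            if quantified < min_substrates:
                continue
            score, p, _ = ksea_sample(v, subs, n_perm=n_perm, rng=rng, method=method)
            scores.loc[k, col] = score
            pvals.loc[k, col] = p
    qualifying = [
        k for k in kinases if int((pvals.loc[k] < p_cut).sum()) >= min_significant_samples
    ]
    return KSEAScores(scores=scores, pvalues=pvals, n_substrates=nsub,
                      qualifying=qualifying)
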