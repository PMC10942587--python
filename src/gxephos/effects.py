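"""Strain and diet effect classification of insulin-regulated phosphopeptides.

Insulin responses (insulin-stimulated log2 intensity minus the unstimulated
median of the same strain-diet combination) isolate acute signalling from
baseline abundance.  Two independent cascades then classify each regulated
peptide:

* Strain effects (control diet only): one-way ANOVA of response ~ strain,
  Storey q across peptides; per-strain Welch t-tests against the reference
  strain for significant peptides; and a piecewise-linear magnitude gate on
  the strain's fold change relative to the reference's.
* Diet effects: two-way ANOVA of response ~ strain * diet.  A significant
  interaction routes to per-strain CHOW-vs-HFD t-tests plus the gate
  (strain x diet effect); otherwise a significant diet main effect routes to
  a gate on the across-strain mean fold changes (uniform diet effect).

The gate accepts a candidate fold change as meaningfully different from a
reference fold change x when it lies above f(x) or below g(x), with
g(x) = -f(-x).  The margin f(x) - x shrinks from 0.58 to 0.29 for weakly
regulated peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import oneway_F, twoway_typeII
from .data import PhosphoTable, SampleMeta, combo_label
from .qvalue import bh_adjust, qvalues

__all__ = [
    "GATE_BASE",
    "REFERENCE_STRAIN",
    "insulin_response",
    "gate_f",
    "gate_g",
    "outside_gate",
    "strain_effects",
    "diet_effects",
    "classify_effects",
    "entity_anova",
    "EffectCalls",
]

log = logging.getLogger(__name__)

GATE_BASE = 0.58  # log2(1.5): base magnitude threshold c
REFERENCE_STRAIN = "C57Bl6J"
CHOW, HFD = "CHOW", "HFD"


# ---------------------------------------------------------------------------
# insulin responses

def insulin_response(
    table: PhosphoTable,
    meta: SampleMeta,
    peptide_ids=None,
    insulin_label: str = "insulin",
) -> pd.DataFrame:
    """Insulin response values: peptide x insulin-stimulated-sample matrix.

    Each insulin-stimulated value is normalised by subtracting the
    unstimulated median of its strain-diet combination.  Responses are
    missing wherever the combination has no unstimulated values.
    """
    if peptide_ids is None:
        peptide_ids = table.peptide_ids
    sub = table.values.loc[peptide_ids]
    ins_samples = meta.select(treatment=insulin_label)
    out = pd.DataFrame(index=sub.index, columns=ins_samples, dtype=float)
    for strain in meta.strains:
        for diet in meta.diets:
            ins = meta.select(strain=strain, diet=diet, treatment=insulin_label)
            uns = [
                s
                for s in meta.select(strain=strain, diet=diet)
                if s not in set(ins)
            ]
            if not uns:
                log.warning(
                    "no unstimulated samples in %s; responses left missing",
                    combo_label(strain, diet),
                )
                continue
            med = sub[uns].median(axis=1)
            for s in ins:
                out[s] = sub[s] - med
    return out


# ---------------------------------------------------------------------------
# magnitude gate

def gate_f(x, c: float = GATE_BASE, printed_g_variant: bool = False):
    """Upper acceptance bound f(x) around a reference log2 fold change x.

    Piecewise linear and continuous, with f(x) - x in [c/2, c]:
    x + c for x >= 2c; (5/4)x + c/2 for 0 <= x < 2c; x + c/2 for
    -c/2 <= x < 0; (4/5)x + (2/5)c for -3c <= x < -c/2; x + c below.
    """
    x = np.asarray(x, dtype=float)
    conds = [
        x >= 2 * c,
        (x >= 0) & (x < 2 * c),
        (x >= -c / 2) & (x < 0),
        (x >= -3 * c) & (x < -c / 2),
        x < -3 * c,
    ]
    funcs = [
        lambda v: v + c,
        lambda v: 1.25 * v + c / 2,
        lambda v: v + c / 2,
        lambda v: 0.8 * v + 0.4 * c,
        lambda v: v + c,
    ]
    return np.piecewise(x, conds, funcs)


def gate_g(x, c: float = GATE_BASE, printed_g_variant: bool = False):
    """Lower acceptance bound g(x) = -f(-x).

    `printed_g_variant=True` reproduces a published variant whose second
    piece uses (4/5)x + (2/5)c on [c/2, 3c); that form is discontinuous at
    both knots and is provided for comparison only.
    """
    x = np.asarray(x, dtype=float)
    g = -gate_f(-x, c)
    if printed_g_variant:
        sel = (x >= c / 2) & (x < 3 * c)
        g = np.where(sel, 0.8 * x + 0.4 * c, g)
    return g


def outside_gate(candidate, reference, c: float = GATE_BASE):
    """True where candidate lfc is meaningfully different from reference lfc."""
    candidate = np.asarray(candidate, dtype=float)
    return (candidate > gate_f(reference, c)) | (candidate < gate_g(reference, c))


# ---------------------------------------------------------------------------
# cascades

def _welch_p(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def strain_effects(
    resp: pd.DataFrame,
    lfc: pd.DataFrame,
    meta: SampleMeta,
    reference_strain: str = REFERENCE_STRAIN,
    chow_label: str = CHOW,
    q_cut: float = 0.05,
    c: float = GATE_BASE,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Strain-effect cascade on control-diet insulin responses.

    Returns a frame with the ANOVA q, per-strain verdicts
    {stronger, weaker, none} against the reference strain, and the overall
    strain_effect flag (>= 1 strain passing ANOVA q, t-test q and gate).
    """
    strains = [s for s in meta.strains if s != reference_strain]
    chow_cols = {
        s: meta.select(strain=s, diet=chow_label, treatment="insulin")
        for s in meta.strains
    }
    X = {s: resp[cols].to_numpy(dtype=float) for s, cols in chow_cols.items()}

    # (1) one-way ANOVA response ~ strain on CHOW
    p_anova = np.full(len(resp), np.nan)
    for i in range(len(resp)):
        groups, labels = [], []
        for s in meta.strains:
            v = X[s][i]
            v = v[np.isfinite(v)]
            if v.size >= 2:
                groups.append(v)
                labels.extend([s] * v.size)
        if len(groups) >= 2:
            y = np.concatenate(groups)
            _, p, _, _ = oneway_F(y, np.asarray(labels))
            p_anova[i] = p
    q_anova = pd.Series(qvalues(p_anova), index=resp.index)

    # (2) per-strain Welch t-tests vs reference within the significant set,
    # pooled into one q-value family across (peptide, strain)
    sig = q_anova < q_cut
    t_p = pd.DataFrame(np.nan, index=resp.index, columns=strains)
    ref_rows = X[reference_strain]
    for i, pid in enumerate(resp.index):
        if not sig.iloc[i]:
            continue
        for s in strains:
            t_p.loc[pid, s] = _welch_p(X[s][i], ref_rows[i], equal_var)
    t_q = pd.DataFrame(
        qvalues(t_p.to_numpy().ravel()).reshape(t_p.shape),
        index=t_p.index,
        columns=t_p.columns,
    )

    # (3) magnitude gate on CHOW fold changes vs the reference strain's
    ref_lfc = lfc[combo_label(reference_strain, chow_label)]
    verdicts = pd.DataFrame("none", index=resp.index, columns=strains)
    for s in strains:
        s_lfc = lfc[combo_label(s, chow_label)]
        passed = (t_q[s] < q_cut) & outside_gate(s_lfc, ref_lfc, c)
        stronger = np.where(
            np.sign(ref_lfc) >= 0, s_lfc > gate_f(ref_lfc, c), s_lfc < gate_g(ref_lfc, c)
        )
        verdicts[s] = np.where(passed, np.where(stronger, "stronger", "weaker"), "none")

    out = verdicts.add_prefix("strain:")
    out.insert(0, "strain_anova_q", q_anova)
    out["strain_effect"] = (verdicts != "none").any(axis=1)
    return out


def diet_effects(
    resp: pd.DataFrame,
    lfc: pd.DataFrame,
    meta: SampleMeta,
    chow_label: str = CHOW,
    hfd_label: str = HFD,
    q_cut: float = 0.05,
    c: float = GATE_BASE,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Diet-effect cascade: two-way ANOVA then interaction- or main-routed gates.

    Returns interaction and diet-main q-values, per-strain HFD-vs-CHOW
    verdicts {stronger, weaker, none} and diet_class in
    {none, uniform, strainxdiet}.
    """
    strains = meta.strains
    cols = {
        (s, d): meta.select(strain=s, diet=d, treatment="insulin")
        for s in strains
        for d in (chow_label, hfd_label)
    }
    X = {key: resp[c_].to_numpy(dtype=float) for key, c_ in cols.items()}

    p_int = np.full(len(resp), np.nan)
    p_diet = np.full(len(resp), np.nan)
    for i in range(len(resp)):
        y, a, b = [], [], []
        for (s, d), arr in X.items():
            v = arr[i]
            v = v[np.isfinite(v)]
            y.extend(v)
            a.extend([s] * v.size)
            b.extend([d] * v.size)
        if len(set(b)) < 2 or len(set(a)) < 2:
            continue
        res = twoway_typeII(np.asarray(y), np.asarray(a), np.asarray(b))
        p_int[i] = res["ab"]["p"]
        p_diet[i] = res["b"]["p"]
    q_int = pd.Series(qvalues(p_int), index=resp.index)
    q_diet = pd.Series(qvalues(p_diet), index=resp.index)

    # interaction branch: per-strain CHOW vs HFD t-tests, pooled q family
    int_sig = q_int < q_cut
    t_p = pd.DataFrame(np.nan, index=resp.index, columns=strains)
    for i, pid in enumerate(resp.index):
        if not int_sig.iloc[i]:
            continue
        for s in strains:
            t_p.loc[pid, s] = _welch_p(
                X[(s, hfd_label)][i], X[(s, chow_label)][i], equal_var
            )
    t_q = pd.DataFrame(
        qvalues(t_p.to_numpy().ravel()).reshape(t_p.shape),
        index=t_p.index,
        columns=t_p.columns,
    )

    verdicts = pd.DataFrame("none", index=resp.index, columns=strains)
    for s in strains:
        chow_lfc = lfc[combo_label(s, chow_label)]
        hfd_lfc = lfc[combo_label(s, hfd_label)]
        passed = int_sig & (t_q[s] < q_cut) & outside_gate(hfd_lfc, chow_lfc, c)
        stronger = np.where(
            np.sign(chow_lfc) >= 0,
            hfd_lfc > gate_f(chow_lfc, c),
            hfd_lfc < gate_g(chow_lfc, c),
        )
        verdicts[s] = np.where(passed, np.where(stronger, "stronger", "weaker"), "none")

    strainxdiet = (verdicts != "none").any(axis=1)

    # uniform branch: gate on across-strain mean fold changes
    chow_mean = lfc[[combo_label(s, chow_label) for s in strains]].mean(axis=1)
    hfd_mean = lfc[[combo_label(s, hfd_label) for s in strains]].mean(axis=1)
    uniform = (~int_sig) & (q_diet < q_cut) & outside_gate(hfd_mean, chow_mean, c)

    diet_class = np.where(strainxdiet, "strainxdiet", np.where(uniform, "uniform", "none"))
    out = verdicts.add_prefix("diet:")
    out.insert(0, "interaction_q", q_int)
    out.insert(1, "diet_main_q", q_diet)
    out["diet_class"] = diet_class
    return out


@dataclass
class EffectCalls:
    """Joined strain- and diet-effect verdicts per regulated peptide."""

    frame: pd.DataFrame
    responses: pd.DataFrame

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index_label="peptide_id")


def classify_effects(
    table: PhosphoTable,
    meta: SampleMeta,
    regulated_ids,
    lfc: pd.DataFrame,
    reference_strain: str = REFERENCE_STRAIN,
    q_cut: float = 0.05,
    c: float = GATE_BASE,
) -> EffectCalls:
    """Run both cascades on the regulated set and join the verdicts."""
    resp = insulin_response(table, meta, regulated_ids)
    lfc = lfc.loc[resp.index]
    s = strain_effects(resp, lfc, meta, reference_strain, q_cut=q_cut, c=c)
    d = diet_effects(resp, lfc, meta, q_cut=q_cut, c=c)
    return EffectCalls(frame=s.join(d), responses=resp)


# ---------------------------------------------------------------------------
# score-matrix ANOVAs (shared by kinase scores and other entity profiles)

def entity_anova(
    scores: pd.DataFrame,
    meta: SampleMeta,
    design: str = "strain-on-CHOW",
    chow_label: str = CHOW,
) -> pd.DataFrame:
    """Per-entity ANOVA across an entity x sample score matrix, BH-adjusted.

    design="strain-on-CHOW": one-way strain ANOVA restricted to control-diet
    samples; design="strainxdiet": two-way strain x diet ANOVA returning
    interaction and diet-main adjusted p separately.
    """
    info = meta.frame.set_index("sample_id")
    cols = [c_ for c_ in scores.columns if c_ in info.index]
    strain = info.loc[cols, "strain"].to_numpy()
    diet = info.loc[cols, "diet"].to_numpy()
    vals = scores[cols].to_numpy(dtype=float)

    if design == "strain-on-CHOW":
        keep = diet == chow_label
        ps = []
        for row in vals:
            y = row[keep]
            g = strain[keep]
            ok = np.isfinite(y)
            counts = pd.Series(g[ok]).value_counts()
            if (counts >= 2).sum() < 2:
                ps.append(np.nan)
                continue
            _, p, _, _ = oneway_F(y[ok], g[ok])
            ps.append(p)
        return pd.DataFrame(
            {"p": ps, "p_adj": bh_adjust(ps)}, index=scores.index
        )
    if design == "strainxdiet":
        p_int, p_diet = [], []
        for row in vals:
            ok = np.isfinite(row)
            if ok.sum() < 4 or len(set(diet[ok])) < 2 or len(set(strain[ok])) < 2:
                p_int.append(np.nan)
                p_diet.append(np.nan)
                continue
            res = twoway_typeII(row[ok], strain[ok], diet[ok])
            p_int.append(res["ab"]["p"])
            p_diet.append(res["b"]["p"])
        return pd.DataFrame(
            {
                "interaction_p": p_int,
                "interaction_p_adj": bh_adjust(p_int),
                "diet_p": p_diet,
                "diet_p_adj": bh_adjust(p_diet),
            },
            index=scores.index,
        )
    raise ValueError(f"unknown design: {design!r}")
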