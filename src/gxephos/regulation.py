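"""Identification of insulin-regulated phosphopeptides.

A phosphopeptide is callable when it is well quantified (>= 3 insulin and
>= 3 unstimulated values) in at least 8 of the strain-diet combinations.
Callable peptides are tested for an insulin main effect in the full
strain x diet x treatment factorial; p-values are converted to Storey
q-values as a single family, and the final call additionally requires the
largest-magnitude log2(insulin/unstimulated) fold change across combinations
(computed from condition medians) to exceed log2(1.5) ~ 0.58.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anova import _f_pvalue, treatment_main_F
from .data import PhosphoTable, SampleMeta, combo_label
from .qvalue import qvalues

__all__ = [
    "LFC_CUT",
    "Q_CUT",
    "quantification_filter",
    "insulin_anova",
    "fold_changes",
    "call_regulated",
    "RegulationResult",
    "analyse_regulation",
]

LFC_CUT = 0.58  # log2(1.5) to the paper-standard 2 dp
Q_CUT = 0.05


def _combo_samples(meta: SampleMeta, insulin_label: str = "insulin"):
    """Per-combination (insulin sample ids, unstimulated sample ids)."""
    out = {}
    for strain in meta.strains:
        for diet in meta.diets:
            ins = meta.select(strain=strain, diet=diet, treatment=insulin_label)
            uns = [
                s
                for s in meta.select(strain=strain, diet=diet)
                if s not in set(ins)
            ]
            out[combo_label(strain, diet)] = (ins, uns)
    return out


def quantification_filter(
    table: PhosphoTable,
    meta: SampleMeta,
    min_per_arm: int = 3,
    min_combinations: int = 8,
    insulin_label: str = "insulin",
) -> tuple[pd.Index, pd.DataFrame]:
    """Quantification filter over strain-diet combinations.

    A combination passes for a peptide iff it holds >= min_per_arm present
    insulin values and >= min_per_arm present unstimulated values; the
    peptide is retained iff >= min_combinations combinations pass.

    Returns (retained peptide index, boolean pass-pattern frame
    peptide x combination).
    """
    combos = _combo_samples(meta, insulin_label)
    present = table.values.notna()
    pattern = pd.DataFrame(index=table.peptide_ids, dtype=bool)
    for combo, (ins, uns) in combos.items():
        ok_ins = present[ins].sum(axis=1) >= min_per_arm
        ok_uns = present[uns].sum(axis=1) >= min_per_arm
        pattern[combo] = ok_ins & ok_uns
    keep = pattern.sum(axis=1) >= min_combinations
    return pattern.index[keep], pattern


def insulin_anova(
    table: PhosphoTable,
    meta: SampleMeta,
    peptide_ids=None,
    insulin_label: str = "insulin",
    ss: str = "II",
) -> pd.DataFrame:
    """Insulin main-effect F-test per peptide on all available samples.

    Fits the strain x diet x treatment factorial by least squares on present
    values (unbalanced, incomplete cells allowed) and returns the F statistic
    and p-value for the treatment main effect with its degrees of freedom.
    """
    if peptide_ids is None:
        peptide_ids = table.peptide_ids
    sample_order = meta.sample_ids
    vals = table.values[sample_order].to_numpy(dtype=float)
    idx = {p: i for i, p in enumerate(table.peptide_ids)}
    mcols = meta.frame.set_index("sample_id").loc[sample_order]
    strain = mcols["strain"].to_numpy()
    diet = mcols["diet"].to_numpy()
    treat = (mcols["treatment"].to_numpy() == insulin_label).astype(float)

    if ss == "II":
        # Fast closed form: the Type-II conditioning set for the treatment
        # main effect saturates the strain-diet combinations, so treatment SS
        # follows from within-combination residualisation and the error term
        # from the saturated three-way cell means.  Same algebra as
        # anova.treatment_main_F, vectorised with bincount group sums.
        _, combo_code = np.unique(
            np.char.add(np.char.add(strain.astype(str), "|"), diet.astype(str)),
            return_inverse=True,
        )
        ncombo = combo_code.max() + 1
        cell_code = combo_code * 2 + treat.astype(int)
        ncells = ncombo * 2
        rows = []
        for pid in peptide_ids:
            y = vals[idx[pid]]
            ok = np.isfinite(y)
            yv, cc, cl, tv = y[ok], combo_code[ok], cell_code[ok], treat[ok]
            n = yv.size
            n_c = np.bincount(cl, minlength=ncells)
            s_c = np.bincount(cl, weights=yv, minlength=ncells)
            ss_c = np.bincount(cl, weights=yv * yv, minlength=ncells)
            nz = n_c > 0
            rss_full = float(np.sum(ss_c[nz] - s_c[nz] ** 2 / n_c[nz]))
            df_err = n - int(nz.sum())
            n_g = np.bincount(cc, minlength=ncombo)
            with np.errstate(invalid="ignore"):
                my = np.bincount(cc, weights=yv, minlength=ncombo) / n_g
                mt = np.bincount(cc, weights=tv, minlength=ncombo) / n_g
            y_res = yv - my[cc]
            t_res = tv - mt[cc]
            denom = float(t_res @ t_res)
            if denom <= 1e-12:
                rows.append((pid, np.nan, np.nan, 1, df_err))
                continue
            ss_t = float(y_res @ t_res) ** 2 / denom
            F, p = _f_pvalue(ss_t, 1, rss_full, df_err)
            rows.append((pid, F, p, 1, df_err))
    else:
        rows = []
        for pid in peptide_ids:
            y = vals[idx[pid]]
            ok = np.isfinite(y)
            F, p, df1, df2 = treatment_main_F(
                y[ok], strain[ok], diet[ok], treat[ok], ss=ss
            )
            rows.append((pid, F, p, df1, df2))
    return pd.DataFrame(
        rows, columns=["peptide_id", "F", "p", "df_num", "df_err"]
    ).set_index("peptide_id")


def fold_changes(
    table: PhosphoTable,
    meta: SampleMeta,
    peptide_ids=None,
    insulin_label: str = "insulin",
) -> pd.DataFrame:
    """log2(insulin/unstimulated) per strain-diet combination from condition medians.

    Sign convention: insulin median minus unstimulated median, so positive
    means insulin-increased.  Missing where either condition median is
    undefined.
    """
    if peptide_ids is None:
        peptide_ids = table.peptide_ids
    sub = table.values.loc[peptide_ids]
    out = pd.DataFrame(index=sub.index)
    for combo, (ins, uns) in _combo_samples(meta, insulin_label).items():
        out[combo] = sub[ins].median(axis=1) - sub[uns].median(axis=1)
    return out


def _max_abs_lfc(lfc: pd.DataFrame) -> pd.Series:
    arr = lfc.to_numpy(dtype=float)
    out = np.full(arr.shape[0], np.nan)
    any_ok = np.isfinite(arr).any(axis=1)
    if any_ok.any():
        sub = arr[any_ok]
        j = np.nanargmax(np.abs(sub), axis=1)
        out[any_ok] = sub[np.arange(sub.shape[0]), j]
    return pd.Series(out, index=lfc.index)


def call_regulated(
    q: pd.Series,
    lfc: pd.DataFrame,
    q_cut: float = Q_CUT,
    lfc_cut: float = LFC_CUT,
) -> pd.DataFrame:
    """Final regulation call: q < q_cut AND |max fold change| > lfc_cut.

    Direction is the sign of the largest-magnitude combination fold change.
    """
    max_lfc = _max_abs_lfc(lfc)
    regulated = (q < q_cut) & (max_lfc.abs() > lfc_cut)
    direction = np.where(regulated, np.where(max_lfc > 0, "up", "down"), "")
    return pd.DataFrame(
        {
            "q": q,
            "max_lfc": max_lfc,
            "regulated": regulated.fillna(False),
            "direction": direction,
        },
        index=q.index,
    )


@dataclass
class RegulationResult:
    """Full output of the regulation stage."""

    stats: pd.DataFrame  # p, q, max_lfc, regulated, direction per tested peptide
    lfc: pd.DataFrame  # peptide x combination fold changes
    pass_pattern: pd.DataFrame  # peptide x combination quantification pattern
    tested: pd.Index

    @property
    def regulated_ids(self) -> pd.Index:
        return self.stats.index[self.stats["regulated"]]

    def to_tsv(self, path):
        out = self.stats.join(self.lfc.add_prefix("lfc:"))
        out.to_csv(path, sep="\t", index_label="peptide_id")


def analyse_regulation(
    table: PhosphoTable,
    meta: SampleMeta,
    min_per_arm: int = 3,
    min_combinations: int = 8,
    q_cut: float = Q_CUT,
    lfc_cut: float = LFC_CUT,
    insulin_label: str = "insulin",
    ss: str = "II",
) -> RegulationResult:
    """Quantification filter -> ANOVA -> q-values -> fold-change gate."""
    tested, pattern = quantification_filter(
        table, meta, min_per_arm, min_combinations, insulin_label
    )
    aov = insulin_anova(table, meta, tested, insulin_label, ss=ss)
    q = pd.Series(qvalues(aov["p"].to_numpy()), index=aov.index, name="q")
    lfc = fold_changes(table, meta, tested, insulin_label)
    calls = call_regulated(q, lfc, q_cut, lfc_cut)
    stats = aov.join(calls)
    stats["n_passing_combinations"] = pattern.loc[tested].sum(axis=1)
    return RegulationResult(stats=stats, lfc=lfc, pass_pattern=pattern, tested=tested)
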