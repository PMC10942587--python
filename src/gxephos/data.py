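"""In-memory containers and plain-text I/O for the pipeline's tables.

A cohort is described by two aligned tables: a phosphopeptide x sample log2
intensity matrix (with missing values as NaN and a per-peptide localisation
score), and per-sample metadata giving strain, diet, treatment and replicate.
Both round-trip through TSV/CSV so every stage can also be driven from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PhosphoTable", "SampleMeta", "combo_label"]

LOC_COL = "localisation_score"


def combo_label(strain, diet) -> str:
    """Canonical strain-diet combination label."""
    return f"{strain}|{diet}"


@dataclass
class SampleMeta:
    """Per-sample design metadata: strain x diet x treatment x replicate."""

    frame: pd.DataFrame  # columns: sample_id, strain, diet, treatment, replicate

    REQUIRED = ("sample_id", "strain", "diet", "treatment", "replicate")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def strains(self) -> list[str]:
        return list(pd.unique(self.frame["strain"]))

    @property
    def diets(self) -> list[str]:
        return list(pd.unique(self.frame["diet"]))

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.frame["treatment"]))

    @property
    def combos(self) -> list[str]:
        return [
            combo_label(s, d)
            for s in self.strains
            for d in self.diets
        ]

    def combo_of(self) -> pd.Series:
        """Strain-diet combination label per sample (indexed by sample_id)."""
        lab = self.frame.apply(lambda r: combo_label(r["strain"], r["diet"]), axis=1)
        return pd.Series(lab.values, index=self.frame["sample_id"].values)

    def select(self, **conditions) -> list[str]:
        """Sample ids matching equality conditions on metadata columns."""
        mask = pd.Series(True, index=self.frame.index)
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.frame[col].isin(list(val))
            else:
                mask &= self.frame[col] == val
        return list(self.frame.loc[mask, "sample_id"])

    def to_csv(self, path):
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleMeta":
        return cls(pd.read_csv(path))


@dataclass
class PhosphoTable:
    """Phosphopeptide x sample log2-intensity matrix with localisation scores.

    `values` is indexed by peptide_id with one column per sample; missing
    measurements are NaN.  `localisation` is the maximum localisation score of
    each peptide across samples, aligned to `values.index`.
    """

    values: pd.DataFrame
    localisation: pd.Series = field(default=None)

    def __post_init__(self):
        if self.localisation is None:
            self.localisation = pd.Series(1.0, index=self.values.index)
        self.localisation = self.localisation.reindex(self.values.index)
        finite_or_nan = np.isfinite(self.values.to_numpy(dtype=float)) | np.isnan(
            self.values.to_numpy(dtype=float)
        )
        if not finite_or_nan.all():
            raise ValueError("intensity matrix contains non-finite, non-missing values")

    @property
    def peptide_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, peptide_ids) -> "PhosphoTable":
        return PhosphoTable(
            self.values.loc[peptide_ids].copy(),
            self.localisation.loc[peptide_ids].copy(),
        )

    def align_to(self, meta: SampleMeta) -> "PhosphoTable":
        """Reorder columns to match metadata; error on mismatch."""
        want = meta.sample_ids
        missing = set(want) - set(self.values.columns)
        if missing:
            raise ValueError(f"samples in metadata but not in matrix: {sorted(missing)}")
        return PhosphoTable(self.values[want].copy(), self.localisation.copy())

    def to_tsv(self, path):
        out = self.values.copy()
        out.insert(0, LOC_COL, self.localisation)
        out.to_csv(path, sep="\t", index_label="peptide_id")

    @classmethod
    def from_tsv(cls, path) -> "PhosphoTable":
        df = pd.read_csv(path, sep="\t", index_col="peptide_id")
        loc = None
        if LOC_COL in df.columns:
            loc = df.pop(LOC_COL)
        return cls(df, loc)

    @classmethod
    def from_long(cls, frame: pd.DataFrame, peptide="peptide_id",
                  sample="sample_id", value="intensity",
                  localisation=LOC_COL) -> "PhosphoTable":
        """Build from a long (peptide, sample, intensity) table.

        Accepts search-engine style exports; localisation scores, when
        present, are collapsed to the per-peptide maximum.
        """
        wide = frame.pivot_table(index=peptide, columns=sample, values=value,
                                 aggfunc="first")
        wide.columns.name = None
        loc = None
        if localisation in frame.columns:
            loc = frame.groupby(peptide)[localisation].max()
        return cls(wide, loc)


def read_table(path) -> PhosphoTable:
    return PhosphoTable.from_tsv(path)


def read_meta(path) -> SampleMeta:
    return SampleMeta.from_csv(Path(path))
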