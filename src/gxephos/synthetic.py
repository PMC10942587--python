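"""Synthetic cohort generator with planted insulin, strain and diet effects.

Emulates the statistical structure of an in vivo phosphoproteomics cohort:
five strains x two diets x two treatments with a handful of replicates per
cell, ~10-20k phosphopeptides on a log2 intensity scale with 40-60%
missingness, a regulated subset carrying insulin effects that vary by strain
and diet, kinase annotations with curation traps, correlated phenotypes, and
tracer time courses.  Every generator is deterministic for a fixed seed and
returns the ground truth needed for recovery tests.

Model for a value of peptide p in sample (strain s, diet d, treatment t,
replicate r), on the log2 scale:

    y = baseline_p + strain_offset_{p,s} + diet_offset_{p,d} + shift_sample
        + insulin_effect_p(s, d) * [t == insulin] + N(0, replicate_sd)

Missingness is the union of a completely-random mask and an
intensity-dependent (logistic in the true value) left-censoring-type mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import PhosphoTable, SampleMeta, combo_label
from .phenotype import TracerExperiment

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_kinase_annotations",
    "SyntheticAnnotations",
    "generate_tracer_experiment",
    "generate_phenotype",
]

DEFAULT_STRAINS = ("C57Bl6J", "NOD", "BXH9", "CAST", "BXD34")


@dataclass
class CohortConfig:
    """Study-design and effect-size parameters of a synthetic cohort.

    Defaults describe the reference design: 5 strains x 2 diets x 2
    treatments with 6 replicates per cell, 10% of peptides
    insulin-regulated at 2.0 log2 units with replicate SD 0.25, and ~40%
    total missingness.  Of the regulated set, about half additionally carry
    a strain effect, a quarter a strain x diet interaction, and a few
    percent a uniform diet effect, mirroring the relative prevalence seen
    in vivo.  `n_replicates` may be an int or an inclusive (lo, hi) range
    sampled per design cell.  `replicate_sd_shape`, when set, draws
    per-peptide SDs from a gamma distribution with that shape (mean kept at
    `replicate_sd`).
    """

    n_strains: int = 5
    strain_labels: tuple = DEFAULT_STRAINS
    diets: tuple = ("CHOW", "HFD")
    treatments: tuple = ("unstimulated", "insulin")
    n_replicates: int | tuple = 6
    n_phosphopeptides: int = 2000
    fraction_insulin_regulated: float = 0.10
    fraction_strain_effect: float = 0.5
    fraction_uniform_diet: float = 0.025
    fraction_interaction: float = 0.25
    effect_size_lfc: float = 2.0
    replicate_sd: float = 0.25
    replicate_sd_shape: float | None = None
    strain_offset_sd: float = 0.5
    diet_offset_sd: float = 0.3
    sample_shift_sd: float = 0.2
    uniform_diet_shift: float | None = None  # default: effect_size_lfc / 2
    missing_rate_random: float = 0.15
    missing_intensity_midpoint: float = 21.5
    missing_intensity_slope: float = 0.9
    reference_strain: str = "C57Bl6J"
    seed: int = 0

    def __post_init__(self):
        self.strain_labels = tuple(self.strain_labels)[: self.n_strains]
        if len(self.strain_labels) != self.n_strains:
            raise ValueError("need n_strains strain labels")
        for name in (
            "fraction_insulin_regulated",
            "fraction_strain_effect",
            "fraction_uniform_diet",
            "fraction_interaction",
            "missing_rate_random",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size_lfc <= 0:
            raise ValueError("effect_size_lfc must be positive")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")
        lo, hi = self._rep_range()
        if lo < 1:
            raise ValueError("every design cell needs at least one replicate")
        if self.uniform_diet_shift is None:
            self.uniform_diet_shift = self.effect_size_lfc / 2.0

    def _rep_range(self) -> tuple[int, int]:
        if isinstance(self.n_replicates, (tuple, list)):
            lo, hi = self.n_replicates
            return int(lo), int(hi)
        return int(self.n_replicates), int(self.n_replicates)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted truth: per-peptide flags and true insulin effects per combo."""

    peptides: pd.DataFrame  # regulated, direction, strain/diet effect labels
    effects: pd.DataFrame  # peptide x combo true insulin log2 effect
    true_intensity: pd.DataFrame  # pre-missingness value matrix

    @property
    def regulated_ids(self) -> pd.Index:
        return self.peptides.index[self.peptides["regulated"]]

    def to_tsv(self, peptide_path, effect_path):
        self.peptides.to_csv(peptide_path, sep="\t", index_label="peptide_id")
        self.effects.to_csv(effect_path, sep="\t", index_label="peptide_id")


def _build_meta(cfg: CohortConfig, rng) -> SampleMeta:
    rows = []
    lo, hi = cfg._rep_range()
    for strain in cfg.strain_labels:
        for diet in cfg.diets:
            for treat in cfg.treatments:
                n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
                for rep in range(1, n + 1):
                    rows.append(
                        {
                            "sample_id": f"{strain}_{diet}_{treat}_{rep}",
                            "strain": strain,
                            "diet": diet,
                            "treatment": treat,
                            "replicate": rep,
                        }
                    )
    return SampleMeta(pd.DataFrame(rows))


def generate_cohort(cfg: CohortConfig) -> tuple[PhosphoTable, SampleMeta, GroundTruth]:
    """Generate one synthetic cohort.

    Returns the observed (masked) intensity table, the sample metadata and
    the ground truth.  Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    meta = _build_meta(cfg, rng)
    n_pep = cfg.n_phosphopeptides
    peptide_ids = pd.Index([f"pep{i:05d}" for i in range(n_pep)], name="peptide_id")
    strains = list(cfg.strain_labels)
    diets = list(cfg.diets)

    # planted flags
    regulated = rng.random(n_pep) < cfg.fraction_insulin_regulated
    direction = np.where(rng.random(n_pep) < 0.5, 1.0, -1.0)
    u = rng.random(n_pep)
    diet_class = np.where(
        regulated & (u < cfg.fraction_interaction),
        "strainxdiet",
        np.where(
            regulated & (u < cfg.fraction_interaction + cfg.fraction_uniform_diet),
            "uniform",
            "none",
        ),
    )
    strain_flag = regulated & (rng.random(n_pep) < cfg.fraction_strain_effect)
    non_ref = [s for s in strains if s != cfg.reference_strain]
    strain_affected = np.where(
        strain_flag, rng.choice(non_ref, size=n_pep), ""
    )
    # interaction may hit any strain whose insulin effect is intact
    int_candidates = np.array(
        [
            rng.choice([s for s in strains if s != sa] or strains)
            for sa in strain_affected
        ]
    )
    diet_affected = np.where(diet_class == "strainxdiet", int_candidates, "")

    # true insulin effect per (peptide, strain, diet)
    eff = {}
    base = direction * cfg.effect_size_lfc * regulated
    for s in strains:
        for d in diets:
            e = base.copy()
            e[(strain_affected == s)] = 0.0  # strain effect: removed on both diets
            if d != diets[0]:
                e[(diet_affected == s)] = 0.0  # interaction: removed on HFD only
                uni = diet_class == "uniform"
                e[uni] -= direction[uni] * cfg.uniform_diet_shift
            eff[combo_label(s, d)] = e
    effects = pd.DataFrame(eff, index=peptide_ids)

    # intensity matrix
    baseline = rng.uniform(18.0, 30.0, size=n_pep)
    strain_off = {s: rng.normal(0.0, cfg.strain_offset_sd, size=n_pep) for s in strains}
    diet_off = {d: rng.normal(0.0, cfg.diet_offset_sd, size=n_pep) for d in diets}
    shifts = rng.normal(0.0, cfg.sample_shift_sd, size=len(meta.frame))
    if cfg.replicate_sd_shape:
        pep_sd = rng.gamma(
            cfg.replicate_sd_shape, cfg.replicate_sd / cfg.replicate_sd_shape, size=n_pep
        )
    else:
        pep_sd = np.full(n_pep, cfg.replicate_sd)

    cols = {}
    for j, row in meta.frame.iterrows():
        mu = baseline + strain_off[row["strain"]] + diet_off[row["diet"]] + shifts[j]
        if row["treatment"] == "insulin":
            mu = mu + effects[combo_label(row["strain"], row["diet"])].to_numpy()
        noise = rng.normal(0.0, 1.0, size=n_pep) * pep_sd
        cols[row["sample_id"]] = mu + noise
    true_vals = pd.DataFrame(cols, index=peptide_ids)

    # missingness: MCAR union intensity-dependent MNAR (logistic in true value)
    X = true_vals.to_numpy()
    mcar = rng.random(X.shape) < cfg.missing_rate_random
    p_mnar = 1.0 / (
        1.0 + np.exp(cfg.missing_intensity_slope * (X - cfg.missing_intensity_midpoint))
    )
    mnar = rng.random(X.shape) < p_mnar
    observed = true_vals.mask(mcar | mnar)

    effect_class = np.where(
        ~regulated,
        "none",
        np.select(
            [
                strain_flag & (diet_class != "none"),
                strain_flag,
                diet_class == "uniform",
                diet_class == "strainxdiet",
            ],
            ["mixed", "strain", "uniform-diet", "strainxdiet"],
            default="regulated-only",
        ),
    )
    peptides = pd.DataFrame(
        {
            "regulated": regulated,
            "direction": np.where(regulated, np.where(direction > 0, "up", "down"), ""),
            "strain_effect": strain_flag,
            "strain_affected": strain_affected,
            "diet_class": np.where(regulated, diet_class, "none"),
            "diet_affected_strain": diet_affected,
            "effect_class": effect_class,
        },
        index=peptide_ids,
    )
    table = PhosphoTable(observed, pd.Series(1.0, index=peptide_ids))
    truth = GroundTruth(peptides=peptides, effects=effects, true_intensity=true_vals)
    return table, meta, truth


# ---------------------------------------------------------------------------
# kinase annotations

@dataclass
class SyntheticAnnotations:
    """Raw annotation edges plus the alias table and planted-signal key."""

    edges: pd.DataFrame  # kinase, substrate, in_vivo, substrate_protein
    alias: dict
    signal_kinases: list[str]
    null_kinases: list[str]


def generate_kinase_annotations(
    truth: GroundTruth,
    n_kinases: int = 10,
    substrates_per_kinase: int = 10,
    seed: int = 0,
    n_signal: int = 2,
    include_traps: bool = True,
) -> SyntheticAnnotations:
    """Generate a raw kinase->substrate edge list for curation and KSEA.

    Signal kinases draw substrates from coherently (same-direction)
    regulated peptides; null kinases draw uniformly.  With
    `include_traps`, the list also contains isoform duplicates (aliases),
    an autophosphorylation edge and one promiscuous site annotated under
    four kinases, to exercise the curation rules.
    """
    rng = np.random.default_rng(seed)
    if n_kinases == 0:
        return SyntheticAnnotations(
            edges=pd.DataFrame(columns=["kinase", "substrate", "in_vivo",
                                        "substrate_protein"]),
            alias={}, signal_kinases=[], null_kinases=[],
        )
    pep = truth.peptides
    # signal substrates carry the full insulin effect in every strain-diet
    # cell, so they are drawn from up-regulated peptides without strain or
    # diet modulation
    up = pep.index[
        pep["regulated"]
        & (pep["direction"] == "up")
        & ~pep["strain_effect"]
        & (pep["diet_class"] == "none")
    ]
    all_ids = pep.index
    rows = []
    signal, null = [], []
    n_signal = min(n_signal, n_kinases)
    for i in range(n_kinases):
        kname = f"SigKin{i + 1}" if i < n_signal else f"NullKin{i + 1 - n_signal}"
        pool = up if i < n_signal else all_ids
        k = min(substrates_per_kinase, len(pool))
        subs = rng.choice(pool, size=k, replace=False)
        (signal if i < n_signal else null).append(kname)
        for s in subs:
            rows.append((kname, s, True, f"prot_of_{s}"))

    alias = {}
    if include_traps and null:
        base = null[0]
        # isoform duplicate: same substrates under an isoform label
        iso = f"{base}beta"
        alias[iso] = base
        for k, s, iv, spr in list(rows):
            if k == base:
                rows.append((iso, s, True, spr))
        # autophosphorylation edge: substrate sits on the kinase protein
        rows.append((base, f"{base}_auto_site", True, base))
        # promiscuous site under four distinct kinases
        promiscuous = "promiscuous_site"
        for k in ([*signal, *null] * 4)[:4]:
            rows.append((k, promiscuous, True, f"prot_of_{promiscuous}"))
        # an in-vitro-only edge that the evidence filter must drop
        rows.append((base, "in_vitro_only_site", False, "other_prot"))
    edges = pd.DataFrame(rows, columns=["kinase", "substrate", "in_vivo",
                                        "substrate_protein"])
    return SyntheticAnnotations(edges=edges, alias=alias,
                                signal_kinases=signal, null_kinases=null)


# ---------------------------------------------------------------------------
# tracer and phenotype

def generate_tracer_experiment(
    cp0: float,
    kp: float,
    ki_true: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    times=(1.0, 5.0, 7.5, 10.0),
    terminal_time: float = 10.0,
) -> TracerExperiment:
    """Blood counts cp0*exp(-kp t) + noise; tissue count chosen so the
    uptake rate-constant equation inverts to `ki_true` at zero noise."""
    if cp0 <= 0 or kp <= 0:
        raise ValueError("cp0 and kp must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    blood = cp0 * np.exp(-kp * t)
    if noise_sd > 0:
        blood = blood + rng.normal(0.0, noise_sd, size=t.size)
    tissue = ki_true * cp0 * (1.0 - np.exp(-kp * terminal_time)) / kp
    return TracerExperiment(
        times=t, blood=blood, tissue_count=float(tissue),
        terminal_time=terminal_time,
    )


def generate_phenotype(
    responses: pd.DataFrame,
    driver_peptides,
    r_target: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Per-sample uptake correlated with the mean driver insulin response.

    The signal is the across-driver mean response per sample; Gaussian noise
    is scaled so the population correlation with the signal is `r_target`
    (r_target = 0 gives pure noise).
    """
    drivers = list(driver_peptides)
    if not drivers:
        raise ValueError("driver set must be non-empty")
    if not abs(r_target) < 1:
        raise ValueError("|r_target| must be < 1")
    rng = np.random.default_rng(seed)
    signal = responses.loc[drivers].mean(axis=0)
    signal = signal.fillna(signal.mean())
    sd = float(signal.std(ddof=0))
    if r_target == 0 or sd == 0:
        return pd.Series(
            rng.normal(0.0, 1.0, size=len(signal)), index=signal.index, name="uptake"
        )
    noise_sd = sd * np.sqrt(1.0 / r_target**2 - 1.0)
    uptake = np.sign(r_target) * signal + rng.normal(0.0, noise_sd, size=len(signal))
    return pd.Series(uptake.to_numpy(), index=signal.index, name="uptake")
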