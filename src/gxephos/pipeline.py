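"""End-to-end orchestration: simulate/load -> preprocess -> regulation ->
effects -> KSEA -> subnetworks -> phenotype association, with a JSON
manifest recording seeds, thresholds and the row counts surviving each
filter."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import PhosphoTable, SampleMeta
from .effects import GATE_BASE, REFERENCE_STRAIN, classify_effects, insulin_response
from .ksea import curate_annotations, ksea_matrix
from .phenotype import R_CUT, Q_CUT_ASSOC, associate_uptake
from .preprocess import preprocess
from .regulation import LFC_CUT, Q_CUT, analyse_regulation
from .subnetworks import (
    DEFAULT_MERGE_CUT,
    DEFAULT_MIN_MODULE_SIZE,
    DEFAULT_POWER,
    build_modules,
    eigenpeptide_trait_correlation,
)
from .synthetic import CohortConfig, generate_cohort, generate_phenotype

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds with their standard defaults, plus paths."""

    out_dir: str = "gxe_out"
    matrix_path: str | None = None  # TSV; None -> simulate a cohort
    meta_path: str | None = None
    annotations_path: str | None = None  # kinase,substrate[,in_vivo] TSV
    uptake_path: str | None = None  # sample_id,uptake CSV
    simulate: dict = field(default_factory=dict)  # CohortConfig overrides
    q_cut: float = Q_CUT
    lfc_cut: float = LFC_CUT
    gate_base: float = GATE_BASE
    r_cut: float = R_CUT
    assoc_q_cut: float = Q_CUT_ASSOC
    min_per_arm: int = 3
    min_combinations: int = 8
    n_perm: int = 1000
    power: int = DEFAULT_POWER
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    merge_cut: float = DEFAULT_MERGE_CUT
    reference_strain: str = REFERENCE_STRAIN
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage_seeds(seed: int) -> dict:
    """Expand one global seed deterministically into per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    names = ["simulate", "ksea", "phenotype"]
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in
            zip(names, ss.spawn(len(names)))}


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Any stage failure raises with the stage name attached.  Result tables
    are written as TSVs under `config.out_dir`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {k: v for k, v in asdict(config).items()},
        "counts": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "load"
    try:
        if config.matrix_path:
            table = PhosphoTable.from_tsv(config.matrix_path)
            meta = SampleMeta.from_csv(config.meta_path)
            truth = None
        else:
            stage = "simulate"
            cohort_cfg = CohortConfig(**{**config.simulate, "seed": seeds["simulate"]})
            table, meta, truth = generate_cohort(cohort_cfg)
            table.to_tsv(out / "matrix.tsv")
            meta.to_csv(out / "meta.csv")
            truth.to_tsv(out / "truth_peptides.tsv", out / "truth_effects.tsv")
        table = table.align_to(meta)
        manifest["counts"]["input_peptides"] = len(table.peptide_ids)

        stage = "preprocess"
        table = preprocess(table)
        manifest["counts"]["after_preprocess"] = len(table.peptide_ids)

        stage = "regulation"
        reg = analyse_regulation(
            table, meta,
            min_per_arm=config.min_per_arm,
            min_combinations=config.min_combinations,
            q_cut=config.q_cut, lfc_cut=config.lfc_cut,
        )
        reg.to_tsv(out / "regulation.tsv")
        manifest["counts"]["tested"] = len(reg.tested)
        manifest["counts"]["regulated"] = int(reg.stats["regulated"].sum())

        effects_calls = None
        model = None
        resp = None
        if manifest["counts"]["regulated"] > 0:
            stage = "effects"
            effects_calls = classify_effects(
                table, meta, reg.regulated_ids, reg.lfc,
                reference_strain=config.reference_strain,
                q_cut=config.q_cut, c=config.gate_base,
            )
            effects_calls.to_tsv(out / "effects.tsv")
            resp = effects_calls.responses
            resp.to_csv(out / "responses.tsv", sep="\t", index_label="peptide_id")
            fr = effects_calls.frame
            manifest["counts"]["strain_effect"] = int(fr["strain_effect"].sum())
            manifest["counts"]["strainxdiet"] = int((fr["diet_class"] == "strainxdiet").sum())
            manifest["counts"]["uniform_diet"] = int((fr["diet_class"] == "uniform").sum())

            if config.annotations_path:
                stage = "ksea"
                edges = pd.read_csv(config.annotations_path, sep="\t")
                annot = curate_annotations(edges)
                # KSEA ranks the full quantified phosphoproteome, not just
                # the regulated subset
                resp_all = insulin_response(table, meta)
                scores = ksea_matrix(
                    resp_all, meta, annot, n_perm=config.n_perm, seed=seeds["ksea"]
                )
                scores.to_tsv(out / "ksea_scores.tsv", out / "ksea_pvalues.tsv")
                manifest["counts"]["qualifying_kinases"] = len(scores.qualifying)

            if len(reg.regulated_ids) >= 2 * config.min_module_size:
                stage = "subnetworks"
                model = build_modules(
                    resp, power=config.power,
                    min_module_size=config.min_module_size,
                    merge_cut=config.merge_cut,
                )
                model.labels.to_csv(out / "modules.tsv", sep="\t",
                                    index_label="peptide_id", header=["module"])
                model.eigenpeptides.to_csv(out / "eigenpeptides.tsv", sep="\t",
                                           index_label="module")
                model.kme.to_csv(out / "kme.tsv", sep="\t", index_label="peptide_id")
                manifest["counts"]["modules"] = len(model.modules)
                manifest["counts"]["unassigned"] = int((model.labels == 0).sum())

            uptake = None
            if config.uptake_path:
                up = pd.read_csv(config.uptake_path)
                uptake = pd.Series(
                    up["uptake"].to_numpy(), index=up["sample_id"], name="uptake"
                )
            elif truth is not None and len(reg.regulated_ids):
                drivers = list(reg.regulated_ids[: max(3, len(reg.regulated_ids) // 50)])
                uptake = generate_phenotype(
                    resp, drivers, r_target=0.8, seed=seeds["phenotype"]
                )
            if uptake is not None:
                stage = "phenotype"
                assoc = associate_uptake(
                    resp, uptake, mode="response",
                    r_cut=config.r_cut, q_cut=config.assoc_q_cut,
                )
                assoc.to_csv(out / "associations.tsv", sep="\t")
                manifest["counts"]["uptake_associated"] = int(assoc["pass"].sum())
                if model is not None:
                    ec = eigenpeptide_trait_correlation(model, uptake)
                    ec.to_csv(out / "module_trait.tsv", sep="\t")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    # funnel sanity: counts are non-increasing along the regulation funnel
    funnel = [
        manifest["counts"].get(k)
        for k in ("input_peptides", "after_preprocess", "tested", "regulated")
        if manifest["counts"].get(k) is not None
    ]
    assert all(a >= b for a, b in zip(funnel, funnel[1:])), funnel
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
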