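"""End-to-end driver: simulate -> phenotype -> niches -> clinical -> correlate.

One config document drives the whole run; every artifact directory carries
a provenance sidecar (config hash, seed, stage) and reruns with the same
config are byte-identical.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clinical, correlative, spatial, synth
from .errors import StageError
from .geometry import TumorMask
from .io import config_hash, write_cell_table, write_provenance
from .phenotype import call_phenotypes, composition_fractions

log = logging.getLogger("nichequant")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "nichequant_out"
    # tissue
    width_um: float = 3000.0
    height_um: float = 3000.0
    background_density: dict = field(
        default_factory=lambda: {"other": 400.0, "CD4+": 40.0, "CD8+": 60.0,
                                 "MHC-II+": 6.0, "TCF1+CD8+": 1.0}
    )
    niche_discs: list = field(
        default_factory=lambda: [
            {"center_um": [900.0, 900.0], "radius_um": 564.19, "mhc2_per_mm2": 40.0,
             "tcf1cd8_per_mm2": 12.0}
        ]
    )
    # phenotyping: "auto", "midpoint" (generator truth), or marker->value map
    thresholds: object = "midpoint"
    # niche windowing
    mhc2_min_per_mm2: float = 16.0
    tcf1cd8_min_per_mm2: float = 4.0
    window_area_mm2: float = 1.0
    stride_um: float = 250.0
    min_window_overlap: float = 0.25
    # cohort
    n_patients: int = 17
    n_pr: int = 6
    # design
    design: dict = field(
        default_factory=lambda: {"n1": 11, "futility_stop_at": 0, "n_total": 17,
                                 "reject_threshold": 3, "p0": 0.05, "p1": 0.24}
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)


def _tissue_spec(cfg: PipelineConfig) -> synth.TissueSpec:
    discs = [
        synth.NicheDisc(tuple(d["center_um"]), d["radius_um"], d["mhc2_per_mm2"],
                        d["tcf1cd8_per_mm2"])
        for d in cfg.niche_discs
    ]
    return synth.TissueSpec(
        width_um=cfg.width_um,
        height_um=cfg.height_um,
        tumor_mask=TumorMask.rectangle(cfg.width_um, cfg.height_um),
        background_density=cfg.background_density,
        niche_specs=discs,
        seed=cfg.seed,
    )


def _niche_params(cfg: PipelineConfig) -> spatial.NicheParams:
    return spatial.NicheParams(
        mhc2_min_per_mm2=cfg.mhc2_min_per_mm2,
        tcf1cd8_min_per_mm2=cfg.tcf1cd8_min_per_mm2,
        window_area_mm2=cfg.window_area_mm2,
        stride_um=cfg.stride_um,
        min_window_overlap=cfg.min_window_overlap,
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            log.info("stage=%s wall_s=%.2f", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages on synthetic data; write artifacts + report under outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.to_dict()

    @_stage("simulate")
    def simulate():
        spec = _tissue_spec(cfg)
        cells, mask, truth = synth.generate_tissue(spec)
        cohort = synth.generate_cohort(
            cfg.n_patients, synth.CohortEffects(n_pr=cfg.n_pr), seed=cfg.seed
        )
        write_cell_table(cells, outdir / "cells.csv")
        mask.to_geojson(outdir / "tumor_mask.geojson")
        cohort.lesions.to_csv(outdir / "lesions.csv", index=False)
        cohort.panel.to_csv(outdir / "panel.csv", index=False)
        cohort.flags.to_csv(outdir / "flags.csv", index=False)
        cohort.survival.to_csv(outdir / "survival.csv", index=False)
        return spec, cells, mask, truth, cohort

    spec, cells, mask, truth, cohort = simulate()

    @_stage("phenotype")
    def phenotype():
        if cfg.thresholds == "midpoint":
            thr = spec.midpoint_thresholds()
        else:
            thr = cfg.thresholds
        pheno = call_phenotypes(cells, thr)
        with open(outdir / "thresholds.json", "w") as fh:
            json.dump(pheno.thresholds_used, fh, sort_keys=True, indent=1)
        return pheno

    pheno = phenotype()

    @_stage("niches")
    def niches():
        params = _niche_params(cfg)
        nm = spatial.detect_niches(pheno, mask, params)
        nm.to_csv(outdir / "niche_grid.csv")
        spatial.export_immunomap(pheno, nm, mask, outdir / "immunomap.geojson")
        return nm

    niche_map = niches()

    @_stage("clinical")
    def clinical_stage():
        records = [
            clinical.classify_recist(s)
            for s in clinical.LesionSeries.from_frame(cohort.lesions)
        ]
        best = [r.best_response for r in records]
        orr, ci = clinical.orr_with_ci(best)
        design = clinical.TwoStageDesign(**cfg.design)
        oc0 = clinical.simon_oc(design, design.p0)
        oc1 = clinical.simon_oc(design, design.p1)
        dfs = cohort.survival[cohort.survival["endpoint"] == "DFS"]
        km12, km_ci = clinical.km_estimate(dfs, 12.0)
        return {
            "best_responses": {r.patient_id: r.best_response for r in records},
            "orr": orr,
            "orr_ci": list(ci),
            "clinical_benefit_rate": clinical.clinical_benefit_rate(best),
            "design_oc": {
                "type1_error_at_p0": oc0.reject_prob,
                "power_at_p1": oc1.reject_prob,
                "early_stop_prob_at_p0": oc0.early_stop_prob,
                "expected_n_at_p0": oc0.expected_n,
            },
            "dfs_12mo": km12,
            "dfs_12mo_ci": list(km_ci),
        }

    clin = clinical_stage()

    @_stage("correlate")
    def correlate():
        folds, excluded = correlative.fold_changes(cohort.panel)
        med = (
            folds[folds["timepoint"] != "baseline"]
            .groupby(["analyte", "timepoint"])["fold"]
            .median()
        )
        det = correlative.detection_rates(cohort.flags)
        return {
            "median_fold_changes": {f"{a}@{t}": v for (a, t), v in med.items()},
            "n_fold_exclusions": int(len(excluded)),
            "detection_rates": det.to_dict(orient="records"),
        }

    corr = correlate()

    report = {
        "provenance": {
            "config_hash": config_hash(cfg_dict),
            "seed": cfg.seed,
            "config": cfg_dict,
        },
        "tissue": {
            "n_cells": int(len(cells)),
            "planted_coverage": truth.planted_coverage,
            "recovered_coverage": niche_map.coverage,
            "niche_area_mm2": niche_map.niche_area_mm2,
            "composition_pct_of_dapi": composition_fractions(pheno),
        },
        "clinical": clin,
        "correlative": corr,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    write_provenance(
        outdir / "provenance.json", config=cfg_dict, seed=cfg.seed, stage="report"
    )
    return report
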