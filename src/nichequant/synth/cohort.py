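"""Synthetic clinical/assay cohorts with planted effects.

Plants: a chosen number of patients crossing the -30% partial-response
boundary at week 12, log-normal analyte fold changes with stated medians,
Bernoulli ctDNA detection flags with stated per-timepoint rates, and simple
survival tables.  Everything is reproducible under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tissue import SyntheticTruth

LESION_TIMEPOINTS = ("baseline", "week6", "week12")
ASSAY_TIMEPOINTS = ("baseline", "W6D1", "PostTx", "PostSx")

DEFAULT_ANALYTES = ("VEGF", "VEGFR2", "HGF", "cMET", "Gas6", "AXL", "cfDNA")


def _default_analyte_effects() -> dict:
    # Median fold change vs baseline per (analyte, timepoint); unlisted pairs are 1.0.
    eff = {}
    for tp in ("W6D1", "PostTx"):
        eff[("VEGF", tp)] = 2.0
        eff[("cMET", tp)] = 1.5
        eff[("Gas6", tp)] = 1.4
        eff[("AXL", tp)] = 1.6
        eff[("cfDNA", tp)] = 1.6
        eff[("VEGFR2", tp)] = 0.6
    return eff


@dataclass(frozen=True)
class CohortEffects:
    n_pr: int = 6
    baseline_size_range_cm: tuple[float, float] = (3.0, 15.0)
    pr_week12_pct_range: tuple[float, float] = (-42.0, -30.0)
    sd_week12_pct_range: tuple[float, float] = (-26.0, -8.0)
    week6_fraction_range: tuple[float, float] = (0.4, 0.8)
    analyte_effects: Mapping[tuple[str, str], float] = field(
        default_factory=_default_analyte_effects
    )
    analyte_log_sd: float = 0.25
    analyte_baseline_range: tuple[float, float] = (50.0, 500.0)
    detection_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "baseline": 0.31,
            "W6D1": 0.43,
            "PostTx": 0.31,
            "PostSx": 0.09,
        }
    )
    dfs_event_prob: float = 0.18
    os_event_prob: float = 0.12
    followup_months_range: tuple[float, float] = (18.0, 30.0)

    def validate(self, n_patients: int) -> None:
        for tp, r in self.detection_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"detection rate for {tp!r} outside [0,1]: {r}")
        for p in (self.dfs_event_prob, self.os_event_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"event probability outside [0,1]: {p}")
        if not 0 <= self.n_pr <= n_patients:
            raise ValueError(f"n_pr={self.n_pr} outside [0, {n_patients}]")
        for (_, _), f in self.analyte_effects.items():
            if f <= 0:
                raise ValueError("median fold changes must be > 0")


@dataclass
class Cohort:
    """Bundle of generated cohort tables plus truth."""

    lesions: pd.DataFrame  # patient_id, timepoint, sum_diameters_cm
    panel: pd.DataFrame  # patient_id, timepoint, analyte, value
    flags: pd.DataFrame  # patient_id, timepoint, detected
    survival: pd.DataFrame  # patient_id, time_months, event, endpoint
    truth: SyntheticTruth


def generate_cohort(
    n_patients: int, effects: CohortEffects | None = None, seed: int = 0
) -> Cohort:
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    effects = effects or CohortEffects()
    effects.validate(n_patients)
    rng = np.random.default_rng(seed)

    patient_ids = [f"P{i+1:02d}" for i in range(n_patients)]
    order = rng.permutation(n_patients)
    pr_ids = frozenset(patient_ids[i] for i in order[: effects.n_pr])

    lo, hi = effects.baseline_size_range_cm
    lesion_rows = []
    for pid in patient_ids:
        baseline = rng.uniform(lo, hi)
        if pid in pr_ids:
            w12 = rng.uniform(*effects.pr_week12_pct_range)
        else:
            w12 = rng.uniform(*effects.sd_week12_pct_range)
        w6 = w12 * rng.uniform(*effects.week6_fraction_range)
        lesion_rows += [
            (pid, "baseline", baseline),
            (pid, "week6", baseline * (1 + w6 / 100.0)),
            (pid, "week12", baseline * (1 + w12 / 100.0)),
        ]
    lesions = pd.DataFrame(
        lesion_rows, columns=["patient_id", "timepoint", "sum_diameters_cm"]
    )

    panel_rows = []
    blo, bhi = effects.analyte_baseline_range
    for pid in patient_ids:
        for analyte in DEFAULT_ANALYTES:
            base = rng.uniform(blo, bhi)
            panel_rows.append((pid, "baseline", analyte, base))
            for tp in ASSAY_TIMEPOINTS[1:]:
                median = effects.analyte_effects.get((analyte, tp), 1.0)
                fold = median * np.exp(rng.normal(0.0, effects.analyte_log_sd))
                panel_rows.append((pid, tp, analyte, base * fold))
    panel = pd.DataFrame(
        panel_rows, columns=["patient_id", "timepoint", "analyte", "value"]
    )

    flag_rows = []
    for tp in ASSAY_TIMEPOINTS:
        rate = float(effects.detection_rates.get(tp, 0.0))
        for pid in patient_ids:
            flag_rows.append((pid, tp, bool(rng.uniform() < rate)))
    flags = pd.DataFrame(flag_rows, columns=["patient_id", "timepoint", "detected"])

    surv_rows = []
    flo, fhi = effects.followup_months_range
    for pid in patient_ids:
        for endpoint, prob in (("DFS", effects.dfs_event_prob), ("OS", effects.os_event_prob)):
            if rng.uniform() < prob:
                surv_rows.append((pid, rng.uniform(2.0, 14.0), 1, endpoint))
            else:
                surv_rows.append((pid, rng.uniform(flo, fhi), 0, endpoint))
    survival = pd.DataFrame(
        surv_rows, columns=["patient_id", "time_months", "event", "endpoint"]
    )

    truth = SyntheticTruth(
        cohort_effects=dict(effects.analyte_effects),
        planted_detection_rates=dict(effects.detection_rates),
        planted_pr_patients=tuple(sorted(pr_ids)),
    )
    return Cohort(lesions, panel, flags, survival, truth)
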