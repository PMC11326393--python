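"""Bundled trial summary tables (plain-text CSV) and worked-example inputs.

These are the small per-patient/per-sample summary tables the downstream
endpoint and correlative operations consume: best RECIST responses for the
17-patient cohort, treatment-related adverse-event records, per-sample
ctDNA detection flags, and the somatic-variant table.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from ..clinical import TwoStageDesign

N_TREATED = 17


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files(__package__) / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, **kwargs)


def load_best_responses() -> pd.DataFrame:
    """17-patient clinical summary: patient_id, clinical_stage, best_response."""
    return _read("best_response.csv")


def load_adverse_events() -> pd.DataFrame:
    """Patient-level treatment-related AE records: patient_id, term, grade.

    Reconstructed from the published per-term any-grade / grade>=3 patient
    counts; tabulating these records reproduces those counts exactly.
    """
    return _read("adverse_events.csv")


def load_ctdna_detection() -> pd.DataFrame:
    """Per-sample ctDNA detection flags: patient_id, timepoint, detected.

    Reconstructed from the published per-timepoint detected/total counts
    (4/13, 6/14, 5/16, 1/11; 16/54 pooled).
    """
    df = _read("ctdna_detection.csv")
    if df["detected"].dtype != bool:
        df["detected"] = df["detected"].map({"true": True, "false": False})
    return df


def load_ctdna_variants() -> pd.DataFrame:
    """The nine published somatic-variant records."""
    return _read("ctdna_variants.csv")


def trial_design() -> TwoStageDesign:
    """The trial's two-stage design: 11 + 6 patients, stop at 0, reject at >= 3."""
    return TwoStageDesign(n1=11, futility_stop_at=0, n_total=17, reject_threshold=3,
                          p0=0.05, p1=0.24)


def one_year_dfs_table() -> pd.DataFrame:
    """17-patient survival table with 3 events in the first year, no earlier
    censoring — the configuration reported for one-year disease-free survival
    (product-limit estimate 14/17)."""
    rows = [("P01", 4.0, 1), ("P02", 7.0, 1), ("P03", 10.0, 1)]
    rows += [(f"P{i:02d}", 25.0, 0) for i in range(4, N_TREATED + 1)]
    df = pd.DataFrame(rows, columns=["patient_id", "time_months", "event"])
    df["endpoint"] = "DFS"
    return df
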