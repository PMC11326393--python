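"""RECIST 1.1 response calls, ORR with exact CI, two-stage design OCs, KM.

Scope: target-lesion diameter sums only (the trial tracked primary renal
tumor size); non-target and new-lesion rules are out of scope.  All tumor
measurements are in centimeters, so the RECIST 5 mm absolute-increase floor
for progression is encoded as 0.5 cm.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, binomtest, norm

from .errors import DataError, IncompleteSeriesError, InvalidMeasurementError

RESPONSE_ORDER = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}  # best -> worst
DEFAULT_TIMEPOINTS = ("baseline", "week6", "week12")
PD_ABS_FLOOR_CM = 0.5


def percent_change(baseline_cm: float, followup_cm: float) -> float:
    """Signed percent change of a diameter sum relative to baseline."""
    if not baseline_cm > 0:
        raise InvalidMeasurementError(f"baseline must be > 0, got {baseline_cm}")
    return 100.0 * (followup_cm - baseline_cm) / baseline_cm


@dataclass(frozen=True)
class LesionSeries:
    patient_id: str
    measurements: Mapping[str, float]  # timepoint -> sum of diameters (cm)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> list["LesionSeries"]:
        out = []
        for pid, g in df.groupby("patient_id", sort=True):
            out.append(
                LesionSeries(
                    str(pid),
                    dict(zip(g["timepoint"], g["sum_diameters_cm"].astype(float))),
                )
            )
        return out


@dataclass
class ResponseRecord:
    patient_id: str
    categories: dict[str, str]  # follow-up timepoint -> CR/PR/SD/PD
    percent_changes: dict[str, float]
    best_response: str


def classify_recist(
    series: LesionSeries, timepoints: Sequence[str] = DEFAULT_TIMEPOINTS
) -> ResponseRecord:
    """Classify each follow-up timepoint and derive the best response.

    Per timepoint: CR if the sum is 0; PD if the increase from the series
    nadir (minimum so far, baseline included) is >= 20% with an absolute
    increase >= 0.5 cm; PR if the change from baseline is <= -30%; SD
    otherwise.  PD is checked before PR (progression from nadir dominates).
    """
    if timepoints[0] not in series.measurements:
        raise IncompleteSeriesError(
            f"patient {series.patient_id}: missing baseline measurement"
        )
    baseline = float(series.measurements[timepoints[0]])
    if not baseline > 0:
        raise InvalidMeasurementError(
            f"patient {series.patient_id}: baseline must be > 0"
        )
    nadir = baseline
    categories: dict[str, str] = {}
    changes: dict[str, float] = {}
    for tp in timepoints[1:]:
        if tp not in series.measurements:
            continue
        value = float(series.measurements[tp])
        if value < 0:
            raise InvalidMeasurementError(
                f"patient {series.patient_id}: negative diameter at {tp}"
            )
        change = percent_change(baseline, value)
        changes[tp] = change
        if value == 0:
            cat = "CR"
        elif (
            nadir > 0
            and percent_change(nadir, value) >= 20.0
            and value - nadir >= PD_ABS_FLOOR_CM
        ):
            cat = "PD"
        elif change <= -30.0:
            cat = "PR"
        else:
            cat = "SD"
        categories[tp] = cat
        nadir = min(nadir, value)
    if not categories:
        raise IncompleteSeriesError(
            f"patient {series.patient_id}: no follow-up measurements"
        )
    best = min(categories.values(), key=RESPONSE_ORDER.__getitem__)
    return ResponseRecord(series.patient_id, categories, changes, best)


def orr_with_ci(
    best_responses: Sequence[str],
    confidence: float = 0.95,
    method: str = "clopper-pearson",
) -> tuple[float, tuple[float, float]]:
    """Objective response rate (CR or PR) with an exact binomial CI.

    Returns the rate as a fraction in [0, 1] and the CI endpoints.
    """
    n = len(best_responses)
    if n == 0:
        raise ValueError("no responses supplied")
    bad = sorted(set(best_responses) - set(RESPONSE_ORDER))
    if bad:
        raise DataError(f"unknown response categories: {bad}")
    k = sum(r in ("CR", "PR") for r in best_responses)
    ci_method = {"clopper-pearson": "exact", "wilson": "wilson"}[method]
    ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method=ci_method)
    return k / n, (float(ci.low), float(ci.high))


def clinical_benefit_rate(best_responses: Sequence[str]) -> float:
    """Fraction with CR, PR or SD (the trial's clinical-benefit convention)."""
    n = len(best_responses)
    if n == 0:
        raise ValueError("no responses supplied")
    return sum(r in ("CR", "PR", "SD") for r in best_responses) / n


@dataclass(frozen=True)
class TwoStageDesign:
    """Simon-style two-stage design parameters (defaults: the trial's design)."""

    n1: int = 11
    futility_stop_at: int = 0
    n_total: int = 17
    reject_threshold: int = 3
    p0: float = 0.05
    p1: float = 0.24

    def __post_init__(self):
        if not 0 <= self.futility_stop_at < self.reject_threshold <= self.n_total:
            raise ValueError("need 0 <= stop < reject threshold <= n_total")
        if not self.n1 < self.n_total:
            raise ValueError("need n1 < n_total")
        if not 0 < self.p0 < self.p1 < 1:
            raise ValueError("need 0 < p0 < p1 < 1")


@dataclass(frozen=True)
class SimonOC:
    reject_prob: float
    early_stop_prob: float
    expected_n: float


def simon_oc(design: TwoStageDesign, p: float) -> SimonOC:
    """Exact operating characteristics of a two-stage design at response rate p.

    Stage 1 accrues ``n1``; if responses <= futility_stop_at the study stops
    (null accepted).  Otherwise ``n_total - n1`` more accrue and the null is
    rejected when total responses >= reject_threshold.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    n1, n2 = design.n1, design.n_total - design.n1
    early_stop = float(binom.cdf(design.futility_stop_at, n1, p))
    reject = 0.0
    for x1 in range(design.futility_stop_at + 1, n1 + 1):
        need = design.reject_threshold - x1
        tail = 1.0 if need <= 0 else float(binom.sf(need - 1, n2, p))
        reject += float(binom.pmf(x1, n1, p)) * tail
    expected_n = n1 + (1.0 - early_stop) * n2
    return SimonOC(reject, early_stop, expected_n)


def km_estimate(
    table: pd.DataFrame, at_time: float, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Product-limit survival at ``at_time`` with a log-scale Greenwood CI.

    ``table`` needs columns ``time_months`` and ``event`` (1 = event,
    0 = censored).  With no censoring before ``at_time`` the estimate equals
    the empirical survivor fraction.
    """
    times = table["time_months"].to_numpy(dtype=float)
    events = table["event"].to_numpy(dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival table")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    n_at_risk = len(times)
    s = 1.0
    greenwood = 0.0
    i = 0
    while i < len(times) and times[i] <= at_time:
        t = times[i]
        d = 0
        c = 0
        while i < len(times) and times[i] == t:
            if events[i] == 1:
                d += 1
            else:
                c += 1
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            if n_at_risk > d:
                greenwood += d / (n_at_risk * (n_at_risk - d))
        n_at_risk -= d + c
    if s <= 0.0 or greenwood == 0.0:
        return s, (s, s)
    z = float(norm.ppf(0.5 + confidence / 2.0))
    se_log = float(np.sqrt(greenwood))
    lo = s * float(np.exp(-z * se_log))
    hi = min(1.0, s * float(np.exp(z * se_log)))
    return s, (lo, hi)


def tabulate_adverse_events(events: pd.DataFrame, n_treated: int) -> pd.DataFrame:
    """Per-term patient counts: any grade and grade >= 3, with percentages.

    ``events`` needs columns ``patient_id, term, grade``.  Patients (not
    events) are counted; percent denominators use ``n_treated``.
    """
    from .correlative import round_half_up

    if n_treated < 1:
        raise ValueError("n_treated must be >= 1")
    required = {"patient_id", "term", "grade"}
    missing = required - set(events.columns)
    if missing:
        raise DataError(f"adverse-event table missing columns: {sorted(missing)}")
    if len(events):
        grades = pd.to_numeric(events["grade"], errors="coerce")
        bad = events.loc[grades.isna() | ~grades.isin([1, 2, 3, 4, 5])]
        if len(bad):
            raise DataError(f"unknown adverse-event grade in rows: {list(bad.index)}")
        events = events.assign(grade=grades.astype(int))
    rows = []
    for term, g in events.groupby("term", sort=True):
        n_any = g["patient_id"].nunique()
        n_ge3 = g.loc[g["grade"] >= 3, "patient_id"].nunique()
        rows.append(
            (
                term,
                n_any,
                round_half_up(100.0 * n_any / n_treated, 1),
                n_ge3,
                round_half_up(100.0 * n_ge3 / n_treated, 1),
            )
        )
    return pd.DataFrame(
        rows, columns=["term", "any_grade_n", "any_grade_pct", "ge3_n", "ge3_pct"]
    )
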