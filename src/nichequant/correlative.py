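"""Baseline-anchored fold changes, rank tests, Spearman correlation, and
ctDNA detection/variant summaries.

Rank tests follow the conventions in the trial's figure legends: paired
Wilcoxon signed-rank for within-patient timepoint comparisons, Mann-Whitney
for two-group comparisons, Spearman for biomarker-versus-tumor-change
association.  P values are reported per comparison (unadjusted); a
Holm-adjusted column is available as a clearly labeled extension.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, rankdata, spearmanr

from .errors import DataError, DegenerateTestError, UndefinedCorrelationError

ASSAY_TIMEPOINT_ORDER = ("baseline", "W6D1", "PostTx", "PostSx")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round-half-up to ``ndigits`` decimals (printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Fold changes vs baseline


def fold_changes(
    panel: pd.DataFrame, baseline_label: str = "baseline"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (patient, timepoint, analyte) ratio to that patient's baseline.

    Pairs with a missing or non-positive baseline are excluded (never a
    division by zero) and reported in the second return value.
    """
    required = {"patient_id", "timepoint", "analyte", "value"}
    missing = required - set(panel.columns)
    if missing:
        raise DataError(f"assay panel missing columns: {sorted(missing)}")
    rows, excluded = [], []
    for (pid, analyte), g in panel.groupby(["patient_id", "analyte"], sort=True):
        base = g.loc[g["timepoint"] == baseline_label, "value"]
        if len(base) == 0:
            excluded.append((pid, analyte, "missing baseline"))
            continue
        b = float(base.iloc[0])
        if not b > 0:
            excluded.append((pid, analyte, "non-positive baseline"))
            continue
        for _, r in g.iterrows():
            rows.append((pid, r["timepoint"], analyte, float(r["value"]) / b))
    folds = pd.DataFrame(rows, columns=["patient_id", "timepoint", "analyte", "fold"])
    report = pd.DataFrame(excluded, columns=["patient_id", "analyte", "reason"])
    return folds, report


# ---------------------------------------------------------------------------
# Wilcoxon matched-pair signed-rank


def _signed_rank_exact_p(doubled_ranks: np.ndarray, w2: int) -> float:
    """Exact two-sided p for the signed-rank sum via DP over sign vectors.

    ``doubled_ranks`` are the mid-ranks times two (integers even with ties);
    ``w2`` is the doubled positive-rank sum.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_paths = 2.0 ** len(doubled_ranks)
    p_le = counts[: w2 + 1].sum() / n_paths
    p_ge = counts[w2:].sum() / n_paths
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_signed_rank(
    x_baseline, x_timepoint, exact_max_n: int = 25
) -> tuple[float, float]:
    """Wilcoxon matched-pair signed-rank test; two-sided.

    Zero differences are dropped; ties get mid-ranks.  The null distribution
    is exact (enumeration by dynamic programming) up to ``exact_max_n``
    non-zero pairs, and a tie-corrected normal approximation beyond.
    Returns (W+, p) where W+ is the positive-rank sum.
    """
    x = np.asarray(x_baseline, dtype=float)
    y = np.asarray(x_timepoint, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        doubled = np.rint(2 * ranks).astype(np.int64)
        p = _signed_rank_exact_p(doubled, int(round(2 * w_plus)))
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mu) / np.sqrt(sigma2)
        p = float(2.0 * norm.sf(abs(z)))
    return w_plus, p


# ---------------------------------------------------------------------------
# Mann-Whitney rank sum


def rank_sum_twogroup(group_a, group_b, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney test: exact when min group size <= exact_max_n
    and there are no ties, tie-corrected normal otherwise.

    Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if min(len(a), len(b)) <= exact_max_n and not has_ties:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(1.0, res.pvalue))


# ---------------------------------------------------------------------------
# Spearman correlation vs tumor change


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_vs_tumor_change(
    values, percent_change, method: str = "approx", exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman rho (mid-ranks) between a biomarker and tumor-size change.

    p by t-approximation by default; ``method='exact'`` enumerates all
    permutations (limited to n <= ``exact_max_n``).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(percent_change, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")
    rho = _spearman_rho(x, y)
    if method not in ("approx", "exact"):
        raise ValueError(f"method must be 'approx' or 'exact', got {method!r}")
    if method == "exact":
        if len(x) > exact_max_n:
            raise ValueError(f"exact permutation limited to n <= {exact_max_n}")
        target = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(_spearman_rho(x, np.asarray(perm))) >= target:
                hits += 1
        p = hits / total
    else:
        p = float(spearmanr(x, y).pvalue)
    return rho, p


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment (extension; the trial reports unadjusted P)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# ctDNA detection and variant summaries


def detection_rates(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint detected/total counts with one-decimal percentages,
    plus a pooled 'overall' row across all samples."""
    required = {"patient_id", "timepoint", "detected"}
    missing = required - set(flags.columns)
    if missing:
        raise DataError(f"detection table missing columns: {sorted(missing)}")
    tps = list(dict.fromkeys(flags["timepoint"]))
    tps.sort(key=lambda t: (ASSAY_TIMEPOINT_ORDER.index(t) if t in ASSAY_TIMEPOINT_ORDER else 99, t))
    rows = []
    detected = flags["detected"].astype(bool)
    for tp in tps:
        sel = flags["timepoint"] == tp
        n = int(sel.sum())
        k = int(detected[sel].sum())
        rows.append((tp, k, n, round_half_up(100.0 * k / n, 1)))
    n_all = len(flags)
    k_all = int(detected.sum())
    pct_all = round_half_up(100.0 * k_all / n_all, 1) if n_all else 0.0
    rows.append(("overall", k_all, n_all, pct_all))
    return pd.DataFrame(rows, columns=["timepoint", "k", "n", "percent"])


@dataclass
class VariantSummary:
    per_gene: pd.Series
    per_timepoint: pd.Series
    max_vaf: float
    oncomap: pd.DataFrame  # patient x gene presence (any timepoint)


def variant_summary(variants: pd.DataFrame) -> VariantSummary:
    """Summarize parsed somatic-variant records (gene/timepoint counts,
    maximum VAF, patient-by-gene presence matrix)."""
    required = {"patient_id", "timepoint", "gene", "vaf_percent"}
    missing = required - set(variants.columns)
    if missing:
        raise DataError(f"variant table missing columns: {sorted(missing)}")
    if len(variants) == 0:
        return VariantSummary(
            pd.Series(dtype=int), pd.Series(dtype=int), 0.0, pd.DataFrame()
        )
    vaf = pd.to_numeric(variants["vaf_percent"], errors="coerce")
    bad = variants.loc[vaf.isna() | (vaf < 0) | (vaf > 100)]
    if len(bad):
        raise DataError(f"malformed VAF in rows: {list(bad.index)}")
    if (variants["gene"].astype(str).str.len() == 0).any():
        raise DataError("empty gene symbol")
    per_gene = variants.groupby("gene").size().sort_index()
    per_tp = variants.groupby("timepoint").size().sort_index()
    oncomap = (
        variants.assign(present=True)
        .pivot_table(index="patient_id", columns="gene", values="present", aggfunc="any", fill_value=False)
        .astype(bool)
    )
    return VariantSummary(per_gene, per_tp, float(vaf.max()), oncomap)
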