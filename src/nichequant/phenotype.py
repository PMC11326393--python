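"""Per-cell phenotype calls from marker intensities, and tissue composition.

A cell is positive for a marker when its intensity is at or above that
marker's threshold, after gating on the nuclear counterstain (DAPI).  The
TCF1 flag is evaluated only inside CD8+ cells.  Thresholds are either
supplied explicitly or derived per tissue with Otsu's criterion on log1p
intensities ("auto") — the original study does not publish its thresholds,
so auto mode is a stand-in and should be pinned via config for
reproducibility.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .errors import EmptyTissueError, FormatError

REQUIRED_MARKERS = ("DAPI", "CD4", "CD8", "MHC-II", "TCF1")

#: phenotype flag column -> marker it gates on
PHENOTYPE_FLAGS = {
    "pheno_DAPI+": "DAPI",
    "pheno_CD4+": "CD4",
    "pheno_CD8+": "CD8",
    "pheno_MHC-II+": "MHC-II",
    "pheno_TCF1+CD8+": "TCF1",
}


def intensity_column(marker: str) -> str:
    return f"{marker}_intensity"


@dataclass
class PhenotypeResult:
    """Cell table with boolean ``pheno_*`` flag columns appended."""

    table: pd.DataFrame
    thresholds_used: dict[str, float]

    def count(self, phenotype: str) -> int:
        return int(self.table[f"pheno_{phenotype}"].sum())

    def points(self, phenotype: str) -> pd.DataFrame:
        """x/y coordinates of cells positive for ``phenotype``."""
        mask = self.table[f"pheno_{phenotype}"].to_numpy(dtype=bool)
        sel = self.table.loc[mask]
        return sel[["cell_id", "x_um", "y_um"]].reset_index(drop=True)


def _auto_threshold(values: np.ndarray) -> float:
    if values.size == 0:
        return np.inf
    if np.ptp(values) == 0:
        return float(values[0])
    t = threshold_otsu(np.log1p(values))
    return float(np.expm1(t))


def call_phenotypes(
    cells: pd.DataFrame,
    thresholds: dict[str, float] | str = "auto",
    markers: tuple[str, ...] = REQUIRED_MARKERS,
) -> PhenotypeResult:
    """Call per-cell phenotypes {DAPI+, CD4+, CD8+, MHC-II+, TCF1+CD8+}.

    Double CD4+/CD8+ calls are resolved to the lineage with the larger
    per-tissue intensity z-score (the analysis treats the lineages as
    disjoint).
    """
    for marker in markers:
        col = intensity_column(marker)
        if col not in cells.columns:
            raise FormatError(f"cell table is missing marker column {col!r}")
    for col in ("cell_id", "x_um", "y_um"):
        if col not in cells.columns:
            raise FormatError(f"cell table is missing column {col!r}")

    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError(f"thresholds must be a mapping or 'auto', got {thresholds!r}")
        thr = {m: _auto_threshold(cells[intensity_column(m)].to_numpy()) for m in markers}
    else:
        missing = [m for m in markers if m not in thresholds]
        if missing:
            raise FormatError(f"thresholds missing for markers: {missing}")
        bad = {m: t for m, t in thresholds.items() if not t > 0}
        if bad:
            raise ValueError(f"thresholds must be positive: {bad}")
        thr = {m: float(thresholds[m]) for m in markers}

    dapi = cells[intensity_column("DAPI")].to_numpy()
    if len(cells) and not np.any(dapi > 0):
        raise EmptyTissueError("all DAPI intensities are zero")

    out = cells.copy()
    dapi_pos = dapi >= thr["DAPI"]
    out["pheno_DAPI+"] = dapi_pos

    def gated(marker: str) -> np.ndarray:
        return dapi_pos & (cells[intensity_column(marker)].to_numpy() >= thr[marker])

    cd4 = gated("CD4")
    cd8 = gated("CD8")
    both = cd4 & cd8
    if both.any():
        z = {}
        for m in ("CD4", "CD8"):
            v = cells[intensity_column(m)].to_numpy(dtype=float)
            sd = v.std()
            z[m] = (v - v.mean()) / sd if sd > 0 else v
        keep_cd8 = z["CD8"] >= z["CD4"]
        cd4 = cd4 & ~(both & keep_cd8)
        cd8 = cd8 & ~(both & ~keep_cd8)
    out["pheno_CD4+"] = cd4
    out["pheno_CD8+"] = cd8
    out["pheno_MHC-II+"] = gated("MHC-II")
    # TCF1 is measured inside CD8+ objects only.
    out["pheno_TCF1+CD8+"] = cd8 & (
        cells[intensity_column("TCF1")].to_numpy() >= thr["TCF1"]
    )
    return PhenotypeResult(out, thr)


def composition_fractions(
    pheno: PhenotypeResult, phenotypes: tuple[str, ...] = ("CD4+", "CD8+", "MHC-II+", "TCF1+CD8+")
) -> dict[str, float]:
    """Percent of DAPI+ cells carrying each phenotype flag (not exclusive)."""
    table = pheno.table
    dapi = table["pheno_DAPI+"].to_numpy()
    n_dapi = int(dapi.sum())
    if n_dapi == 0:
        raise EmptyTissueError("no DAPI+ cells; composition undefined")
    return {
        p: 100.0 * float((table[f"pheno_{p}"].to_numpy() & dapi).sum()) / n_dapi
        for p in phenotypes
    }


def composition_partition(pheno: PhenotypeResult) -> dict[str, float]:
    """Exclusive partition of DAPI+ cells; values sum to exactly 100.

    Priority: CD8+ (incl. TCF1+CD8+) > CD4+ > MHC-II+ > other.
    """
    table = pheno.table
    dapi = table["pheno_DAPI+"].to_numpy()
    n_dapi = int(dapi.sum())
    if n_dapi == 0:
        raise EmptyTissueError("no DAPI+ cells; composition undefined")
    cd8 = table["pheno_CD8+"].to_numpy() & dapi
    cd4 = table["pheno_CD4+"].to_numpy() & dapi & ~cd8
    mhc2 = table["pheno_MHC-II+"].to_numpy() & dapi & ~cd8 & ~cd4
    other = dapi & ~cd8 & ~cd4 & ~mhc2
    return {
        "CD8+": 100.0 * cd8.sum() / n_dapi,
        "CD4+": 100.0 * cd4.sum() / n_dapi,
        "MHC-II+": 100.0 * mhc2.sum() / n_dapi,
        "other": 100.0 * other.sum() / n_dapi,
    }
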