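"""Synthetic tissue point patterns with planted immune niches.

The generator plants hard discs in which the densities of the two
niche-defining phenotypes are raised to stated per-mm² levels; everywhere
else each phenotype follows a homogeneous Poisson process at its background
density.  Overlapping discs take the max of their densities, so the true
niche region is exactly the disc union clipped to the tumor and its
coverage is analytic.

Coordinates are continuous µm, origin top-left, y downward (slide-scanner
convention).  Marker intensities are Gaussian with a floor at zero — only
their order statistics matter for thresholding downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

from ..errors import GeometryError
from ..geometry import UM2_PER_MM2, TumorMask, sample_points_in_polygon

# Phenotype labels used throughout the package.
PHENO_MHC2 = "MHC-II+"
PHENO_TCF1CD8 = "TCF1+CD8+"
PHENO_CD8 = "CD8+"
PHENO_CD4 = "CD4+"
PHENO_OTHER = "other"

#: Markers switched "on" for each planted phenotype (every cell is DAPI+).
POSITIVE_MARKERS: dict[str, frozenset] = {
    PHENO_OTHER: frozenset({"DAPI"}),
    PHENO_CD4: frozenset({"DAPI", "CD4"}),
    PHENO_CD8: frozenset({"DAPI", "CD8"}),
    PHENO_TCF1CD8: frozenset({"DAPI", "CD8", "TCF1"}),
    PHENO_MHC2: frozenset({"DAPI", "MHC-II"}),
}

DEFAULT_MARKERS = ("DAPI", "CD4", "CD8", "MHC-II", "TCF1")


@dataclass(frozen=True)
class MarkerModel:
    """Gaussian intensity model for one marker (arbitrary fluorescence units)."""

    positive_mean: float
    negative_mean: float
    sd: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.positive_mean + self.negative_mean)


def default_intensity_model(
    positive_mean: float = 10.0, negative_mean: float = 1.0, sd: float = 0.8
) -> dict[str, MarkerModel]:
    """Well-separated model (>5 sd between classes) for all default markers."""
    return {m: MarkerModel(positive_mean, negative_mean, sd) for m in DEFAULT_MARKERS}


@dataclass(frozen=True)
class NicheDisc:
    """A planted niche: disc in which both niche phenotypes are dense."""

    center_um: tuple[float, float]
    radius_um: float
    mhc2_per_mm2: float
    tcf1cd8_per_mm2: float


@dataclass(frozen=True)
class TissueSpec:
    width_um: float
    height_um: float
    tumor_mask: TumorMask
    background_density: Mapping[str, float]  # phenotype -> cells per mm²
    niche_specs: Sequence[NicheDisc] = ()
    intensity_model: Mapping[str, MarkerModel] = field(
        default_factory=default_intensity_model
    )
    seed: int = 0

    def __post_init__(self):
        if self.tumor_mask.area_mm2 <= 0:
            raise GeometryError("tumor polygon must have positive area")
        for pheno, d in self.background_density.items():
            if d < 0:
                raise ValueError(f"negative background density for {pheno!r}: {d}")
        for disc in self.niche_specs:
            if disc.radius_um <= 0:
                raise ValueError("niche disc radius must be > 0")
            if disc.mhc2_per_mm2 < 0 or disc.tcf1cd8_per_mm2 < 0:
                raise ValueError("niche densities must be >= 0")

    def midpoint_thresholds(self) -> dict[str, float]:
        """Per-marker positivity thresholds halfway between the two classes."""
        return {m: mm.midpoint for m, mm in self.intensity_model.items()}


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated artifact."""

    niche_mask: np.ndarray | None = None  # binary raster, shape (ny, nx)
    mask_resolution_um: float = 25.0
    planted_coverage: float = 0.0
    planted_counts: dict = field(default_factory=dict)
    labels: pd.Series | None = None  # per-cell planted phenotype (index = cell_id)
    niche_geometry: object = None
    cohort_effects: dict = field(default_factory=dict)
    planted_detection_rates: dict = field(default_factory=dict)
    planted_pr_patients: tuple = ()


def _niche_density_at(x, y, background: float, discs, attr: str) -> np.ndarray:
    d = np.full(x.shape, background, dtype=float)
    for disc in discs:
        cx, cy = disc.center_um
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= disc.radius_um**2
        d[inside] = np.maximum(d[inside], getattr(disc, attr))
    return d


def _sample_phenotype_points(rng, spec: TissueSpec, pheno: str) -> np.ndarray:
    """Points for one phenotype: inhomogeneous Poisson via thinning."""
    geom = spec.tumor_mask.geom
    area_mm2 = spec.tumor_mask.area_mm2
    background = float(spec.background_density.get(pheno, 0.0))
    attr = {PHENO_MHC2: "mhc2_per_mm2", PHENO_TCF1CD8: "tcf1cd8_per_mm2"}.get(pheno)
    if attr is None or not spec.niche_specs:
        n = rng.poisson(background * area_mm2)
        return sample_points_in_polygon(rng, geom, int(n))
    dmax = max([background] + [getattr(d, attr) for d in spec.niche_specs])
    if dmax == 0:
        return np.empty((0, 2))
    n = rng.poisson(dmax * area_mm2)
    pts = sample_points_in_polygon(rng, geom, int(n))
    dens = _niche_density_at(pts[:, 0], pts[:, 1], background, spec.niche_specs, attr)
    keep = rng.uniform(0.0, dmax, len(pts)) < dens
    return pts[keep]


def _planted_niche_geometry(spec: TissueSpec):
    discs = [
        Point(*d.center_um).buffer(d.radius_um, quad_segs=64) for d in spec.niche_specs
    ]
    if not discs:
        return None
    return unary_union(discs).intersection(spec.tumor_mask.geom)


def _rasterize(geom, width_um, height_um, resolution_um) -> np.ndarray:
    import shapely

    nx = max(1, int(np.ceil(width_um / resolution_um)))
    ny = max(1, int(np.ceil(height_um / resolution_um)))
    cx = (np.arange(nx) + 0.5) * resolution_um
    cy = (np.arange(ny) + 0.5) * resolution_um
    gx, gy = np.meshgrid(cx, cy)
    if geom is None or geom.is_empty:
        return np.zeros((ny, nx), dtype=bool)
    return shapely.intersects_xy(geom, gx.ravel(), gy.ravel()).reshape(ny, nx)


def generate_tissue(
    spec: TissueSpec, mask_resolution_um: float = 25.0
) -> tuple[pd.DataFrame, TumorMask, SyntheticTruth]:
    """Generate one tissue: cell table, tumor mask, and ground truth.

    Returns
    -------
    cells : DataFrame with ``cell_id, x_um, y_um, <marker>_intensity`` columns.
    mask : the spec's tumor mask (pass-through for convenience).
    truth : planted labels, counts, niche raster, and analytic coverage.
    """
    rng = np.random.default_rng(spec.seed)

    phenos = sorted(
        set(spec.background_density) | ({PHENO_MHC2, PHENO_TCF1CD8} if spec.niche_specs else set())
    )
    parts, labels = [], []
    for pheno in phenos:
        if pheno not in POSITIVE_MARKERS:
            raise ValueError(f"unknown phenotype {pheno!r}")
        pts = _sample_phenotype_points(rng, spec, pheno)
        parts.append(pts)
        labels.extend([pheno] * len(pts))
    xy = np.concatenate(parts) if parts else np.empty((0, 2))
    labels = np.asarray(labels, dtype=object)

    cell_ids = [f"c{i:06d}" for i in range(len(xy))]
    cells = pd.DataFrame({"cell_id": cell_ids, "x_um": xy[:, 0], "y_um": xy[:, 1]})
    for marker in spec.intensity_model:
        mm = spec.intensity_model[marker]
        means = np.where(
            [marker in POSITIVE_MARKERS[lab] for lab in labels],
            mm.positive_mean,
            mm.negative_mean,
        )
        vals = rng.normal(means, mm.sd) if len(xy) else np.empty(0)
        cells[f"{marker}_intensity"] = np.maximum(vals, 0.0)

    niche_geom = _planted_niche_geometry(spec)
    raster = _rasterize(niche_geom, spec.width_um, spec.height_um, mask_resolution_um)
    coverage = 0.0
    if niche_geom is not None and not niche_geom.is_empty:
        coverage = niche_geom.area / spec.tumor_mask.geom.area

    counts = {p: int((labels == p).sum()) for p in phenos}
    truth = SyntheticTruth(
        niche_mask=raster,
        mask_resolution_um=mask_resolution_um,
        planted_coverage=coverage,
        planted_counts=counts,
        labels=pd.Series(labels, index=pd.Index(cell_ids, name="cell_id")),
        niche_geometry=niche_geom,
    )
    return cells, spec.tumor_mask, truth
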