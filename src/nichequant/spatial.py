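"""Density grids, immune-niche detection, nearest-neighbor distances, immunomaps.

A niche is a region where antigen-presenting (MHC-II+) cells and stem-like
(TCF1+CD8+) T cells co-occur above per-mm² density thresholds "in the same
area".  This is realized as a sliding square window (default 1 mm², 250 µm
stride) over the tumor mask: a window is niche-positive when both phenotype
densities meet their thresholds inside that same window, and the niche
region is the union of positive windows clipped to the mask.

Windows straddling the mask boundary count cells in window∩mask and
normalize density by the clipped area; windows with less than a minimum
in-mask fraction are classified "outside".
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box, mapping, shape
from shapely.ops import unary_union

from .errors import GeometryError, UndefinedDistanceError
from .geometry import UM2_PER_MM2, TumorMask
from .phenotype import PhenotypeResult

NICHE_PHENO_MHC2 = "MHC-II+"
NICHE_PHENO_TCF1CD8 = "TCF1+CD8+"


@dataclass(frozen=True)
class NicheParams:
    """Thresholds and windowing scheme for niche detection."""

    mhc2_min_per_mm2: float = 16.0
    tcf1cd8_min_per_mm2: float = 4.0
    window_area_mm2: float = 1.0
    stride_um: float = 250.0
    min_window_overlap: float = 0.25

    def __post_init__(self):
        if self.mhc2_min_per_mm2 <= 0 or self.tcf1cd8_min_per_mm2 <= 0:
            raise ValueError("density thresholds must be > 0")
        if not 0 < self.min_window_overlap <= 1:
            raise ValueError("min_window_overlap must be in (0, 1]")
        if self.window_area_mm2 <= 0:
            raise ValueError("window_area_mm2 must be > 0")
        if self.stride_um <= 0 or self.stride_um > self.window_side_um + 1e-9:
            raise ValueError("stride_um must be in (0, window side]")

    @property
    def window_side_um(self) -> float:
        return float(np.sqrt(self.window_area_mm2) * 1000.0)


def _window_lattice(mask: TumorMask, params: NicheParams):
    minx, miny, maxx, maxy = mask.bounds
    stride = params.stride_um
    nx = int(np.floor((maxx - minx) / stride)) + 1
    ny = int(np.floor((maxy - miny) / stride)) + 1
    return minx, miny, nx, ny


def _rect_counts(x, y, x0, y0, stride, side, nx, ny) -> np.ndarray:
    """Counts per window; window (k,l) covers the half-open square
    [x0+k·stride, x0+k·stride+side) × [y0+l·stride, y0+l·stride+side)."""
    counts = np.zeros((nx, ny), dtype=np.int64)
    if len(x) == 0:
        return counts
    m = side / stride
    mi = int(round(m))
    if abs(m - mi) < 1e-9:
        # window edges align with the stride grid: bin + 2-D prefix sums
        bx = np.floor((x - x0) / stride).astype(np.int64)
        by = np.floor((y - y0) / stride).astype(np.int64)
        ok = (bx >= 0) & (by >= 0) & (bx < nx + mi) & (by < ny + mi)
        hist = np.zeros((nx + mi, ny + mi), dtype=np.int64)
        np.add.at(hist, (bx[ok], by[ok]), 1)
        S = np.zeros((nx + mi + 1, ny + mi + 1), dtype=np.int64)
        S[1:, 1:] = hist.cumsum(0).cumsum(1)
        counts = (
            S[mi : nx + mi, mi : ny + mi]
            - S[0:nx, mi : ny + mi]
            - S[mi : nx + mi, 0:ny]
            + S[0:nx, 0:ny]
        )
        return counts
    for k in range(nx):
        wx0 = x0 + k * stride
        selx = (x >= wx0) & (x < wx0 + side)
        ys = y[selx]
        for l in range(ny):
            wy0 = y0 + l * stride
            counts[k, l] = int(np.count_nonzero((ys >= wy0) & (ys < wy0 + side)))
    return counts


def density_grid(
    pheno: PhenotypeResult, mask: TumorMask, params: NicheParams | None = None
) -> pd.DataFrame:
    """Per-window counts/densities of the two niche phenotypes.

    Returns one row per lattice window with columns ``cx_um, cy_um, n_mhc2,
    n_tcf1cd8, area_mm2, outside, density_mhc2, density_tcf1cd8``.  Counts
    are over cells inside window∩mask; densities are normalized by the
    clipped in-mask area.  Counts are recorded for every window (including
    "outside" ones) so that at stride = window side the grid partitions the
    plane and per-window counts sum to the total in-mask counts exactly.
    """
    params = params or NicheParams()
    if mask.area_mm2 <= 0:
        raise GeometryError("mask area must be positive")
    side = params.window_side_um
    x0, y0, nx, ny = _window_lattice(mask, params)

    per_pheno = {}
    for name, col in ((NICHE_PHENO_MHC2, "n_mhc2"), (NICHE_PHENO_TCF1CD8, "n_tcf1cd8")):
        pts = pheno.points(name)
        x = pts["x_um"].to_numpy(dtype=float)
        y = pts["y_um"].to_numpy(dtype=float)
        inmask = mask.contains_points(x, y)
        per_pheno[col] = _rect_counts(
            x[inmask], y[inmask], x0, y0, params.stride_um, side, nx, ny
        )

    win_area_um2 = side * side
    geom = mask.geom
    rows = []
    for k in range(nx):
        wx0 = x0 + k * params.stride_um
        for l in range(ny):
            wy0 = y0 + l * params.stride_um
            w = box(wx0, wy0, wx0 + side, wy0 + side)
            inter_um2 = geom.intersection(w).area
            frac = inter_um2 / win_area_um2
            rows.append(
                (
                    wx0 + side / 2,
                    wy0 + side / 2,
                    per_pheno["n_mhc2"][k, l],
                    per_pheno["n_tcf1cd8"][k, l],
                    inter_um2 / UM2_PER_MM2,
                    frac < params.min_window_overlap,
                )
            )
    grid = pd.DataFrame(
        rows, columns=["cx_um", "cy_um", "n_mhc2", "n_tcf1cd8", "area_mm2", "outside"]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        grid["density_mhc2"] = np.where(
            grid["area_mm2"] > 0, grid["n_mhc2"] / grid["area_mm2"], np.nan
        )
        grid["density_tcf1cd8"] = np.where(
            grid["area_mm2"] > 0, grid["n_tcf1cd8"] / grid["area_mm2"], np.nan
        )
    return grid


@dataclass
class NicheMap:
    """Niche classification of a tumor: per-window grid plus region geometry."""

    grid: pd.DataFrame
    params: NicheParams
    mask: TumorMask
    niche_geometry: object
    niche_area_mm2: float
    coverage: float

    def to_csv(self, path) -> None:
        cols = ["cx_um", "cy_um", "n_mhc2", "n_tcf1cd8", "area_mm2", "is_niche"]
        self.grid[cols].to_csv(path, index=False)


def detect_niches(
    pheno: PhenotypeResult, mask: TumorMask, params: NicheParams | None = None
) -> NicheMap:
    """Classify windows as niche / non-niche / outside and measure coverage.

    A window is niche-positive iff both phenotype densities meet their
    thresholds in that same window.  Each positive window contributes its
    center cell (stride x stride; the raster resolution) to the niche
    region, which is clipped to the mask; with stride = window side this is
    the window itself.  Coverage = niche area / mask area.  Attributing the
    whole (overlapping) window instead would dilate the region by roughly
    the window footprint and systematically overestimate coverage.
    """
    params = params or NicheParams()
    grid = density_grid(pheno, mask, params)
    usable = ~grid["outside"] & (grid["area_mm2"] > 0)
    is_niche = (
        usable
        & (grid["density_mhc2"] >= params.mhc2_min_per_mm2)
        & (grid["density_tcf1cd8"] >= params.tcf1cd8_min_per_mm2)
    )
    grid = grid.copy()
    grid["is_niche"] = is_niche

    half = params.stride_um / 2
    boxes = [
        box(cx - half, cy - half, cx + half, cy + half)
        for cx, cy in grid.loc[is_niche, ["cx_um", "cy_um"]].itertuples(index=False)
    ]
    if boxes:
        niche_geom = unary_union(boxes).intersection(mask.geom)
    else:
        niche_geom = Polygon()
    niche_area_mm2 = niche_geom.area / UM2_PER_MM2
    coverage = niche_area_mm2 / mask.area_mm2
    return NicheMap(grid, params, mask, niche_geom, niche_area_mm2, coverage)


def nn_distances(
    pheno: PhenotypeResult, from_phenotype: str, to_phenotype: str
) -> pd.Series:
    """Euclidean distance (µm) from each from-cell to its nearest to-cell.

    When the two sets are identical (same cell ids), each cell's self-match
    is excluded.
    """
    src = pheno.points(from_phenotype)
    dst = pheno.points(to_phenotype)
    if len(dst) == 0:
        raise UndefinedDistanceError(
            f"no cells with phenotype {to_phenotype!r}; distances undefined"
        )
    if len(src) == 0:
        return pd.Series(dtype=float, name="distance_um")
    same = sorted(src["cell_id"]) == sorted(dst["cell_id"])
    tree = cKDTree(dst[["x_um", "y_um"]].to_numpy(dtype=float))
    q = src[["x_um", "y_um"]].to_numpy(dtype=float)
    if same:
        if len(dst) < 2:
            raise UndefinedDistanceError(
                "self-distance requested with a single cell; undefined"
            )
        d, _ = tree.query(q, k=2)
        d = d[:, 1]
    else:
        d, _ = tree.query(q, k=1)
    return pd.Series(d, index=pd.Index(src["cell_id"], name="cell_id"), name="distance_um")


# ---------------------------------------------------------------------------
# Immunomap export: point layers + niche/mask geometry as GeoJSON.

IMMUNOMAP_LAYERS = ("CD8+", "TCF1+CD8+", "MHC-II+")
_EMPTY_GEOM = {"type": "GeometryCollection", "geometries": []}


@dataclass
class ImmunoMap:
    """Raw immunomap content; geometry kept as GeoJSON dicts for exact I/O."""

    layers: dict = field(default_factory=dict)  # phenotype -> [[x, y], ...]
    niche: dict = field(default_factory=lambda: dict(_EMPTY_GEOM))
    mask: dict = field(default_factory=lambda: dict(_EMPTY_GEOM))
    frame: list = field(default_factory=lambda: [0.0, 0.0, 0.0, 0.0])


def build_immunomap(
    pheno: PhenotypeResult,
    niche_map: NicheMap | None,
    mask: TumorMask,
    frame: tuple[float, float, float, float] | None = None,
) -> ImmunoMap:
    if frame is None:
        frame = mask.bounds
    minx, miny, maxx, maxy = frame
    layers = {}
    for name in IMMUNOMAP_LAYERS:
        pts = pheno.points(name)
        xy = pts[["x_um", "y_um"]].to_numpy(dtype=float)
        if len(xy) and (
            xy[:, 0].min() < minx - 1e-9
            or xy[:, 0].max() > maxx + 1e-9
            or xy[:, 1].min() < miny - 1e-9
            or xy[:, 1].max() > maxy + 1e-9
        ):
            raise GeometryError(f"layer {name!r} has points outside the frame")
        layers[name] = [[float(x), float(y)] for x, y in xy]
    niche = dict(_EMPTY_GEOM)
    if niche_map is not None and not niche_map.niche_geometry.is_empty:
        niche = mapping(niche_map.niche_geometry)
    return ImmunoMap(layers, niche, mapping(mask.geom), [float(v) for v in frame])


def write_immunomap(im: ImmunoMap, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "MultiPoint", "coordinates": im.layers[name]},
            "properties": {"layer": "points", "phenotype": name},
        }
        for name in sorted(im.layers)
    ]
    features.append(
        {"type": "Feature", "geometry": im.niche, "properties": {"layer": "niche"}}
    )
    features.append(
        {"type": "Feature", "geometry": im.mask, "properties": {"layer": "tumor_mask"}}
    )
    fc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"units": "um", "frame": im.frame},
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, sort_keys=True, separators=(",", ":"))


def read_immunomap(path) -> ImmunoMap:
    with open(path) as fh:
        fc = json.load(fh)
    im = ImmunoMap(frame=fc["properties"]["frame"])
    for feat in fc["features"]:
        layer = feat["properties"]["layer"]
        if layer == "points":
            im.layers[feat["properties"]["phenotype"]] = feat["geometry"]["coordinates"]
        elif layer == "niche":
            im.niche = feat["geometry"]
        elif layer == "tumor_mask":
            im.mask = feat["geometry"]
    return im


def export_immunomap(
    pheno: PhenotypeResult,
    niche_map: NicheMap | None,
    mask: TumorMask,
    path,
    frame: tuple[float, float, float, float] | None = None,
) -> ImmunoMap:
    im = build_immunomap(pheno, niche_map, mask, frame)
    write_immunomap(im, path)
    return im


def immunomap_niche_area_mm2(im: ImmunoMap) -> float:
    geom = shape(im.niche)
    return geom.area / UM2_PER_MM2
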