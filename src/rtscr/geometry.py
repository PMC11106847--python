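"""Survey geometry: hexagonal detector grids, effort, habitat masks, sample aggregation.

Linear river transects are discretized into a flat-top hexagonal cell grid;
samples collected inside a cell are assigned to its centroid, which then acts
as a point "detector" for the spatial capture-recapture model.  Sampling
effort (km of transect walked inside each cell) becomes a detector-level
covariate, and a rasterized habitat mask restricts the state space to the
flooded area over which activity centers may lie.

All geometry is planar and in meters; geographic (lon/lat) input is rejected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import LineString, MultiLineString, Point, Polygon, shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree
from shapely.validation import make_valid
import shapely

__all__ = [
    "HexGrid",
    "HabitatMask",
    "SurveyDesign",
    "EncounterData",
    "build_hex_grid",
    "assign_effort",
    "build_habitat_mask",
    "aggregate_samples",
    "hex_centroid_spacing",
    "read_transects",
    "read_polygon",
    "read_samples",
    "write_detector_table",
    "read_detector_table",
    "write_ascii_grid",
    "read_ascii_grid",
]


def hex_centroid_spacing(cell_area: float) -> float:
    """Distance between adjacent centroids of a hexagonal tiling of given cell area.

    For regular hexagons of area A the centers of adjacent cells are
    sqrt(2 A / sqrt(3)) apart; 1-ha cells give 107.46 m.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    return math.sqrt(2.0 * cell_area / math.sqrt(3.0))


def _looks_geographic(xs: np.ndarray, ys: np.ndarray, scale_hint: float) -> bool:
    # Heuristic: all coordinates fit in the lon/lat box *and* the geometry is
    # sub-unit scale (degrees are ~1e5 m, so metric survey geometry in that box
    # still has feature scales of tens of meters or more).
    if xs.size == 0:
        return False
    inbox = xs.min() >= -180 and xs.max() <= 180 and ys.min() >= -90 and ys.max() <= 90
    return bool(inbox and scale_hint < 1.0)


@dataclass(frozen=True)
class HexGrid:
    """Flat-top hexagonal tiling of a rectangular extent.

    Attributes
    ----------
    centroids : (J, 2) array of cell centers (meters).
    cell_area : area of each hexagon in m^2.
    extent : (xmin, ymin, xmax, ymax) the tiling is guaranteed to cover.
    """

    centroids: np.ndarray
    cell_area: float
    extent: tuple[float, float, float, float]
    _tree: cKDTree = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_tree", cKDTree(self.centroids))

    @property
    def n_cells(self) -> int:
        return len(self.centroids)

    @property
    def side(self) -> float:
        return math.sqrt(2.0 * self.cell_area / (3.0 * math.sqrt(3.0)))

    @property
    def spacing(self) -> float:
        return hex_centroid_spacing(self.cell_area)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def polygon(self, j: int) -> Polygon:
        """Hexagon polygon of cell j (flat-top: vertices at 0, 60, ... degrees)."""
        cx, cy = self.centroids[j]
        a = self.side
        ang = np.deg2rad(np.arange(0, 360, 60))
        return Polygon(np.column_stack([cx + a * np.cos(ang), cy + a * np.sin(ang)]))

    def polygons(self) -> list[Polygon]:
        return [self.polygon(j) for j in range(self.n_cells)]

    def locate(self, xy: np.ndarray) -> np.ndarray:
        """Cell index of each point (nearest centroid == hexagonal Voronoi cell).

        Boundary points get the single nearest-by-index cell, a deterministic
        half-open membership rule.  Points outside the tiled extent are
        reported with -1.
        """
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d, idx = self._tree.query(xy)
        # any point actually covered by its hexagon is within the circumradius
        idx = np.where(d <= self.side * (1 + 1e-9), idx, -1)
        # points between inradius and circumradius need the exact test
        border = np.nonzero((d > self.spacing / 2 * (1 + 1e-9)) & (idx >= 0))[0]
        if len(border):
            for j in np.unique(idx[border]):
                pts = border[idx[border] == j]
                ok = shapely.contains_xy(
                    self.polygon(j).buffer(1e-9), xy[pts, 0], xy[pts, 1]
                )
                idx[pts[~ok]] = -1
        return idx


def build_hex_grid(
    extent: tuple[float, float, float, float], cell_area: float = 10_000.0
) -> HexGrid:
    """Tile a rectangular extent with flat-top hexagons of the given area.

    The tiling covers every point of the extent (cells overhang the border);
    the grid origin is anchored at the lower-left corner so the result is
    deterministic for a fixed extent.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent is degenerate (zero width or height)")
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    a = math.sqrt(2.0 * cell_area / (3.0 * math.sqrt(3.0)))
    dx = 1.5 * a                   # column pitch
    dy = math.sqrt(3.0) * a        # row pitch
    ncols = int(math.ceil((xmax - xmin) / dx)) + 2
    nrows = int(math.ceil((ymax - ymin) / dy)) + 2
    cents = []
    for c in range(-1, ncols):
        cx = xmin + c * dx
        off = 0.5 * dy if (c % 2) else 0.0
        for r in range(-1, nrows):
            cents.append((cx, ymin + r * dy + off))
    return HexGrid(np.array(cents, dtype=float), cell_area, (xmin, ymin, xmax, ymax))


def assign_effort(
    transects: BaseGeometry | Sequence[BaseGeometry], grid: HexGrid
) -> np.ndarray:
    """Km of transect length clipped into each hexagonal cell.

    The clipped lengths are conserved: their sum equals the total transect
    length.  Raises if the input looks like unprojected lon/lat coordinates or
    if part of a transect falls outside the tiled extent.
    """
    if isinstance(transects, BaseGeometry):
        geoms = [transects]
    else:
        geoms = list(transects)
    parts: list[LineString] = []
    for g in geoms:
        if isinstance(g, LineString):
            parts.append(g)
        elif isinstance(g, MultiLineString):
            parts.extend(g.geoms)
        else:
            raise TypeError(f"transects must be LineString geometries, got {g.geom_type}")
    if not parts:
        return np.zeros(grid.n_cells)
    coords = np.concatenate([np.asarray(p.coords)[:, :2] for p in parts])
    if _looks_geographic(coords[:, 0], coords[:, 1], grid.spacing):
        raise ValueError(
            "transect coordinates look geographic (lon/lat); reproject to a "
            "planar CRS in meters before building the survey design"
        )
    total = sum(p.length for p in parts)
    polys = grid.polygons()
    tree = STRtree(polys)
    L = np.zeros(grid.n_cells)
    for p in parts:
        for j in tree.query(p, predicate="intersects"):
            L[int(j)] += polys[int(j)].intersection(p).length
    clipped = L.sum()
    if total > 0 and abs(clipped - total) > 1e-6 * total + 1e-9:
        raise ValueError(
            f"transects extend outside the grid extent: clipped length "
            f"{clipped:.3f} m != total {total:.3f} m"
        )
    return L / 1000.0


@dataclass(frozen=True)
class HabitatMask:
    """Raster of habitable pixels defining the state space S.

    ``grid[r, c]`` is True where the pixel center falls inside the habitat
    polygon.  Row 0 is the *bottom* row (yll origin, as in ESRI ASCII grids).
    """

    grid: np.ndarray            # bool (nrows, ncols)
    pixel_size: float           # m
    xll: float                  # lower-left corner of raster
    yll: float

    @property
    def nrows(self) -> int:
        return self.grid.shape[0]

    @property
    def ncols(self) -> int:
        return self.grid.shape[1]

    @property
    def habitable_area_km2(self) -> float:
        return float(self.grid.sum()) * self.pixel_size**2 / 1e6

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.pixel_size,
            self.yll + self.nrows * self.pixel_size,
        )

    @property
    def diagonal(self) -> float:
        xmin, ymin, xmax, ymax = self.extent
        return math.hypot(xmax - xmin, ymax - ymin)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """True for points lying on a habitable pixel."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        c = np.floor((xy[:, 0] - self.xll) / self.pixel_size).astype(int)
        r = np.floor((xy[:, 1] - self.yll) / self.pixel_size).astype(int)
        ok = (r >= 0) & (r < self.nrows) & (c >= 0) & (c < self.ncols)
        out = np.zeros(len(xy), dtype=bool)
        out[ok] = self.grid[r[ok], c[ok]]
        return out

    def habitable_centers(self) -> np.ndarray:
        """(n, 2) coordinates of habitable pixel centers."""
        r, c = np.nonzero(self.grid)
        return np.column_stack(
            [
                self.xll + (c + 0.5) * self.pixel_size,
                self.yll + (r + 0.5) * self.pixel_size,
            ]
        )

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw points uniformly over the habitable area (pixel + jitter)."""
        centers = self.habitable_centers()
        if len(centers) == 0:
            raise ValueError("mask has no habitable pixels")
        pick = rng.integers(0, len(centers), size=n)
        jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * self.pixel_size
        return centers[pick] + jitter


def build_habitat_mask(polygon: Polygon, pixel_size: float = 25.0) -> HabitatMask:
    """Rasterize a habitat polygon: a pixel is habitable iff its center is inside.

    Self-intersecting polygons are repaired with ``make_valid``; if repair
    fails to produce a polygonal geometry an error is raised.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if not polygon.is_valid:
        polygon = make_valid(polygon)
        if polygon.is_empty or polygon.area == 0:
            raise ValueError("habitat polygon is invalid and could not be repaired")
    xmin, ymin, xmax, ymax = polygon.bounds
    xll = math.floor(xmin / pixel_size) * pixel_size
    yll = math.floor(ymin / pixel_size) * pixel_size
    ncols = int(math.ceil((xmax - xll) / pixel_size))
    nrows = int(math.ceil((ymax - yll) / pixel_size))
    xs = xll + (np.arange(ncols) + 0.5) * pixel_size
    ys = yll + (np.arange(nrows) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(nrows, ncols)
    if not inside.any():
        raise ValueError("habitat mask has no habitable pixels (polygon too small?)")
    return HabitatMask(inside, float(pixel_size), float(xll), float(yll))


@dataclass(frozen=True)
class SurveyDesign:
    """Detector array for the SCR model: hex grid, per-cell effort, habitat mask."""

    grid: HexGrid
    effort_km: np.ndarray       # (J,) km of transect per cell
    mask: HabitatMask
    active: np.ndarray = None   # indices of retained detectors within the grid

    def __post_init__(self):
        eff = np.asarray(self.effort_km, dtype=float)
        if eff.shape != (self.grid.n_cells,):
            raise ValueError("effort vector length must equal number of grid cells")
        if (eff < 0).any():
            raise ValueError("effort must be non-negative")
        object.__setattr__(self, "effort_km", eff)
        if self.active is None:
            object.__setattr__(self, "active", np.arange(self.grid.n_cells))

    @property
    def detectors(self) -> np.ndarray:
        """(J_active, 2) coordinates of retained detector centroids."""
        return self.grid.centroids[self.active]

    @property
    def detector_effort(self) -> np.ndarray:
        return self.effort_km[self.active]

    def retain_surveyed(self) -> "SurveyDesign":
        """Drop cells with zero effort; zero-count surveyed cells are kept
        (absences are informative)."""
        keep = np.nonzero(self.effort_km > 0)[0]
        return SurveyDesign(self.grid, self.effort_km, self.mask, keep)


@dataclass
class EncounterData:
    """Single-occasion (K=1) encounter data for the rt-SCR model.

    y_id[i, j]  - identified samples of individual i in detector j
    nnid[j]     - genotyped but unidentified samples in detector j
    """

    y_id: np.ndarray
    nnid: np.ndarray
    individual_ids: list[str]
    detector_ids: np.ndarray = None

    def __post_init__(self):
        self.y_id = np.asarray(self.y_id, dtype=int)
        self.nnid = np.asarray(self.nnid, dtype=int)
        if self.y_id.ndim != 2 or self.nnid.ndim != 1:
            raise ValueError("y_id must be 2-D and nnid 1-D")
        if self.y_id.shape[1] != self.nnid.shape[0]:
            raise ValueError("y_id and nnid disagree on the number of detectors")
        if (self.y_id < 0).any() or (self.nnid < 0).any():
            raise ValueError("encounter counts must be non-negative")
        if len(self.individual_ids) != self.y_id.shape[0]:
            raise ValueError("individual_ids length must match y_id rows")
        if self.detector_ids is None:
            self.detector_ids = np.arange(self.y_id.shape[1])

    @property
    def n_individuals(self) -> int:
        return self.y_id.shape[0]

    @property
    def n_detectors(self) -> int:
        return self.y_id.shape[1]

    @property
    def total_detections(self) -> int:
        return int(self.y_id.sum() + self.nnid.sum())

    def subset_detectors(self, idx: np.ndarray) -> "EncounterData":
        return EncounterData(
            self.y_id[:, idx], self.nnid[idx], list(self.individual_ids), np.asarray(idx)
        )


def aggregate_samples(samples: pd.DataFrame, grid: HexGrid) -> EncounterData:
    """Collapse geo-referenced sample records onto the detector grid (K = 1).

    ``samples`` needs columns ``x``, ``y`` and ``individual_id``; records with
    missing/"unknown" individual_id are counted as unidentified.  All sampling
    days are collapsed into a single occasion.  Individuals are ordered by
    first appearance, so the aggregation is deterministic in the input order
    but the resulting count matrix is permutation-invariant.
    """
    req = {"x", "y"}
    if not req.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(req)}")
    xy = samples[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("sample coordinates must be finite")
    cell = grid.locate(xy)
    if (cell < 0).any():
        bad = samples.index[cell < 0].tolist()
        raise ValueError(f"samples outside the detector grid: records {bad}")
    ind = samples.get("individual_id")
    if ind is None:
        ind = pd.Series([None] * len(samples), index=samples.index)
    ind = ind.astype(object).where(ind.notna(), None)
    ind = ind.map(lambda v: None if v in (None, "", "unknown", "NA") else str(v))
    known = ind.dropna()
    ids = list(dict.fromkeys(known))           # first-seen order
    row = {lab: i for i, lab in enumerate(ids)}
    y_id = np.zeros((len(ids), grid.n_cells), dtype=int)
    nnid = np.zeros(grid.n_cells, dtype=int)
    for k, j in enumerate(cell):
        lab = ind.iloc[k]
        if lab is None:
            nnid[j] += 1
        else:
            y_id[row[lab], j] += 1
    return EncounterData(y_id, nnid, ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _geojson_geoms(path: str) -> list[BaseGeometry]:
    with open(path) as fh:
        gj = json.load(fh)
    t = gj.get("type")
    if t == "FeatureCollection":
        return [shape(f["geometry"]) for f in gj["features"]]
    if t == "Feature":
        return [shape(gj["geometry"])]
    return [shape(gj)]


def _reject_geographic(geoms: Iterable[BaseGeometry], assume_planar: bool):
    if assume_planar:
        return
    xs, ys = [], []
    for g in geoms:
        xmin, ymin, xmax, ymax = g.bounds
        xs += [xmin, xmax]
        ys += [ymin, ymax]
    xs, ys = np.array(xs), np.array(ys)
    span = max(xs.max() - xs.min(), ys.max() - ys.min(), 1e-12)
    if _looks_geographic(xs, ys, span / 100.0):
        raise ValueError(
            "coordinates look geographic (lon/lat degrees); reproject to a planar "
            "CRS in meters, or pass assume_planar=True if they really are planar"
        )


def read_transects(path: str, assume_planar: bool = False) -> list[BaseGeometry]:
    """Read transect polylines from a GeoJSON file (planar meters required)."""
    geoms = _geojson_geoms(path)
    _reject_geographic(geoms, assume_planar)
    return geoms


def read_polygon(path: str, assume_planar: bool = False) -> Polygon:
    """Read a (multi)polygon from GeoJSON; multiple parts are unioned."""
    geoms = _geojson_geoms(path)
    _reject_geographic(geoms, assume_planar)
    poly = shapely.union_all(geoms)
    if poly.geom_type == "MultiPolygon":
        return poly
    return poly


def read_samples(path: str) -> pd.DataFrame:
    """Read sample records CSV: sample_id, x, y[, individual_id, sex, date]."""
    df = pd.read_csv(path)
    missing = {"sample_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"sample CSV missing columns: {sorted(missing)}")
    return df


def write_detector_table(path: str, design: SurveyDesign, enc: EncounterData | None = None):
    """Write the detector table CSV (cell_id, x, y, L_km[, n_id, n_noid])."""
    idx = design.active
    out = pd.DataFrame(
        {
            "cell_id": idx,
            "x": design.grid.centroids[idx, 0],
            "y": design.grid.centroids[idx, 1],
            "L_km": design.effort_km[idx],
        }
    )
    if enc is not None:
        if enc.n_detectors == len(idx):
            out["n_id"] = enc.y_id.sum(axis=0)
            out["n_noid"] = enc.nnid
        else:
            out["n_id"] = enc.y_id.sum(axis=0)[idx]
            out["n_noid"] = enc.nnid[idx]
    out.to_csv(path, index=False)


def read_detector_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ascii_grid(path: str, mask: HabitatMask, nodata: int = -9999):
    """Write the habitat mask as an ESRI ASCII grid (1 habitable / 0 not)."""
    with open(path, "w") as fh:
        fh.write(f"ncols {mask.ncols}\n")
        fh.write(f"nrows {mask.nrows}\n")
        fh.write(f"xllcorner {mask.xll}\n")
        fh.write(f"yllcorner {mask.yll}\n")
        fh.write(f"cellsize {mask.pixel_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in mask.grid[::-1]:                 # ASCII grids are top-down
            fh.write(" ".join("1" if v else "0" for v in row) + "\n")


def read_ascii_grid(path: str) -> HabitatMask:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for k in range(6):
        key, val = lines[k].split()
        header[key.lower()] = float(val)
    data = np.loadtxt(lines[6:], dtype=float)
    data = np.atleast_2d(data)[::-1]                # back to bottom-up rows
    return HabitatMask(
        data > 0.5,
        header["cellsize"],
        header["xllcorner"],
        header["yllcorner"],
    )
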