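"""Field rasters, fishnet plot grids, and per-plot tile extraction.

A field epoch is described by three co-registered rasters: an RGB
orthomosaic, a digital surface model (DSM, metres) and a ground-elevation
reference (the first-epoch DSM).  The field is partitioned into rectangular
plots by a fishnet grid, and each plot is cut out of the rasters as a
:class:`PlotTile` that downstream stages (segmentation, traits, outline)
operate on.

Conventions
-----------
* Raster indices are 0-based ``(row, col)``; world coordinates are
  ``(x east, y north)`` in metres; rows advance southwards (``-y``).
* Elevation no-data is represented as NaN and excluded from every
  percentile / sum downstream.
* Plot vectors are GeoJSON; rasters are GeoTIFF (pixel-scale and tiepoint
  tags); masks are 0/255 PNG; tables are CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon, shape as shapely_shape, mapping as shapely_mapping
from shapely.geometry.polygon import orient

from .errors import CoRegistrationError, EmptyTileError, InvalidInputError

__all__ = [
    "GeoTransform",
    "FieldRasterSet",
    "PlotPolygon",
    "PlotTile",
    "make_fishnet",
    "extract_tile",
    "read_field",
    "read_raster",
    "write_raster",
    "read_mask",
    "write_mask",
    "read_traits",
    "write_traits",
    "read_matrix",
    "write_matrix",
    "read_plots",
    "write_plots",
]

# GeoTIFF tag ids for a north-up affine grid.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine pixel grid: ``x = x0 + col*px``, ``y = y0 - row*py``.

    ``(x0, y0)`` is the world coordinate of the *outer corner* of pixel
    (0, 0); ``px``/``py`` are pixel width/height in metres and must be
    positive.
    """

    x0: float
    y0: float
    px: float
    py: float

    def __post_init__(self) -> None:
        if not (self.px > 0 and self.py > 0):
            raise InvalidInputError(f"pixel size must be positive, got ({self.px}, {self.py})")

    @property
    def pixel_area(self) -> float:
        return self.px * self.py

    def pixel_centers(self, n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of every pixel center, as 2-D arrays."""
        cols = self.x0 + (np.arange(n_cols) + 0.5) * self.px
        rows = self.y0 - (np.arange(n_rows) + 0.5) * self.py
        return np.meshgrid(cols, rows)

    def world_to_index(self, x: float, y: float) -> tuple[float, float]:
        """Fractional (row, col) of a world point (0 at the outer corner)."""
        return (self.y0 - y) / self.py, (x - self.x0) / self.px

    def window_transform(self, row0: int, col0: int) -> "GeoTransform":
        return GeoTransform(self.x0 + col0 * self.px, self.y0 - row0 * self.py, self.px, self.py)


@dataclass
class FieldRasterSet:
    """Co-registered orthomosaic + DSM + ground-reference for one epoch."""

    ortho: np.ndarray  # (H, W, 3) uint8
    dsm: np.ndarray  # (H, W) float, metres, NaN = no-data
    ground: np.ndarray  # (H, W) float, metres, NaN = no-data
    transform: GeoTransform
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.ortho.ndim != 3 or self.ortho.shape[2] != 3:
            raise InvalidInputError("orthomosaic must be (H, W, 3)")
        for name, arr in (("dsm", self.dsm), ("ground_ref", self.ground)):
            if arr.shape != self.ortho.shape[:2]:
                raise CoRegistrationError(name, f"shape {arr.shape} != {self.ortho.shape[:2]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ortho.shape[:2]


@dataclass(frozen=True)
class PlotPolygon:
    """One fishnet cell: a positively-oriented quad with a deterministic id."""

    plot_id: str
    row_index: int
    col_index: int
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.polygon.area <= 0:
            raise InvalidInputError(f"plot {self.plot_id}: degenerate polygon")


@dataclass
class PlotTile:
    """Raster windows for one plot, co-registered, with an inside-plot mask."""

    plot_id: str
    rgb: np.ndarray  # (h, w, 3) uint8
    dsm: np.ndarray  # (h, w) float
    ground: np.ndarray  # (h, w) float
    inside: np.ndarray  # (h, w) bool — pixel center falls inside the plot polygon
    transform: GeoTransform
    ridge_axis: tuple[float, float] = (1.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dsm.shape


def _boundary_corners(boundary) -> np.ndarray:
    """Boundary as 4 corner points ordered TL, TR, BR, BL in grid sense.

    Accepts a shapely Polygon (4 distinct vertices) or a (4, 2) array.  The
    first vertex is taken as the grid origin (row 0, col 0) and the second as
    the far end of row 0 — the caller controls orientation through vertex
    order.
    """
    if isinstance(boundary, Polygon):
        pts = np.asarray(boundary.exterior.coords)[:-1]
    else:
        pts = np.asarray(boundary, dtype=float)
    if pts.shape != (4, 2):
        raise InvalidInputError(f"boundary must have exactly 4 corners, got shape {pts.shape}")
    if abs(Polygon(pts).area) <= 0:
        raise InvalidInputError("boundary has zero area")
    return pts


def make_fishnet(boundary, n_rows: int, n_cols: int) -> list[PlotPolygon]:
    """Tile a quadrilateral field boundary into ``n_rows × n_cols`` plots.

    Cells are produced by bilinear interpolation of the four boundary
    corners, so they partition the boundary exactly (no gaps, no overlaps
    beyond shared edges).  Plot ids are assigned deterministically in
    row-major order as ``r{row}c{col}``.
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidInputError("n_rows and n_cols must be >= 1")
    tl, tr, br, bl = _boundary_corners(boundary)

    def corner(u: float, v: float) -> np.ndarray:
        # u in [0,1] across columns, v in [0,1] down rows
        top = (1 - u) * tl + u * tr
        bot = (1 - u) * bl + u * br
        return (1 - v) * top + v * bot

    cells: list[PlotPolygon] = []
    for r in range(n_rows):
        v0, v1 = r / n_rows, (r + 1) / n_rows
        for c in range(n_cols):
            u0, u1 = c / n_cols, (c + 1) / n_cols
            quad = Polygon([corner(u0, v0), corner(u1, v0), corner(u1, v1), corner(u0, v1)])
            cells.append(
                PlotPolygon(
                    plot_id=f"r{r:02d}c{c:02d}",
                    row_index=r,
                    col_index=c,
                    polygon=orient(quad, sign=1.0),
                )
            )
    return cells


def extract_tile(
    field: FieldRasterSet,
    plot: PlotPolygon,
    ridge_axis: tuple[float, float] | float = (1.0, 0.0),
) -> PlotTile:
    """Cut the plot's bounding-box window out of all three rasters.

    ``ridge_axis`` is the planting-line direction, either a world-coordinate
    vector or an angle in degrees from the x-axis; it is normalised and
    carried on the tile for the outline stage.  Pixels whose centers fall
    outside the plot polygon are flagged in ``tile.inside``.
    """
    if np.isscalar(ridge_axis):
        ang = np.deg2rad(float(ridge_axis))
        axis = (float(np.cos(ang)), float(np.sin(ang)))
    else:
        ax = np.asarray(ridge_axis, dtype=float)
        n = float(np.hypot(*ax))
        if n == 0:
            raise InvalidInputError("ridge_axis must be non-zero")
        axis = (float(ax[0] / n), float(ax[1] / n))

    gt = field.transform
    h, w = field.shape
    minx, miny, maxx, maxy = plot.polygon.bounds
    eps = 1e-9
    col0 = int(np.floor((minx - gt.x0) / gt.px + eps))
    col1 = int(np.ceil((maxx - gt.x0) / gt.px - eps))
    row0 = int(np.floor((gt.y0 - maxy) / gt.py + eps))
    row1 = int(np.ceil((gt.y0 - miny) / gt.py - eps))
    col0, col1 = max(col0, 0), min(col1, w)
    row0, row1 = max(row0, 0), min(row1, h)
    if col1 <= col0 or row1 <= row0:
        raise EmptyTileError(f"plot {plot.plot_id} lies outside the raster extent")

    win_gt = gt.window_transform(row0, col0)
    xs, ys = win_gt.pixel_centers(row1 - row0, col1 - col0)
    inside = shapely.contains_xy(plot.polygon, xs.ravel(), ys.ravel()).reshape(xs.shape)

    return PlotTile(
        plot_id=plot.plot_id,
        rgb=field.ortho[row0:row1, col0:col1],
        dsm=field.dsm[row0:row1, col0:col1],
        ground=field.ground[row0:row1, col0:col1],
        inside=inside,
        transform=win_gt,
        ridge_axis=axis,
    )


# ---------------------------------------------------------------------------
# Raster I/O (GeoTIFF via pixel-scale + tiepoint tags)
# ---------------------------------------------------------------------------


def write_raster(path, data: np.ndarray, transform: GeoTransform, crs_label: str = "local-metric") -> None:
    """Write a raster as GeoTIFF with north-up pixel-scale/tiepoint tags."""
    meta = json.dumps({"crs": crs_label})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.px, transform.py, 0.0), False),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0), False),
    ]
    tifffile.imwrite(path, data, description=meta, extratags=extratags)


def read_raster(path) -> tuple[np.ndarray, GeoTransform, str]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        scale = page.tags.get(_TAG_PIXEL_SCALE)
        tie = page.tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            raise InvalidInputError(f"{path}: missing GeoTIFF georeferencing tags")
        px, py = float(scale.value[0]), float(scale.value[1])
        x0, y0 = float(tie.value[3]), float(tie.value[4])
        crs = "local-metric"
        desc = page.tags.get(270)
        if desc is not None:
            try:
                crs = json.loads(desc.value).get("crs", crs)
            except (json.JSONDecodeError, AttributeError, TypeError):
                pass
    return data, GeoTransform(x0, y0, px, py), crs


def _resample_nearest(
    data: np.ndarray, src_gt: GeoTransform, dst_gt: GeoTransform, dst_shape: tuple[int, int]
) -> np.ndarray:
    """Nearest-neighbour resample onto the destination grid; outside -> NaN.

    Nearest-neighbour is deliberate: elevations must not be blended across
    the plant/soil edge.
    """
    xs, ys = dst_gt.pixel_centers(*dst_shape)
    rows = np.floor((src_gt.y0 - ys) / src_gt.py).astype(int)
    cols = np.floor((xs - src_gt.x0) / src_gt.px).astype(int)
    ok = (rows >= 0) & (rows < data.shape[0]) & (cols >= 0) & (cols < data.shape[1])
    out = np.full(dst_shape, np.nan, dtype=float)
    out[ok] = data[rows[ok], cols[ok]]
    return out


def read_field(ortho_path, dsm_path, ground_path) -> FieldRasterSet:
    """Load the three rasters, resampling DSM/ground to the ortho grid if needed."""
    ortho, gt, crs = read_raster(ortho_path)
    if ortho.ndim != 3 or ortho.shape[2] < 3:
        raise InvalidInputError(f"{ortho_path}: orthomosaic must have 3 color bands")
    ortho = ortho[:, :, :3]
    shape = ortho.shape[:2]

    layers = {}
    for name, path in (("dsm", dsm_path), ("ground_ref", ground_path)):
        data, src_gt, _ = read_raster(path)
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise CoRegistrationError(name, f"expected single band, got shape {data.shape}")
        if data.shape != shape or src_gt != gt:
            data = _resample_nearest(data, src_gt, gt, shape)
            if np.all(np.isnan(data)):
                raise CoRegistrationError(name, "no overlap with the orthomosaic grid")
        layers[name] = data
    return FieldRasterSet(ortho=ortho, dsm=layers["dsm"], ground=layers["ground_ref"], transform=gt, crs_label=crs)


# ---------------------------------------------------------------------------
# Mask / table / vector I/O
# ---------------------------------------------------------------------------


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def write_traits(path, records: pd.DataFrame | Sequence) -> None:
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame([r.as_dict() for r in records])
    df.to_csv(path, index=False)


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_matrix(path, matrix: np.ndarray, labels: Sequence[str]) -> None:
    pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels)).to_csv(path)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_plots(path, plots: Sequence[PlotPolygon]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"plot_id": p.plot_id, "row_index": p.row_index, "col_index": p.col_index},
            "geometry": shapely_mapping(p.polygon),
        }
        for p in plots
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def read_plots(path) -> list[PlotPolygon]:
    gj = json.loads(Path(path).read_text())
    out = []
    for feat in gj["features"]:
        props = feat.get("properties", {})
        out.append(
            PlotPolygon(
                plot_id=str(props.get("plot_id", len(out))),
                row_index=int(props.get("row_index", 0)),
                col_index=int(props.get("col_index", 0)),
                polygon=orient(shapely_shape(feat["geometry"]), sign=1.0),
            )
        )
    return out


def read_boundary(path) -> Polygon:
    """Read a single boundary polygon from a GeoJSON file."""
    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    return shapely_shape(geom)
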