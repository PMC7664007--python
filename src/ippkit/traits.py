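"""Per-plant scalar traits from a segmented plot tile.

Twelve planar shape descriptors of the plant mask (region properties in
world units), the 99th-percentile canopy height

    H_p = percentile_99(DSM | plant pixels) - median(ground reference | plant pixels)

and the cylinder-sum canopy volume

    Vol = sum_i max(dsm_i - ground_i, 0) * pixel_area

over the plant pixels.  Percentiles use linear interpolation between order
statistics throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from skimage.measure import label as cc_label, regionprops

from .errors import EmptyMaskError, InvalidInputError
from .plots import PlotTile

__all__ = [
    "TraitRecord",
    "SHAPE_DESCRIPTOR_NAMES",
    "shape_descriptors",
    "plant_height",
    "plant_volume",
    "extract_traits",
]

SHAPE_DESCRIPTOR_NAMES = (
    "cover_area",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "orientation",
    "convex_area",
    "filled_area",
    "equivalent_diameter",
    "solidity",
    "extent",
    "perimeter",
    "roundness",
)


@dataclass
class TraitRecord:
    """Scalar traits of one plant at one epoch (SI units: m, m2, m3, degrees)."""

    plot_id: str
    epoch: str
    cover_area: float
    major_axis: float
    minor_axis: float
    eccentricity: float
    orientation: float
    convex_area: float
    filled_area: float
    equivalent_diameter: float
    solidity: float
    extent: float
    perimeter: float
    roundness: float
    height: float
    volume: float
    warning: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def _single_region(mask: np.ndarray):
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no plant pixels")
    labels, n = cc_label(mask, connectivity=2, return_num=True)
    if n != 1:
        raise InvalidInputError(f"mask must be a single connected component, found {n}")
    return regionprops(labels)[0]


def _orientation_from_x_deg(orientation_rc: float) -> float:
    """Convert the region orientation (from the row axis, image coords) to
    degrees from the world x-axis (east), in (-90, 90]."""
    # major axis direction in (row, col) is (cos o, sin o); world y = -row
    deg = math.degrees(math.atan2(-math.cos(orientation_rc), math.sin(orientation_rc)))
    while deg <= -90.0:
        deg += 180.0
    while deg > 90.0:
        deg -= 180.0
    return deg


def shape_descriptors(mask: np.ndarray, pixel_size: float) -> dict[str, float]:
    """The 12 planar shape descriptors of a single-component mask.

    ``pixel_size`` is the side of a (square) pixel in metres; lengths come
    out in metres, areas in square metres, orientation in degrees from the
    x-axis in (-90, 90].
    """
    if pixel_size <= 0:
        raise InvalidInputError("pixel_size must be positive")
    p = _single_region(mask)
    s, s2 = pixel_size, pixel_size * pixel_size
    cover_area = float(p.area) * s2
    convex_area = float(p.area_convex) * s2
    filled_area = float(p.area_filled) * s2
    # Crofton (4-direction) perimeter: unbiased for smooth outlines, where
    # the chain-code estimate overestimates a disk by ~5%
    perimeter = float(p.perimeter_crofton) * s
    bbox_area = float((p.bbox[2] - p.bbox[0]) * (p.bbox[3] - p.bbox[1])) * s2
    return {
        "cover_area": cover_area,
        "major_axis": float(p.axis_major_length) * s,
        "minor_axis": float(p.axis_minor_length) * s,
        "eccentricity": float(p.eccentricity),
        "orientation": _orientation_from_x_deg(float(p.orientation)),
        "convex_area": convex_area,
        "filled_area": filled_area,
        "equivalent_diameter": math.sqrt(4.0 * cover_area / math.pi),
        "solidity": filled_area / convex_area,
        "extent": cover_area / bbox_area,
        "perimeter": perimeter,
        "roundness": 4.0 * math.pi * cover_area / perimeter**2 if perimeter > 0 else float("nan"),
    }


def plant_height(
    dsm: np.ndarray, ground: np.ndarray, mask: np.ndarray, percentile: float = 99.0
) -> float:
    """Canopy height: high percentile of the DSM over the plant pixels minus
    the median ground-reference elevation under the same pixels.

    The percentile (default 99) rejects isolated tall noise pixels; the
    median ground reference is robust to first-epoch reconstruction noise.
    A negative result (DSM below ground reference, e.g. registration error)
    passes through so validation stays sensitive to it.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("plant_height: empty mask")
    dsm_v = np.asarray(dsm, dtype=float)[mask]
    gnd_v = np.asarray(ground, dtype=float)[mask]
    if np.all(np.isnan(dsm_v)) or np.all(np.isnan(gnd_v)):
        raise EmptyMaskError("plant_height: all masked pixels are no-data")
    e_p = float(np.nanpercentile(dsm_v, percentile))
    e_r = float(np.nanmedian(gnd_v))
    return e_p - e_r


def plant_volume(
    dsm: np.ndarray, ground: np.ndarray, mask: np.ndarray, pixel_area: float
) -> tuple[float, int]:
    """Cylinder-sum canopy volume over the plant pixels (m3).

    Per-pixel heights below the ground reference are clamped to zero;
    returns ``(volume, n_clamped)``.  An empty mask gives volume 0 (with a
    warning) so trait time series stay rectangular.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("plant_volume: empty mask, volume = 0", stacklevel=2)
        return 0.0, 0
    h = np.asarray(dsm, dtype=float)[mask] - np.asarray(ground, dtype=float)[mask]
    h = h[~np.isnan(h)]
    n_neg = int((h < 0).sum())
    vol = float(np.clip(h, 0.0, None).sum() * pixel_area)
    return vol, n_neg


def extract_traits(
    tile: PlotTile, mask: np.ndarray, epoch: str = "", percentile: float = 99.0
) -> TraitRecord:
    """Assemble the full trait record for one plant."""
    gt = tile.transform
    if not math.isclose(gt.px, gt.py, rel_tol=1e-6):
        raise InvalidInputError("shape descriptors require square pixels")
    try:
        desc = shape_descriptors(mask, gt.px)
        height = plant_height(tile.dsm, tile.ground, mask, percentile)
        volume, n_neg = plant_volume(tile.dsm, tile.ground, mask, gt.pixel_area)
    except (EmptyMaskError, InvalidInputError) as e:
        raise type(e)(f"plot {tile.plot_id}: {e}") from e
    warning = ""
    if height < 0:
        warning = f"negative height {height:.4f} m"
    if n_neg:
        warning += ("; " if warning else "") + f"{n_neg} negative-height pixels clamped in volume"
    return TraitRecord(plot_id=tile.plot_id, epoch=epoch, height=height, volume=volume, warning=warning, **desc)
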