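"""WEIPS — Weed Elimination for Individual Plant Segmentation.

Weeds share the color of the focal plant but not its height; stakes and
other artifacts can share its height but not its color.  WEIPS therefore
derives two candidate masks per plot tile:

1. a color-based vegetation mask from the orthomosaic (supervised
   decision-tree pixel classifier, or an unsupervised excess-green + Otsu
   fallback when no labelled pixels are available), and
2. an adaptive height mask from the canopy height model (DSM minus ground
   reference), thresholded from the within-tile histogram of positive
   heights with an absolute floor so near-ground weeds are excluded even in
   unimodal tiles,

and combines them: by default color components are validated by their
overlap with the height mask (green blobs without tall support are weeds,
tall blobs without green are artifacts) and the validated component nearest
the plot center is the focal plant; a strict pixel-wise intersection mode
is also available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing, disk, opening
from sklearn.tree import DecisionTreeClassifier

from .errors import EmptyTileError, InvalidInputError
from .plots import PlotTile

__all__ = [
    "ColorModel",
    "ExGOtsuModel",
    "WeipsParams",
    "PlantMask",
    "pixel_features",
    "excess_green",
    "train_color_model",
    "classify_vegetation",
    "height_mask",
    "combine_masks",
    "weips",
]

FEATURE_NAMES = ("R", "G", "B", "exg", "green_chromaticity")


def excess_green(rgb: np.ndarray) -> np.ndarray:
    """Excess-green index 2G - R - B, a standard vegetation color index."""
    r = rgb[..., 0].astype(float)
    g = rgb[..., 1].astype(float)
    b = rgb[..., 2].astype(float)
    return 2.0 * g - r - b


def pixel_features(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel color features: R, G, B, excess-green, green chromaticity."""
    flat = np.asarray(rgb, dtype=float).reshape(-1, 3)
    r, g, b = flat[:, 0], flat[:, 1], flat[:, 2]
    total = r + g + b
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = np.where(total > 0, g / np.where(total > 0, total, 1.0), 1.0 / 3.0)
    return np.column_stack([r, g, b, 2 * g - r - b, chroma])


@dataclass
class ColorModel:
    """Fitted per-pixel vegetation classifier (decision tree)."""

    kind: str
    estimator: DecisionTreeClassifier
    n_per_class: dict[str, int]
    seed: int
    resubstitution_accuracy: float

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        """Binary vegetation mask for an (H, W, 3) image."""
        labels = self.estimator.predict(pixel_features(rgb))
        return labels.reshape(rgb.shape[:2]).astype(bool)


@dataclass
class ExGOtsuModel:
    """Label-free fallback: threshold the excess-green index by Otsu.

    The threshold is fit per image, clipped below at ``min_exg`` so that an
    all-soil tile (where Otsu would split soil texture noise) stays empty.
    """

    kind: str = "exg-otsu"
    min_exg: float = 20.0

    def predict(self, rgb: np.ndarray) -> np.ndarray:
        exg = excess_green(rgb)
        if np.ptp(exg) <= 0:
            return np.zeros(rgb.shape[:2], bool) if exg.flat[0] < self.min_exg else np.ones(rgb.shape[:2], bool)
        t = max(float(threshold_otsu(exg, nbins=128)), self.min_exg)
        return exg > t


def train_color_model(labeled_pixels: pd.DataFrame, seed: int = 0) -> ColorModel:
    """Fit the decision-tree color classifier on labelled (R, G, B, class) rows.

    ``class`` must be binary with vegetation encoded as 1 / True /
    "vegetation"; at least 10 pixels per class are required.
    """
    df = labeled_pixels
    required = {"R", "G", "B", "class"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"labeled pixels need columns {sorted(required)}")
    raw = df["class"]
    if raw.dtype == object:
        y = raw.astype(str).str.lower().isin(("vegetation", "veg", "plant", "1", "true")).to_numpy()
    else:
        y = raw.to_numpy().astype(bool)
    counts = {"vegetation": int(y.sum()), "background": int((~y).sum())}
    if min(counts.values()) < 10:
        raise InvalidInputError(f"need >= 10 pixels per class, got {counts}")
    X = pixel_features(df[["R", "G", "B"]].to_numpy(dtype=float).reshape(-1, 1, 3))
    tree = DecisionTreeClassifier(random_state=seed, max_depth=8)
    tree.fit(X, y)
    acc = float(tree.score(X, y))
    return ColorModel(
        kind="decision-tree",
        estimator=tree,
        n_per_class=counts,
        seed=seed,
        resubstitution_accuracy=acc,
    )


def classify_vegetation(tile: PlotTile, model) -> np.ndarray:
    """Color-based vegetation mask; outside-plot and no-data pixels are background."""
    mask = model.predict(tile.rgb)
    mask &= tile.inside
    mask &= ~np.isnan(tile.dsm)
    return mask


def height_mask(
    dsm: np.ndarray,
    ground: np.ndarray,
    min_height_floor: float = 0.05,
    nbins: int = 64,
    inside: np.ndarray | None = None,
    method: Literal["triangle", "otsu"] = "triangle",
) -> tuple[np.ndarray, float]:
    """Adaptive height mask from the canopy height model.

    Heights ``h = dsm - ground`` are thresholded at ``max(t, floor)`` where
    ``t`` is estimated from the histogram of positive in-plot heights.  The
    default estimator is the triangle method: a smooth canopy dome has an
    almost uniform height histogram topped by a dominant near-ground mode
    (soil noise + weeds), and the triangle method finds the foot of that
    mode.  Otsu's method is available for genuinely bimodal tiles but
    bisects a dome's flat-tailed histogram, cutting away the canopy skirt.
    Returns the mask and the threshold actually applied; a tile of
    (near-)uniform height falls back to the floor alone.
    """
    h = np.asarray(dsm, dtype=float) - np.asarray(ground, dtype=float)
    valid = ~np.isnan(h)
    if inside is not None:
        valid &= inside
    if not valid.any():
        raise EmptyTileError("height_mask: tile has no valid pixels")
    pos = h[valid & (h > 0)]
    if pos.size >= 2 and np.ptp(pos) > 1e-9:
        if method == "otsu":
            t = float(threshold_otsu(pos, nbins=nbins))
        elif method == "triangle":
            t = float(threshold_triangle(pos, nbins=nbins))
        else:
            raise InvalidInputError(f"unknown threshold method {method!r}")
    else:
        t = 0.0
    t = max(t, float(min_height_floor))
    mask = valid & (h >= t)
    return mask, t


def _select_component(mask: np.ndarray, center_rc: tuple[float, float]) -> np.ndarray:
    """Keep the connected component whose centroid is nearest ``center_rc``.

    Ties break to the largest area, then the lowest component label.
    """
    labels = cc_label(mask, connectivity=2)
    props = regionprops(labels)
    if not props:
        return np.zeros_like(mask)
    keys = [
        (
            float(np.hypot(p.centroid[0] - center_rc[0], p.centroid[1] - center_rc[1])),
            -int(p.area),
            int(p.label),
        )
        for p in props
    ]
    return labels == min(keys)[2]


@dataclass
class WeipsParams:
    """Tunables for one segmentation run (TOML-serialisable)."""

    floor_m: float = 0.05  # absolute minimum plant height (m)
    otsu_bins: int = 64  # histogram bins for the adaptive threshold
    threshold_method: Literal["triangle", "otsu"] = "triangle"
    open_radius_px: int = 1
    close_radius_px: int = 2
    combine_mode: Literal["region", "intersect"] = "region"
    min_height_support: float = 0.2  # region mode: min fraction of a color component in the height mask
    cap_m: float | None = None  # optional stake guard: ignore heights above cap
    seed: int = 0


@dataclass
class PlantMask:
    """Final focal-plant mask plus per-stage provenance."""

    plot_id: str
    mask: np.ndarray
    warning: str | None = None
    veg_mask: np.ndarray | None = None
    hgt_mask: np.ndarray | None = None
    height_threshold: float | None = None

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def combine_masks(
    veg: np.ndarray,
    hgt: np.ndarray,
    params: WeipsParams | None = None,
    center_rc: tuple[float, float] | None = None,
) -> tuple[np.ndarray, str | None]:
    """Combine the color and height candidate masks into the focal-plant mask.

    Two modes:

    * ``"region"`` (default): the color mask is cleaned morphologically and
      split into connected components; components whose area overlaps the
      height mask by at least ``min_height_support`` are the plant
      candidates (green blobs without tall support are weeds; tall blobs
      without green are stakes or other artifacts).  The candidate nearest
      the plot center is the focal plant, with its full color extent — the
      canopy skirt below the height threshold is kept.
    * ``"intersect"``: strict pixel-wise AND of the two masks, then
      morphological opening/closing, then component selection.  The final
      mask is contained in ``veg & hgt`` up to the morphology's reach, at
      the cost of losing the low canopy skirt.

    Returns ``(mask, warning)``; when color and height evidence never
    coincide the mask is all-false with a warning string, not an exception.
    """
    if veg.shape != hgt.shape:
        raise InvalidInputError(f"mask shapes differ: {veg.shape} vs {hgt.shape}")
    params = params or WeipsParams()
    if center_rc is None:
        center_rc = ((veg.shape[0] - 1) / 2.0, (veg.shape[1] - 1) / 2.0)

    if params.combine_mode == "intersect":
        combined = veg & hgt
        if not combined.any():
            return np.zeros_like(combined), "empty intersection of color and height masks"
        if params.open_radius_px > 0:
            combined = opening(combined, disk(params.open_radius_px))
        if params.close_radius_px > 0:
            combined = closing(combined, disk(params.close_radius_px))
        if not combined.any():
            return np.zeros_like(combined), "mask vanished during morphological cleanup"
        return _select_component(combined, center_rc), None

    if params.combine_mode != "region":
        raise InvalidInputError(f"unknown combine_mode {params.combine_mode!r}")
    cleaned = veg
    if params.open_radius_px > 0:
        cleaned = opening(cleaned, disk(params.open_radius_px))
    if params.close_radius_px > 0:
        cleaned = closing(cleaned, disk(params.close_radius_px))
    if not cleaned.any():
        return np.zeros_like(cleaned), "no vegetation pixels after cleanup"
    labels = cc_label(cleaned, connectivity=2)
    supported = np.zeros_like(cleaned)
    for p in regionprops(labels):
        comp = labels == p.label
        if (comp & hgt).sum() >= params.min_height_support * p.area:
            supported |= comp
    if not supported.any():
        return np.zeros_like(cleaned), "no color component has height support"
    return _select_component(supported, center_rc), None


def _plot_center_rc(tile: PlotTile) -> tuple[float, float]:
    if tile.inside.any():
        rr, cc = np.nonzero(tile.inside)
        return float(rr.mean()), float(cc.mean())
    return ((tile.shape[0] - 1) / 2.0, (tile.shape[1] - 1) / 2.0)


def weips(tile: PlotTile, model, params: WeipsParams | None = None) -> PlantMask:
    """Full WEIPS segmentation of one plot tile.

    Composes :func:`classify_vegetation`, :func:`height_mask` and
    :func:`combine_masks`; per-stage masks and the applied height threshold
    are kept on the result for inspection.
    """
    params = params or WeipsParams()
    try:
        veg = classify_vegetation(tile, model)
    except Exception as e:  # pragma: no cover - stage naming contract
        raise type(e)(f"[color stage] {e}") from e
    dsm = tile.dsm
    if params.cap_m is not None:
        dsm = np.where(dsm - tile.ground > params.cap_m, tile.ground + params.cap_m, dsm)
    try:
        hgt, t = height_mask(
            dsm, tile.ground, params.floor_m, params.otsu_bins, tile.inside, params.threshold_method
        )
    except EmptyTileError as e:
        raise EmptyTileError(f"[height stage] plot {tile.plot_id}: {e}") from e
    mask, warning = combine_masks(veg, hgt, params, _plot_center_rc(tile))
    return PlantMask(
        plot_id=tile.plot_id,
        mask=mask,
        warning=warning,
        veg_mask=veg,
        hgt_mask=hgt,
        height_threshold=t,
    )
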