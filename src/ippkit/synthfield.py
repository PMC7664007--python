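"""Synthetic field scenes with known ground truth.

Emulates the single-grown field trial the pipeline targets: a rectangular
field divided into 1 m plots, one focal plant per plot rendered as a smooth
radial height dome, green weed clutter near the ground, brown soil with
mulch strips along the planting rows, optional tall thin stake artifacts,
and additive Gaussian noise on both elevation rasters.  Every scene carries
its noiseless height fields and per-plot truth (masks, 99th-percentile
height, Riemann-sum volume) so each pipeline stage can be scored against
ground truth without any external data.

The dome profile is a paraboloid ``h(r) = H * (1 - (r/R)^2)`` for ``r <= R``,
whose exact volume is ``pi * H * R^2 / 2`` — a closed form the volume
estimator can be checked against.  A Gaussian dome option exists (no closed
form; integrate the stored noiseless field instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .outline import DEFAULT_BIN_WIDTH, DEFAULT_LENGTH, DEFAULT_MAX_SLIDE, OutlineVector
from .plots import FieldRasterSet, GeoTransform, PlotPolygon, make_fishnet

__all__ = ["SceneParams", "PlotTruth", "SyntheticScene", "generate_scene", "generate_outline_set"]


@dataclass
class SceneParams:
    """Study conditions for one synthetic scene.

    Defaults mirror the field protocol the pipeline was designed around:
    1 m plant spacing, ~4 mm/pixel ground sampling distance, weeds no taller
    than 5 cm, 60 cm mulch strips along the planting rows, and ~1 cm
    elevation noise.
    """

    n_rows: int = 3
    n_cols: int = 5
    plot_size_m: float = 1.0
    gsd: float = 0.004  # metres / pixel
    plant_height_range: tuple[float, float] = (0.5, 1.5)
    plant_radius_range: tuple[float, float] = (0.15, 0.35)
    center_jitter_m: float = 0.05
    weed_density_per_m2: float = 10.0
    weed_height_range: tuple[float, float] = (0.01, 0.05)
    weed_radius_range: tuple[float, float] = (0.01, 0.04)
    soil_rgb: tuple[int, int, int] = (120, 85, 50)
    mulch_rgb: tuple[int, int, int] = (70, 70, 75)
    veg_rgb: tuple[int, int, int] = (45, 160, 50)
    stake_rgb: tuple[int, int, int] = (165, 150, 130)
    color_noise_sd: float = 12.0
    dsm_noise_sd: float = 0.01  # metres
    mulch_width_m: float = 0.6
    stake_prob: float = 0.0
    stake_height_m: float = 2.0
    stake_width_m: float = 0.03
    stake_length_m: float = 0.20
    dome: Literal["paraboloid", "gaussian"] = "paraboloid"
    seed: int = 0

    def validate(self) -> None:
        if self.gsd <= 0 or self.plot_size_m <= 0:
            raise InvalidInputError("gsd and plot size must be positive")
        for name, rng_ in (
            ("plant_height_range", self.plant_height_range),
            ("plant_radius_range", self.plant_radius_range),
            ("weed_height_range", self.weed_height_range),
            ("weed_radius_range", self.weed_radius_range),
        ):
            lo, hi = rng_
            if not (0 < lo <= hi):
                raise InvalidInputError(f"{name} must be positive and ordered, got {rng_}")
        if not 0 <= self.stake_prob <= 1:
            raise InvalidInputError("stake_prob must be in [0, 1]")
        if self.plot_size_m < 2 * self.plant_radius_range[1]:
            raise InvalidInputError(
                f"plots overlap: spacing {self.plot_size_m} m < 2 x max plant radius "
                f"{self.plant_radius_range[1]} m"
            )


@dataclass
class PlotTruth:
    """Ground truth for one plot's focal plant (masks on the full field grid)."""

    plot_id: str
    center_xy: tuple[float, float]
    height_max: float  # dome apex H (m)
    radius: float  # dome radius R (m)
    plant_mask: np.ndarray
    height_p99: float  # 99th percentile of the noiseless dome over plant_mask
    volume: float  # Riemann sum of the noiseless dome over plant_mask (m3)
    has_stake: bool


@dataclass
class SyntheticScene:
    params: SceneParams
    field: FieldRasterSet
    plots: list[PlotPolygon]
    truth: list[PlotTruth]
    vegetation_mask: np.ndarray  # plants + weeds
    weed_mask: np.ndarray
    stake_mask: np.ndarray
    plant_height_field: np.ndarray  # noiseless, plants only (m)
    surface_height_field: np.ndarray  # noiseless, plants + weeds + stakes (m)

    def mask_window(self, tile, full_mask: np.ndarray) -> np.ndarray:
        """Restrict a full-field truth mask to a tile's raster window."""
        gt = self.field.transform
        r0 = int(round((gt.y0 - tile.transform.y0) / gt.py))
        c0 = int(round((tile.transform.x0 - gt.x0) / gt.px))
        h, w = tile.shape
        return full_mask[r0 : r0 + h, c0 : c0 + w]

    def sample_labeled_pixels(self, n_per_class: int = 200, seed: int = 0) -> pd.DataFrame:
        """Draw labelled (R, G, B, class) rows from the rendered orthomosaic.

        Vegetation pixels are sampled from the truth vegetation mask and
        background pixels from its complement — the supervision a user would
        provide by clicking on the image.
        """
        rng = np.random.default_rng(seed)
        rows = []
        for cls, mask in (("vegetation", self.vegetation_mask), ("background", ~self.vegetation_mask)):
            rr, cc = np.nonzero(mask)
            if rr.size == 0:
                raise InvalidInputError(f"scene has no {cls} pixels to sample")
            take = rng.choice(rr.size, size=min(n_per_class, rr.size), replace=False)
            for r, c in zip(rr[take], cc[take]):
                px = self.field.ortho[r, c]
                rows.append({"R": int(px[0]), "G": int(px[1]), "B": int(px[2]), "class": cls})
        return pd.DataFrame(rows)


def _dome(dist: np.ndarray, height: float, radius: float, kind: str) -> np.ndarray:
    if kind == "paraboloid":
        return height * np.clip(1.0 - (dist / radius) ** 2, 0.0, None)
    if kind == "gaussian":
        sigma = radius / 2.0
        out = height * np.exp(-0.5 * (dist / sigma) ** 2)
        return np.where(dist <= radius, out, 0.0)
    raise InvalidInputError(f"unknown dome profile {kind!r}")


def generate_scene(params: SceneParams | None = None) -> SyntheticScene:
    """Render one field epoch with full ground truth; deterministic per seed."""
    p = params or SceneParams()
    p.validate()
    rng = np.random.default_rng(p.seed)

    width_m = p.n_cols * p.plot_size_m
    height_m = p.n_rows * p.plot_size_m
    n_cols_px = int(round(width_m / p.gsd))
    n_rows_px = int(round(height_m / p.gsd))
    gt = GeoTransform(0.0, height_m, p.gsd, p.gsd)
    xs = (np.arange(n_cols_px) + 0.5) * p.gsd
    ys = height_m - (np.arange(n_rows_px) + 0.5) * p.gsd

    boundary = [(0.0, height_m), (width_m, height_m), (width_m, 0.0), (0.0, 0.0)]
    plots = make_fishnet(boundary, p.n_rows, p.n_cols)

    plant_field = np.zeros((n_rows_px, n_cols_px))
    # material codes: 0 soil, 1 mulch, 2 vegetation, 3 stake
    material = np.zeros((n_rows_px, n_cols_px), dtype=np.uint8)
    for r in range(p.n_rows):
        cy = height_m - (r + 0.5) * p.plot_size_m
        strip = np.abs(ys - cy) <= p.mulch_width_m / 2.0
        material[strip, :] = 1

    # focal plants, one per plot (row-major to keep plot ids aligned)
    truth: list[PlotTruth] = []
    max_center_off = p.plot_size_m / 2.0 - p.plant_radius_range[1]
    jitter = min(p.center_jitter_m, max(max_center_off, 0.0))
    for plot in plots:
        cx0, cy0 = plot.polygon.centroid.x, plot.polygon.centroid.y
        cx = cx0 + rng.uniform(-jitter, jitter)
        cy = cy0 + rng.uniform(-jitter, jitter)
        h_max = rng.uniform(*p.plant_height_range)
        radius = rng.uniform(*p.plant_radius_range)
        c0 = max(int((cx - radius) / p.gsd) - 1, 0)
        c1 = min(int((cx + radius) / p.gsd) + 2, n_cols_px)
        r0 = max(int((height_m - (cy + radius)) / p.gsd) - 1, 0)
        r1 = min(int((height_m - (cy - radius)) / p.gsd) + 2, n_rows_px)
        dx = xs[c0:c1] - cx
        dy = ys[r0:r1] - cy
        dist = np.hypot(dx[None, :], dy[:, None])
        dome = _dome(dist, h_max, radius, p.dome)
        plant_field[r0:r1, c0:c1] = np.maximum(plant_field[r0:r1, c0:c1], dome)
        plant_mask = np.zeros((n_rows_px, n_cols_px), dtype=bool)
        plant_mask[r0:r1, c0:c1] = dome > 0
        heights = dome[dome > 0]
        truth.append(
            PlotTruth(
                plot_id=plot.plot_id,
                center_xy=(cx, cy),
                height_max=h_max,
                radius=radius,
                plant_mask=plant_mask,
                height_p99=float(np.percentile(heights, 99)),
                volume=float(heights.sum() * gt.pixel_area),
                has_stake=False,
            )
        )

    # weeds: flat green discs with heights well below the plants
    weed_field = np.zeros_like(plant_field)
    n_weeds = int(rng.poisson(p.weed_density_per_m2 * width_m * height_m))
    for _ in range(n_weeds):
        wx = rng.uniform(0, width_m)
        wy = rng.uniform(0, height_m)
        wr = rng.uniform(*p.weed_radius_range)
        wh = rng.uniform(*p.weed_height_range)
        c0 = max(int((wx - wr) / p.gsd) - 1, 0)
        c1 = min(int((wx + wr) / p.gsd) + 2, n_cols_px)
        r0 = max(int((height_m - (wy + wr)) / p.gsd) - 1, 0)
        r1 = min(int((height_m - (wy - wr)) / p.gsd) + 2, n_rows_px)
        if c1 <= c0 or r1 <= r0:
            continue
        dist = np.hypot((xs[c0:c1] - wx)[None, :], (ys[r0:r1] - wy)[:, None])
        weed_field[r0:r1, c0:c1] = np.maximum(weed_field[r0:r1, c0:c1], np.where(dist <= wr, wh, 0.0))

    # stakes: tall thin rectangles crossing the plant, per-plot Bernoulli.
    # The DSM spike is rendered at full stake height; where the stake crosses
    # the canopy the orthomosaic keeps the canopy color (thin stakes are
    # under-resolved in the mosaic), which is exactly what lets the artifact
    # corrupt height-based processing downstream.
    stake_mask = np.zeros_like(material, dtype=bool)
    stake_field = np.zeros_like(plant_field)
    if p.stake_prob > 0:
        for t in truth:
            if rng.uniform() >= p.stake_prob:
                continue
            cx, cy = t.center_xy
            sx = cx + 0.3 * t.radius  # offset so the stake crosses the dome flank
            in_x = np.abs(xs - sx) <= p.stake_width_m / 2.0
            in_y = np.abs(ys - cy) <= p.stake_length_m / 2.0
            region = in_y[:, None] & in_x[None, :]
            stake_mask |= region
            stake_field[region] = np.maximum(stake_field[region], p.stake_height_m)
            t.has_stake = True

    veg_field = np.maximum(plant_field, weed_field)
    vegetation_mask = veg_field > 0
    weed_mask = (weed_field > 0) & ~(plant_field > 0)
    material[vegetation_mask] = 2
    material[stake_mask & ~vegetation_mask] = 3

    surface = np.maximum(veg_field, stake_field)

    palette = np.array([p.soil_rgb, p.mulch_rgb, p.veg_rgb, p.stake_rgb], dtype=float)
    ortho = palette[material]
    ortho += rng.normal(0.0, p.color_noise_sd, ortho.shape)
    ortho = np.clip(ortho, 0, 255).astype(np.uint8)

    ground_elev = 0.0
    dsm = ground_elev + surface + rng.normal(0.0, p.dsm_noise_sd, surface.shape)
    ground_ref = ground_elev + rng.normal(0.0, p.dsm_noise_sd, surface.shape)

    field = FieldRasterSet(ortho=ortho, dsm=dsm, ground=ground_ref, transform=gt, crs_label="synthetic-local")
    return SyntheticScene(
        params=p,
        field=field,
        plots=plots,
        truth=truth,
        vegetation_mask=vegetation_mask,
        weed_mask=weed_mask,
        stake_mask=stake_mask,
        plant_height_field=plant_field,
        surface_height_field=surface,
    )


def generate_outline_set(
    n_per_group: int = 20,
    group_offsets: tuple[float, ...] = (0.0, 0.12, 0.24),
    noise_sd: float = 0.01,
    length: int = DEFAULT_LENGTH,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_slide: int = DEFAULT_MAX_SLIDE,
    seed: int = 0,
) -> tuple[list[OutlineVector], list[str]]:
    """Outline vectors from group-specific canopy templates, under nuisance
    transforms.

    Each group's template is a pair of paraboloid bumps whose separation is
    the group's ``offset`` (0 gives a single merged peak; larger offsets an
    increasingly double-peaked form).  Every sample gets element-wise
    Gaussian noise on its support, a random slide within ``±max_slide`` and
    a random flip, so only form differences — not position or orientation —
    distinguish the groups.
    """
    if n_per_group < 2:
        raise InvalidInputError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    s = (np.arange(length) - length // 2 + 0.5) * bin_width

    def template(offset: float) -> np.ndarray:
        bump_w = 0.12
        left = 0.55 * np.clip(1 - ((s + offset / 2) / bump_w) ** 2, 0, None)
        right = 0.45 * np.clip(1 - ((s - offset / 2) / bump_w) ** 2, 0, None)
        return np.maximum(left, right)

    # templates must keep >= max_slide zero bins on each side so nuisance
    # slides never truncate signal
    for off in group_offsets:
        support = np.nonzero(template(off))[0]
        if support.size and (support[0] < max_slide or support[-1] >= length - max_slide):
            raise InvalidInputError(
                f"template with offset {off} has < {max_slide} zero-bin margins at length {length}"
            )

    outlines: list[OutlineVector] = []
    labels: list[str] = []
    for g, off in enumerate(group_offsets):
        base = template(off)
        for i in range(n_per_group):
            vals = base.copy()
            on = vals > 0
            if noise_sd > 0:
                vals[on] = np.clip(vals[on] + rng.normal(0.0, noise_sd, on.sum()), 0.0, None)
            n_slide = int(rng.integers(-max_slide, max_slide + 1))
            if n_slide > 0:
                vals = np.concatenate([vals[n_slide:], np.zeros(n_slide)])
            elif n_slide < 0:
                vals = np.concatenate([np.zeros(-n_slide), vals[:n_slide]])
            if rng.uniform() < 0.5:
                vals = vals[::-1].copy()
            outlines.append(OutlineVector(vals, bin_width, plot_id=f"g{g}_s{i:02d}"))
            labels.append(f"g{g}")
    return outlines, labels
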