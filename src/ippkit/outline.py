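"""Canopy outline morphometrics.

The canopy outline is the upper boundary of the DSM projected onto the
planting-line (ridge) axis: plant pixels are binned by their position along
the ridge, and each bin holds the 99th percentile of the canopy heights
falling in it (empty bins hold 0).  Outlines are compared by a
form dissimilarity that is invariant to translation along the ridge and to
mirror reflection: the minimum vector distance over all admissible slides
(zero-pad one end, truncate the other) and horizontal flips.

Defaults follow the field protocol the package targets: vectors of
L = 433 bins of 0.375 cm, slides up to +/-108 bins (40.5 cm of admissible
translation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence
import warnings

import numpy as np

from .errors import EmptyMaskError, InvalidInputError, InvalidShiftError
from .plots import PlotTile

__all__ = [
    "OutlineVector",
    "DistanceMatrix",
    "DEFAULT_LENGTH",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_MAX_SLIDE",
    "project_outline",
    "slide",
    "hflip",
    "outline_dissimilarity",
    "dissimilarity_matrix",
]

DEFAULT_LENGTH = 433
DEFAULT_BIN_WIDTH = 0.00375  # metres (0.375 cm)
DEFAULT_MAX_SLIDE = 108


@dataclass
class OutlineVector:
    """Binned 99th-percentile canopy heights along the ridge axis (metres)."""

    values: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    plot_id: str = ""
    ridge_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidInputError("outline values must be a 1-D vector")
        if self.bin_width <= 0:
            raise InvalidInputError("bin_width must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DistanceMatrix:
    """Symmetric outline-dissimilarity matrix with sample labels and groups."""

    matrix: np.ndarray
    labels: list[str]
    groups: list[str] | None = None
    max_slide: int = DEFAULT_MAX_SLIDE

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("distance matrix must be square")
        if m.shape[0] != len(self.labels):
            raise InvalidInputError("labels do not match matrix size")
        self.matrix = m


def project_outline(
    tile: PlotTile,
    mask: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    length: int = DEFAULT_LENGTH,
    percentile: float = 99.0,
) -> OutlineVector:
    """Project the masked canopy heights onto the ridge axis and bin them.

    Each plant pixel contributes its canopy height ``max(dsm - ground, 0)``
    at its signed distance along the ridge axis from the mask centroid; the
    vector is centered so the centroid maps to bin ``length // 2``.  Bins
    with no points hold 0.  An empty mask yields an all-zero vector with a
    warning rather than an error so outline sets stay rectangular.
    """
    mask = np.asarray(mask, dtype=bool)
    vec = np.zeros(length, dtype=float)
    if not mask.any():
        warnings.warn(f"project_outline: empty mask for plot {tile.plot_id!r}", stacklevel=2)
        return OutlineVector(vec, bin_width, tile.plot_id, tile.ridge_axis)

    h = np.asarray(tile.dsm, dtype=float) - np.asarray(tile.ground, dtype=float)
    valid = mask & ~np.isnan(h)
    if not valid.any():
        warnings.warn(f"project_outline: all masked pixels no-data for {tile.plot_id!r}", stacklevel=2)
        return OutlineVector(vec, bin_width, tile.plot_id, tile.ridge_axis)

    rr, cc = np.nonzero(valid)
    gt = tile.transform
    xs = gt.x0 + (cc + 0.5) * gt.px
    ys = gt.y0 - (rr + 0.5) * gt.py
    ux, uy = tile.ridge_axis
    s = (xs - xs.mean()) * ux + (ys - ys.mean()) * uy
    bins = np.floor(s / bin_width).astype(int) + length // 2
    keep = (bins >= 0) & (bins < length)
    if not keep.all():
        warnings.warn(
            f"project_outline: {(~keep).sum()} pixels fall outside the {length}-bin window",
            stacklevel=2,
        )
    heights = np.clip(h[rr, cc], 0.0, None)
    for b in np.unique(bins[keep]):
        vec[b] = np.percentile(heights[keep][bins[keep] == b], percentile)
    return OutlineVector(vec, bin_width, tile.plot_id, tile.ridge_axis)


def _as_values(v) -> np.ndarray:
    return v.values if isinstance(v, OutlineVector) else np.asarray(v, dtype=float)


def slide(v, n: int):
    """n-slide an outline: zero-pad one end and truncate the other.

    ``n > 0`` appends n zeros to the tail and deletes n head elements
    (content moves toward the head); ``n < 0`` is the mirror operation.
    Length is preserved; the operation is lossy at the truncated end.
    """
    vals = _as_values(v)
    L = vals.size
    if abs(n) >= L:
        raise InvalidShiftError(f"|n| = {abs(n)} must be < vector length {L}")
    if n == 0:
        out = vals.copy()
    elif n > 0:
        out = np.concatenate([vals[n:], np.zeros(n)])
    else:
        out = np.concatenate([np.zeros(-n), vals[:n]])
    if isinstance(v, OutlineVector):
        return replace(v, values=out)
    return out


def hflip(v):
    """Mirror-flip an outline (reverse element order); an involution."""
    vals = _as_values(v)[::-1].copy()
    if isinstance(v, OutlineVector):
        return replace(v, values=vals)
    return vals


def _transform_stack(vals: np.ndarray, max_slide: int) -> np.ndarray:
    """All 2*(2*max_slide + 1) slide x flip transforms of a vector, stacked."""
    L = vals.size
    shifts = np.arange(-max_slide, max_slide + 1)
    stack = np.zeros((2 * shifts.size, L))
    for half, src in enumerate((vals, vals[::-1])):
        for i, n in enumerate(shifts):
            row = half * shifts.size + i
            if n >= 0:
                stack[row, : L - n] = src[n:]
            else:
                stack[row, -n:] = src[: L + n]
    return stack


def _directed_min(a: np.ndarray, b: np.ndarray, max_slide: int, metric: str) -> float:
    stack = _transform_stack(b, max_slide)
    diff = stack - a[None, :]
    if metric == "l2":
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    elif metric == "l1":
        d = np.abs(diff).sum(axis=1)
    else:
        raise InvalidInputError(f"unknown metric {metric!r}")
    return float(d.min())


def outline_dissimilarity(
    a,
    b,
    max_slide: int = DEFAULT_MAX_SLIDE,
    metric: Literal["l2", "l1"] = "l2",
) -> float:
    """Form dissimilarity between two outlines.

    Minimum distance between ``a`` and any slide (|n| <= max_slide) and/or
    flip of ``b``; symmetrised as ``min(d(a -> b), d(b -> a))`` because
    sliding truncates and is therefore not invertible.  Invariant to flips
    and to admissible slides of either argument (when the slid content fits
    in the zero margins); not a metric — the triangle inequality may fail.
    """
    av, bv = _as_values(a), _as_values(b)
    if av.size != bv.size:
        raise InvalidInputError(f"outline lengths differ: {av.size} vs {bv.size}")
    if isinstance(a, OutlineVector) and isinstance(b, OutlineVector):
        if not np.isclose(a.bin_width, b.bin_width, rtol=1e-9):
            raise InvalidInputError("outline bin widths differ")
    if max_slide < 0 or max_slide >= av.size:
        raise InvalidInputError(f"max_slide must be in [0, {av.size - 1}]")
    return min(
        _directed_min(av, bv, max_slide, metric),
        _directed_min(bv, av, max_slide, metric),
    )


def dissimilarity_matrix(
    outlines: Sequence[OutlineVector],
    max_slide: int = DEFAULT_MAX_SLIDE,
    metric: Literal["l2", "l1"] = "l2",
    groups: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-pairs form dissimilarities, as a labelled symmetric matrix."""
    n = len(outlines)
    labels = [o.plot_id if isinstance(o, OutlineVector) and o.plot_id else f"s{i}" for i, o in enumerate(outlines)]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = outline_dissimilarity(outlines[i], outlines[j], max_slide, metric)
    return DistanceMatrix(matrix=m, labels=labels, groups=list(groups) if groups is not None else None, max_slide=max_slide)
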