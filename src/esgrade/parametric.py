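"""Parametric image formation: colorized B-mode, moment maps, moment heat maps.

Four image types feed the classifier: (1) the normalized envelope rendered
through a jet palette (B-mode style but gain-independent), (2) the
first-order moment map, (3) the fourth-order moment map, and (4) a 2-D
histogram ("moment heat map") of per-pixel (M1, M4) pairs with M1 on the
horizontal and M4 on the vertical axis.  The heat map shows the joint
distribution of the two moments at a glance: fully developed speckle piles
up near (0.886, 2.0), pre-Rayleigh regions shift left/up, post-Rayleigh
right/down.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from skimage.transform import resize

from .envelope import (
    EllipticalWindow,
    MomentMap,
    MOMENT_MAP_WINDOW_MM,
    NormalizedImage,
    local_moment,
)

#: Display range of normalized-envelope values; survivors of the 3x RMS
#: exclusion are bounded near 3.
BMODE_RANGE = (0.0, 3.0)
#: Display/heat-map range of the normalized first-order moment.
M1_RANGE = (0.0, 1.5)
#: Display/heat-map range of the normalized fourth-order moment; covers the
#: Nakagami family down to m = 0.5 (M4 = 3) with margin.
M4_RANGE = (0.0, 8.0)
#: Heat-map grid resolution (bins per axis).
DEFAULT_HEATMAP_BINS = 224


@dataclass
class MomentHeatMap:
    """2-D count histogram over (M1, M4) pairs of an ROI's valid pixels."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_pixels: int


@dataclass
class RenderedImage:
    """RGB rendering in [0, 1] of one of the four classifier input types."""

    rgb: np.ndarray
    source_kind: str
    provenance: str = ""


def colorize(
    values: np.ndarray,
    value_range: tuple[float, float],
    palette: str = "jet",
    valid: np.ndarray | None = None,
    source_kind: str = "bmode",
) -> RenderedImage:
    """Clip to ``value_range``, scale to [0, 1], map through a palette.

    ``gray`` reproduces conventional B-mode shading; ``jet`` is the
    colorized style.  Invalid/excluded pixels render black.
    """
    lo, hi = value_range
    if not lo < hi:
        raise ValueError("value range must satisfy lo < hi")
    if palette not in ("gray", "jet"):
        raise ValueError(f"unknown palette {palette!r}")
    vals = np.asarray(values, dtype=float)
    scaled = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    scaled = np.nan_to_num(scaled, nan=0.0)
    cmap = matplotlib.colormaps[palette]
    rgb = cmap(scaled)[..., :3]
    bad = ~np.isfinite(vals)
    if valid is not None:
        bad |= ~np.asarray(valid, dtype=bool)
    rgb[bad] = 0.0
    return RenderedImage(rgb=rgb, source_kind=source_kind)


def build_moment_maps(
    normalized: NormalizedImage,
    window: EllipticalWindow | None = None,
) -> tuple[MomentMap, MomentMap]:
    """First- and fourth-order moment maps of a normalized image.

    Both expectations run over the same non-excluded liver pixels through
    the same window, so the two maps share one validity mask.
    """
    if window is None:
        window = EllipticalWindow(MOMENT_MAP_WINDOW_MM)
    m1 = local_moment(normalized, 1, window)
    m4 = local_moment(normalized, 4, window)
    assert np.array_equal(m1.valid, m4.valid)
    return m1, m4


def build_heat_map(
    m1_roi: MomentMap,
    m4_roi: MomentMap,
    bins: int = DEFAULT_HEATMAP_BINS,
    ranges: tuple[tuple[float, float], tuple[float, float]] = (M1_RANGE, M4_RANGE),
) -> MomentHeatMap:
    """Histogram the (M1, M4) pair of every valid pixel onto a 2-D grid.

    Out-of-range pairs are clipped into the edge bins so every valid pixel
    contributes exactly one count (count conservation).
    """
    if m1_roi.values.shape != m4_roi.values.shape:
        raise ValueError("moment maps must share a shape")
    valid = m1_roi.valid & m4_roi.valid
    x = m1_roi.values[valid]
    y = m4_roi.values[valid]
    (x_lo, x_hi), (y_lo, y_hi) = ranges
    x = np.clip(x, x_lo, x_hi)
    y = np.clip(y, y_lo, y_hi)
    counts, x_edges, y_edges = np.histogram2d(
        x, y, bins=bins, range=[[x_lo, x_hi], [y_lo, y_hi]]
    )
    counts = counts.astype(int)
    return MomentHeatMap(
        counts=counts, x_edges=x_edges, y_edges=y_edges, n_pixels=int(valid.sum())
    )


def render_heat_map(
    h: MomentHeatMap,
    out_size: tuple[int, int] | None = None,
    palette: str = "jet",
) -> RenderedImage:
    """Render counts as log(1 + count) intensity through a palette.

    The image axes follow display convention: M1 left-to-right, M4
    bottom-to-top (row 0 is the largest M4 bin).  The log compression keeps
    sparse off-mode bins visible next to the dominant speckle mode; it is
    monotone, so bin ordering by count is preserved in intensity.
    """
    log_counts = np.log1p(h.counts.astype(float))
    peak = log_counts.max()
    intensity = log_counts / peak if peak > 0 else log_counts
    # counts[i, j] indexes (x=M1 bin i, y=M4 bin j); transpose to rows=M4
    # and flip so M4 increases upward.
    img = np.flipud(intensity.T)
    if out_size is not None and img.shape != tuple(out_size):
        img = resize(img, out_size, order=1, anti_aliasing=False)
    cmap = matplotlib.colormaps[palette]
    rgb = cmap(np.clip(img, 0.0, 1.0))[..., :3]
    return RenderedImage(rgb=rgb, source_kind="heatmap")
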