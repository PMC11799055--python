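"""ROI enumeration, validity filtering, and per-case subsampling.

Square regions of interest (20 mm a side; 400 px at 50 um spacing) are slid
across each image on a regular grid with at least 4 mm between origins.  A
candidate ROI is kept only if fewer than 1% of its pixels are unusable
(outside the liver mask, excluded as non-speckle, or lacking moment-window
support).  Surviving candidates are pooled per case and randomly
subsampled to a per-case budget; all four image views of one ROI crop the
identical pixel window.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .envelope import MomentMap, NormalizedImage
from .parametric import (
    BMODE_RANGE,
    M1_RANGE,
    M4_RANGE,
    RenderedImage,
    build_heat_map,
    colorize,
    render_heat_map,
)

VIEW_KINDS = ("bmode", "m1_map", "m4_map", "heatmap")


@dataclass
class ROISpec:
    """Geometry and budget of ROI extraction."""

    size_mm: float = 20.0
    stride_mm: float = 4.0
    max_invalid_fraction: float = 0.01
    per_case_target: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_mm <= 0:
            raise ValueError("ROI size must be positive")
        if self.stride_mm < 4.0:
            raise ValueError("stride must be at least 4 mm")
        if not 0 <= self.max_invalid_fraction < 1:
            raise ValueError("max_invalid_fraction must lie in [0, 1)")
        if self.per_case_target < 1:
            raise ValueError("per-case target must be positive")

    def size_px(self, pixel_spacing_um: tuple[float, float]) -> tuple[int, int]:
        return (
            int(round(self.size_mm * 1000.0 / pixel_spacing_um[0])),
            int(round(self.size_mm * 1000.0 / pixel_spacing_um[1])),
        )

    def stride_px(self, pixel_spacing_um: tuple[float, float]) -> tuple[int, int]:
        return (
            max(1, int(round(self.stride_mm * 1000.0 / pixel_spacing_um[0]))),
            max(1, int(round(self.stride_mm * 1000.0 / pixel_spacing_um[1]))),
        )


@dataclass
class ROIRecord:
    """One extracted ROI with its co-located views."""

    case_id: str
    image_id: str
    origin_px: tuple[int, int]
    size_px: tuple[int, int]
    invalid_fraction: float
    grade_label: str
    views: dict = field(default_factory=dict)


def enumerate_rois(
    mask: np.ndarray,
    spec: ROISpec,
    invalid: np.ndarray | None = None,
    pixel_spacing_um: tuple[float, float] = (50.0, 50.0),
) -> list[tuple[tuple[int, int], float]]:
    """Candidate ROI origins on the stride grid, with invalid fractions.

    ``invalid`` marks pixels that may not count as usable ROI content
    (defaults to the complement of ``mask``); a candidate survives iff its
    window lies inside the image and its invalid fraction is below the
    spec's cap.  Ordering is row-major, hence deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if invalid is None:
        invalid = ~mask
    else:
        invalid = np.asarray(invalid, dtype=bool) | ~mask
    h, w = mask.shape
    sz = spec.size_px(pixel_spacing_um)
    st = spec.stride_px(pixel_spacing_um)
    if sz[0] > h or sz[1] > w:
        warnings.warn(f"ROI {sz} px exceeds image {mask.shape}; no candidates")
        return []
    # summed-area table gives each window's invalid count in O(1)
    sat = np.zeros((h + 1, w + 1), dtype=np.int64)
    sat[1:, 1:] = invalid.cumsum(0).cumsum(1)
    n_window = sz[0] * sz[1]
    out = []
    for r in range(0, h - sz[0] + 1, st[0]):
        for c in range(0, w - sz[1] + 1, st[1]):
            bad = int(
                sat[r + sz[0], c + sz[1]] - sat[r, c + sz[1]]
                - sat[r + sz[0], c] + sat[r, c]
            )
            frac = bad / n_window
            if frac < spec.max_invalid_fraction:
                out.append(((r, c), frac))
    return out


def _case_rng(seed: int, case_id: str) -> np.random.Generator:
    """Stable per-case stream so cases are independently reproducible."""
    h = hashlib.sha256(f"{seed}:{case_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big"))


def sample_case_rois(
    candidates: list[tuple[str, tuple[int, int], float]],
    spec: ROISpec,
    case_id: str,
    grade_label: str,
    size_px: tuple[int, int],
) -> list[ROIRecord]:
    """Uniform subsample (without replacement) of a case's candidate pool.

    Keeps min(per_case_target, available) ROIs; raises if the case has no
    usable candidate at all.
    """
    if not candidates:
        raise ValueError(f"case {case_id}: no valid ROI candidates")
    rng = _case_rng(spec.seed, case_id)
    k = min(spec.per_case_target, len(candidates))
    idx = rng.choice(len(candidates), size=k, replace=False)
    records = []
    for i in sorted(idx):
        image_id, origin, frac = candidates[i]
        records.append(
            ROIRecord(
                case_id=case_id,
                image_id=image_id,
                origin_px=origin,
                size_px=size_px,
                invalid_fraction=frac,
                grade_label=grade_label,
            )
        )
    return records


def export_roi_views(records, outdir) -> int:
    """Write each record's rendered views as 8-bit RGB PNGs.

    Files land in one directory per source kind,
    ``<outdir>/<kind>/<case>_<image>_<row>_<col>.png``.  Returns the
    number of files written.
    """
    import imageio.v3 as iio
    from pathlib import Path

    outdir = Path(outdir)
    n = 0
    for rec in records:
        for kind, view in rec.views.items():
            d = outdir / kind
            d.mkdir(parents=True, exist_ok=True)
            r, c = rec.origin_px
            name = f"{rec.case_id}_{rec.image_id}_{r}_{c}.png"
            iio.imwrite(d / name, (view.rgb * 255).astype(np.uint8))
            n += 1
    return n


def extract_roi_views(
    record: ROIRecord,
    normalized: NormalizedImage,
    m1: MomentMap,
    m4: MomentMap,
    input_size: tuple[int, int] = (224, 224),
    heatmap_bins: int | None = None,
) -> dict:
    """Render the four co-located views of one ROI at classifier input size.

    B-mode and moment-map views crop the shared pixel window, colorize
    (jet), and resize bilinearly; the heat-map view is histogrammed from
    the ROI's own (M1, M4) values and rendered directly at input size.
    """
    r, c = record.origin_px
    dr, dc = record.size_px
    sl = (slice(r, r + dr), slice(c, c + dc))
    prov = f"{record.case_id}/{record.image_id}@{r},{c}"

    def crop_map(mm: MomentMap) -> MomentMap:
        return MomentMap(mm.order_n, mm.values[sl], mm.valid[sl], mm.window)

    views = {}
    bmode = colorize(normalized.values[sl], BMODE_RANGE, "jet",
                     valid=normalized.valid[sl], source_kind="bmode")
    m1c = crop_map(m1)
    m4c = crop_map(m4)
    views["bmode"] = bmode
    views["m1_map"] = colorize(m1c.values, M1_RANGE, "jet",
                               valid=m1c.valid, source_kind="m1_map")
    views["m4_map"] = colorize(m4c.values, M4_RANGE, "jet",
                               valid=m4c.valid, source_kind="m4_map")
    bins = heatmap_bins if heatmap_bins is not None else input_size[0]
    heat = build_heat_map(m1c, m4c, bins=bins)
    views["heatmap"] = render_heat_map(heat, out_size=input_size)
    for kind, view in views.items():
        if view.rgb.shape[:2] != tuple(input_size):
            view.rgb = resize(view.rgb, input_size, order=1, anti_aliasing=True)
        view.rgb = view.rgb.astype(np.float32)
        view.provenance = prov
    record.views = views
    return views
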