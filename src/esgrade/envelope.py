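"""Windowed echo-envelope moments and iterative speckle normalization.

The echo envelope ``x`` of a B-mode image carries tissue texture in its
local statistics.  The central primitive is the local moment

    M_n(i, j) = E[x_k^n],

the mean of the n-th power of the envelope over an elliptical neighborhood
centered on pixel (i, j).  Dividing the envelope by the square root of the
local second-order moment removes depth- and gain-dependent brightness
(focus, TGC, attenuation) and leaves a dimensionless speckle field whose
first- and fourth-order moments characterize the shape of the amplitude
distribution: for fully developed (Rayleigh) speckle the normalized moments
are sqrt(pi)/2 ~ 0.886 and 2.0; pre-Rayleigh speckle pushes M1 down and M4
up, post-Rayleigh the reverse.

Bright non-speckle structures (vessel walls, ligaments) bias the moments,
so normalization is iterative: pixels brighter than ``threshold_factor``
times the local RMS amplitude are excluded, the second-order moment is
recomputed over the survivors, and the sweep repeats until no pixel is
newly excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gammaln

#: Default elliptical window (depth, lateral) full-axis extents in mm used
#: for the normalizing second-order moment.
NORMALIZATION_WINDOW_MM = (4.6, 10.8)

#: Smaller window used to form the first-/fourth-order moment maps.
MOMENT_MAP_WINDOW_MM = (3.0, 8.1)

#: Nominal (depth, lateral) resolution-cell size in mm of the imaging
#: configuration the window extents were derived from (6 x 8 resolution
#: cells for normalization, 4 x 6 for the maps).  Metadata only.
RESOLUTION_CELL_MM = (0.76, 1.35)

#: Exclusion threshold: amplitude > factor * sqrt(local M2) is non-speckle.
DEFAULT_THRESHOLD_FACTOR = 3.0

#: A moment estimate is marked invalid when fewer than this fraction of
#: the window's pixels are usable (inside the image, mask and valid set).
DEFAULT_MIN_VALID_FRACTION = 0.25


@dataclass
class EnvelopeImage:
    """A scan-converted envelope image with spacing metadata and liver mask.

    Parameters
    ----------
    amplitudes
        2-D grid of nonnegative envelope amplitudes (rows = depth).
    pixel_spacing_um
        (depth, lateral) pixel spacing in micrometres.
    liver_mask
        Boolean grid of the segmented liver region; ``None`` means the
        whole frame.
    """

    amplitudes: np.ndarray
    pixel_spacing_um: tuple[float, float] = (50.0, 50.0)
    liver_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be a 2-D grid")
        if np.any(self.amplitudes < 0):
            raise ValueError("envelope amplitudes must be nonnegative")
        if any(s <= 0 for s in self.pixel_spacing_um):
            raise ValueError("pixel spacing must be positive")
        if self.liver_mask is None:
            self.liver_mask = np.ones(self.amplitudes.shape, dtype=bool)
        else:
            self.liver_mask = np.asarray(self.liver_mask, dtype=bool)
            if self.liver_mask.shape != self.amplitudes.shape:
                raise ValueError("liver mask shape must match amplitudes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitudes.shape


@dataclass(frozen=True)
class EllipticalWindow:
    """Elliptical neighborhood specified by full axis extents in mm.

    ``extent_mm`` are full axis lengths (diameters), not semi-axes: the
    4.6 x 10.8 mm normalization window spans 6 x 8 resolution cells of
    0.76 x 1.35 mm.  Pixel membership for an offset (di, dj) from the
    center is (di/a)^2 + (dj/b)^2 <= 1 with semi-axes a, b in pixels.
    """

    extent_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError("window extents must be positive")

    def semi_axes_px(self, pixel_spacing_um: tuple[float, float]) -> tuple[float, float]:
        """Semi-axis lengths in pixels for the given (depth, lateral) spacing."""
        a = self.extent_mm[0] * 1000.0 / (2.0 * pixel_spacing_um[0])
        b = self.extent_mm[1] * 1000.0 / (2.0 * pixel_spacing_um[1])
        if a < 1 or b < 1:
            raise ValueError(
                f"window {self.extent_mm} mm is below one pixel semi-axis "
                f"at spacing {pixel_spacing_um} um"
            )
        return a, b

    def footprint(self, pixel_spacing_um: tuple[float, float]) -> np.ndarray:
        """Boolean membership stencil centered on the target pixel."""
        a, b = self.semi_axes_px(pixel_spacing_um)
        ra, rb = int(np.floor(a)), int(np.floor(b))
        di = np.arange(-ra, ra + 1)[:, None]
        dj = np.arange(-rb, rb + 1)[None, :]
        return (di / a) ** 2 + (dj / b) ** 2 <= 1.0


@dataclass
class MomentMap:
    """Per-pixel order-n moment over an elliptical window."""

    order_n: int
    values: np.ndarray
    valid: np.ndarray
    window: EllipticalWindow

    def mean(self) -> float:
        """Spatial mean of the moment over valid pixels."""
        if not self.valid.any():
            return float("nan")
        return float(self.values[self.valid].mean())


@dataclass
class NormalizedImage:
    """Envelope divided by the square root of its local second-order moment.

    ``values`` are defined (finite) only where ``valid`` is set: inside the
    liver mask, not excluded as non-speckle, and with enough window support
    for the local M2 estimate.
    """

    values: np.ndarray
    excluded: np.ndarray
    valid: np.ndarray
    iterations_run: int
    pixel_spacing_um: tuple[float, float]
    liver_mask: np.ndarray
    sqrt_m2: np.ndarray = field(repr=False, default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _as_grid(image) -> tuple[np.ndarray, tuple[float, float], np.ndarray]:
    """Pull (values, spacing, default validity) out of either image type."""
    if isinstance(image, EnvelopeImage):
        return image.amplitudes, image.pixel_spacing_um, image.liver_mask
    if isinstance(image, NormalizedImage):
        return image.values, image.pixel_spacing_um, image.valid
    raise TypeError(f"expected EnvelopeImage or NormalizedImage, got {type(image)!r}")


def local_moment(
    image,
    order_n: int,
    window: EllipticalWindow,
    valid_mask: np.ndarray | None = None,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> MomentMap:
    """Windowed order-n moment map M_n(i, j) = mean of x^n over the window.

    At each target pixel the expectation runs over window pixels that are
    inside the image and flagged in ``valid_mask`` (defaults to the image's
    own mask/validity).  The target pixel itself participates.  Targets
    whose window holds fewer than ``min_valid_fraction`` of its nominal
    pixel count are marked invalid.

    Implemented with FFT convolutions of x^n * valid and of the validity
    indicator; equivalent to the direct per-pixel double loop up to
    floating-point rounding.
    """
    if int(order_n) != order_n or order_n < 1:
        raise ValueError("moment order must be an integer >= 1")
    values, spacing, default_valid = _as_grid(image)
    valid = default_valid if valid_mask is None else np.asarray(valid_mask, dtype=bool)
    if valid.shape != values.shape:
        raise ValueError("valid_mask shape must match image shape")

    foot = window.footprint(spacing).astype(float)
    if foot.shape[0] > values.shape[0] or foot.shape[1] > values.shape[1]:
        raise ValueError(
            f"window footprint {foot.shape} exceeds image shape {values.shape}"
        )

    out_valid = np.zeros(values.shape, dtype=bool)
    out = np.full(values.shape, np.nan)
    if not valid.any():
        warnings.warn("valid_mask is empty; returning an all-invalid moment map")
        return MomentMap(int(order_n), out, out_valid, window)

    x = np.where(valid, values, 0.0)
    num = fftconvolve(x ** order_n, foot, mode="same")
    cnt = np.rint(fftconvolve(valid.astype(float), foot, mode="same"))
    min_count = max(1.0, min_valid_fraction * foot.sum())
    out_valid = cnt >= min_count
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_valid, num / np.maximum(cnt, 1.0), np.nan)
    # FFT round-off can leave tiny negatives on near-zero moments.
    out = np.where(out_valid, np.maximum(out, 0.0), np.nan)
    return MomentMap(int(order_n), out, out_valid, window)


def iterative_normalize(
    image: EnvelopeImage,
    window: EllipticalWindow | None = None,
    threshold_factor: float = DEFAULT_THRESHOLD_FACTOR,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    max_iterations: int = 100,
) -> NormalizedImage:
    """Normalize by sqrt(local M2), iteratively excluding non-speckle pixels.

    Each sweep computes the local second-order moment over currently
    usable liver pixels, then excludes every liver pixel whose amplitude
    exceeds ``threshold_factor * sqrt(local M2)``.  Sweeps are synchronous
    (all over-threshold pixels flagged against the same M2 map) and the
    exclusion set grows monotonically, so the loop terminates; it stops at
    the fixed point where no new pixel is excluded.

    Returns the normalized image ``x / sqrt(M2_final)`` with the exclusion
    mask and the number of sweeps run (the final, non-excluding sweep
    included).
    """
    if window is None:
        window = EllipticalWindow(NORMALIZATION_WINDOW_MM)
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    if not image.liver_mask.any():
        raise ValueError("liver mask is empty; nothing to normalize")

    amp = image.amplitudes
    excluded = np.zeros(amp.shape, dtype=bool)
    iterations = 0
    m2 = None
    for _ in range(max_iterations):
        iterations += 1
        usable = image.liver_mask & ~excluded
        if not usable.any():
            raise RuntimeError(
                f"all liver pixels excluded at threshold factor {threshold_factor}"
            )
        m2 = local_moment(image, 2, window, valid_mask=usable,
                          min_valid_fraction=min_valid_fraction)
        with np.errstate(invalid="ignore"):
            over = usable & m2.valid & (amp > threshold_factor * np.sqrt(m2.values))
        if not over.any():
            break
        excluded |= over
    else:
        warnings.warn(f"normalization did not converge in {max_iterations} sweeps")

    valid = image.liver_mask & ~excluded & m2.valid
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(valid, amp / np.sqrt(m2.values), np.nan)
    return NormalizedImage(
        values=values,
        excluded=excluded,
        valid=valid,
        iterations_run=iterations,
        pixel_spacing_um=image.pixel_spacing_um,
        liver_mask=image.liver_mask,
        sqrt_m2=np.sqrt(m2.values),
    )


def nakagami_normalized_moments(shape_m: float) -> tuple[float, float]:
    """Closed-form normalized moments of a Nakagami(m, Omega) amplitude.

    For X ~ Nakagami(m), E[X^n] = Gamma(m + n/2) / Gamma(m) * (Omega/m)^(n/2),
    so the scale-free moments are

        E[X] / sqrt(E[X^2])   = Gamma(m + 1/2) / (Gamma(m) sqrt(m))
        E[X^4] / E[X^2]^2     = (m + 1) / m.

    Rayleigh (m = 1) gives (sqrt(pi)/2, 2); the constant-amplitude limit
    m -> inf gives (1, 1).
    """
    if shape_m < 0.5:
        raise ValueError("Nakagami shape parameter must be >= 0.5")
    m1 = float(np.exp(gammaln(shape_m + 0.5) - gammaln(shape_m)) / np.sqrt(shape_m))
    m4 = float((shape_m + 1.0) / shape_m)
    return m1, m4
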