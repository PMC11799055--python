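"""Synthetic speckle cohorts with controllable envelope statistics.

Two generator modes:

``iid``
    Every pixel is an independent Nakagami(m, Omega) amplitude draw
    (Rayleigh when m = 1).  No spatial correlation — marginals are exact,
    so windowed-moment estimators can be checked against closed forms.

``convolved``
    A sparse field of zero-mean complex Gaussian scatterers is convolved
    with a Gaussian point-spread function and the envelope is the
    magnitude.  With many scatterers per PSF area the envelope approaches
    fully developed (Rayleigh) speckle with realistic spatial correlation.

The cohort generator maps steatosis grade to a Nakagami shape parameter so
that the normalized first-order moment rises and the fourth-order moment
falls with grade — the direction the envelope statistics of fatty livers
move in vivo.  The mapping itself is a synthetic stand-in: no generative
model links fat fraction to envelope statistics here, only the trend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .envelope import EnvelopeImage, EllipticalWindow, NORMALIZATION_WINDOW_MM, local_moment
from .grading import GradeThresholds, CaseRecord, GRADE_NAMES, grade_from_pdff

#: Default grade -> Nakagami shape, chosen so normalized M1 increases and
#: M4 decreases from G0 to G2-3 (pre-Rayleigh normal liver through
#: post-Rayleigh-leaning fatty liver).  Magnitudes are this package's own.
DEFAULT_GRADE_TO_M = {"G0": 0.7, "G1": 1.0, "G2-3": 1.5}

#: Default grade -> MRI-PDFF range (%), spanning each grade's threshold
#: interval with the clinically observed extremes (1.9% and 32.1%).
DEFAULT_PDFF_RANGES = {"G0": (1.9, 5.2), "G1": (5.2, 11.3), "G2-3": (11.3, 32.1)}


@dataclass
class SpeckleConfig:
    """Configuration of a single simulated envelope frame."""

    mode: str = "iid"
    shape_m: float = 1.0
    omega: float = 1.0
    image_size_mm: tuple[float, float] = (40.0, 40.0)
    pixel_spacing_um: tuple[float, float] = (50.0, 50.0)
    psf_sigma_mm: tuple[float, float] = (0.25, 0.45)
    scatterers_per_psf: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("iid", "convolved"):
            raise ValueError(f"unknown speckle mode {self.mode!r}")
        if self.mode == "iid" and self.shape_m < 0.5:
            raise ValueError("Nakagami shape_m must be >= 0.5 in iid mode")
        if self.omega <= 0:
            raise ValueError("omega (second moment) must be positive")
        if any(s <= 0 for s in self.image_size_mm) or any(
            s <= 0 for s in self.pixel_spacing_um
        ):
            raise ValueError("image size and pixel spacing must be positive")
        if self.mode == "convolved":
            if any(s <= 0 for s in self.psf_sigma_mm):
                raise ValueError("PSF sigma must be positive")
            if self.scatterers_per_psf <= 0:
                raise ValueError("scatterer density must be positive")

    @property
    def shape_px(self) -> tuple[int, int]:
        n = [
            int(round(self.image_size_mm[k] * 1000.0 / self.pixel_spacing_um[k]))
            for k in (0, 1)
        ]
        if any(v < 1 for v in n):
            raise ValueError("image smaller than one pixel")
        return n[0], n[1]


@dataclass
class CohortSpec:
    """A graded cohort: cases per grade, images per case, grade -> statistics."""

    n_cases_per_grade: int = 10
    images_per_case: int = 4
    grade_to_m: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_TO_M))
    pdff_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PDFF_RANGES))
    nonspeckle_rate: float = 0.001
    mode: str = "iid"
    image_size_mm: tuple[float, float] = (40.0, 40.0)
    pixel_spacing_um: tuple[float, float] = (50.0, 50.0)
    mask_margin: float = 0.04
    with_indicators: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grade_to_m:
            raise ValueError("grade_to_m must not be empty")
        if self.n_cases_per_grade < 1:
            raise ValueError("need at least one case per grade")
        if not 4 <= self.images_per_case <= 10:
            raise ValueError("images_per_case must lie in [4, 10]")
        if not 0 <= self.nonspeckle_rate <= 0.05:
            raise ValueError("nonspeckle_rate must lie in [0, 0.05]")
        thr = GradeThresholds()
        for g, (lo, hi) in self.pdff_ranges.items():
            if lo >= hi:
                raise ValueError(f"empty PDFF range for grade {g}")
            for p in (lo, min(hi, lo + 0.5 * (hi - lo))):
                if grade_from_pdff(p, thr) != g:
                    raise ValueError(
                        f"PDFF range {lo}-{hi} inconsistent with grade {g}"
                    )


def simulate_speckle_field(config: SpeckleConfig) -> EnvelopeImage:
    """Draw one envelope frame according to ``config`` (seeded, reproducible).

    iid mode: amplitudes are X = sqrt(G) with G ~ Gamma(m, Omega/m), the
    Nakagami(m, Omega) construction, so E[X^2] = Omega exactly in
    expectation.  convolved mode: complex scatterers smoothed by a Gaussian
    PSF; the output is rescaled analytically so E[|field|^2] = Omega.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape_px
    if config.mode == "iid":
        g = rng.gamma(shape=config.shape_m,
                      scale=config.omega / config.shape_m, size=shape)
        amp = np.sqrt(g)
    else:
        sig_px = (
            config.psf_sigma_mm[0] * 1000.0 / config.pixel_spacing_um[0],
            config.psf_sigma_mm[1] * 1000.0 / config.pixel_spacing_um[1],
        )
        psf_area_px = 2.0 * np.pi * sig_px[0] * sig_px[1]
        p = min(1.0, config.scatterers_per_psf / psf_area_px)
        # unit-amplitude, random-phase point scatterers: lower excess
        # kurtosis at a given density than Gaussian-amplitude ones, so the
        # Rayleigh limit is reached faster
        hit = rng.random(shape) < p
        theta = rng.uniform(0.0, 2.0 * np.pi, shape)
        re = gaussian_filter(np.where(hit, np.cos(theta), 0.0), sig_px, mode="constant")
        im = gaussian_filter(np.where(hit, np.sin(theta), 0.0), sig_px, mode="constant")
        # E[|field|^2] = p * sum(k^2), unit-integral Gaussian kernel:
        # sum(k^2) = 1/(4 pi sx sy)
        mean_sq = p / (4.0 * np.pi * sig_px[0] * sig_px[1])
        amp = np.hypot(re, im) * np.sqrt(config.omega / mean_sq)
    return EnvelopeImage(amplitudes=amp, pixel_spacing_um=config.pixel_spacing_um)


def inject_nonspeckle(
    image: EnvelopeImage,
    rate: float,
    amplitude_factor: float,
    seed: int,
    window: EllipticalWindow | None = None,
) -> tuple[EnvelopeImage, np.ndarray]:
    """Replace a random sparse set of liver pixels with bright outliers.

    Each liver pixel is independently chosen with probability ``rate`` and
    replaced by ``amplitude_factor`` times the local RMS amplitude, so that
    with a factor above the exclusion threshold every injected pixel is a
    guaranteed non-speckle outlier.  Returns the modified image and the
    (row, col) positions of injected pixels for ground-truth checks.
    """
    if not 0 <= rate <= 0.05:
        raise ValueError("injection rate must lie in [0, 0.05]")
    if amplitude_factor <= 3.0:
        raise ValueError("amplitude_factor must exceed the 3x exclusion threshold")
    if rate == 0:
        return (
            EnvelopeImage(image.amplitudes.copy(), image.pixel_spacing_um,
                          image.liver_mask.copy()),
            np.empty((0, 2), dtype=int),
        )
    rng = np.random.default_rng(seed)
    if window is None:
        window = EllipticalWindow(NORMALIZATION_WINDOW_MM)
    m2 = local_moment(image, 2, window)
    pick = image.liver_mask & m2.valid & (rng.random(image.shape) < rate)
    positions = np.argwhere(pick)
    amp = image.amplitudes.copy()
    amp[pick] = amplitude_factor * np.sqrt(m2.values[pick])
    return (
        EnvelopeImage(amp, image.pixel_spacing_um, image.liver_mask.copy()),
        positions,
    )


def make_liver_mask(shape: tuple[int, int], rng: np.random.Generator,
                    margin: float = 0.04, min_coverage: float = 0.5) -> np.ndarray:
    """Irregular convex blob covering at least ``min_coverage`` of the frame.

    The mask is the filled convex hull of random boundary points placed
    near the frame edges — a crude stand-in for a segmented liver region
    (the pipeline only needs a binary mask, not anatomy).
    """
    h, w = shape
    for attempt in range(32):
        n_pts = rng.integers(8, 14)
        theta = np.sort(rng.uniform(0, 2 * np.pi, n_pts))
        # radial jitter shrinks as attempts grow so coverage is guaranteed
        lo = 0.75 + 0.02 * attempt
        r = rng.uniform(min(lo, 0.98), 1.0, n_pts)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        ry = (0.5 - margin) * (h - 1)
        rx = (0.5 - margin) * (w - 1)
        rows = cy + r * ry * np.sin(theta)
        cols = cx + r * rx * np.cos(theta)
        rr, cc = draw_polygon(rows, cols, shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        if mask.mean() >= min_coverage:
            return mask
    raise RuntimeError("failed to draw a liver mask with required coverage")


def _synthetic_indicators(pdff: float, rng: np.random.Generator) -> dict:
    """Plausible CAP/ATI/elasticity values loosely tied to fat fraction.

    Linear trends with noise spanning the clinically reported ranges
    (CAP 142-358 dB/m, ATI 0.36-1.21 dB/cm/MHz, stiffness 3.4-46.1 kPa);
    synthetic stand-ins for testing indicator reports, not physiology.
    """
    cap = 150.0 + 6.0 * pdff + rng.normal(0.0, 25.0)
    ati = 0.40 + 0.02 * pdff + rng.normal(0.0, 0.12)
    elast = float(np.clip(rng.lognormal(np.log(8.0), 0.55), 3.4, 46.1))
    return {
        "cap_db_per_m": float(np.clip(cap, 142.0, 358.0)),
        "ati_db_cm_mhz": float(np.clip(ati, 0.36, 1.21)),
        "elasticity_kpa": elast,
    }


def simulate_cohort(
    spec: CohortSpec,
) -> list[tuple[CaseRecord, list[EnvelopeImage]]]:
    """Generate a graded cohort of cases, each with several masked frames.

    Per grade, ``n_cases_per_grade`` cases draw a PDFF uniformly from that
    grade's range and all of a case's frames share the grade's Nakagami
    shape.  Every frame gets its own convex liver mask.  Fully reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    thresholds = GradeThresholds()
    cohort: list[tuple[CaseRecord, list[EnvelopeImage]]] = []
    case_no = 0
    for grade in spec.grade_to_m:
        if grade not in spec.pdff_ranges:
            raise ValueError(f"no PDFF range for grade {grade}")
        lo, hi = spec.pdff_ranges[grade]
        for _ in range(spec.n_cases_per_grade):
            case_no += 1
            pdff = float(rng.uniform(lo, hi))
            assert grade_from_pdff(pdff, thresholds) == grade
            indicators = (
                _synthetic_indicators(pdff, rng) if spec.with_indicators else {}
            )
            record = CaseRecord(
                case_id=f"case{case_no:03d}",
                mri_pdff_percent=pdff,
                grade=grade,
                **indicators,
            )
            images = []
            for _ in range(spec.images_per_case):
                cfg = SpeckleConfig(
                    mode=spec.mode,
                    shape_m=spec.grade_to_m[grade],
                    omega=1.0,
                    image_size_mm=spec.image_size_mm,
                    pixel_spacing_um=spec.pixel_spacing_um,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                img = simulate_speckle_field(cfg)
                img.liver_mask[:] = make_liver_mask(
                    img.shape, rng, margin=spec.mask_margin
                )
                if spec.nonspeckle_rate > 0:
                    img, _ = inject_nonspeckle(
                        img, spec.nonspeckle_rate, amplitude_factor=5.0,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                images.append(img)
            cohort.append((record, images))
    return cohort


def write_cohort(cohort, outdir: str | Path, spec: CohortSpec | None = None) -> Path:
    """Write a cohort to disk: per-image .npz (+ JSON sidecar) and metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record, images in cohort:
        case_dir = outdir / record.case_id
        case_dir.mkdir(exist_ok=True)
        for i, img in enumerate(images):
            stem = case_dir / f"image{i:02d}"
            np.savez_compressed(
                stem.with_suffix(".npz"),
                amplitudes=img.amplitudes.astype(np.float32),
                liver_mask=img.liver_mask,
            )
            sidecar = {"pixel_spacing_um": list(img.pixel_spacing_um)}
            stem.with_suffix(".json").write_text(json.dumps(sidecar))
        rows.append(
            {
                "case_id": record.case_id,
                "grade": record.grade,
                "pdff_percent": record.mri_pdff_percent,
                "cap": record.cap_db_per_m,
                "ati": record.ati_db_cm_mhz,
                "elasticity": record.elasticity_kpa,
                "n_images": len(images),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    if spec is not None:
        meta = asdict(spec)
        meta["grade_to_m"] = {k: float(v) for k, v in spec.grade_to_m.items()}
        (outdir / "cohort_spec.json").write_text(json.dumps(meta, default=list))
    return outdir


def read_cohort(indir: str | Path) -> list[tuple[CaseRecord, list[EnvelopeImage]]]:
    """Inverse of :func:`write_cohort`."""
    indir = Path(indir)
    table = pd.read_csv(indir / "cohort.csv")
    cohort = []
    for _, row in table.iterrows():
        record = CaseRecord(
            case_id=row["case_id"],
            mri_pdff_percent=float(row["pdff_percent"]),
            grade=row["grade"],
            cap_db_per_m=None if pd.isna(row["cap"]) else float(row["cap"]),
            ati_db_cm_mhz=None if pd.isna(row["ati"]) else float(row["ati"]),
            elasticity_kpa=None if pd.isna(row["elasticity"]) else float(row["elasticity"]),
        )
        images = []
        for stem in sorted((indir / row["case_id"]).glob("image*.npz")):
            data = np.load(stem)
            sidecar = json.loads(stem.with_suffix(".json").read_text())
            images.append(
                EnvelopeImage(
                    amplitudes=data["amplitudes"].astype(float),
                    pixel_spacing_um=tuple(sidecar["pixel_spacing_um"]),
                    liver_mask=data["liver_mask"],
                )
            )
        cohort.append((record, images))
    return cohort
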