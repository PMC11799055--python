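"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own fast paths: moments
are recomputed with naive per-pixel double loops, and distributional
expectations come from closed forms via scipy's incomplete gamma
functions, so agreement is a real cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy.special import gammainc, gammaln

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from esgrade import (
    CohortSpec,
    ROISpec,
    SpeckleConfig,
    simulate_cohort,
    simulate_speckle_field,
)
from esgrade.pipeline import process_cohort


# --------------------------------------------------------------------------
# oracles

def naive_local_moment(values, order_n, footprint, valid, min_valid_fraction=0.25):
    """Direct double-loop windowed moment; the reference for the FFT path."""
    h, w = values.shape
    fh, fw = footprint.shape
    ra, rb = fh // 2, fw // 2
    out = np.full((h, w), np.nan)
    ok = np.zeros((h, w), dtype=bool)
    min_count = max(1.0, min_valid_fraction * footprint.sum())
    for i in range(h):
        for j in range(w):
            acc, cnt = 0.0, 0
            for di in range(-ra, ra + 1):
                for dj in range(-rb, rb + 1):
                    if not footprint[di + ra, dj + rb]:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and valid[ii, jj]:
                        acc += values[ii, jj] ** order_n
                        cnt += 1
            if cnt >= min_count:
                out[i, j] = acc / cnt
                ok[i, j] = True
    return out, ok


def truncated_nakagami_normalized_moments(shape_m: float, factor: float = 3.0):
    """Normalized M1/M4 of a Nakagami amplitude after iterated 3x-RMS
    truncation, at the fixed point t = factor * sqrt(M2 of survivors).

    E[X^n 1{X<=t}] for Nakagami(m, 1) is m^{-n/2} Gamma(m+n/2)/Gamma(m)
    times the regularized lower incomplete gamma P(m+n/2, m t^2).  This is
    what the iterative normalization converges to on an iid field.
    """

    def trunc(n, t):
        a = shape_m + n / 2.0
        return (
            np.exp(gammaln(a) - gammaln(shape_m))
            * shape_m ** (-n / 2.0)
            * gammainc(a, shape_m * t * t)
        )

    t = factor
    for _ in range(200):
        p_keep = gammainc(shape_m, shape_m * t * t)
        m2 = trunc(2, t) / p_keep
        t_next = factor * np.sqrt(m2)
        if abs(t_next - t) < 1e-13:
            t = t_next
            break
        t = t_next
    p_keep = gammainc(shape_m, shape_m * t * t)
    m1 = trunc(1, t) / p_keep
    m2 = trunc(2, t) / p_keep
    m4 = trunc(4, t) / p_keep
    return m1 / np.sqrt(m2), m4 / m2**2, 1.0 - p_keep


# --------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def rayleigh_field_512():
    """512x512 iid Rayleigh (Nakagami m=1) envelope, unit second moment."""
    cfg = SpeckleConfig(
        mode="iid", shape_m=1.0, omega=1.0,
        image_size_mm=(25.6, 25.6), pixel_spacing_um=(50.0, 50.0), seed=7,
    )
    return simulate_speckle_field(cfg)


@pytest.fixture(scope="session")
def small_cohort_records():
    """A processed 30-case cohort at reduced scale (200 um pixels, 60 mm
    frames, 64 ROIs/case) shared by the training-dependent tests."""
    spec = CohortSpec(
        n_cases_per_grade=10, images_per_case=4,
        image_size_mm=(60.0, 60.0), pixel_spacing_um=(200.0, 200.0), seed=11,
    )
    cohort = simulate_cohort(spec)
    roi_spec = ROISpec(per_case_target=64, seed=12)
    records, summaries = process_cohort(cohort, roi_spec, input_size=(32, 32))
    return {
        "records": records,
        "cases": [c for c, _ in cohort],
        "summaries": summaries,
    }
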