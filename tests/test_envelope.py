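"""Windowed moments, iterative normalization, and Nakagami closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esgrade import (
    EllipticalWindow,
    EnvelopeImage,
    SpeckleConfig,
    inject_nonspeckle,
    iterative_normalize,
    local_moment,
    nakagami_normalized_moments,
    simulate_speckle_field,
)
from esgrade.envelope import NORMALIZATION_WINDOW_MM, RESOLUTION_CELL_MM

from conftest import naive_local_moment


SMALL_WINDOW = EllipticalWindow((0.6, 1.0))  # 12 x 20 px at 50 um


class TestEllipticalWindow:
    def test_semi_axes_follow_full_extent_reading(self):
        # 4.6 x 10.8 mm at 50 um spacing: semi-axes 46 x 108 px
        w = EllipticalWindow(NORMALIZATION_WINDOW_MM)
        assert w.semi_axes_px((50.0, 50.0)) == (46.0, 108.0)

    def test_extents_are_integer_multiples_of_resolution(self):
        # normalization window = 6 x 8 resolution cells (lateral exact,
        # depth rounded to 0.1 mm in the stated extent)
        assert NORMALIZATION_WINDOW_MM[1] / RESOLUTION_CELL_MM[1] == pytest.approx(8)
        assert NORMALIZATION_WINDOW_MM[0] / RESOLUTION_CELL_MM[0] == pytest.approx(6, abs=0.06)

    def test_footprint_is_elliptical_and_symmetric(self):
        foot = SMALL_WINDOW.footprint((50.0, 50.0))
        assert foot.shape == (13, 21)
        assert foot[6, 0] and foot[6, 20] and foot[0, 10] and foot[12, 10]
        assert not foot[0, 0]
        assert np.array_equal(foot, foot[::-1, ::-1])

    def test_subpixel_window_rejected(self):
        with pytest.raises(ValueError):
            EllipticalWindow((0.05, 0.05)).footprint((50.0, 50.0))


class TestLocalMoment:
    @given(
        c=st.floats(0.1, 5.0),
        n=st.integers(1, 4),
    )
    @settings(max_examples=20, deadline=None)
    def test_constant_image_gives_power_of_constant(self, c, n):
        img = EnvelopeImage(np.full((40, 40), c))
        mm = local_moment(img, n, SMALL_WINDOW)
        assert np.allclose(mm.values[mm.valid], c**n, rtol=1e-9)
        assert mm.valid.all()

    def test_rayleigh_second_moment_map_mean(self, rayleigh_field_512):
        # E[X^2] = omega = 1 for the generated field
        mm = local_moment(rayleigh_field_512, 2, EllipticalWindow(NORMALIZATION_WINDOW_MM))
        assert mm.mean() == pytest.approx(1.0, rel=0.02)

    def test_single_valid_pixel_dominates_its_window(self):
        img = EnvelopeImage(np.arange(1.0, 577.0).reshape(24, 24))
        valid = np.zeros((24, 24), dtype=bool)
        valid[10, 10] = True
        v = img.amplitudes[10, 10]
        mm = local_moment(img, 4, SMALL_WINDOW, valid_mask=valid,
                          min_valid_fraction=0.0)
        assert mm.values[10, 10] == pytest.approx(v**4)
        # neighbors inside the window see only that pixel too
        assert mm.values[10, 12] == pytest.approx(v**4)

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.exponential(1.0, (64, 64))
        valid = rng.random((64, 64)) > 0.2
        img = EnvelopeImage(values, liver_mask=valid)
        for order in (1, 2, 4):
            mm = local_moment(img, order, SMALL_WINDOW)
            ref, ref_ok = naive_local_moment(
                values, order, SMALL_WINDOW.footprint((50.0, 50.0)), valid
            )
            assert np.array_equal(mm.valid, ref_ok)
            assert np.allclose(mm.values[mm.valid], ref[ref_ok], atol=1e-8, rtol=1e-9)

    def test_rejects_bad_order_and_empty_mask(self):
        img = EnvelopeImage(np.ones((40, 40)))
        with pytest.raises(ValueError):
            local_moment(img, 0, SMALL_WINDOW)
        with pytest.warns(UserWarning):
            mm = local_moment(img, 2, SMALL_WINDOW, valid_mask=np.zeros((40, 40), bool))
        assert not mm.valid.any()


class TestIterativeNormalize:
    def test_constant_image_normalizes_to_one_without_exclusion(self):
        img = EnvelopeImage(np.full((60, 60), 7.3))
        out = iterative_normalize(img, SMALL_WINDOW)
        assert out.iterations_run == 1
        assert not out.excluded.any()
        assert np.allclose(out.values[out.valid], 1.0)

    def test_rayleigh_exclusion_fraction_matches_tail_probability(
        self, rayleigh_field_512
    ):
        # P(X > 3 sqrt(E[X^2])) = exp(-9) for Rayleigh; iterated exclusion
        # with an estimated local M2 stays within 3 binomial SDs of it
        out = iterative_normalize(rayleigh_field_512)
        n = rayleigh_field_512.amplitudes.size
        p = np.exp(-9.0)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(out.excluded.sum() - n * p) <= 3 * sd

    def test_injected_outliers_are_fully_excluded_and_m1_robust(self):
        cfg = SpeckleConfig(mode="iid", shape_m=1.0, omega=1.0,
                            image_size_mm=(12.8, 12.8), seed=21)
        clean = simulate_speckle_field(cfg)
        dirty, pos = inject_nonspeckle(clean, rate=0.002, amplitude_factor=5.0,
                                       seed=22)
        assert len(pos) > 0
        out_clean = iterative_normalize(clean)
        out_dirty = iterative_normalize(dirty)
        assert out_dirty.excluded[pos[:, 0], pos[:, 1]].all()
        m1_clean = out_clean.values[out_clean.valid].mean()
        m1_dirty = out_dirty.values[out_dirty.valid].mean()
        assert abs(m1_clean - m1_dirty) < 0.005

    def test_idempotence_on_converged_image(self, rayleigh_field_512):
        first = iterative_normalize(rayleigh_field_512)
        survivors = EnvelopeImage(
            np.where(first.excluded, 0.0, rayleigh_field_512.amplitudes),
            rayleigh_field_512.pixel_spacing_um,
            rayleigh_field_512.liver_mask & ~first.excluded,
        )
        second = iterative_normalize(survivors)
        assert second.iterations_run == 1
        assert not second.excluded[survivors.liver_mask].any()

    def test_self_normalization_unit_second_moment(self, rayleigh_field_512):
        out = iterative_normalize(rayleigh_field_512)
        m2 = (out.values[out.valid] ** 2).mean()
        assert m2 == pytest.approx(1.0, rel=0.02)

    def test_window_larger_than_image_rejected(self):
        img = EnvelopeImage(np.ones((30, 30)))
        with pytest.raises(ValueError):
            iterative_normalize(img, EllipticalWindow((4.6, 10.8)))

    def test_empty_mask_rejected(self):
        img = EnvelopeImage(np.ones((40, 40)),
                            liver_mask=np.zeros((40, 40), bool))
        with pytest.raises(ValueError):
            iterative_normalize(img, SMALL_WINDOW)


class TestNakagamiClosedForms:
    def test_rayleigh_values(self):
        m1, m4 = nakagami_normalized_moments(1.0)
        assert m1 == pytest.approx(np.sqrt(np.pi) / 2, abs=1e-12)
        assert m4 == pytest.approx(2.0)

    def test_m2_values(self):
        from scipy.special import gamma
        m1, m4 = nakagami_normalized_moments(2.0)
        assert m1 == pytest.approx(gamma(2.5) / (gamma(2.0) * np.sqrt(2.0)))
        assert m4 == pytest.approx(1.5)

    def test_constant_amplitude_limit(self):
        m1, m4 = nakagami_normalized_moments(1e7)
        assert m1 == pytest.approx(1.0, abs=1e-6)
        assert m4 == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(3)
        for m in (0.6, 1.0, 2.0):
            x = np.sqrt(rng.gamma(m, 1.0 / m, size=1_000_000))
            m1_ref, m4_ref = nakagami_normalized_moments(m)
            assert x.mean() / np.sqrt((x**2).mean()) == pytest.approx(m1_ref, abs=0.002)
            assert (x**4).mean() / (x**2).mean() ** 2 == pytest.approx(m4_ref, rel=0.01)

    def test_below_half_rejected(self):
        with pytest.raises(ValueError):
            nakagami_normalized_moments(0.3)
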