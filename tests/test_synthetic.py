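"""Speckle generator statistics, cohort structure, and reproducibility."""

import numpy as np
import pytest
from scipy import stats

from esgrade import (
    CohortSpec,
    SpeckleConfig,
    inject_nonspeckle,
    nakagami_normalized_moments,
    simulate_cohort,
    simulate_speckle_field,
)
from esgrade.envelope import EllipticalWindow, local_moment
from esgrade.synthetic import make_liver_mask, read_cohort, write_cohort


class TestIidMode:
    def test_second_moment_equals_omega(self):
        cfg = SpeckleConfig(mode="iid", shape_m=1.0, omega=1.0,
                            image_size_mm=(25.6, 25.6), seed=7)
        a = simulate_speckle_field(cfg).amplitudes
        # Omega is E[X^2]; X^2 is exponential with SD = omega
        se = 1.0 / np.sqrt(a.size)
        assert abs((a**2).mean() - 1.0) <= 2 * se

    def test_rayleigh_normalized_first_moment(self):
        cfg = SpeckleConfig(mode="iid", shape_m=1.0, omega=1.0,
                            image_size_mm=(25.6, 25.6), seed=8)
        a = simulate_speckle_field(cfg).amplitudes
        assert a.mean() / np.sqrt((a**2).mean()) == pytest.approx(
            np.sqrt(np.pi) / 2, abs=0.01
        )

    def test_nakagami_fourth_moment_ratio(self):
        cfg = SpeckleConfig(mode="iid", shape_m=2.0, omega=1.0,
                            image_size_mm=(25.6, 25.6), seed=9)
        a = simulate_speckle_field(cfg).amplitudes
        assert (a**4).mean() / (a**2).mean() ** 2 == pytest.approx(1.5, abs=0.02)

    @pytest.mark.parametrize("m", [0.6, 1.0, 1.5, 2.0])
    def test_marginals_pass_ks_against_nakagami(self, m):
        cfg = SpeckleConfig(mode="iid", shape_m=m, omega=1.0,
                            image_size_mm=(20.0, 20.0),
                            pixel_spacing_um=(62.5, 62.5), seed=int(m * 10))
        a = simulate_speckle_field(cfg).amplitudes.ravel()[:100_000]
        # scipy's standard nakagami has E[X^2] = 1, i.e. scale = sqrt(omega)
        res = stats.kstest(a, stats.nakagami(m).cdf)
        assert res.pvalue > 0.01

    def test_seed_determinism(self):
        cfg = SpeckleConfig(mode="iid", shape_m=1.0, image_size_mm=(5, 5), seed=3)
        a = simulate_speckle_field(cfg).amplitudes
        b = simulate_speckle_field(cfg).amplitudes
        assert np.array_equal(a, b)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SpeckleConfig(mode="iid", shape_m=0.4)
        with pytest.raises(ValueError):
            SpeckleConfig(image_size_mm=(0, 10))
        with pytest.raises(ValueError):
            SpeckleConfig(omega=-1.0)


class TestConvolvedMode:
    def test_dense_scatterers_reach_rayleigh_limit(self):
        # >= 10 scatterers per PSF area: normalized M4 within 5% of 2.0
        m4s = []
        for seed in range(8):
            cfg = SpeckleConfig(
                mode="convolved", omega=1.0, image_size_mm=(51.2, 51.2),
                psf_sigma_mm=(0.25, 0.45), scatterers_per_psf=10.0, seed=seed,
            )
            a = simulate_speckle_field(cfg).amplitudes
            m4s.append((a**4).mean() / (a**2).mean() ** 2)
        assert abs(np.mean(m4s) - 2.0) < 0.1

    def test_omega_scaling(self):
        cfg = SpeckleConfig(mode="convolved", omega=3.0, image_size_mm=(25.6, 25.6),
                            scatterers_per_psf=20.0, seed=4)
        a = simulate_speckle_field(cfg).amplitudes
        assert (a**2).mean() == pytest.approx(3.0, rel=0.1)

    def test_spatial_correlation_present(self):
        cfg = SpeckleConfig(mode="convolved", image_size_mm=(12.8, 12.8), seed=5)
        a = simulate_speckle_field(cfg).amplitudes
        x = a - a.mean()
        lag1 = (x[:, :-1] * x[:, 1:]).mean() / (x**2).mean()
        assert lag1 > 0.5  # neighboring pixels share the PSF


class TestInjectNonspeckle:
    def test_zero_rate_is_identity(self):
        img = simulate_speckle_field(SpeckleConfig(image_size_mm=(6.4, 6.4), seed=1))
        out, pos = inject_nonspeckle(img, 0.0, 5.0, seed=2)
        assert np.array_equal(out.amplitudes, img.amplitudes)
        assert len(pos) == 0

    def test_injected_count_is_binomial(self):
        img = simulate_speckle_field(
            SpeckleConfig(image_size_mm=(25.6, 25.6), seed=13)
        )
        _, pos = inject_nonspeckle(img, 0.001, 5.0, seed=14)
        n = img.amplitudes.size
        sd = np.sqrt(n * 0.001 * 0.999)
        assert abs(len(pos) - n * 0.001) <= 3 * sd

    def test_injected_pixels_exceed_threshold(self):
        img = simulate_speckle_field(
            SpeckleConfig(image_size_mm=(12.8, 12.8), seed=15)
        )
        out, pos = inject_nonspeckle(img, 0.002, 5.0, seed=16)
        m2 = local_moment(out, 2, EllipticalWindow((4.6, 10.8)))
        vals = out.amplitudes[pos[:, 0], pos[:, 1]]
        thr = 3.0 * np.sqrt(m2.values[pos[:, 0], pos[:, 1]])
        assert (vals > thr).all()

    def test_rate_out_of_range_rejected(self):
        img = simulate_speckle_field(SpeckleConfig(image_size_mm=(6.4, 6.4), seed=1))
        with pytest.raises(ValueError):
            inject_nonspeckle(img, 0.2, 5.0, seed=0)
        with pytest.raises(ValueError):
            inject_nonspeckle(img, 0.01, 2.0, seed=0)


TINY_COHORT = dict(
    n_cases_per_grade=10, images_per_case=4,
    image_size_mm=(12.0, 12.0), pixel_spacing_um=(200.0, 200.0), seed=42,
)


class TestCohort:
    def test_cohort_shape_ten_cases_per_grade(self):
        cohort = simulate_cohort(CohortSpec(**TINY_COHORT))
        assert len(cohort) == 30
        from collections import Counter
        counts = Counter(rec.grade for rec, _ in cohort)
        assert counts == {"G0": 10, "G1": 10, "G2-3": 10}
        for rec, images in cohort:
            assert len(images) == 4
            for img in images:
                assert img.liver_mask.mean() >= 0.5

    def test_same_seed_reproduces_cohort_exactly(self):
        a = simulate_cohort(CohortSpec(**TINY_COHORT))
        b = simulate_cohort(CohortSpec(**TINY_COHORT))
        for (ra, ia), (rb, ib) in zip(a, b):
            assert ra == rb
            for x, y in zip(ia, ib):
                assert np.array_equal(x.amplitudes, y.amplitudes)
                assert np.array_equal(x.liver_mask, y.liver_mask)

    def test_moment_trends_follow_grade_to_m(self):
        # increasing Nakagami shape across grades: cohort-mean normalized
        # M1 must rise and M4 fall, per the closed forms
        cohort = simulate_cohort(CohortSpec(**TINY_COHORT))
        by_grade = {}
        for rec, images in cohort:
            a = np.concatenate([img.amplitudes.ravel() for img in images])
            m2 = (a**2).mean()
            by_grade.setdefault(rec.grade, []).append(
                (a.mean() / np.sqrt(m2), (a**4).mean() / m2**2)
            )
        m1s = [np.mean([v[0] for v in by_grade[g]]) for g in ("G0", "G1", "G2-3")]
        m4s = [np.mean([v[1] for v in by_grade[g]]) for g in ("G0", "G1", "G2-3")]
        assert m1s[0] < m1s[1] < m1s[2]
        assert m4s[0] > m4s[1] > m4s[2]
        expected = [nakagami_normalized_moments(m)[0] for m in (0.7, 1.0, 1.5)]
        assert np.allclose(m1s, expected, atol=0.01)

    def test_pdff_consistent_with_grade(self):
        from esgrade import grade_from_pdff
        cohort = simulate_cohort(CohortSpec(**TINY_COHORT))
        for rec, _ in cohort:
            assert grade_from_pdff(rec.mri_pdff_percent) == rec.grade

    def test_empty_grade_map_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(grade_to_m={})

    def test_images_per_case_bounds(self):
        with pytest.raises(ValueError):
            CohortSpec(images_per_case=3)
        with pytest.raises(ValueError):
            CohortSpec(images_per_case=11)

    def test_roundtrip_through_disk(self, tmp_path):
        spec = CohortSpec(n_cases_per_grade=4, **{
            k: v for k, v in TINY_COHORT.items() if k != "n_cases_per_grade"
        })
        cohort = simulate_cohort(spec)
        write_cohort(cohort, tmp_path / "c", spec)
        back = read_cohort(tmp_path / "c")
        assert len(back) == len(cohort)
        for (ra, ia), (rb, ib) in zip(cohort, back):
            assert ra.case_id == rb.case_id
            assert ra.grade == rb.grade
            assert ra.mri_pdff_percent == pytest.approx(rb.mri_pdff_percent)
            for x, y in zip(ia, ib):
                assert np.allclose(x.amplitudes, y.amplitudes, rtol=1e-6)


def test_liver_mask_is_convex_blob():
    rng = np.random.default_rng(0)
    mask = make_liver_mask((120, 120), rng)
    assert 0.5 <= mask.mean() <= 1.0
    # convexity: every row's filled span is contiguous
    for row in mask:
        idx = np.flatnonzero(row)
        if len(idx):
            assert len(idx) == idx[-1] - idx[0] + 1
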