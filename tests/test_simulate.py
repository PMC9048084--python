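"""Synthetic-delivery generator: injectors, determinism, noise model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from portalwatch.simulate import (
    DeliverySpec,
    ErrorSpec,
    PatientCohortSpec,
    PhantomSpec,
    ValidationError,
    cohort_cases,
    inject_air_gap,
    inject_aperture_opening,
    inject_aperture_shift,
    inject_mu_error,
    load_delivery,
    save_delivery,
    simulate_delivery,
)

from .conftest import make_spec


class TestErrorSpec:
    @pytest.mark.parametrize(
        "kind,magnitude,ranking",
        [
            ("none", 0, 0),
            ("mu_increase", 2, 1),
            ("mu_increase", 10, 5),
            ("mlc_retraction", 6, 3),
            ("mlc_shift", 8, 4),
            ("air_gap", 10, 1),
            ("air_gap", 50, 5),
        ],
    )
    def test_ranking_follows_magnitude(self, kind, magnitude, ranking):
        assert ErrorSpec(kind, magnitude).ranking == ranking

    @pytest.mark.parametrize(
        "kind,magnitude",
        [("mu_increase", 3), ("mlc_shift", 12), ("air_gap", 15), ("none", 2)],
    )
    def test_invalid_magnitudes_rejected(self, kind, magnitude):
        with pytest.raises(ValidationError):
            ErrorSpec(kind, magnitude)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            ErrorSpec("gantry_wobble", 2)


class TestInjectors:
    def test_mu_zero_is_identity(self, rng):
        img = rng.uniform(0, 10, (8, 8))
        np.testing.assert_array_equal(inject_mu_error(img, 0), img)

    def test_mu_scales_pixels(self):
        img = np.full((4, 4), 100.0)
        assert inject_mu_error(img, 10)[0, 0] == pytest.approx(110.0)

    @given(pct=st.floats(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_mu_preserves_mean_ratio(self, pct):
        img = np.arange(1, 17, dtype=float).reshape(4, 4)
        out = inject_mu_error(img, pct)
        assert out.mean() / img.mean() == pytest.approx(1 + pct / 100)

    def test_mu_negative_rejected(self):
        with pytest.raises(ValidationError):
            inject_mu_error(np.ones((2, 2)), -1)

    def test_opening_zero_is_identity(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[3:7, 5:25] = True
        np.testing.assert_array_equal(inject_aperture_opening(mask, 0), mask)

    def test_opening_widens_rectangle_per_side(self):
        # a 20-pixel-wide opening dilated by 4 mm at 1 mm/pixel -> 28 pixels
        mask = np.zeros((10, 40), dtype=bool)
        mask[3:7, 10:30] = True
        out = inject_aperture_opening(mask, 4, pitch_mm=1.0)
        assert out[4].sum() == 28
        assert out[0].sum() == 0  # closed leaves stay closed

    @given(mm=st.sampled_from([0, 2, 4, 6, 8, 10]), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_opening_never_shrinks(self, mm, seed):
        r = np.random.default_rng(seed)
        mask = r.random((12, 24)) > 0.6
        out = inject_aperture_opening(mask, mm)
        assert out.sum() >= mask.sum()
        assert (out | mask).sum() == out.sum()  # superset

    def test_shift_moves_centroid(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[5:15, 10:20] = True
        out = inject_aperture_shift(mask, 4, pitch_mm=1.0)
        cx_before = np.argwhere(mask)[:, 1].mean()
        cx_after = np.argwhere(out)[:, 1].mean()
        assert cx_after - cx_before == pytest.approx(4.0)

    def test_shift_composes(self):
        mask = np.zeros((10, 60), dtype=bool)
        mask[2:8, 10:20] = True
        twice = inject_aperture_shift(inject_aperture_shift(mask, 4), 4)
        once = inject_aperture_shift(mask, 8)
        np.testing.assert_array_equal(twice, once)

    def test_air_gap_zero_is_identity(self, rng):
        img = rng.uniform(1, 2, (64, 64))
        out = inject_air_gap(img, 0, geometry=None)
        np.testing.assert_array_equal(out, img)

    def test_air_gap_band_boost_closed_form(self, small_geometry):
        # mu=0.005/mm, width 20 mm: in-band pixel 100 -> 100*e^0.1
        n = small_geometry.n_pixels
        img = np.full((n, n), 100.0)
        out = inject_air_gap(img, 20, geometry=small_geometry, mu_per_mm=0.005)
        y = small_geometry.axis_mm()
        in_band = np.abs(y - 30.0) <= 10.0
        assert out[in_band, 0] == pytest.approx(100 * np.exp(0.1))
        np.testing.assert_array_equal(out[~in_band, :], img[~in_band, :])

    def test_air_gap_boost_monotone_in_width(self, small_geometry):
        n = small_geometry.n_pixels
        img = np.ones((n, n))
        ratios = []
        for w in (10, 20, 30, 40, 50):
            out = inject_air_gap(img, w, geometry=small_geometry)
            ratios.append(out.max() / img.max())
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_air_gap_wider_than_phantom_rejected(self):
        with pytest.raises(ValidationError):
            inject_air_gap(np.ones((16, 16)), 250, PhantomSpec(height_mm=200))

    @pytest.mark.parametrize("mm", [2, 6])
    def test_injectors_commute_with_scaling(self, mm, small_geometry, rng):
        img = rng.uniform(0.5, 2.0, (small_geometry.n_pixels,) * 2)
        for f in (
            lambda a: inject_mu_error(a, mm),
            lambda a: inject_air_gap(a, 10 * mm, geometry=small_geometry),
        ):
            np.testing.assert_allclose(f(3.0 * img), 3.0 * f(img), rtol=1e-12)


class TestSimulateDelivery:
    def test_noiseless_error_free_measured_equals_predicted(self, small_geometry):
        pairs = simulate_delivery(make_spec(), geometry=small_geometry)
        assert len(pairs) == 30
        for p in pairs:
            np.testing.assert_array_equal(p.measured, p.predicted)
            assert (p.predicted > 0).any()

    def test_seeded_runs_are_bit_identical(self, small_geometry):
        spec = make_spec(noise_sd=0.01, error=ErrorSpec("air_gap", 20))
        a = simulate_delivery(spec, geometry=small_geometry)
        b = simulate_delivery(spec, geometry=small_geometry)
        for x, y in zip(a, b):
            assert x.measured.tobytes() == y.measured.tobytes()
            assert x.predicted.tobytes() == y.predicted.tobytes()

    def test_mu_error_scales_every_pixel(self, small_geometry, mu10_spec):
        pairs = simulate_delivery(mu10_spec, geometry=small_geometry)
        for p in pairs:
            np.testing.assert_allclose(p.measured, 1.10 * p.predicted, rtol=1e-12)

    def test_different_seeds_differ(self, small_geometry):
        a = simulate_delivery(make_spec(noise_sd=0.01, seed=1), geometry=small_geometry)
        b = simulate_delivery(make_spec(noise_sd=0.01, seed=2), geometry=small_geometry)
        assert not np.array_equal(a[0].measured, b[0].measured)

    def test_predicted_independent_of_noise_and_error(self, small_geometry):
        a = simulate_delivery(make_spec(), geometry=small_geometry)
        b = simulate_delivery(
            make_spec(noise_sd=0.01, error=ErrorSpec("mlc_shift", 4), seed=99),
            geometry=small_geometry,
        )
        np.testing.assert_array_equal(a[10].predicted, b[10].predicted)

    def test_too_short_delivery_rejected(self):
        with pytest.raises(ValidationError):
            DeliverySpec(patient_id="P1", n_segments=10)


class TestCohort:
    def test_default_design_counts(self):
        cohort = PatientCohortSpec()
        cases = cohort_cases(cohort)
        assert len(cases) == 78  # 3*(1+20) + 3*(1+4)
        errors = [c for c in cases if c[1].kind != "none"]
        assert len(errors) == 72
        per_patient = {p: 0 for p in cohort.patients}
        for pid, e in errors:
            per_patient[pid] += 1
        assert [per_patient[p] for p in cohort.full_error_patients] == [20, 20, 20]
        assert [per_patient[p] for p in cohort.partial_error_patients] == [4, 4, 4]

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValidationError):
            PatientCohortSpec(("A", "B", "C"), ("C", "D", "E"))


def test_delivery_roundtrip(tmp_path, small_geometry):
    spec = make_spec(n_segments=20, noise_sd=0.01)
    pairs = simulate_delivery(spec, geometry=small_geometry)
    out = save_delivery(pairs, spec, tmp_path / "d")
    loaded, manifest = load_delivery(out)
    assert manifest["patient_id"] == "P1"
    assert len(loaded) == 20
    np.testing.assert_allclose(loaded[5].measured, pairs[5].measured, rtol=1e-12)
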