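"""Isotherm preprocessing, compression modulus, descriptors and stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raftfilm.datatypes import CompressionProfile, Isotherm, StabilityTrace
from raftfilm.errors import InvalidInputError, OutOfRangeError
from raftfilm.monolayer import (
    IsothermAnalyzer,
    StabilityAnalyzer,
    area_at_pressure,
    classify_phase,
    compression_modulus,
    detect_transitions,
    extract_a0,
    preprocess,
    stability_metrics,
)

from conftest import linear_isotherm


class TestPreprocess:
    def test_clean_input_is_identity(self):
        iso = linear_isotherm()
        out = preprocess(iso)
        np.testing.assert_allclose(out.area, iso.area)
        np.testing.assert_allclose(out.pressure, iso.pressure)

    def test_duplicate_areas_are_averaged(self):
        area = np.concatenate([np.linspace(50, 41, 10), [41.0]])
        pressure = np.concatenate([np.linspace(0, 9, 10), [11.0]])  # 9 and 11 at A=41
        out = preprocess(Isotherm(area=area, pressure=pressure))
        assert out.area.size == 10
        assert out.pressure[out.area == 41.0] == pytest.approx(10.0)

    def test_shuffled_rows_match_sorted_input(self):
        iso = linear_isotherm()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(iso))
        shuffled = preprocess(Isotherm(area=iso.area[perm], pressure=iso.pressure[perm]))
        # oracle: explicit argsort of the raw rows
        order = np.argsort(iso.area)[::-1]
        np.testing.assert_allclose(shuffled.area, iso.area[order])
        np.testing.assert_allclose(shuffled.pressure, iso.pressure[order])

    def test_small_negative_pressures_clip_to_zero(self):
        area = np.linspace(60, 40, 20)
        pressure = np.linspace(-0.3, 10, 20)
        out = preprocess(Isotherm(area=area, pressure=pressure))
        assert out.pressure.min() == 0.0

    @pytest.mark.parametrize(
        "area, pressure",
        [
            (np.linspace(50, 45, 5), np.linspace(0, 5, 5)),  # too short
            (np.linspace(50, 30, 20), np.r_[np.nan, np.zeros(19)]),  # non-finite
            (np.linspace(50, 30, 20), np.r_[-3.0, np.zeros(19)]),  # below sensor floor
            (np.linspace(5, -5, 20), np.zeros(20)),  # non-positive areas
        ],
    )
    def test_invalid_inputs_raise(self, area, pressure):
        with pytest.raises(InvalidInputError):
            preprocess(Isotherm(area=area, pressure=pressure))


class TestCompressionModulus:
    def test_ideal_two_dimensional_gas(self):
        # π·A = kT  ⇒  C_s⁻¹ = −A dπ/dA = kT/A = π exactly
        area = np.linspace(90, 30, 800)
        kt = 1200.0
        prof = compression_modulus(Isotherm(area=area, pressure=kt / area))
        interior = slice(10, -10)
        np.testing.assert_allclose(
            prof.cs_inverse[interior], prof.pressure[interior], rtol=0.01
        )

    def test_constant_pressure_plateau_gives_zero(self):
        area = np.linspace(60, 30, 400)
        pressure = np.where(area > 45, 2 * (60 - area), 30.0)
        prof = compression_modulus(Isotherm(area=area, pressure=pressure))
        plateau = (prof.area < 42) & (prof.area > 32)
        assert np.all(np.abs(prof.cs_inverse[plateau]) < 0.5)

    def test_too_short_for_window_raises(self):
        iso = Isotherm(area=np.linspace(50, 49.9, 12), pressure=np.linspace(0, 1, 12))
        with pytest.raises(InvalidInputError):
            compression_modulus(iso, grid_step=0.1, window=25)

    @settings(max_examples=15, deadline=None)
    @given(scale=st.floats(min_value=0.2, max_value=5.0))
    def test_scale_covariance(self, scale):
        # multiplying all areas by c leaves C_s⁻¹(π) unchanged
        area = np.linspace(90, 30, 600)
        kt = 1100.0
        base = compression_modulus(Isotherm(area=area, pressure=kt / area))
        scaled = compression_modulus(
            Isotherm(area=scale * area, pressure=kt / area),
            grid_step=0.1 * scale,
        )
        np.testing.assert_allclose(
            scaled.cs_inverse[20:-20], base.cs_inverse[20:-20], rtol=0.01
        )

    @pytest.mark.parametrize("kind", ["exponential", "power"])
    def test_symbolic_derivative_oracle(self, kind):
        pressure = np.linspace(0.5, 45, 1500)
        if kind == "exponential":
            # A = a + b e^{−π/τ}  ⇒  C_s⁻¹ = A τ e^{π/τ} / b
            a, b, tau = 35.0, 40.0, 15.0
            area = a + b * np.exp(-pressure / tau)
            cs_true = (area * tau / b) * np.exp(pressure / tau)
        else:
            # A = a (π+c)^{−β}  ⇒  C_s⁻¹ = (π+c)/β
            a, beta, c = 120.0, 0.4, 5.0
            area = a * (pressure + c) ** -beta
            cs_true = (pressure + c) / beta
        prof = compression_modulus(Isotherm(area=area, pressure=pressure), grid_step=0.02)
        # compare on the interior 90% of the area grid
        n = prof.pressure.size
        interior = slice(int(0.05 * n), int(0.95 * n))
        cs_ref = np.interp(prof.pressure[interior], pressure, cs_true)
        np.testing.assert_allclose(prof.cs_inverse[interior], cs_ref, rtol=0.01)


class TestClassifyPhase:
    @pytest.mark.parametrize(
        "cs_max, phase",
        [
            (5.0, "G"),
            (12.5, "G"),
            (30.0, "G-LE"),
            (50.0, "LE"),
            (98.0, "LE"),
            (100.0, "LC"),
            (125.0, "LC"),
            (162.0, "LC"),
            (250.0, "LC"),
            (300.0, "S"),
        ],
    )
    def test_bins(self, cs_max, phase):
        assert classify_phase(cs_max) == phase

    def test_negative_raises(self):
        with pytest.raises(InvalidInputError):
            classify_phase(-1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0, max_value=1e4, allow_nan=False))
    def test_total_function_on_nonnegative_reals(self, x):
        assert classify_phase(x) in {"G", "G-LE", "LE", "LC", "S"}


class TestExtractA0:
    @pytest.mark.parametrize("n", [20, 60, 300])
    def test_linear_branch_is_exact(self, n):
        iso = linear_isotherm(a0=50.0, slope=2.5, n=n)
        assert extract_a0(iso) == pytest.approx(50.0, abs=0.05)

    def test_sm_fixture_limiting_area(self, registry):
        assert extract_a0(registry["iso_sm"]) == pytest.approx(50.7, abs=0.5)

    def test_dopc_rich_fixture_limiting_area(self, registry):
        assert extract_a0(registry["iso_2:1:1"]) == pytest.approx(62.0, abs=0.5)

    def test_post_collapse_window(self, registry):
        # SM-rich film: the branch above the partial collapse extrapolates far
        # below the main limiting area
        a0pc = extract_a0(registry["iso_1:1:2"], segment=(46.0, 52.0))
        assert a0pc == pytest.approx(31.0, abs=1.0)
        assert a0pc < extract_a0(registry["iso_1:1:2"])


class TestDetectTransitions:
    def test_monotone_profile_has_no_transitions(self):
        p = np.linspace(0, 40, 200)
        prof = CompressionProfile(
            pressure=p, cs_inverse=2.0 + 3.0 * p, area=np.linspace(80, 40, 200),
            cs_max=122.0, pressure_at_cs_max=40.0,
        )
        assert detect_transitions(prof) == ([], [])

    def test_equimolar_fixture_kink_and_collapse(self, registry):
        prof = compression_modulus(registry["iso_1:1:1"])
        collapses, kinks = detect_transitions(prof)
        assert any(abs(k - 30.0) <= 1.0 for k in kinks)
        assert any(abs(c - 47.8) <= 0.5 for c in collapses)

    def test_cholesterol_rich_fixture_kink_without_collapse(self, registry):
        prof = compression_modulus(registry["iso_1:2:1"])
        collapses, kinks = detect_transitions(prof)
        assert collapses == []
        assert any(abs(k - 50.0) <= 1.5 for k in kinks)


class TestAreaAtPressure:
    def test_linear_inverse(self):
        area = np.linspace(55, 20, 100)
        iso = Isotherm(area=area, pressure=60.0 - area)
        assert area_at_pressure(iso, 30.0) == pytest.approx(30.0, rel=1e-9)

    def test_grid_node_is_exact(self):
        iso = linear_isotherm()
        i = 37
        assert area_at_pressure(iso, float(iso.pressure[i])) == pytest.approx(
            float(iso.area[i])
        )

    def test_quadratic_closed_form_inverse(self):
        # π = ((60 − A)/2)²  ⇔  A = 60 − 2√π
        area = np.linspace(59.5, 20, 2000)
        iso = Isotherm(area=area, pressure=((60.0 - area) / 2.0) ** 2)
        for pi in [3.3, 17.7, 101.1]:
            assert area_at_pressure(iso, pi) == pytest.approx(
                60.0 - 2.0 * np.sqrt(pi), rel=1e-3
            )

    def test_out_of_range_raises(self):
        with pytest.raises(OutOfRangeError):
            area_at_pressure(linear_isotherm(), 1e6)


class TestStability:
    @staticmethod
    def _trace(pressure_fn, duration=14400.0, step=5.0):
        t = np.arange(0.0, duration, step)
        return StabilityTrace(time=t, pressure=pressure_fn(t))

    def test_constant_trace(self):
        out = stability_metrics(self._trace(lambda t: np.full_like(t, 28.0)))
        assert out.plateau_pressure == pytest.approx(28.0)
        assert out.drift_rate == pytest.approx(0.0, abs=1e-9)

    def test_linear_decay_has_no_plateau(self):
        out = stability_metrics(self._trace(lambda t: 30.0 - 1.25 * t / 3600.0))
        assert out.plateau_pressure is None
        assert out.drift_rate == pytest.approx(-1.25, abs=0.01)

    def test_sm_rich_fixture_plateau(self, registry):
        out = stability_metrics(registry["stab_1:1:2"])
        assert out.plateau_pressure == pytest.approx(28.0, abs=0.5)
        assert out.time_to_plateau < 1800.0  # settles within half an hour

    def test_dopc_rich_fixture_keeps_decaying(self, registry):
        out = stability_metrics(registry["stab_2:1:1"])
        assert out.plateau_pressure is None
        assert out.drift_rate < -0.5

    def test_short_trace_raises(self):
        with pytest.raises(InvalidInputError):
            stability_metrics(self._trace(lambda t: np.full_like(t, 28.0), duration=900.0))


class TestEstimators:
    def test_isotherm_analyzer_full_descriptor_set(self, registry):
        an = IsothermAnalyzer().fit(registry["iso_1:1:1"])
        assert an.phase_ == "LC"
        assert an.features_.a0 == an.a0_
        assert an.a0_post_collapse_ is not None and an.a0_post_collapse_ < an.a0_
        # sklearn param plumbing
        assert an.get_params()["collapse_threshold"] == 10.0
        clone_params = IsothermAnalyzer(**an.get_params()).get_params()
        assert clone_params == an.get_params()

    def test_analyzer_accepts_plain_arrays(self):
        iso = linear_isotherm()
        an = IsothermAnalyzer().fit(np.column_stack([iso.area, iso.pressure]))
        assert an.a0_ == pytest.approx(50.0, abs=0.1)

    def test_stability_analyzer(self, registry):
        an = StabilityAnalyzer().fit(registry["stab_1:2:1"])
        assert an.plateau_pressure_ == pytest.approx(26.0, abs=0.5)
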