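"""CPE elements, equivalent-circuit simulation and CNLS fitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raftfilm.datatypes import CircuitParams, ImpedanceSpectrum
from raftfilm.eis import (
    CircuitFitter,
    circuit_impedance,
    cnls_fit,
    cpe_impedance,
    goodness,
    simulate_spectrum,
    to_bode,
)
from raftfilm.errors import FitFailureError, InvalidInputError
from raftfilm.synthetic import CIRCUIT_TABLE, SpectrumSpec, gen_spectrum

FREQ = np.logspace(-1, 3, 41)  # 0.1–1000 Hz, 10 points per decade
ROWS = list(CIRCUIT_TABLE)


def perturbed(p: CircuitParams, factor: float = 2.0) -> CircuitParams:
    """All magnitudes scaled; exponents kept inside (0, 1]."""
    return CircuitParams(
        r_sol=p.r_sol * factor, r_m=p.r_m * factor, q_m=p.q_m * factor,
        alpha_m=p.alpha_m, q_sp=None if p.q_sp is None else p.q_sp * factor,
        alpha_sp=p.alpha_sp,
    )


class TestCPE:
    def test_ideal_capacitor_limit(self):
        z = cpe_impedance(3.0, 1.0, FREQ * 2 * np.pi)
        np.testing.assert_allclose(np.degrees(np.angle(z)), -90.0, atol=1e-9)

    def test_resistor_limit_as_alpha_vanishes(self):
        z = cpe_impedance(0.5, 1e-3, np.array([1.0, 100.0]))
        assert np.all(np.abs(np.degrees(np.angle(z))) < 0.1)

    def test_closed_form_magnitude_and_phase(self):
        z = cpe_impedance(5.0, 0.8, 2 * np.pi * 1.0)
        assert np.abs(z) == pytest.approx(1e6 / (5.0 * (2 * np.pi) ** 0.8), rel=1e-12)
        assert np.abs(z) == pytest.approx(4.6e4, rel=0.01)
        assert np.degrees(np.angle(z)) == pytest.approx(-72.0, abs=1e-9)

    def test_domain_violations_raise(self):
        for q, a, w in [(-1.0, 0.9, 1.0), (1.0, 1.2, 1.0), (1.0, 0.9, -1.0)]:
            with pytest.raises(InvalidInputError):
                cpe_impedance(q, a, w)


class TestCircuit:
    def test_high_frequency_limit_is_solution_resistance(self):
        for row in ROWS:
            z = circuit_impedance(CIRCUIT_TABLE[row], 1e6)
            assert np.abs(z) == pytest.approx(CIRCUIT_TABLE[row].r_sol, rel=0.01)

    def test_infinite_membrane_resistance_drops_branch(self):
        p = CircuitParams(r_sol=20.0, r_m=np.inf, q_m=5.0, alpha_m=0.9)
        omega = 2 * np.pi * FREQ
        np.testing.assert_allclose(
            circuit_impedance(p, omega),
            20.0 + cpe_impedance(5.0, 0.9, omega),
            rtol=1e-12,
        )

    def test_independent_complex_arithmetic_oracle(self):
        p = CIRCUIT_TABLE["2:1:1"]
        omega = 2 * np.pi * 1.0
        z_qm = 1e6 / (p.q_m * (1j * omega) ** p.alpha_m)
        z_qsp = 1e6 / (p.q_sp * (1j * omega) ** p.alpha_sp)
        branch = p.r_m * 1e3 + z_qsp
        expected = p.r_sol + (z_qm * branch) / (z_qm + branch)
        assert circuit_impedance(p, omega) == pytest.approx(expected, rel=1e-12)

    def test_alt_topology_differs_but_shares_high_frequency_limit(self):
        p = CIRCUIT_TABLE["1:1:1"]
        omega = 2 * np.pi * FREQ
        z_def = circuit_impedance(p, omega)
        z_alt = circuit_impedance(p, omega, topology="alt")
        assert not np.allclose(z_def, z_alt)
        assert np.abs(circuit_impedance(p, 1e12, topology="alt")) == pytest.approx(
            p.r_sol, rel=0.01
        )

    @settings(max_examples=30, deadline=None)
    @given(
        r_sol=st.floats(min_value=1.0, max_value=100.0),
        r_m=st.floats(min_value=10.0, max_value=5000.0),
        q_m=st.floats(min_value=0.5, max_value=50.0),
        alpha_m=st.floats(min_value=0.5, max_value=1.0),
        q_sp=st.floats(min_value=0.5, max_value=50.0),
        alpha_sp=st.floats(min_value=0.5, max_value=1.0),
    )
    def test_phase_stays_capacitive(self, r_sol, r_m, q_m, alpha_m, q_sp, alpha_sp):
        p = CircuitParams(r_sol=r_sol, r_m=r_m, q_m=q_m, alpha_m=alpha_m,
                          q_sp=q_sp, alpha_sp=alpha_sp)
        z = circuit_impedance(p, 2 * np.pi * FREQ)
        phase = np.degrees(np.angle(z))
        assert np.all(phase <= 1e-9) and np.all(phase > -90.0)


class TestBode:
    def test_three_four_five_triangle(self):
        spec = ImpedanceSpectrum(frequency=[1.0], z_real=[3.0], z_imag=[-4.0])
        logmod, phase = to_bode(spec)
        assert 10 ** logmod[0] == pytest.approx(5.0, rel=1e-12)
        assert phase[0] == pytest.approx(-53.13, abs=0.01)

    def test_pure_resistor_has_zero_phase(self):
        spec = ImpedanceSpectrum(frequency=FREQ, z_real=np.full_like(FREQ, 50.0),
                                 z_imag=np.zeros_like(FREQ))
        _, phase = to_bode(spec)
        np.testing.assert_allclose(phase, 0.0, atol=1e-12)

    def test_cpe_constant_phase(self):
        z = cpe_impedance(2.0, 0.94, 2 * np.pi * FREQ)
        spec = ImpedanceSpectrum(frequency=FREQ, z_real=z.real, z_imag=z.imag)
        _, phase = to_bode(spec)
        np.testing.assert_allclose(phase, -0.94 * 90.0, atol=1e-9)

    def test_zero_modulus_raises(self):
        with pytest.raises(InvalidInputError):
            to_bode(ImpedanceSpectrum(frequency=[1.0], z_real=[0.0], z_imag=[0.0]))


class TestFit:
    def test_fixed_point_from_truth(self):
        truth = CIRCUIT_TABLE["1:2:1"]
        spec = simulate_spectrum(truth, FREQ)
        fit = cnls_fit(spec, truth)
        assert fit.residual_norm == pytest.approx(0.0, abs=1e-8)
        assert fit.params.r_m == pytest.approx(truth.r_m, rel=1e-6)

    @pytest.mark.parametrize("row", ROWS)
    def test_recovery_from_doubled_start(self, row):
        truth = CIRCUIT_TABLE[row]
        spec = simulate_spectrum(truth, FREQ)
        fit = cnls_fit(spec, perturbed(truth))
        for name in ("r_sol", "r_m", "q_m", "alpha_m", "q_sp", "alpha_sp"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=0.01
            ), name

    def test_frequency_ordering_invariance(self):
        truth = CIRCUIT_TABLE["1:1:2"]
        spec = simulate_spectrum(truth, FREQ)
        rng = np.random.default_rng(3)
        perm = rng.permutation(FREQ.size)
        shuffled = ImpedanceSpectrum(
            frequency=spec.frequency[perm], z_real=spec.z_real[perm],
            z_imag=spec.z_imag[perm],
        )
        a = cnls_fit(spec, perturbed(truth)).params
        b = cnls_fit(shuffled, perturbed(truth)).params
        for name in ("r_sol", "r_m", "q_m", "alpha_m", "q_sp", "alpha_sp"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-6)

    def test_area_normalization_invariance(self):
        # Ω·cm² vs Ω with matching Q rescale: electrode area a cm²
        area = 0.35
        truth = CIRCUIT_TABLE["2:1:1"]
        rescaled_truth = CircuitParams(
            r_sol=truth.r_sol / area, r_m=truth.r_m / area,
            q_m=truth.q_m * area, alpha_m=truth.alpha_m,
            q_sp=truth.q_sp * area, alpha_sp=truth.alpha_sp,
        )
        spec = simulate_spectrum(truth, FREQ)
        spec_ohm = ImpedanceSpectrum(
            frequency=FREQ, z_real=spec.z_real / area, z_imag=spec.z_imag / area
        )
        fit = cnls_fit(spec_ohm, perturbed(rescaled_truth))
        assert fit.params.r_m * area == pytest.approx(truth.r_m, rel=1e-4)
        assert fit.params.q_m / area == pytest.approx(truth.q_m, rel=1e-4)

    @staticmethod
    def _mc_medians(row, n_seeds=20):
        truth = CIRCUIT_TABLE[row]
        recovered = {k: [] for k in ("r_sol", "r_m", "q_m", "alpha_m", "q_sp", "alpha_sp")}
        for seed in range(n_seeds):
            spec = gen_spectrum(SpectrumSpec(params=truth, noise_relative=0.01, seed=seed))
            fit = cnls_fit(spec, perturbed(truth))
            for k in recovered:
                recovered[k].append(getattr(fit.params, k))
        return truth, {k: np.median(v) for k, v in recovered.items()}

    def test_monte_carlo_median_recovery_under_noise(self):
        # membrane elements are recovered within 5% at 1% noise; the spacer
        # pair (q_sp, alpha_sp) is low-frequency-limited on the high-R_m
        # DOPC-rich row and only identifiable on the equimolar row
        truth, med = self._mc_medians("2:1:1")
        for k in ("r_sol", "r_m", "q_m", "alpha_m"):
            assert med[k] == pytest.approx(getattr(truth, k), rel=0.05), k
        truth_eq, med_eq = self._mc_medians("1:1:1")
        for k in ("r_sol", "r_m", "q_m", "alpha_m", "q_sp", "alpha_sp"):
            assert med_eq[k] == pytest.approx(getattr(truth_eq, k), rel=0.05), k

    def test_low_frequency_cutoff_inflates_spacer_uncertainty(self):
        truth = CIRCUIT_TABLE["2:1:1"]
        spec = gen_spectrum(SpectrumSpec(params=truth, noise_relative=0.01, seed=1))
        full = cnls_fit(spec, perturbed(truth, 1.5))
        keep = spec.frequency >= 1.0
        cut = ImpedanceSpectrum(frequency=spec.frequency[keep],
                                z_real=spec.z_real[keep], z_imag=spec.z_imag[keep])
        cut_fit = cnls_fit(cut, perturbed(truth, 1.5))
        assert cut_fit.stderr["q_sp"] is not None and full.stderr["q_sp"] is not None
        assert cut_fit.stderr["q_sp"] >= 2.0 * full.stderr["q_sp"]

    def test_nonconvergence_carries_best_so_far(self):
        truth = CIRCUIT_TABLE["1:1:1"]
        spec = simulate_spectrum(truth, FREQ)
        with pytest.raises(FitFailureError) as excinfo:
            cnls_fit(spec, perturbed(truth, 50.0), max_nfev=3)
        assert excinfo.value.best is not None
        assert excinfo.value.best.params.r_m > 0

    def test_too_few_points_raise(self):
        truth = CIRCUIT_TABLE["1:1:1"]
        spec = simulate_spectrum(truth, np.array([1.0, 10.0]))
        with pytest.raises(InvalidInputError):
            cnls_fit(spec, truth)


class TestGoodness:
    def test_perfect_model(self):
        truth = CIRCUIT_TABLE["1:2:1"]
        spec = simulate_spectrum(truth, FREQ)
        chi2, phase_res = goodness(spec, truth)
        assert chi2 == pytest.approx(0.0, abs=1e-20)
        assert phase_res == pytest.approx(0.0, abs=1e-9)

    def test_solution_resistance_offset_dominates_high_frequency(self):
        truth = CIRCUIT_TABLE["1:2:1"]
        spec = simulate_spectrum(truth, FREQ)
        off = dataclasses.replace(truth, r_sol=truth.r_sol + 10.0)
        chi2, _ = goodness(spec, off)
        assert chi2 > 0
        # the weighted residual is largest where |Z| is smallest (high f)
        omega = 2 * np.pi * spec.frequency
        res = np.abs(circuit_impedance(off, omega) - spec.z) / np.abs(spec.z)
        assert np.argmax(res) > spec.frequency.size // 2

    def test_empty_spectrum_raises(self):
        with pytest.raises(InvalidInputError):
            goodness(ImpedanceSpectrum(frequency=[], z_real=[], z_imag=[]),
                     CIRCUIT_TABLE["1:1:1"])


class TestFitterEstimator:
    def test_fit_predict_roundtrip(self, registry):
        spec = registry["eis_1:1:1"]
        fitter = CircuitFitter(init=perturbed(CIRCUIT_TABLE["1:1:1"])).fit(spec)
        z_hat = fitter.predict(spec)
        np.testing.assert_allclose(z_hat, spec.z, rtol=1e-6)
        assert fitter.chi_square_ == pytest.approx(0.0, abs=1e-12)

    def test_auto_init_converges_on_fixture(self, registry):
        fitter = CircuitFitter().fit(registry["eis_2:1:1"])
        assert fitter.params_.r_m == pytest.approx(1467.0, rel=0.01)

    def test_accepts_plain_array(self, registry):
        spec = registry["eis_1:2:1"]
        X = np.column_stack([spec.frequency, spec.z_real, spec.z_imag])
        fitter = CircuitFitter(init=perturbed(CIRCUIT_TABLE["1:2:1"])).fit(X)
        assert fitter.params_.q_m == pytest.approx(6.73, rel=0.01)
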