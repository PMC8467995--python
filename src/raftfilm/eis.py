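"""Constant-phase-element equivalent circuits and CNLS impedance fitting.

The supported-bilayer electrode is modelled as a solution resistance in
series with the membrane constant-phase element (CPE), which is in parallel
with the series combination of the membrane resistance and the CPE of the
thin water ("spacer") layer between membrane and gold:

    Z(ω) = R_sol + [ Z_Qm ∥ (R_m + Z_Qsp) ],     Z_Q = 1/(Q (jω)^α)

A CPE with exponent α has constant phase −α·90°; α = 1 is an ideal capacitor.
Q magnitudes are in µF·cm⁻²·s^(α−1), R_sol in Ω·cm², R_m in kΩ·cm², giving
impedances in Ω·cm².  Measured spectra are fitted by complex nonlinear least
squares (CNLS): trust-region least squares on log10-magnitude parameters with
modulus weighting (each point's real and imaginary residuals scaled by 1/|Z|),
the standard choice for spectra spanning several decades.
"""

from __future__ import annotations

import numpy as np
import lmfit
from sklearn.base import BaseEstimator

from .datatypes import CircuitParams, FitResult, ImpedanceSpectrum
from .errors import FitFailureError, InvalidInputError

__all__ = [
    "cpe_impedance",
    "circuit_impedance",
    "to_bode",
    "cnls_fit",
    "goodness",
    "CircuitFitter",
]

_Q_UNIT = 1e6  # Z(Ω·cm²) = 1e6 / (Q[µF cm⁻² s^(α−1)] · ω^α)
_R_M_UNIT = 1e3  # R_m is carried in kΩ·cm²


def cpe_impedance(q: float, alpha: float, omega) -> np.ndarray:
    """Impedance of a constant-phase element, Z = 1/(Q (jω)^α), in Ω·cm².

    ``q`` in µF·cm⁻²·s^(α−1), ``omega`` in rad/s.  |Z| = 1e6/(q ω^α) and the
    phase is −α·90° at every frequency.
    """
    omega = np.asarray(omega, dtype=float)
    if q <= 0 or not (0 < alpha <= 1) or np.any(omega <= 0):
        raise InvalidInputError("CPE requires q > 0, 0 < alpha <= 1, omega > 0")
    return _Q_UNIT / (q * (1j * omega) ** alpha)


def circuit_impedance(
    p: CircuitParams, omega, topology: str = "default"
) -> np.ndarray:
    """Complex impedance of the equivalent circuit at angular frequency ``omega``.

    ``default``: R_sol + (Q_m ∥ (R_m + Q_sp)); the spacer CPE sits behind the
    membrane resistance, as for a hydrated submembrane reservoir.
    ``alt``: R_sol + (Q_m ∥ R_m) + Q_sp, a nested alternative with the spacer
    element in series.  ``q_sp=None`` drops the spacer element in either case.
    """
    p.validate()
    omega = np.asarray(omega, dtype=float)
    z_qm = cpe_impedance(p.q_m, p.alpha_m, omega)
    r_m = p.r_m * _R_M_UNIT
    z_sp = (
        cpe_impedance(p.q_sp, p.alpha_sp, omega)
        if p.q_sp is not None
        else np.zeros_like(z_qm)
    )
    if topology == "default":
        branch = r_m + z_sp
        if np.isfinite(r_m):
            z_par = 1.0 / (1.0 / z_qm + 1.0 / branch)
        else:
            z_par = z_qm
        return p.r_sol + z_par
    if topology == "alt":
        if np.isfinite(r_m):
            z_par = 1.0 / (1.0 / z_qm + 1.0 / r_m)
        else:
            z_par = z_qm
        return p.r_sol + z_par + z_sp
    raise InvalidInputError(f"unknown topology '{topology}'")


def simulate_spectrum(
    p: CircuitParams, frequency, topology: str = "default", label: str = ""
) -> ImpedanceSpectrum:
    """Evaluate the circuit on a frequency grid (Hz) as an ImpedanceSpectrum."""
    frequency = np.asarray(frequency, dtype=float)
    z = circuit_impedance(p, 2.0 * np.pi * frequency, topology=topology)
    return ImpedanceSpectrum(
        frequency=frequency, z_real=z.real, z_imag=z.imag, label=label
    )


def to_bode(spec: ImpedanceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """(log10 |Z|, phase in degrees) per frequency; capacitive phase negative."""
    mod = spec.modulus
    if np.any(mod == 0):
        raise InvalidInputError("zero impedance modulus; Bode transform undefined")
    return np.log10(mod), spec.phase_deg


def _weights(z: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "modulus":
        return 1.0 / np.abs(z)
    if weighting == "unit":
        return np.ones_like(z, dtype=float)
    if weighting == "proportional":
        # guard vanishing components
        floor = 1e-12 * np.abs(z).max()
        return 1.0 / np.maximum(np.abs(z), floor)
    raise InvalidInputError(f"unknown weighting '{weighting}'")


def _residuals(params, omega, z_obs, w, topology, with_spacer):
    p = _params_to_circuit(params, with_spacer)
    z_mod = circuit_impedance(p, omega, topology=topology)
    d = (z_mod - z_obs) * w
    return np.concatenate([d.real, d.imag])


def _params_to_circuit(params, with_spacer) -> CircuitParams:
    vals = params.valuesdict()
    return CircuitParams(
        r_sol=10.0 ** vals["log_r_sol"],
        r_m=10.0 ** vals["log_r_m"],
        q_m=10.0 ** vals["log_q_m"],
        alpha_m=vals["alpha_m"],
        q_sp=10.0 ** vals["log_q_sp"] if with_spacer else None,
        alpha_sp=vals["alpha_sp"] if with_spacer else None,
    )


def cnls_fit(
    spec: ImpedanceSpectrum,
    init: CircuitParams,
    weighting: str = "modulus",
    topology: str = "default",
    max_nfev: int = 2000,
) -> FitResult:
    """Complex nonlinear least-squares fit of the equivalent circuit.

    Minimizes Σ w_i (ΔZ_real,i² + ΔZ_imag,i²); magnitudes are optimized as
    log10 values (positivity by construction) and exponents bounded in (0, 1].
    Parameter standard errors come from the local curvature at the optimum and
    are mapped back to the linear scale; a singular curvature yields None.
    """
    init.validate()
    with_spacer = init.q_sp is not None
    n_free = 6 if with_spacer else 4
    if 2 * spec.frequency.size < 2 * n_free:
        raise InvalidInputError(
            f"need at least {n_free} frequencies to fit {n_free} parameters"
        )
    omega = 2.0 * np.pi * spec.frequency
    z_obs = spec.z
    w = _weights(z_obs, weighting)

    params = lmfit.Parameters()
    params.add("log_r_sol", value=np.log10(init.r_sol), min=-4, max=8)
    params.add("log_r_m", value=np.log10(init.r_m), min=-6, max=9)
    params.add("log_q_m", value=np.log10(init.q_m), min=-6, max=6)
    params.add("alpha_m", value=init.alpha_m, min=1e-3, max=1.0)
    if with_spacer:
        params.add("log_q_sp", value=np.log10(init.q_sp), min=-6, max=6)
        params.add("alpha_sp", value=init.alpha_sp, min=1e-3, max=1.0)

    result = lmfit.minimize(
        _residuals,
        params,
        args=(omega, z_obs, w, topology, with_spacer),
        method="least_squares",
        max_nfev=max_nfev,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    fitted = _params_to_circuit(result.params, with_spacer)
    residuals = result.residual
    norm = float(np.sqrt(np.sum(residuals**2)))
    stderr = _linear_stderr(result, fitted, with_spacer)
    fit = FitResult(
        params=fitted,
        stderr=stderr,
        residual_norm=norm,
        residuals=residuals,
        success=bool(result.success),
        nfev=int(result.nfev),
        message=str(result.message),
    )
    if not result.success:
        raise FitFailureError(f"CNLS fit did not converge: {result.message}", best=fit)
    return fit


def _linear_stderr(result, fitted: CircuitParams, with_spacer) -> dict:
    ln10 = np.log(10.0)
    mapping = {
        "r_sol": ("log_r_sol", fitted.r_sol),
        "r_m": ("log_r_m", fitted.r_m),
        "q_m": ("log_q_m", fitted.q_m),
        "alpha_m": ("alpha_m", None),
    }
    if with_spacer:
        mapping["q_sp"] = ("log_q_sp", fitted.q_sp)
        mapping["alpha_sp"] = ("alpha_sp", None)
    out = {}
    for name, (pname, value) in mapping.items():
        se = result.params[pname].stderr
        if se is None or not np.isfinite(se):
            out[name] = None
        elif value is None:
            out[name] = float(se)
        else:
            out[name] = float(value * ln10 * se)
    return out


def goodness(
    spec: ImpedanceSpectrum,
    p: CircuitParams,
    weighting: str = "modulus",
    topology: str = "default",
) -> tuple[float, float]:
    """(weighted chi-square per point, max |phase residual| in degrees)."""
    if spec.frequency.size == 0:
        raise InvalidInputError("empty spectrum")
    omega = 2.0 * np.pi * spec.frequency
    z_mod = circuit_impedance(p, omega, topology=topology)
    w = _weights(spec.z, weighting)
    d = (z_mod - spec.z) * w
    chi2 = float(np.sum(d.real**2 + d.imag**2) / spec.frequency.size)
    phase_res = np.degrees(np.arctan2(z_mod.imag, z_mod.real)) - spec.phase_deg
    return chi2, float(np.max(np.abs(phase_res)))


def _auto_init(spec: ImpedanceSpectrum, with_spacer: bool = True) -> CircuitParams:
    """Heuristic starting point: R_sol from the high-frequency real limit,
    CPE magnitudes from |Z| at the band edges assuming near-capacitive phase.
    """
    f = spec.frequency
    order = np.argsort(f)
    f, zr, zm = f[order], spec.z_real[order], spec.modulus[order]
    r_sol = max(float(zr[-1]), 1e-2)
    alpha0 = 0.9
    omega_hi = 2.0 * np.pi * f[-1]
    q_m = _Q_UNIT / (max(zm[-1] - r_sol, 1e-6) * omega_hi**alpha0)
    omega_lo = 2.0 * np.pi * f[0]
    z_lo = max(zm[0], 1.0)
    r_m = z_lo / _R_M_UNIT  # low-frequency modulus as resistance scale
    q_sp = _Q_UNIT / (z_lo * omega_lo**alpha0) if with_spacer else None
    return CircuitParams(
        r_sol=r_sol,
        r_m=max(r_m, 1e-3),
        q_m=max(q_m, 1e-4),
        alpha_m=alpha0,
        q_sp=max(q_sp, 1e-4) if with_spacer else None,
        alpha_sp=alpha0 if with_spacer else None,
    )


class CircuitFitter(BaseEstimator):
    """Scikit-learn-style CNLS fitter for the membrane equivalent circuit.

    ``fit`` accepts an :class:`ImpedanceSpectrum` or an (n, 3) array of
    [frequency Hz, Z_real Ω·cm², Z_imag Ω·cm²].  Fitted attributes:
    ``params_`` (CircuitParams), ``stderr_``, ``result_`` (full FitResult),
    ``chi_square_``, ``max_phase_residual_``.
    """

    def __init__(
        self,
        init: CircuitParams | None = None,
        weighting: str = "modulus",
        topology: str = "default",
        max_nfev: int = 2000,
    ):
        self.init = init
        self.weighting = weighting
        self.topology = topology
        self.max_nfev = max_nfev

    def fit(self, X, y=None):
        spec = self._as_spectrum(X)
        init = self.init if self.init is not None else _auto_init(spec)
        self.result_ = cnls_fit(
            spec,
            init,
            weighting=self.weighting,
            topology=self.topology,
            max_nfev=self.max_nfev,
        )
        self.params_ = self.result_.params
        self.stderr_ = self.result_.stderr
        self.chi_square_, self.max_phase_residual_ = goodness(
            spec, self.params_, weighting=self.weighting, topology=self.topology
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Model impedance (complex, Ω·cm²) at the frequencies of ``X``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        spec = self._as_spectrum(X, allow_missing_z=True)
        return circuit_impedance(
            self.params_, 2.0 * np.pi * spec.frequency, topology=self.topology
        )

    @staticmethod
    def _as_spectrum(X, allow_missing_z: bool = False) -> ImpedanceSpectrum:
        if isinstance(X, ImpedanceSpectrum):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim == 1 and allow_missing_z:
            return ImpedanceSpectrum(
                frequency=X, z_real=np.zeros_like(X), z_imag=np.zeros_like(X)
            )
        if X.ndim != 2 or X.shape[1] != 3:
            raise InvalidInputError(
                "expected an ImpedanceSpectrum or an (n, 3) [f, z_real, z_imag] array"
            )
        return ImpedanceSpectrum(frequency=X[:, 0], z_real=X[:, 1], z_imag=X[:, 2])
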