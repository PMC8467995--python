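"""AC-voltammetry: differential capacitance, charge density, E_pzfc, coverage.

A membrane-covered electrode driven by a small AC perturbation behaves, per
potential, as a series RC circuit.  With rms perturbation amplitude E_ac at
angular frequency ω, the in-phase and out-of-phase rms current densities are

    i_in  = E_ac ω² R C² / (1 + (ωRC)²),    i_out = E_ac ω C / (1 + (ωRC)²),

so the capacitance inverts exactly as C = (i_in² + i_out²)/(ω E_ac i_out),
for any series resistance.  Integrating C(E) from an anchor potential gives
the free-charge density σ(E); its zero crossing is the potential of zero free
charge (E_pzfc).  Surface coverage is estimated from the capacitance minimum
against a bare-electrode and an ideal defect-free bilayer capacitance
(0.8 µF/cm²) with the two-capacitor formula θ = (C_bare − C_min)/(C_bare − C_ideal).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.integrate import cumulative_trapezoid
from sklearn.base import BaseEstimator

from .datatypes import ACVCurve, ChargeProfile, CoverageEstimate
from .errors import (
    DegenerateResponseError,
    InvalidInputError,
    NotFoundError,
    OutOfRangeError,
)

__all__ = [
    "capacitance_from_ac",
    "min_capacitance",
    "charge_density",
    "find_pzfc",
    "coverage",
    "ACVAnalyzer",
]

C_IDEAL_BILAYER = 0.8  # µF/cm², defect-free lipid bilayer


def capacitance_from_ac(curve: ACVCurve, peak_amplitude: bool = False) -> ACVCurve:
    """Fill in capacitance (µF/cm²) from lock-in current components.

    Series-RC inversion C = (i_in² + i_out²)/(ω E_ac i_out); exact for any
    series resistance.  Amplitude and currents are rms by default; set
    ``peak_amplitude`` when the instrument reports the perturbation amplitude
    as a peak value while the lock-in currents are rms (the amplitude is then
    converted to rms before inversion).
    """
    if curve.i_in is None or curve.i_out is None:
        raise InvalidInputError("current components are required for inversion")
    if np.any(curve.i_out <= 0):
        raise DegenerateResponseError(
            "out-of-phase current must be positive everywhere (no capacitive response)"
        )
    omega = 2.0 * np.pi * curve.frequency
    e_ac = curve.amplitude / np.sqrt(2.0) if peak_amplitude else curve.amplitude
    i_in, i_out = curve.i_in, curve.i_out
    c_farad = (i_in**2 + i_out**2) / (omega * e_ac * i_out)  # F/cm²
    return dataclasses.replace(curve, capacitance=c_farad * 1e6)


def _require_capacitance(curve: ACVCurve) -> ACVCurve:
    if curve.capacitance is None:
        curve = capacitance_from_ac(curve)
    return curve


def min_capacitance(
    curve: ACVCurve,
    window: tuple[float, float] = (-0.3, 0.0),
    c_bare: float | None = None,
    c_ideal: float = C_IDEAL_BILAYER,
) -> CoverageEstimate:
    """Locate the capacitance minimum within a potential window.

    On a flat (degenerate) window the first grid point of the window is
    returned and the estimate is flagged.
    """
    curve = _require_capacitance(curve)
    lo, hi = min(window), max(window)
    e, c = curve.potential, curve.capacitance
    mask = (e >= lo) & (e <= hi)
    if not np.any(mask):
        raise OutOfRangeError(f"window {window} V outside the recorded sweep")
    e_w, c_w = e[mask], c[mask]
    i = int(np.argmin(c_w))
    degenerate = bool(np.ptp(c_w) < 1e-12)
    if degenerate:
        i = 0
    return CoverageEstimate(
        c_min=float(c_w[i]),
        e_at_min=float(e_w[i]),
        c_bare=c_bare,
        c_ideal=c_ideal,
        degenerate=degenerate,
    )


def charge_density(
    curve: ACVCurve,
    anchor_potential: float,
    anchor_sigma: float = 0.0,
) -> ChargeProfile:
    """Free-charge density σ(E) = σ_anchor + ∫ C dE from the anchor potential.

    Trapezoidal integration; C in µF/cm² and E in V give σ in µC/cm².  The
    location of the zero crossing (E_pzfc) depends on the anchor condition.
    """
    curve = _require_capacitance(curve)
    order = np.argsort(curve.potential)
    e, c = curve.potential[order], curve.capacitance[order]
    if not (e[0] <= anchor_potential <= e[-1]):
        raise OutOfRangeError(
            f"anchor potential {anchor_potential} V outside sweep [{e[0]}, {e[-1]}]"
        )
    cum = np.concatenate([[0.0], cumulative_trapezoid(c, e)])
    at_anchor = np.interp(anchor_potential, e, cum)
    sigma = anchor_sigma + (cum - at_anchor)
    return ChargeProfile(potential=e, sigma=sigma)


def find_pzfc(profile: ChargeProfile) -> float:
    """Potential of zero free charge: sign change of σ(E) by linear interpolation.

    With several crossings, all are recorded on the profile and the most
    positive one is returned (the crossing on the desorption-free branch).
    """
    e, s = profile.potential, profile.sigma
    crossings = []
    for i in range(e.size - 1):
        if s[i] == 0.0:
            crossings.append(float(e[i]))
        elif s[i] * s[i + 1] < 0:
            frac = -s[i] / (s[i + 1] - s[i])
            crossings.append(float(e[i] + frac * (e[i + 1] - e[i])))
    if s[-1] == 0.0:
        crossings.append(float(e[-1]))
    if not crossings:
        raise NotFoundError("charge density does not change sign within the sweep")
    profile.crossings = sorted(set(crossings))
    profile.e_pzfc = profile.crossings[-1]
    return profile.e_pzfc


def coverage(est: CoverageEstimate, formula: str = "ideal_corrected") -> float:
    """Surface coverage θ from the capacitance minimum.

    ``ideal_corrected`` (default): θ = (C_bare − C_min)/(C_bare − C_ideal);
    ``ratio``: θ = 1 − C_min/C_bare.
    """
    if est.c_bare is None:
        raise InvalidInputError("coverage needs a bare-electrode capacitance c_bare")
    if not (est.c_ideal <= est.c_min <= est.c_bare) or est.c_bare <= est.c_ideal:
        raise InvalidInputError(
            f"expected c_ideal <= c_min <= c_bare, got "
            f"{est.c_ideal}, {est.c_min}, {est.c_bare}"
        )
    if formula == "ideal_corrected":
        theta = (est.c_bare - est.c_min) / (est.c_bare - est.c_ideal)
    elif formula == "ratio":
        theta = 1.0 - est.c_min / est.c_bare
    else:
        raise InvalidInputError(f"unknown coverage formula '{formula}'")
    est.theta = float(theta)
    return est.theta


class ACVAnalyzer(BaseEstimator):
    """Full ACV workflow: inversion, minimum, charge density, E_pzfc, coverage.

    Attributes after ``fit``: ``curve_`` (capacitance filled), ``estimate_``
    (minimum + coverage when ``c_bare`` given), ``profile_`` (charge density),
    ``e_pzfc_``, ``theta_``.
    """

    def __init__(
        self,
        window: tuple[float, float] = (-0.3, 0.0),
        anchor_potential: float | None = None,
        anchor_sigma: float = 0.0,
        c_bare: float | None = None,
        c_ideal: float = C_IDEAL_BILAYER,
        coverage_formula: str = "ideal_corrected",
    ):
        self.window = window
        self.anchor_potential = anchor_potential
        self.anchor_sigma = anchor_sigma
        self.c_bare = c_bare
        self.c_ideal = c_ideal
        self.coverage_formula = coverage_formula

    def fit(self, X, y=None):
        if not isinstance(X, ACVCurve):
            X = np.asarray(X, dtype=float)
            X = ACVCurve(potential=X[:, 0], capacitance=X[:, 1])
        curve = _require_capacitance(X)
        self.curve_ = curve
        self.estimate_ = min_capacitance(
            curve, window=self.window, c_bare=self.c_bare, c_ideal=self.c_ideal
        )
        self.theta_ = None
        if self.c_bare is not None:
            self.theta_ = coverage(self.estimate_, formula=self.coverage_formula)
        anchor_e = self.anchor_potential
        anchor_s = self.anchor_sigma
        if anchor_e is None:
            if curve.anchor_potential is not None:
                anchor_e = curve.anchor_potential
                anchor_s = curve.anchor_sigma
            else:
                anchor_e = float(curve.potential.min())
        self.profile_ = charge_density(curve, anchor_e, anchor_s)
        try:
            self.e_pzfc_ = find_pzfc(self.profile_)
        except NotFoundError:
            self.e_pzfc_ = None
        return self
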