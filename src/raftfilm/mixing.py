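"""Ideal-mixing reference and excess quantities for multi-component monolayers.

For a film of N components with mole fractions X_i and single-component
areas A_i(π):

    A_id(π)   = Σ X_i A_i(π)                    ideal (additive) mixing area
    A_exc(π)  = A_mix(π) − A_id(π)              excess area
    ΔG_exc(π) = N_A ∫₀^π A_exc dπ'              excess Gibbs energy of mixing
    %A(π)     = 100 (A_id − A_mix) / A_id       percent condensation

Negative A_exc/ΔG_exc indicate attractive interactions (miscibility); a
negative %A means the mixed film is expanded relative to ideal mixing.  The
unit chain for ΔG_exc is Å² → m² (1e−20) and mN/m → N/m (1e−3), times
Avogadro's number, giving J/mol: a constant 1 Å² excess integrated over
30 mN/m is ≈ 180.7 J/mol.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import Isotherm, MixingResult, MixtureSpec
from .errors import OutOfRangeError
from .monolayer import area_at_pressure

__all__ = [
    "AVOGADRO",
    "GIBBS_UNIT_FACTOR",
    "ideal_area",
    "excess_area",
    "excess_gibbs",
    "percent_condensation",
    "excess_sweep",
    "MixingAnalyzer",
]

AVOGADRO = 6.02214076e23  # 1/mol
#: J/mol per (Å² · mN/m): N_A · 1e−20 m²/Å² · 1e−3 (N/m)/(mN/m)
GIBBS_UNIT_FACTOR = AVOGADRO * 1e-20 * 1e-3


def _component_area(label: str, iso: Isotherm, pi: float) -> float:
    try:
        return area_at_pressure(iso, pi)
    except OutOfRangeError as exc:
        raise OutOfRangeError(
            f"component '{label}' does not cover {pi} mN/m: {exc}"
        ) from exc


def ideal_area(spec: MixtureSpec, pi: float) -> float:
    """Ideal-mixing area Σ X_i A_i(π) in Å²/molecule."""
    return float(
        sum(x * _component_area(lbl, iso, pi) for lbl, iso, x in spec.components)
    )


def excess_area(spec: MixtureSpec, pi: float) -> float:
    """Measured mixture area minus the ideal-mixing area, sign preserved."""
    a_mix = _component_area(spec.mixture.label or "mixture", spec.mixture, pi)
    return float(a_mix - ideal_area(spec, pi))


def excess_gibbs(spec: MixtureSpec, pi_max: float, grid: float = 0.5) -> float:
    """Excess Gibbs energy of mixing, trapezoid-integrated from 0 to ``pi_max``.

    ``grid`` is the uniform pressure step (mN/m) of the integrand grid; the
    excess area is interpolated at each node.  Result in J/mol.
    """
    if pi_max < 0:
        raise OutOfRangeError("pi_max must be non-negative")
    if pi_max == 0:
        return 0.0
    n = max(int(np.ceil(pi_max / grid)) + 1, 2)
    pressures = np.linspace(0.0, pi_max, n)
    integrand = np.array([excess_area(spec, p) for p in pressures])
    return float(np.trapezoid(integrand, pressures) * GIBBS_UNIT_FACTOR)


def percent_condensation(spec: MixtureSpec, pi: float) -> float:
    """100 · (A_id − A_mix)/A_id at pressure ``pi``; negative for expansion."""
    a_id = ideal_area(spec, pi)
    a_mix = _component_area(spec.mixture.label or "mixture", spec.mixture, pi)
    return float(100.0 * (a_id - a_mix) / a_id)


def excess_sweep(
    spec: MixtureSpec, pressures, grid: float = 0.5
) -> list[MixingResult]:
    """One :class:`MixingResult` per requested pressure.

    ΔG_exc is cumulative from 0 to each pressure, computed on one shared
    integration grid so that adjacent intervals add exactly.
    """
    pressures = np.asarray(pressures, dtype=float)
    if pressures.size == 0:
        return []
    pi_top = float(pressures.max())
    results = []
    if pi_top > 0:
        n = max(int(np.ceil(pi_top / grid)) + 1, 2)
        base_p = np.linspace(0.0, pi_top, n)
        base_exc = np.array([excess_area(spec, p) for p in base_p])
        from scipy.integrate import cumulative_trapezoid

        cum = np.concatenate(
            [[0.0], cumulative_trapezoid(base_exc, base_p)]
        ) * GIBBS_UNIT_FACTOR
    for pi in pressures:
        try:
            a_id = ideal_area(spec, pi)
            a_mix = _component_area(spec.mixture.label or "mixture", spec.mixture, pi)
        except OutOfRangeError as exc:
            raise OutOfRangeError(f"sweep pressure {pi} mN/m: {exc}") from exc
        g = float(np.interp(pi, base_p, cum)) if pi_top > 0 else 0.0
        results.append(
            MixingResult(
                pressure=float(pi),
                a_ideal=a_id,
                a_measured=a_mix,
                a_excess=a_mix - a_id,
                g_excess=g,
                percent_condensation=100.0 * (a_id - a_mix) / a_id,
            )
        )
    return results


class MixingAnalyzer(BaseEstimator):
    """Excess-mixing analysis of a ternary (or N-ary) film.

    Construct with the component isotherms and mole fractions, then ``fit``
    the measured mixture isotherm.  ``results_`` holds one
    :class:`MixingResult` per pressure in ``pressures``.
    """

    def __init__(self, components=None, pressures=(5, 10, 15, 20, 25, 30, 35, 40, 45),
                 grid: float = 0.5):
        self.components = components
        self.pressures = pressures
        self.grid = grid

    def fit(self, X, y=None):
        if not isinstance(X, Isotherm):
            X = np.asarray(X, dtype=float)
            X = Isotherm(area=X[:, 0], pressure=X[:, 1], label="mixture")
        if not self.components:
            raise ValueError("MixingAnalyzer needs components=[(label, Isotherm, X_i), ...]")
        spec = MixtureSpec(components=list(self.components), mixture=X)
        self.spec_ = spec
        usable = [
            p for p in self.pressures
            if self._covered(spec, p)
        ]
        self.results_ = excess_sweep(spec, usable, grid=self.grid)
        return self

    @staticmethod
    def _covered(spec: MixtureSpec, pi: float) -> bool:
        try:
            excess_area(spec, pi)
            return True
        except OutOfRangeError:
            return False
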