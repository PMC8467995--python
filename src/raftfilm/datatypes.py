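"""Core containers for monolayer, voltammetry and impedance data.

Units follow surface-chemistry convention throughout: areas in Å² per molecule,
surface pressure in mN/m, potentials in V vs Ag|AgCl, capacitance in µF/cm²,
charge density in µC/cm², impedance in Ω·cm², membrane resistance in kΩ·cm²
and CPE magnitudes in µF·cm⁻²·s^(α−1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Isotherm",
    "CompressionProfile",
    "IsothermFeatures",
    "StabilityTrace",
    "MixtureSpec",
    "MixingResult",
    "ACVCurve",
    "ChargeProfile",
    "CoverageEstimate",
    "ImpedanceSpectrum",
    "CircuitParams",
    "FitResult",
]


def _arr(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class Isotherm:
    """A π–A compression record at fixed temperature.

    ``area`` is in Å²/molecule, ``pressure`` in mN/m.  After
    :func:`raftfilm.monolayer.preprocess` the areas are strictly decreasing
    (compression order) and pressures are clipped at 0.
    """

    area: np.ndarray
    pressure: np.ndarray
    temperature: float = 21.0
    label: str = ""

    def __post_init__(self):
        self.area = _arr(self.area)
        self.pressure = _arr(self.pressure)
        if self.area.shape != self.pressure.shape:
            raise ValueError("area and pressure must have the same length")

    def __len__(self) -> int:
        return self.area.size


@dataclass
class CompressionProfile:
    """Reciprocal compression modulus C_s⁻¹ = −A(dπ/dA) along an isotherm."""

    pressure: np.ndarray
    cs_inverse: np.ndarray
    area: np.ndarray
    cs_max: float
    pressure_at_cs_max: float

    def __post_init__(self):
        self.pressure = _arr(self.pressure)
        self.cs_inverse = _arr(self.cs_inverse)
        self.area = _arr(self.area)


@dataclass
class IsothermFeatures:
    """Scalar descriptors of one isotherm (limiting area, transitions, phase)."""

    a0: float
    a_at_30: float | None
    cs_max: float
    pressure_at_cs_max: float
    phase: str
    collapse_pressures: list[float] = field(default_factory=list)
    kink_pressures: list[float] = field(default_factory=list)
    a0_post_collapse: float | None = None


@dataclass
class StabilityTrace:
    """Surface pressure vs time of a film held at constant trough area."""

    time: np.ndarray
    pressure: np.ndarray
    plateau_pressure: float | None = None
    drift_rate: float | None = None  # mN/m per hour, over the final hour
    time_to_plateau: float | None = None

    def __post_init__(self):
        self.time = _arr(self.time)
        self.pressure = _arr(self.pressure)
        if self.time.shape != self.pressure.shape:
            raise ValueError("time and pressure must have the same length")


@dataclass
class MixtureSpec:
    """Component isotherms with mole fractions plus the measured mixed film."""

    components: list[tuple[str, Isotherm, float]]
    mixture: Isotherm

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValueError("a mixture needs at least two components")
        fractions = np.array([x for _, _, x in self.components], dtype=float)
        if np.any(fractions <= 0):
            raise ValueError("mole fractions must be positive")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"mole fractions must sum to 1 (got {fractions.sum():.12g})"
            )

    @property
    def mole_fractions(self) -> np.ndarray:
        return np.array([x for _, _, x in self.components], dtype=float)


@dataclass
class MixingResult:
    """Excess-mixing quantities at one surface pressure."""

    pressure: float
    a_ideal: float  # Å²/molecule
    a_measured: float  # Å²/molecule
    a_excess: float  # Å²/molecule
    g_excess: float  # J/mol, cumulative from π = 0
    percent_condensation: float  # %, positive = condensed vs ideal


@dataclass
class ACVCurve:
    """Potential-resolved AC response of a supported bilayer.

    Carries either lock-in current densities (``i_in``/``i_out``, A/cm² rms,
    with the perturbation ``amplitude`` in V rms and ``frequency`` in Hz) or a
    precomputed ``capacitance`` in µF/cm².  ``anchor_potential``/``anchor_sigma``
    record the charge-integration anchor when the curve was generated with one.
    """

    potential: np.ndarray
    i_in: np.ndarray | None = None
    i_out: np.ndarray | None = None
    capacitance: np.ndarray | None = None
    amplitude: float | None = None
    frequency: float | None = None
    anchor_potential: float | None = None
    anchor_sigma: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.potential = _arr(self.potential)
        for name in ("i_in", "i_out", "capacitance"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, _arr(v))
        has_currents = self.i_in is not None and self.i_out is not None
        if not has_currents and self.capacitance is None:
            raise ValueError(
                "ACVCurve needs either both current components or capacitance"
            )
        if has_currents:
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("current-mode ACVCurve needs frequency > 0")
            if self.amplitude is None or self.amplitude <= 0:
                raise ValueError("current-mode ACVCurve needs amplitude > 0")


@dataclass
class ChargeProfile:
    """Integrated free-charge density σ(E) and its zero crossing(s)."""

    potential: np.ndarray
    sigma: np.ndarray
    e_pzfc: float | None = None
    crossings: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.potential = _arr(self.potential)
        self.sigma = _arr(self.sigma)


@dataclass
class CoverageEstimate:
    """Capacitance minimum and the surface coverage derived from it."""

    c_min: float
    e_at_min: float
    c_bare: float | None = None
    c_ideal: float = 0.8  # defect-free bilayer, µF/cm²
    theta: float | None = None
    degenerate: bool = False  # flat window: minimum is a tie-break


@dataclass
class ImpedanceSpectrum:
    """Frequency-resolved complex impedance of the membrane-covered electrode."""

    frequency: np.ndarray
    z_real: np.ndarray
    z_imag: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.frequency = _arr(self.frequency)
        self.z_real = _arr(self.z_real)
        self.z_imag = _arr(self.z_imag)
        if not (self.frequency.shape == self.z_real.shape == self.z_imag.shape):
            raise ValueError("frequency, z_real, z_imag must share a length")

    @property
    def z(self) -> np.ndarray:
        return self.z_real + 1j * self.z_imag

    @property
    def modulus(self) -> np.ndarray:
        return np.hypot(self.z_real, self.z_imag)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.z_imag, self.z_real))


@dataclass
class CircuitParams:
    """Elements of the solution / membrane / spacer equivalent circuit.

    ``r_sol`` in Ω·cm², ``r_m`` in kΩ·cm², CPE magnitudes ``q_m``/``q_sp`` in
    µF·cm⁻²·s^(α−1) with exponents in (0, 1].  ``q_sp`` may be None for the
    reduced circuit without a submembrane spacer element.
    """

    r_sol: float
    r_m: float
    q_m: float
    alpha_m: float
    q_sp: float | None = None
    alpha_sp: float | None = None

    def validate(self):
        from .errors import InvalidInputError

        if not (self.r_sol > 0 and self.r_m > 0 and self.q_m > 0):
            raise InvalidInputError("circuit magnitudes must be positive")
        if not (0 < self.alpha_m <= 1):
            raise InvalidInputError("alpha_m must lie in (0, 1]")
        if self.q_sp is not None:
            if self.q_sp <= 0:
                raise InvalidInputError("q_sp must be positive when present")
            if self.alpha_sp is None or not (0 < self.alpha_sp <= 1):
                raise InvalidInputError("alpha_sp must lie in (0, 1]")
        return self

    def as_dict(self) -> dict:
        d = {
            "r_sol": self.r_sol,
            "r_m": self.r_m,
            "q_m": self.q_m,
            "alpha_m": self.alpha_m,
        }
        if self.q_sp is not None:
            d["q_sp"] = self.q_sp
            d["alpha_sp"] = self.alpha_sp
        return d


@dataclass
class FitResult:
    """Outcome of a complex nonlinear least-squares circuit fit."""

    params: CircuitParams
    stderr: dict[str, float | None]
    residual_norm: float
    residuals: np.ndarray
    success: bool
    nfev: int
    message: str = ""
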