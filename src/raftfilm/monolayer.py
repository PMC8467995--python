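"""Langmuir π–A isotherm and π–t stability analysis.

The central quantity is the reciprocal compression modulus

    C_s⁻¹ = −A (dπ/dA)_T

whose magnitude classifies the monolayer phase (gas, liquid-expanded,
liquid-condensed, solid) and whose extrema locate structural transitions:
a local minimum that drops to (near) zero marks a partial collapse of the
two-dimensional film, while a minimum that stays clearly above zero marks a
structural reorganization ("kink") without collapse.  The limiting area A₀ is
obtained by linear extrapolation of the steepest branch of the isotherm to
zero surface pressure.

The derivative is taken on a uniform area grid with a local-polynomial
(Savitzky–Golay) filter, window 5 and degree 2 by default, which is stable on
noisy trough data while exact on locally quadratic segments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from sklearn.base import BaseEstimator

from .datatypes import CompressionProfile, Isotherm, IsothermFeatures, StabilityTrace
from .errors import ExtractionError, InvalidInputError, OutOfRangeError

__all__ = [
    "preprocess",
    "compression_modulus",
    "classify_phase",
    "extract_a0",
    "detect_transitions",
    "area_at_pressure",
    "stability_metrics",
    "IsothermAnalyzer",
    "StabilityAnalyzer",
]

#: Phase bins on max C_s⁻¹ (mN/m): lower-edge-inclusive where ambiguous.
PHASE_BINS = (
    (0.0, 12.5, "G"),
    (12.5, 50.0, "G-LE"),
    (50.0, 100.0, "LE"),
    (100.0, 250.0, "LC"),
    (250.0, np.inf, "S"),
)

MIN_POINTS = 10
_NEGATIVE_PRESSURE_FLOOR = -0.5  # mN/m; small sensor negatives tolerated


def preprocess(raw: Isotherm, grid_step: float | None = None) -> Isotherm:
    """Clean a raw isotherm: sort by decreasing area, average duplicate areas,
    clip small negative pressures to zero and optionally resample to a uniform
    area grid of ``grid_step`` Å².
    """
    a, p = raw.area, raw.pressure
    if a.size < MIN_POINTS:
        raise InvalidInputError(f"isotherm needs >= {MIN_POINTS} points, got {a.size}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
        raise InvalidInputError("isotherm contains non-finite values")
    if np.any(a <= 0):
        raise InvalidInputError("areas must be strictly positive")
    if np.any(p < _NEGATIVE_PRESSURE_FLOOR):
        raise InvalidInputError(
            f"pressures below {_NEGATIVE_PRESSURE_FLOOR} mN/m indicate corrupt data"
        )
    # average rows that share an area value, then order by decreasing area
    uniq, inverse = np.unique(a, return_inverse=True)
    psum = np.zeros_like(uniq)
    counts = np.zeros_like(uniq)
    np.add.at(psum, inverse, p)
    np.add.at(counts, inverse, 1.0)
    a_asc, p_asc = uniq, psum / counts
    p_asc = np.clip(p_asc, 0.0, None)
    if grid_step is not None:
        if grid_step <= 0:
            raise InvalidInputError("grid_step must be positive")
        n = max(int(round((a_asc[-1] - a_asc[0]) / grid_step)) + 1, MIN_POINTS)
        grid = np.linspace(a_asc[0], a_asc[-1], n)
        p_asc = np.interp(grid, a_asc, p_asc)
        a_asc = grid
    return Isotherm(
        area=a_asc[::-1].copy(),
        pressure=p_asc[::-1].copy(),
        temperature=raw.temperature,
        label=raw.label,
    )


def _uniform_grid(iso: Isotherm, grid_step: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Ascending-area uniform resampling of a preprocessed isotherm."""
    a_asc = iso.area[::-1]
    p_asc = iso.pressure[::-1]
    if np.any(np.diff(a_asc) <= 0):
        iso = preprocess(iso)
        a_asc, p_asc = iso.area[::-1], iso.pressure[::-1]
    span = a_asc[-1] - a_asc[0]
    n = max(int(round(span / grid_step)) + 1, 2)
    grid = np.linspace(a_asc[0], a_asc[-1], n)
    return grid, np.interp(grid, a_asc, p_asc), span / (n - 1)


def compression_modulus(
    iso: Isotherm,
    grid_step: float = 0.1,
    window: int = 5,
    polyorder: int = 2,
) -> CompressionProfile:
    """Evaluate C_s⁻¹ = −A(dπ/dA) along the isotherm.

    The derivative is a Savitzky–Golay smoothing derivative on a uniform area
    grid (central inside, polynomial-extrapolated at the ends).
    """
    a_asc, p_asc, delta = _uniform_grid(iso, grid_step)
    if a_asc.size < window:
        raise InvalidInputError(
            f"isotherm shorter than the smoothing window ({a_asc.size} < {window})"
        )
    dpi_da = savgol_filter(p_asc, window, polyorder, deriv=1, delta=delta, mode="interp")
    cs = -a_asc * dpi_da
    # back to compression order (decreasing area, rising pressure)
    cs, a_desc, p_desc = cs[::-1], a_asc[::-1], p_asc[::-1]
    imax = int(np.argmax(cs))
    return CompressionProfile(
        pressure=p_desc,
        cs_inverse=cs,
        area=a_desc,
        cs_max=float(cs[imax]),
        pressure_at_cs_max=float(p_desc[imax]),
    )


def classify_phase(cs_max: float) -> str:
    """Map a maximum C_s⁻¹ value (mN/m) onto the monolayer phase label.

    0–12.5 gas (G), 12.5–50 gas/liquid-expanded transition (G-LE), 50–100
    liquid-expanded (LE), 100–250 liquid-condensed (LC), above 250 solid (S).
    """
    if not np.isfinite(cs_max) or cs_max < 0:
        raise InvalidInputError(f"cs_max must be finite and >= 0, got {cs_max}")
    if cs_max <= 12.5:
        return "G"
    if cs_max < 50.0:
        return "G-LE"
    if cs_max < 100.0:
        return "LE"
    if cs_max <= 250.0:
        return "LC"
    return "S"


def extract_a0(
    iso: Isotherm,
    segment: tuple[float, float] | None = None,
    grid_step: float = 0.1,
    steepness_fraction: float = 0.8,
) -> float:
    """Limiting area: A-intercept at π = 0 of a line through the steepest branch.

    The steepest branch is the contiguous run of points whose C_s⁻¹ is at least
    ``steepness_fraction`` of the segment-local maximum; ``segment`` (a
    pressure window, mN/m) restricts the search, e.g. to the post-collapse
    branch.  Without a window the search is confined to the pre-collapse
    branch (the limiting area refers to the intact film).
    """
    profile = compression_modulus(iso, grid_step=grid_step)
    p, a, cs = profile.pressure, profile.area, profile.cs_inverse
    if segment is None:
        collapses, _ = detect_transitions(profile)
        mask = p < collapses[0] - 0.5 if collapses else np.ones_like(p, dtype=bool)
        if not np.any(mask):
            mask = np.ones_like(p, dtype=bool)
    else:
        lo, hi = segment
        mask = (p >= lo) & (p <= hi)
        if not np.any(mask):
            raise ExtractionError(f"no isotherm points in pressure window {segment}")
    idx = np.flatnonzero(mask)
    local_max_pos = idx[np.argmax(cs[idx])]
    threshold = steepness_fraction * cs[local_max_pos]
    steep = mask & (cs >= threshold)
    # contiguous run containing the local maximum
    run_lo = run_hi = local_max_pos
    while run_lo > 0 and steep[run_lo - 1]:
        run_lo -= 1
    while run_hi < steep.size - 1 and steep[run_hi + 1]:
        run_hi += 1
    sel = slice(run_lo, run_hi + 1)
    if run_hi - run_lo < 1:
        raise ExtractionError("steepest segment too short for a line fit")
    slope, intercept = np.polyfit(a[sel], p[sel], 1)
    if slope >= 0:
        raise ExtractionError(
            "no branch with pressure rising under compression; cannot extrapolate"
        )
    a0 = -intercept / slope
    if a0 <= 0:
        raise ExtractionError(f"extrapolated limiting area is non-positive ({a0:.3g})")
    return float(a0)


def detect_transitions(
    profile: CompressionProfile,
    collapse_threshold: float = 10.0,
    prominence: float = 1.0,
) -> tuple[list[float], list[float]]:
    """Locate collapses and kinks as interior minima of C_s⁻¹(π).

    A minimum that drops below ``collapse_threshold`` (mN/m) after a preceding
    maximum is a (partial) collapse; a minimum that stays above the threshold
    is a kink — a structural reorganization without breakdown of the film.
    Returns ``(collapse_pressures, kink_pressures)``, each sorted ascending and
    possibly empty.
    """
    cs = profile.cs_inverse
    p = profile.pressure
    order = np.argsort(p)
    cs, p = cs[order], p[order]
    minima, _ = find_peaks(-cs, prominence=prominence)
    maxima, _ = find_peaks(cs, prominence=prominence)
    collapses, kinks = [], []
    for i in minima:
        preceding = maxima[maxima < i]
        # a genuine transition needs a developed film before it: the preceding
        # maximum must clear the collapse threshold comfortably (filters
        # lift-off artefacts in the near-zero-pressure head)
        if preceding.size == 0 or cs[preceding].max() < 2.0 * collapse_threshold:
            continue
        if cs[preceding].max() <= cs[i]:
            continue
        if cs[i] < collapse_threshold:
            collapses.append(float(p[i]))
        else:
            kinks.append(float(p[i]))
    return sorted(collapses), sorted(kinks)


def area_at_pressure(iso: Isotherm, pi: float) -> float:
    """Area per molecule at surface pressure ``pi`` by linear interpolation on
    the pre-collapse rising branch (the prefix on which π is non-decreasing).
    """
    p = iso.pressure
    a = iso.area
    if p.size < 2:
        raise InvalidInputError("isotherm too short for interpolation")
    # keep the monotone (compression) branch: stop at the first genuine drop
    cummax = np.maximum.accumulate(p)
    drop = np.flatnonzero(p < cummax - 0.2)
    if drop.size:
        p, a = p[: drop[0]], a[: drop[0]]
    if not (p.min() <= pi <= p.max()):
        raise OutOfRangeError(
            f"pressure {pi} mN/m outside recorded range [{p.min():.3g}, {p.max():.3g}]"
        )
    # last point at or below the query, so that a flat (clipped) head yields
    # the lift-off area rather than the start-of-record area
    below = np.flatnonzero(p <= pi)
    if below.size == 0:
        raise OutOfRangeError(f"pressure {pi} mN/m below the recorded branch")
    i = below[-1]
    if p[i] == pi or i == p.size - 1:
        return float(a[i])
    frac = (pi - p[i]) / (p[i + 1] - p[i])
    return float(a[i] + frac * (a[i + 1] - a[i]))


def stability_metrics(
    trace: StabilityTrace,
    plateau_tol: float = 0.5,
    slope_window_s: float = 600.0,
) -> StabilityTrace:
    """Plateau detection and drift of a π–t trace.

    A plateau starts at the earliest time after which every rolling
    ``slope_window_s`` window has |slope| below ``plateau_tol`` (mN/m per
    hour); its pressure is the mean over the plateau region.  ``drift_rate``
    is the least-squares slope over the final hour.
    """
    t, p = trace.time, trace.pressure
    if t.size < 4 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("time must be strictly increasing")
    span = t[-1] - t[0]
    if span < 1800.0:
        raise InvalidInputError("stability trace must cover at least 30 minutes")

    # rolling slopes (mN/m per hour) over windows starting at each sample
    starts = np.flatnonzero(t <= t[-1] - slope_window_s)
    slopes = np.full(starts.size, np.nan)
    for k, i in enumerate(starts):
        j = int(np.searchsorted(t, t[i] + slope_window_s, side="right"))
        if j - i >= 2:
            slopes[k] = np.polyfit(t[i:j], p[i:j], 1)[0] * 3600.0
    ok = np.abs(slopes) < plateau_tol
    # earliest start from which every later window is quiet
    quiet_from = None
    suffix_ok = True
    for k in range(starts.size - 1, -1, -1):
        suffix_ok = suffix_ok and bool(ok[k])
        if suffix_ok:
            quiet_from = starts[k]
    plateau_pressure = time_to_plateau = None
    if quiet_from is not None:
        time_to_plateau = float(t[quiet_from])
        plateau_pressure = float(np.mean(p[quiet_from:]))

    final_hour = t >= t[-1] - 3600.0
    if final_hour.sum() >= 2:
        drift = float(np.polyfit(t[final_hour], p[final_hour], 1)[0] * 3600.0)
    else:
        drift = float(np.polyfit(t, p, 1)[0] * 3600.0)
    return dataclasses.replace(
        trace,
        plateau_pressure=plateau_pressure,
        drift_rate=drift,
        time_to_plateau=time_to_plateau,
    )


def _as_isotherm(X) -> Isotherm:
    if isinstance(X, Isotherm):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise InvalidInputError("expected an Isotherm or an (n, 2) [area, pressure] array")
    return Isotherm(area=X[:, 0], pressure=X[:, 1])


class IsothermAnalyzer(BaseEstimator):
    """Extract the full descriptor set of one π–A isotherm.

    Parameters
    ----------
    grid_step : float
        Uniform area grid step (Å²) for resampling and differentiation.
    window, polyorder : int
        Savitzky–Golay smoothing-derivative settings.
    collapse_threshold : float
        C_s⁻¹ level (mN/m) separating a kink from a partial collapse.
    prominence : float
        Minimum prominence (mN/m) for extrema of the C_s⁻¹ profile.
    a0_window : tuple or None
        Optional pressure window overriding the steepest-segment rule for A₀.
    reference_pressure : float
        Pressure (mN/m) at which the cross-composition comparison area is
        reported (A at 30 mN/m by convention).

    Attributes (after ``fit``)
    --------------------------
    isotherm_, profile_, features_, a0_, cs_max_, phase_,
    collapse_pressures_, kink_pressures_, a_at_30_, a0_post_collapse_
    """

    def __init__(
        self,
        grid_step: float = 0.1,
        window: int = 5,
        polyorder: int = 2,
        collapse_threshold: float = 10.0,
        prominence: float = 1.0,
        a0_window: tuple[float, float] | None = None,
        reference_pressure: float = 30.0,
    ):
        self.grid_step = grid_step
        self.window = window
        self.polyorder = polyorder
        self.collapse_threshold = collapse_threshold
        self.prominence = prominence
        self.a0_window = a0_window
        self.reference_pressure = reference_pressure

    def fit(self, X, y=None):
        iso = preprocess(_as_isotherm(X), grid_step=None)
        self.isotherm_ = iso
        self.profile_ = compression_modulus(
            iso, grid_step=self.grid_step, window=self.window, polyorder=self.polyorder
        )
        collapses, kinks = detect_transitions(
            self.profile_,
            collapse_threshold=self.collapse_threshold,
            prominence=self.prominence,
        )
        self.a0_ = extract_a0(iso, segment=self.a0_window, grid_step=self.grid_step)
        self.cs_max_ = self.profile_.cs_max
        self.phase_ = classify_phase(self.cs_max_)
        self.collapse_pressures_ = collapses
        self.kink_pressures_ = kinks
        pmax = float(self.profile_.pressure.max())
        self.a0_post_collapse_ = None
        if collapses and pmax > collapses[-1] + 2.0:
            try:
                self.a0_post_collapse_ = extract_a0(
                    iso, segment=(collapses[-1] + 1.0, pmax), grid_step=self.grid_step
                )
            except ExtractionError:
                pass
        try:
            self.a_at_30_ = area_at_pressure(iso, self.reference_pressure)
        except OutOfRangeError:
            self.a_at_30_ = None
        self.features_ = IsothermFeatures(
            a0=self.a0_,
            a_at_30=self.a_at_30_,
            cs_max=self.cs_max_,
            pressure_at_cs_max=self.profile_.pressure_at_cs_max,
            phase=self.phase_,
            collapse_pressures=collapses,
            kink_pressures=kinks,
            a0_post_collapse=self.a0_post_collapse_,
        )
        return self

    def transform(self, X=None):
        """Return the fitted descriptor set (ignores X; analysis is per-record)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "features_")
        return self.features_


class StabilityAnalyzer(BaseEstimator):
    """Plateau and drift analysis of a π–t stability trace.

    Attributes after ``fit``: ``trace_``, ``plateau_pressure_``,
    ``drift_rate_``, ``time_to_plateau_``.
    """

    def __init__(self, plateau_tol: float = 0.5, slope_window_s: float = 600.0):
        self.plateau_tol = plateau_tol
        self.slope_window_s = slope_window_s

    def fit(self, X, y=None):
        if isinstance(X, StabilityTrace):
            trace = X
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 2:
                raise InvalidInputError(
                    "expected a StabilityTrace or an (n, 2) [time, pressure] array"
                )
            trace = StabilityTrace(time=X[:, 0], pressure=X[:, 1])
        self.trace_ = stability_metrics(
            trace, plateau_tol=self.plateau_tol, slope_window_s=self.slope_window_s
        )
        self.plateau_pressure_ = self.trace_.plateau_pressure
        self.drift_rate_ = self.trace_.drift_rate
        self.time_to_plateau_ = self.trace_.time_to_plateau
        return self
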