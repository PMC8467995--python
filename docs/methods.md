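# Methods

## Scope and data model

raftfilm analyzes four kinds of records from a lipid-raft model-membrane
study: π–A compression isotherms and π–t stability traces of Langmuir
monolayers (areas in Å²/molecule, pressures in mN/m, 21 °C by default),
potential-resolved AC-voltammetric responses of electrode-supported bilayers
(V vs Ag|AgCl, µF/cm², µC/cm²), and frequency-resolved complex impedance
spectra (Ω·cm²).  All quantities carry these units throughout; nothing is
rescaled implicitly.

## Compression modulus and isotherm descriptors

The reciprocal compression modulus is `C_s⁻¹ = −A (dπ/dA)_T`.  The
derivative is computed on a uniform area grid (default step 0.1 Å²,
linear-interpolated resampling) with a Savitzky–Golay smoothing derivative,
window 5 and polynomial degree 2: exact on locally quadratic branches,
stable against trough noise, with polynomial (one-sided) treatment at the
record ends.  Phase assignment bins the maximum of C_s⁻¹: gas below
12.5 mN/m, liquid-expanded from 50 to 100, liquid-condensed from 100 to 250,
solid above 250; the unnamed 12.5–50 region is labelled "G-LE".  Boundary
values are assigned to the lower-edge-inclusive bin as listed in
`raftfilm.monolayer.classify_phase`.

The limiting area A₀ is the A-intercept at π = 0 of a straight line fitted
through the steepest contiguous branch — the run of points whose C_s⁻¹ is at
least 80% of the segment-local maximum.  Without a user-supplied pressure
window the search is confined to the pre-collapse branch: the limiting area
refers to the intact film, and the confinement also guards against a
smoothing-derivative overshoot at the sharp collapse-recovery elbow
electing a spurious post-collapse segment.  Passing a window above the
collapse pressure yields the post-collapse limiting area.

Transitions are interior minima of C_s⁻¹(π) with prominence ≥ 1 mN/m.  A
minimum below the collapse threshold (default 10 mN/m, configurable) after
a developed maximum (required to exceed twice the threshold, which filters
lift-off artefacts in the clipped near-zero-pressure head) is a partial
collapse; a minimum staying above the threshold is a kink (structural
reorganization).  The 10 mN/m default operationalizes the qualitative
convention that a collapse shows as a compressibility minimum approaching
zero, while a kink does not.

Stability traces: a plateau starts at the earliest time after which every
rolling 10-minute window has |slope| < 0.5 mN/m per hour; its pressure is
the mean over the plateau region, and the drift rate is the least-squares
slope over the final hour.  Traces shorter than 30 minutes are rejected.

Small negative sensor pressures (≥ −0.5 mN/m) are clipped to zero during
preprocessing; anything more negative is treated as corrupt data.

## Mixing thermodynamics

For components with mole fractions X_i and areas A_i(π) interpolated on the
pre-collapse branch: `A_id = Σ X_i A_i`, `A_exc = A_mix − A_id`,
`%A = 100 (A_id − A_mix)/A_id` (positive = condensation) and
`ΔG_exc(π) = N_A ∫₀^π A_exc dπ'`.  The integral uses the trapezoid rule on
a uniform pressure grid (default 0.5 mN/m) with the integrand interpolated
at each node; the unit chain Å² → m² (10⁻²⁰) and mN/m → N/m (10⁻³) times
Avogadro's number makes a constant 1 Å² excess over 30 mN/m equal
≈ 180.7 J/mol, which fixes the convention and is asserted in the tests.
Queries at π = 0 resolve to the lift-off point of the clipped record, so the
lower integration limit is exact and adjacent intervals add to within
1 part in 10⁹ when their endpoints lie on the shared grid.

## AC voltammetry

Per potential, the membrane-covered electrode is treated as a series RC
element.  With rms amplitude E_ac at angular frequency ω the inversion
`C = (i_in² + i_out²)/(ω E_ac i_out)` is algebraically exact for any series
resistance; amplitudes and currents are rms by convention (a peak-amplitude
flag converts).  Charge density is the trapezoid integral of C(E) from an
explicit anchor (potential, charge); the potential of zero free charge
(E_pzfc) is the linear-interpolated sign change of σ(E), the most positive
one when several exist (all are reported).  Because σ is only defined up to
the anchor condition, E_pzfc inherits the anchor choice; generated fixtures
therefore store their anchor on the curve.  Coverage uses the two-capacitor
form θ = (C_bare − C_min)/(C_bare − C_ideal) with C_ideal = 0.8 µF/cm² for
a defect-free bilayer (a plain-ratio variant is selectable); C_bare must be
supplied — 40 µF/cm² is a reasonable value for Au(111) near −0.2 V in PBS
and is the fixtures' default.

## Impedance model and CNLS fitting

The equivalent circuit is a solution resistance in series with the membrane
CPE in parallel with [membrane resistance in series with the spacer CPE of
the thin water layer between bilayer and gold]:
`Z(ω) = R_sol + [Z_Qm ∥ (R_m + Z_Qsp)]`, `Z_Q = 1/(Q(jω)^α)` with Q in
µF·cm⁻²·s^(α−1) (so `|Z| = 10⁶/(Q ω^α)` Ω·cm²) and phase −α·90°.  An
alternative nested topology (spacer element in series) is selectable and
flagged in reports.  Fitting minimizes the modulus-weighted sum of squared
real and imaginary residuals (weights 1/|Z|, the standard choice for
spectra spanning decades; unit and proportional weighting available) using
trust-region least squares on log₁₀-magnitudes — positivity by
construction — with exponents bounded in (0, 1].  Standard errors come from
the local curvature at the optimum, mapped back to the linear scale; a
singular curvature reports them absent.  Non-convergence raises an error
carrying the best-so-far parameters.

## Synthetic data

The generators define the study conditions and are deterministic functions
of their spec including the seed.

**Isotherms** come from an analytic compressibility profile integrated
through `dA/dπ = −A/C_s⁻¹(π)`: a fast rise just above lift-off to a
liquid-expanded level, a logistic condensed-phase rise whose peak equals the
target C_s⁻¹ maximum (with a mild post-peak decay), and multiplicative
Gaussian dips — asymmetric, with a gentler recovery side so the elbow stays
resolvable by the smoothing derivative — for kinks and collapses.  The curve
is rescaled so the steepest-segment extrapolation hits the target A₀
exactly; one shape knob is then solved so the area at a reference pressure
(30 mN/m) matches a requested value, and the collapse-dip depth is solved to
a requested post-collapse limiting area.

**The fixture registry** (`composition_fixtures`) realizes single-component
DOPC, cholesterol and egg-sphingomyelin films plus the four ternary
compositions, calibrated to their published descriptor set: limiting areas
(62.0, 48.1, 52.7 Å²; SM 50.7 Å²), compression-modulus maxima (98, 169,
162, 125 mN/m), the equimolar kink at 30 mN/m and partial collapse at
47.8 mN/m, post-collapse limiting areas (31.0, 50.5 Å²), percent
condensation at 30 mN/m (11.9, 3.9, 3.6%, negative for 1:1:1), stability
plateaus at 28 and 26 mN/m with a non-plateauing DOPC-rich trace,
capacitance minima in 2.6–3.5 µF/cm², zero-free-charge potentials at
+270/+290/+300/+330 mV, and the four published circuit-element rows.
Ternary mixtures are calibrated jointly against the single-component set:
an inner solve pins the 30 mN/m area to the percent-condensation target
exactly, an outer solve shapes the excess-area profile (signs of ΔG_exc at
30 mN/m: negative for the three non-equimolar films, positive — along with
a positive excess area at 35 mN/m — for the equimolar film).

Free choices the published descriptors do not determine, fixed once at
design time: the single components' areas at 30 mN/m (68, 37, 43 Å²), their
low-pressure expansion levels, lift-off areas (emergent, 51–160 Å²), the
equimolar film's A₀ = 60 Å² and %A(30) = −1%, dip depths/widths, and the
solution resistance R_sol = 25 Ω·cm² (typical for dilute PBS; the published
table reports membrane elements only).  Within this shape family the
magnitude of ΔG_exc for the cholesterol-rich film reaches ≈ −450 J/mol at
30 mN/m — the right sign and order of magnitude, though smaller than the
≈ −1000 J/mol scale of the laboratory films; the fixture set reproduces all
published signs but not the exact ΔG ordering between compositions.

**ACV curves** are capacitance shapes with a controlled minimum, sigmoid
rises at positive potentials (poorly organized film) and at negative
potentials (electroporation/detachment), and an anchor charge chosen so
σ(E) crosses zero exactly at the target E_pzfc; they can be emitted as
capacitance or as exact series-RC lock-in currents (20 Hz, 10 mV rms).

**Spectra** evaluate the circuit on a log grid (0.1–1000 Hz, 10
points/decade by default) with optional proportional Gaussian noise applied
per measured quadrature — the error structure of a frequency-response
analyzer.  Under complex-multiplicative noise instead, R_m of the high-R_m
rows stops being identifiable at 1% noise, which is why the per-quadrature
form is the package's noise model.

### What passing tests do and do not show

The fixtures share one smooth equation-of-state family; real isotherms have
measurement noise, hysteresis, barrier-speed artefacts and richer fine
structure, and real impedance spectra drift and violate stationarity.
Round-trip recovery of the calibrated descriptors therefore validates the
analysis chain (derivatives, extrapolations, integrals, fits and their unit
conventions), not the laboratory values themselves, whose raw data are not
publicly deposited.

### Identifiability of the spacer element

A Monte-Carlo experiment (1% per-quadrature noise, 20 seeds, doubled
starting magnitudes) recovers R_sol, R_m, Q_m and α_m with median error
well under 5% for every composition row.  The spacer pair (Q_sp, α_sp) is
informed only by the lowest decade of the 0.1–1000 Hz window and is
strongly mutually correlated: on the high-R_m rows its maximum-likelihood
median deviates by 15–20% (fits started at the truth reach the same
optima), while on the equimolar row all six parameters recover within 5%.
Consistently, removing frequencies below 1 Hz inflates the reported Q_sp
standard error several-fold — the uncertainty estimates flag the weak
identification.  Practical consequence: spacer parameters from band-limited
spectra should be read together with their standard errors.

## Numerical choices and degenerate inputs

- Duplicate areas are averaged; records shorter than 10 points rejected.
- Flat capacitance windows return the first grid point, flagged degenerate.
- Multiple σ zero crossings: all reported, the most positive returned.
- CNLS convergence: relative tolerances 10⁻¹², default cap 2000 function
  evaluations; log-magnitude bounds span ±6 decades around realistic values.
- Optimization/simulation seeds default to 0 and are explicit everywhere.
- Analysis problem sizes: fixtures carry ~1400-point isotherms (0.05 Å²
  sampling), 601-point ACV sweeps (2 mV), 41-frequency spectra and 2881-point
  stability traces — matching typical instrument exports.

## Known limitations

- The excess-quantity magnitudes of the synthetic mixtures are
  family-limited (see above); only signs and the %A values are exact.
- The coverage formula's literature original is not reproducible from the
  published account; both implemented variants are documented and the choice
  is configurable.
- No equation-of-state fitting, no regular-solution interaction parameters,
  no Kramers–Kronig validation, no image-based (BAM/AFM) analysis.
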