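# Methods

## Scope and model structure

The package evaluates rearing conditions for lobster sea-based container
culture as a five-stage pipeline: rearing limits → external conditions →
container transfer → internal conditions → exceedance statistics. The
container and its biofouling state enter only through linear transfer
coefficients; hydrodynamic detail (mooring response, container wake,
boundary layers) is deliberately outside the model.

## Wave kinematics

Wavelength comes from a damped fixed-point iteration on

    λ = (g T² / 2π) · tanh(2π a / λ)

seeded at the deep-water wavelength g T²/2π, damping 0.5, tolerance
1e-4 m, at most 200 iterations. Two forms of the tanh argument are
selectable: the default `printed` form uses the wave height (`a = H`),
which is the form the framework was calibrated with and which gives
44.0 m for the reference storm (H = 3.99 m, T = 7.4 s); the `standard`
form uses the water depth (`a = d`), the classical Airy relation. For the
reference storm in ~30 m of water both classify as deep (d > λ/2). The
wave number is k = 2π/λ everywhere — the only choice consistent with the
exponential decay e^{kz} of the orbital amplitude.

Orbital kinematics are implemented for the deep-water regime only, as the
amplitude envelope (phase θ = 0) since the evaluation compares peak
magnitudes; shallow/intermediate elliptic orbits raise an explicit error
rather than silently extrapolating.

## Transfer functions

Internal velocity is linear in external velocity with zero intercept.
Defaults (mean current m_cur = 0.2411, turbulence m_turb = 0.8855,
biofouling slopes n_cur = −0.4762, n_turb = +0.1243, bulk intensity
I = 0.8) characterise one container design at 90° angle of attack and are
config-overridable for other designs. Coverage is a fraction in [0, 1]
internally; the CLI and config accept percent spellings and convert,
because the (1 + n·Bio) factors require fractional units. A coverage that
drives (1 + n_cur·Bio) negative is outside the linear model's validity
and raises. Wave orbital amplitudes, when included, are transferred with
the current coefficients — no wave-specific coefficients exist for the
reference container, and the evaluation treats current-plus-wave as one
combined magnitude.

## Dissolved-oxygen budget

Units are enforced at the boundary — concentrations mg/L, volume L, rate
mg/s, length m — so the time constant t = V(DO_sea − DO_lobster)/C
emerges in seconds with no hidden factors. The default budget uses the
case-study values (DO_sea = 8.98 mg/L annual minimum, optimal-growth
limit 6.4 mg/L, maximum consumption 5e-5 mg/s of a 150 g lobster, 97.6 m
array). The container volume is not published; the shipped default
1.109 L is back-derived from the published 15.9 h time constant and is a
placeholder for a real design volume, not an authoritative value. u_DO is
always recomputed from the configured budget, never hard-coded; note the
exact quotient 97.6 m / 15.9 h is 1.7051 mm/s.

## Exceedance statistics

Inequalities at the limits are strict ("less than" / "greater than");
ties count as non-exceeding, a measure-zero choice on continuous data.
Percentages are taken over valid samples only; missing samples (explicit
NaN marks) are excluded from the denominator. The longest continuous run
is the run length in samples times the nominal cadence; a missing sample
or a timestamp gap larger than 1.5× the cadence terminates a run. That
gap policy is a documented choice — deployment records typically contain
servicing gaps whose handling is rarely stated. DO and foraging
conditions use the mean-current internal profile; the mobility condition
is evaluated both without and with the turbulence term, which roughly
triples the peak internal velocity (I·m_turb/m_cur ≈ 2.94). Each height
bin is evaluated independently.

## Synthetic site conditions

The generator emulates the statistical character of a macrotidal bay
rather than any particular record:

* **Currents** — speed(t, h) = shear(h) · tide(t) · noise(t). The shear
  is linear in height above the seabed between the configured long-run
  means (defaults 0.11 m/s seabed, 0.24 m/s surface). The tide is the
  rectified beat of two semidiurnal constituents (M2 at 12.42 h, S2 at
  12.00 h, weights 0.75/0.25), which produces the half-monthly
  spring–neap envelope (14.77 d) with minimal parameters; it is
  normalised by its analytic long-run mean so per-height means equal the
  configured shear regardless of run length. The multiplicative noise is
  mean-one lognormal (σ = 0.15), drawn once per timestamp and shared
  across heights: vertically coherent modulation keeps the instantaneous
  vertical ordering equal to the shear profile, which is also what makes
  the depth-monotonicity properties exactly testable.
* **Turbulence** — per-window Gaussian fluctuations with RMS equal to
  intensity × window mean (default intensity 0.8, the site's maximum
  depth-averaged value). Samples are unclipped so the RMS is unbiased;
  they represent the along-stream component about the mean.
* **DO** — a sinusoidal annual cycle between the configured minimum
  (8.98 mg/L, attained exactly at the configured phase day when noise is
  zero) and maximum. The annual maximum is not published for the case
  study; 10.5 mg/L is used as a realistic winter value for well-mixed
  temperate coastal water.

What the generator does **not** emulate: current direction (the framework
consumes speed magnitude only), the wind-driven mid-column velocity dip
seen in real profiles, storm-surge/wave-driven current extremes, tidal
asymmetry, and DO stratification. Passing tests on synthetic data
therefore demonstrate the statistical machinery and the directional
responses (biofouling raises DO shortfall time, turbulence raises
mobility exceedance, surface bins exceed the foraging limit more than
seabed bins), not site-specific percentages: published field-record
statistics derive from data that is not publicly deposited and are not
reproduction targets.

## Problem sizes and numerical choices

Tests run the generator at 15 days (one full spring–neap beat, so tidal
means are unbiased) for monotonicity properties and 330 days for shear
recovery; 10-min cadence throughout. The dispersion solver is
cross-checked against an independent bisection oracle to 1e-3 m over
random sea states (H ∈ [0.1, 8] m, T ∈ [3, 15] s); the longest-run
statistic against a brute-force all-windows scan on random boolean
series. Timestamps are ISO-8601 and treated as UTC; CSV serialisation
uses 10 significant digits, so file round-trips are exact to well below
measurement accuracy.

## Known limitations

* Transfer coefficients are taken as given for one container design;
  re-deriving them from flume data is out of scope.
* The DO budget is a worst-case single-lobster, fixed-consumption model:
  no temperature/salinity dependence of saturation, no biofouling
  respiration, no size-structured stocking.
* Behavioural limits (0.1 / 0.27 m/s) come from adult-lobster flume
  observations and carry that extrapolation caveat.
* Food availability, temperature, salinity, contaminants and motion
  severity are not modelled; the report structure is designed so further
  limits can be added as they are quantified.
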