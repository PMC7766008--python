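# Methods

This note records the models, conventions and numerical choices behind
`hazemet`, and what the synthetic-data tests do and do not demonstrate.

## Station data: screening, aggregation, gap-filling

Hourly values are screened against closed per-variable intervals reflecting
instrument detectable limits and physically probable ranges: PM2.5/PM10
3–1000 µg m⁻³, temperature −5–50 °C, RH 0–100 %, wind speed 0–50 m s⁻¹,
wind direction 0–360°, rain 0–1000 mm h⁻¹, global radiation 0–1000 W m⁻²,
surface pressure 800–1100 hPa. Out-of-range values are retained but flagged
`out_of_range`, never silently dropped; screening is idempotent. Manual
removal of erratic values is supported only as an explicit user-supplied
exclusion list (station, variable, timestamp) — there is deliberately no
automatic spike detector, so the provenance of every rejected value is
auditable.

Hour convention: the timestamp with clock hour H (0–23) carries local-time
hour label H+1 and covers (H, H+1], so labels 1–24 span one calendar day.
Daily aggregation takes the mean of valid values inside an hour-label
window — the full day by default, 11–16 LT for global radiation (late
morning to mid-afternoon) — and reports a day missing when fewer than 50 %
of the window's hours are valid. The threshold is inclusive: 12 valid hours
of 24 compute a mean. Wind direction is aggregated as a unit-vector mean
(result in [0, 360)); all other variables arithmetically. The daily
PM2.5/PM10 ratio is the daily mean of *hourly* ratios (computed only where
both values are valid and PM10 > 0), not the ratio of daily means — the two
differ whenever the hourly values co-vary, and the tests pin the
distinction on an asymmetric fixture.

Gap-filling regresses the target station on a reference station (OLS,
`target = a + b·reference`) over paired valid hours and fills only hours
that are missing in the target and valid in the reference, flagging them
`filled`. A minimum of 100 paired hours is required to fit; with fewer the
filler refuses and warns. Originally valid hours are never altered.

## Haze events

A haze day requires a non-missing daily PM2.5 ≥ 50 µg m⁻³ (inclusive) at
one station at least. Days where every station is missing are
*indeterminate*: they are never haze days, and by default they break a run
of consecutive haze days (conservative). Because a multi-station network
can carry a day that a single station would drop, segmentation optionally
bridges indeterminate days inside a run (`bridge_indeterminate=True`);
bridged events still begin and end on actual haze days. Episode windows
(pre/haze/post) are pure calendar arithmetic around an event and carry no
haze-freeness guarantee of their own.

## Obukhov length

The solver uses the two-level formulation with virtual-temperature humidity
correction: saturation vapor pressure by the Bolton formula
e_s = 6.112·exp(17.67·T/(T+243.5)) hPa, specific humidity
q = 0.622e/(p − 0.378e), virtual temperature T_v = T_K(1 + 0.608q), and
virtual potential temperature θ_v = T_v(1000/p)^0.2854 with pressure at
each measurement height from the hydrostatic relation
p(z) = p_sfc·exp(−gz/(R_d T_mean)). The single near-surface RH measurement
is applied at both temperature heights; over a 48 m span the error this
introduces in Δθ_v is far below the temperature-sensor noise floor. The
defining relation uses the arithmetic mean of the two virtual temperatures.
When no pressure column is supplied, a constant 1010 hPa is assumed with a
logged warning (appropriate for a low-elevation tropical site).

Stability corrections are the Businger–Dyer/Paulson forms with the
conventional constants (γ = 16 unstable, β = 5 stable):
unstable ζ < 0, x = (1−16ζ)^¼, Ψ_M = 2ln((1+x)/2) + ln((1+x²)/2) −
2arctan(x) + π/2, Ψ_H = 2ln((1+x²)/2); stable Ψ_M = Ψ_H = −5ζ. The tests
verify both against numerical quadrature of the corresponding φ functions.

Numerics: fixed-point iteration on 1/L from the neutral start (Ψ ≡ 0),
relative tolerance 1e-4 on L, at most 50 iterations, with 0.5 damping
applied to the 1/L update whenever successive updates flip sign (the linear
stable correction can overshoot). Degenerate inputs short-circuit:
|Δθ_v| < 0.001 K or an iterate with |1/L| < 1e-6 m⁻¹ return the neutral
closed form u* = kU/ln(z_u/z₀) with L = ±∞ as sentinel; wind below
0.1 m s⁻¹ (anemometer sensitivity) returns no result, flagged `calm`.
Converged hours with ζ = z_u/L > 5 are flagged `very_stable` — outside the
similarity framework's validity — and are meant to be excluded from daily
statistics rather than trusted.

The stable branch has a genuine no-solution regime: for sufficiently strong
stratification relative to wind shear (e.g. U = 2 m s⁻¹ with
Δθ_v = +0.5 K over 2→50 m), the coupled relations admit no root — the
critical-stability property of the −5ζ scheme, physically the collapse of
continuous turbulence. The solver reports `not_converged` with L = NaN
there, and an independent dense scan of the self-consistency residual
confirms no root exists; returning a number instead would be an artifact.

Constants: k = 0.4, g = 9.81 m s⁻², z₀ = 0.25 m (Davenport roughness
class 5, "sparsely built" — a suburban tower site), R_d = 287.05 J kg⁻¹K⁻¹.
Hourly L from the 50 m and 100 m wind levels is combined as the per-hour
mean over finite members (neutral sentinels excluded), with their Pearson
correlation over jointly finite hours reported; on synthetic episodes the
correlation is ≈ 0.999.

## Inversion detection

"Monotonically increasing" is read strictly: an isothermal step terminates
a run (an isothermal layer has IV = 0 and would fail the intensity filter
regardless). The intensity filter is a strict inequality — IV exactly
0.1 °C/100 m is dropped. Band assignment uses the layer *bottom* (a layer
straddling 1500 m counts as low and is not split), bottoms below 100 m are
excluded as surface-radiative, and only levels at or below 4000 m are
considered. Heights are AGL; the Wyoming-format reader subtracts the
station elevation from MSL heights (a 2–4 m correction at a coastal plain
station — retained for generality). IV is invariant to inserting
intermediate levels along a linear warming segment, which the tests check.

## Fire gridding

Cells are half-open [edge, edge + 0.5°) with edges anchored at multiples of
the cell size, so each point lands in exactly one cell and per-period grid
sums equal in-domain point counts exactly (checked against a per-point
brute-force loop). No confidence filtering is applied by default. The grid
anchor (edges on multiples of the cell size) is a convention choice; a
center-anchored grid would shift all indices by half a cell but preserve
every conservation property.

## Synthetic data

The generator emulates the phenomenology of a wintertime cold-surge haze
episode in a tropical megacity. Defaults describe a 7/16/4-day
pre/haze/post January episode: daily-mean temperature 28 °C and RH 65 %
dropping abruptly by 6 °C and 15 % over a 2-day ramp when the surge arrives
on the last pre-haze day, then relaxing back with an 8-day e-folding time;
wind 2 m s⁻¹ roughly doubling while the surge is active; global radiation a
clear-sky half-sine (peak 850 W m⁻²) halved on cloudy pre-surge days; PM2.5
daily means 30 µg m⁻³ rising to 65 µg m⁻³ during the haze phase, with a
±35 % diurnal factor peaking at 04 LT and dipping mid-afternoon, and
PM10 = PM2.5/0.55 with 3 % relative noise. The 2 m→50 m temperature offset
is +0.5 °C daytime (superadiabatic) and −0.6 °C at night (nocturnal
inversion) so both stability branches are exercised. An 8-day December
variant (6/8/5 days) is used where a shorter event is wanted.

Simplifications, stated as such: noise is Gaussian and independent
hour-to-hour (no autocorrelation), stations share the regional signal and
differ only by independent noise, and missing data are injected as
configured consecutive-hour outage blocks. Passing tests therefore
demonstrate the *algorithms* — threshold logic, segmentation, solver
convergence, conservation — under known ground truth; they do not
demonstrate robustness to instrument drift, autocorrelated gaps, or
multi-station spatial structure in real networks.

Sounding scenarios implant strictly disjoint warming layers (bottom, top,
IV) into an otherwise linearly cooling profile (6.5 °C km⁻¹), with levels
on a regular grid plus the exact implant endpoints; detection then recovers
implanted boundaries exactly and IV to machine precision, which is the
round-trip the tests and acceptance script measure. Implants that share a
boundary are rejected, since two adjacent warming runs would merge into one
detected layer.

The similarity-inversion generator (`gen_most_consistent_sample`) builds a
dry two-level sample whose exact Obukhov length is prescribed, by running
the profile relations in reverse and iterating the weak pressure/mean-
temperature coupling to fixed point; solver recovery to well within 2 %
validates both directions.

## Problem sizes

The validation suite runs at desk scale, chosen so the full test suite and
the acceptance script each complete in seconds on one CPU while leaving the
statistics unambiguous: 200 random tower samples against the residual-scan
oracle (20,001-point scan per sample), 100 sounding scenarios, 1,000 random
calendars against the naive segmentation scan, 10,000 hotspots, and
multi-week hourly episodes (≈ 650 hours) for the dual-height correlation.
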