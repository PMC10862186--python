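# Methods

## The model

`ectotemp` reconstructs the hourly body temperature of a small
ground-dwelling ectotherm — the reference parameterisation is an adult
field cricket (*Gryllus campestris*) sitting on bare ground in a meadow —
from near-ground microclimate forcing. The body is treated as a prolate
ellipsoid with zero heat capacity: at every hour the body temperature
T_b is the unique root of the steady-state energy budget

    Q_net(T_b) = Q_solar + Q_lw_gain − Q_lw_loss(T_b) − Q_conv(T_b) − Q_cond(T_b) = 0

with

* **Q_solar** = α · [ S_beam·A_sil + S_dif·(A/2)(1−f_c) + ρ_g·S_tot·(A/2)(1−f_c) ] —
  absorbed shortwave: the direct beam (converted from horizontal flux by
  1/sin(elevation), capped at 1100 W/m² beam-normal) intercepted by the
  silhouette area, plus diffuse sky and ground-reflected flux on the
  upward-facing half of the free surface. α is solar absorptivity, ρ_g
  ground albedo, A surface area, f_c the ground-contact fraction.
* **Q_lw_gain** = ε·A(1−f_c)·[½ e_sky σT_air⁴ + ½ e_g σT_ground⁴] and
  **Q_lw_loss** = ε·A(1−f_c)·σT_b⁴ — thermal radiation with half view
  factors to sky and ground for the free surface. Sky radiance is tied to
  the 2 m air temperature through the effective sky emissivity e_sky;
  e_sky < 1 under clear skies is what lets the body cool radiatively
  below air temperature at night.
* **Q_conv** = h·A(1−f_c)·(T_b − T_air,ground) — forced convection
  against the air at organism height: Re = u·d/ν, Nu = C·Reⁿ with
  Reynolds-banded coefficients (0.615, 0.466 in the 40–4000 band; the
  neighbouring classic cross-flow bands are rescaled for continuity at
  the band edges), h = Nu·k/d, with air conductivity and viscosity
  evaluated at the film temperature from linear fits valid 0–60 °C. A
  free-convection floor h ≥ 5 W m⁻² K⁻¹ keeps still-air exchange
  physical.
* **Q_cond** = (k_sub/t_bl)·f_c·A·(T_b − T_ground) — conduction through
  the contact patch with a fixed substrate conductance
  k_sub/t_bl = 0.30 W m⁻¹ K⁻¹ / 5 mm = 60 W m⁻² K⁻¹ (dry sandy-loam
  surface under a thin contact layer).

Gains are independent of T_b and every loss is non-decreasing in it, so
Q_net is strictly decreasing and the root on [−50, 80] °C is unique.
The scalar solver (Brent) keeps the residual below 10⁻⁶ W; the series
solver uses 90 vectorized bisection halvings of the same bracket, which
is orders of magnitude tighter than the scalar tolerance, and the two
agree to < 10⁻⁶ °C in tests. A brute-force 0.001 °C grid scan serves as
the independent oracle for the solver.

### Geometry

Volume follows from mass and body density (defaults 1.0 g, 1000 kg/m³);
semi-axes from the 3:1:1 axis ratio via V = 4/3·π·a·b·c; surface area by
the Knud-Thomsen approximation (p = 1.6075, within ~1.1 % of the
numerically integrated 3:1:1 ellipsoid area, exact for a sphere). The
characteristic convective dimension is the body length along the wind
(2a ≈ 2.6 cm at 1 g).

### Default organism parameters

| parameter | default | meaning |
|---|---|---|
| mass | 1.0 g | adult field cricket |
| solar absorptivity α | 0.90 | dark-bodied insect cuticle |
| thermal emissivity ε | 0.95 | organic surface in the thermal infrared |
| axis ratio | 3:1:1 | elongate insect body |
| ground-contact fraction f_c | 0.20 | resting posture on bare ground |
| silhouette factor | 0.25 | fraction of A projected to the beam |
| ground albedo ρ_g | 0.20 | bare soil / short grass |
| ground emissivity e_g | 0.95 | soil surface |

These are implementation choices consistent with a dark ground insect;
all are configurable, and the flux constants (convection coefficients,
substrate conductance, air-property fits) are module-level named
constants so a different parameterisation can be swapped in without
structural change.

### Deliberate exclusions

No evaporative water loss (small closed-integument insect at modest
temperatures), no thermal inertia (the hourly step is long against the
equilibration time of a ~1 g body), and no behaviour — no shade-seeking,
basking or burrow retreat. The reconstruction is the *operative*
temperature of an animal that stays put in the open; the 40 °C threshold
in the metrics is where behaviour would take over in reality.

## Synthetic weather

The generator emulates the statistical structure of hourly forcing at a
mid-latitude (~43°N) coastal meadow rather than any particular year of
weather:

* 2 m air temperature = seasonal cosine (amplitude 6 °C, minimum
  mid-January, centred so the May–July mean equals the configured
  16.4 °C) + diurnal cosine (amplitude 5 °C, peak 15:00) + AR(1) noise
  (persistence 0.95, SD 1.5 °C).
* Solar elevation from standard declination/hour-angle formulae; direct
  clear-sky irradiance 1000·sin(elevation) W/m², attenuated by an AR(1)
  latent-Gaussian cloudiness (persistence 0.8, probit-mapped to [0,1])
  that also raises the diffuse fraction (0.15 clear → 1.0 overcast) and
  the sky emissivity (0.70 clear → 0.95 overcast).
* Near-ground air and ground-surface temperature from fixed linear
  transfer rules: +6 °C (air at 1 cm) and +12 °C (ground surface) per
  1000 W/m² of total shortwave, with 1.5/3.0 °C clear-night depressions —
  so the ground is at least as warm as screen air whenever the sun is up,
  by construction.
* Wind at organism height = 0.30 × the lognormal-AR(1) 2 m wind
  (log-profile reduction into short grass); precipitation as Bernoulli
  wet days (configurable dry-day fraction, default 0.55) with gamma
  daily totals spread over a 1–6 h block.

Timestamps are naive local civil time with one fixed UTC offset per run
(default 0); there is no daylight-saving modelling, and the 06–19 h
daytime filter is interpreted in civil time. What the generator does
**not** emulate: weather fronts and multi-day synoptic structure, canopy
radiative transfer, soil heat diffusion, humidity and latent-heat
coupling, or correlated cloud–wind–rain dependence. Tests that pass on
this forcing therefore demonstrate the correctness and physical
behaviour of the machinery, not the climatology of any real site: with
this generator's mild seasons the reconstructed body temperature almost
never reaches 40 °C, whereas hotter forcing readily produces exceedance
hours.

For bias-correction experiments, `distort_series` builds a "coarse
product" from a generated truth by a strictly monotone polynomial warp
plus Gaussian noise, and `distort_precip` adds drizzle to a stated
fraction of dry days — both invertible targets for parameter recovery.

## Bias correction

The transfer fit pairs the two series' empirical quantile functions at
10,000 equally spaced probability points (quantile mapping). Pairing
equally spaced *values* from two unpaired ranges is ill-defined, so the
probability reading is the default; a `paired` mode that regresses
time-matched hourly pairs is provided for when matched pairs exist.
The paired quantiles are averaged into ≤1000 evenly spaced abscissa bins
(raw quantile pairs contain near-duplicate abscissae that make the
spline system numerically singular), fitted with a penalized cubic
smoothing spline whose penalty is chosen by generalized cross-validation
(with a small fixed-penalty fallback when the GCV search is ill-posed on
effectively noise-free data), evaluated on a 10,000-point equally spaced
value grid spanning the union of both ranges, forced monotone by
pooled-adjacent-violators, and linearly continued outside the training
support with the boundary slopes (a spline's polynomial tails are unsafe
when the full record exceeds the calibration range). Monotonicity makes
the applied correction rank-preserving, up to exact ties on pooled
stretches. Fit diagnostics carry the residual RMSE and point counts;
effective degrees of freedom are not reported because the GCV fit does
not expose its hat matrix.

The wet-day adjustment works on daily totals: if the coarse record has
fewer dry days than observed, the coarse days with the smallest positive
totals are zeroed (earliest first on ties) until the dry-day fractions
agree to the nearest whole day. It never increases precipitation and
never touches a day already at zero.

## Metrics

Daytime is hourly stamps 06:00–19:00 inclusive (14 per day), the season
May–July; both are configurable. Per year: mean offset
(T_b − T_air,2m) with its standard error; degree-hours above air as the
positive part of the offset summed over hours with T_b ≤ 40 °C (hours
above the shade-seeking threshold are excluded from this metric only —
the animal would be in shade — not from the offset mean or the
regressions); and counts of hours strictly above 40 °C for body and air.
Offsets are computed against the 2 m air temperature while convection in
the heat budget uses the near-ground air temperature — the offset is the
quantity a screen-height weather record would get wrong. Missing hours
are skipped, never imputed, and per-year coverage counts are reported.
Regressions are ordinary least squares via statsmodels.

## Problem sizes and numerical choices

The analysis drivers use one season (2,208 h) for the single-year runs
and ten years (87,648 h) for the between-year comparison; both complete
in seconds thanks to the vectorized solver. The radiation sweep in the
acceptance script uses 50 levels over 0–1000 W/m² under fixed warm
forcing (air 22 °C, wind 0.5 m/s, ground warming linearly to 40 °C at
full sun, sky emissivity 0.95 for warm humid maritime air, beam
conversion at the midsummer midday elevation of 70°). Solver tolerance
is 10⁻⁶ W residual; ties in the wet-day adjustment break
deterministically by date; all randomness flows from one seeded
generator per run.

## Known limitations

* The flux coefficients (convection correlation, substrate conductance,
  silhouette factor) are literature-plausible defaults, not fitted to
  any measured cricket; absolute body temperatures carry their
  uncertainty even though the qualitative structure (radiation-driven
  offsets of 10–20 °C, radiative cooling below air at night) is robust
  to them.
* The steady-state assumption overstates minute-scale excursions during
  rapidly varying cloud; at the hourly scale this is negligible for a
  1 g body but would not be for a 100 g one.
* Each weather variable is bias-corrected independently; no multivariate
  or copula coupling.
* The synthetic generator's limitations listed above mean site-level
  statistics (e.g. exceedance-hour counts) should not be read as
  predictions for any real meadow.
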