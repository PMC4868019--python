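# Methods

This note documents the models and procedures implemented in `gullforage`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Geometry and time

All coordinates are WGS84 decimal degrees; all distances are great-circle
(haversine, Earth radius 6371.0088 km). At the ≤ 100 km ranges of a
breeding gull the difference to an ellipsoidal distance is well under the
GPS error of a 300 s fix interval, so no map projection is used. All
timestamps are UTC. The only "local time" notion in the package is the
local solar calendar day (UTC shifted by longitude/15 h), used to decide
which day's sunrise a trip departure is compared against and which calendar
day a departure falls on for the breeding-stage windows; this avoids any
dependence on civil time zones or DST.

Sunrise is computed from the NOAA low-precision solar series (equation of
time + declination, sun centre at −0.833° altitude). Against published
ephemerides this is accurate to about ±2 min at mid latitudes, far below
the 2 h spread of the departure-time process it feeds. Latitudes ≥ 66° are
rejected (polar day/night).

## Trip segmentation

A trip opens at the first fix > 500 m from the individual's nest following
a fix within 500 m, and closes symmetrically. Departure and return
instants are the midpoints of the bracketing inside/outside fix pairs —
unbiased under regular sampling; the raw fixes carry no information about
the crossing instant beyond the bracketing interval. Excursions already
open at the start of a track, or still open at its end, have an
unbracketed endpoint and are flagged incomplete; they are excluded by the
default filter because their duration and return covariates are undefined.

Filter defaults (all surfaced in `FilterConfig`): duration ≥ 30 min,
maximum colony distance ≥ 3 km, ≥ 5 raw fixes, largest internal gap ≤ 50 %
of trip duration, complete trips only, departure inside the May 20 –
July 21 focal window (extendable to April 30 for pre-laying analyses).
These are working conventions for "adequately sampled foraging trip", not
measured constants; every exclusion is logged with its reason so the trip
accounting is auditable.

Interpolation resamples each trip's positions (and speeds) linearly in
time onto a regular grid at the sampling interval (default 300 s), so each
grid point represents an equal slice of trip time and the per-trip land
proportion reads as a proportion of foraging *time*. Grid points inside
raw gaps longer than 45 min are omitted rather than bridged — linear
bridging across multi-hour gaps would fabricate locations.

## Foraging classification

A (grid) fix is a likely foraging location iff its speed lies in
[v_low, v_high] and it is ≥ 3 km from the colony. Defaults v_low = 0,
v_high = 4 m/s: at 300 s sampling, displacement speeds of gulls in
flapping flight sit well above 4 m/s while walking, swimming and
search-on-foot sit below it; the 3 km exclusion removes loafing and
bathing near the colony. Both thresholds are mandatory, visible
configuration — they are the analysis's main tunables and the right values
are colony- and logger-specific.

Habitat is assigned by boundary-inclusive point-in-polygon membership
against the land mask (a gull standing on the waterline is on land; any
single consistent rule would do, but it must be consistent).

`p_land` is the fraction of a trip's foraging points on land. Trip classes
are sea (< 0.05), mixed (0.05–0.95, boundaries inclusive — the printed
class bounds are strict inequalities for sea and land, so exact equality
falls to mixed), land (> 0.95), or unclassified when a trip yields no
foraging point at all (e.g. pure transit). Unclassified trips remain in
the trip table but drop out of the binomial models, which need a positive
trial count.

## Binomial mixed models

The proportion response is modelled as a weighted binomial: successes
= n_land, trials = n_forage_points per trip, logit link, with a Gaussian
random intercept per individual; the field-survey analysis uses Bernoulli
presence/absence with field-within-transect nested intercepts. Modelling
the proportion with its point count as the denominator is the natural
binomial reading of a per-trip proportion; it also reproduces the drop of
zero-denominator (unclassified) trips from the model table.

Estimation maximises the Laplace approximation to the marginal
log-likelihood. For a single grouping factor the inner mode search is a
per-group scalar Newton iteration (vectorised across groups); for nested
intercepts the joint mode over the stacked random-effect vector is found
by full Newton steps with the dense penalised Hessian (≤ 60 dimensions at
the field-survey design). The outer optimisation is bounded L-BFGS-B over
(β, log σ), started from the no-random-effect IRLS fit, with log σ bounded
in [−7, 4]; convergence is the optimiser's own criterion and is reported
as a flag, never silently ignored. The log-likelihood includes the
binomial combinatorial constant, so values are comparable with other
software: on shared fixtures the fit agrees with R's `lme4::glmer` to
about four significant figures in log-likelihood, coefficients and the
variance component (verified in the test suite). An adaptive Gauss–Hermite
quadrature evaluation (≥ 9 nodes; mode-centred, curvature-scaled) is
available for single-grouping models as an independent check of the
Laplace value; the suite requires agreement within 0.1 on fixtures up to
50 groups.

Model comparison: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = number of
fixed coefficients + number of variance components and n = number of rows.
Counting variance components in k must be fixed one way for rankings to be
self-consistent; this convention reproduces the degrees of freedom printed
for the reference model set (e.g. intercept-only = 2). Marginal and
conditional R² follow the latent-scale variance decomposition for logit
models: σ²_f is the population variance of the fixed linear predictor over
the data, the residual is π²/3, marginal = σ²_f / (σ²_f + Σσ²_rand +
π²/3), conditional adds Σσ²_rand to the numerator. Standardisation centres
numeric predictors and divides by two standard deviations (binary
predictors centred only), making binary and continuous coefficients
directly comparable. κ is the exact 2-norm condition number of the
fitted fixed-effects design including the intercept, with κ < 10 the
conventional acceptability bound. Single-term deletions respect
marginality (mains under a retained interaction are not dropped) and use
χ² = 2Δℓ with df = number of coefficients removed.

## Repeatability

Adjusted repeatability is computed on the latent scale from the
standardised best model: r = σ²_ind / (σ²_ind + π²/3). The latent scale is
used because the response's trial counts vary per trip, making
observation-scale variance heterogeneous; the analysis's own R²
decomposition is latent-scale for the same reason. The permutation test
shuffles individual labels across trips, refits, and reports
p = (1 + #{r_perm ≥ r_obs}) / (n_ok + 1); the plus-one correction keeps
p > 0 and matches the conventional "< 1/(N+1)" floor. The confidence
interval is a percentile parametric bootstrap: simulate new responses from
the fitted model (fresh Gaussian intercepts + binomial noise at the
observed trial counts), refit, recompute r. Percentile intervals from this
scheme undercover with few groups: at 19 groups the measured coverage of a
nominal 95 % interval is only ~85–88 % (the ML variance estimate is biased
low and left-skewed, and even an interval built from the true sampling SD
reaches only ~93 %), recovering to ~93 % by 40 groups. This is a known
property of percentile bootstrap for variance ratios, accepted here for
its simplicity and convention; the suite's calibration test runs at 40
groups, and intervals reported for a 19-bird dataset should be read as
slightly narrow.
Every resampling refit is cold-started: warm-starting from the observed
fit can strand the optimiser on permuted data.

## The synthetic scenario

The generator's default configuration ("S1") encodes the study conditions
the pipeline is calibrated against: 19 individuals over three breeding
seasons (May 20 – July 21, 2011–2013) producing ≈ 1038 trips at 300 s
sampling with short logger gaps; a land/mixed/sea trip mixture of
(220, 93, 711)/1024 of classified trips with a 14/1038 unclassified rate;
class-wise lognormal durations (medians 6.2/11.3/3.9 h) and maximum
distances (20.8/39.3/23.2 km) matched to printed medians and IQRs by
quartile-matching (σ = ln(q75/q25)/(2·0.6745)); land-trip departures
wrapped-normal around 1 h before sunrise (SD 2 h) against uniform
departures for marine trips; 6-hourly AR(1) colony weather (cloud clamped
to [0,100] %, rain co-varying with cloud); and a between-individual
propensity SD of 3.7945 on the logit scale, i.e. a latent intraclass
correlation of 0.814.

Habitat choice: each trip carries a latent land propensity
η = b_i + β'x + e (e standard logistic, so the latent within-individual
variance is exactly π²/3), and a class-decision score b_i + β'x + κe with
κ = 0.5 — birds choose *where to go* more consistently than the scatter of
their individual foraging points implies; with κ = 1 no 19-bird cohort can
jointly exhibit a 69 % pure-sea mixture and an individual repeatability of
0.81, because class mixing dilutes even strongly terrestrial birds.
Classes are allocated by rank of the score so the configured mixture is
reproduced exactly at cohort level. Within the sea and land bands, trips
sit at a fixed depth d inside the printed class bands (a "pure marine"
trip still yields a small share of land-side points); d is self-calibrated
per cohort by root-finding so that the spread of the birds' expected
aggregate land rates on the logit scale equals the configured
between-individual variance, floored at 0.005 so every bird's expected
land-point count stays estimable. Mixed-band fractions are kept interior
([0.08, 0.92]) so rendering jitter cannot flip a class. Two cohort-level
calibrations stabilise the 19-bird design: the individual intercepts are
moment-standardised to the configured SD (with 19 birds the χ²₁₈ noise of
a free normal sample's variance would otherwise dominate every
variance-component check), and the class thresholds/depth are computed on
the realised cohort. The cohort is the study condition, not an estimate of
one.

Trips are rendered as contiguous fix-slot blocks — out-commute, sea bout,
transfer, land bout, return — with commute speeds 8–25 m/s chosen to fit
the drawn duration (durations are never altered; infeasible
duration/distance pairs shrink the distance instead) and foraging-walk
speeds 0.4–3.2 m/s around the bout target. Land targets lie ≥ 9.5 km into
the mainland polygon (a 100 km rectangle starting 7 km east of the colony
islet) so foraging walks cannot cross the coast; sea targets take westward
bearings. "Unclassified" trips are rendered as transit-only (4.5–7 m/s
throughout), which yields no foraging point downstream.

What the generator does **not** emulate: real coastline geometry, wind- or
energetics-dependent movement, area-restricted search structure within
bouts, seasonal trends in the class mixture (the printed decline of
terrestrial foraging across stages is not built in), device-specific error
models, or nest attendance patterns beyond bracketing fixes. Passing the
recovery tests therefore demonstrates that the pipeline correctly measures
the statistical structure it targets — not that it would be robust to
every pathology of real tracking data.

The field-observation generator produces the full 10 transects × 5 fields
× 3 periods × morning/evening design (300 rows): per-field-period
vegetation from five lognormal quadrats with medians rising across periods
(12/22/35 cm) but high within-period spread, presence of the focal gull
from a logistic model (height slope −0.08 per cm, period effects 0/−0.7/
−1.4, σ_transect 0.5, σ_field 1.0), and co-occurring species counts whose
rates fall with vegetation height, producing the positive gull–gull and
gull–wader associations through shared habitat preference rather than
direct interaction.

## Problem sizes used in the checks

The automated checks run the standard scenario at full scale (≈ 1030
trips, 19 birds); GLMM calibration suites use 100 replicates at ~1000 rows
and 19 groups (coefficient coverage), 200 small replicates (deletion-test
type-I), 100 datasets × 60 bootstrap refits at the 19-group scale
(interval coverage), and 100 replicates of the 300-row field design
(ranking recovery); the permutation test runs its full 1000 iterations,
the bootstrap check 200. These sizes keep each recovery statistic's own
sampling noise comfortably inside the tolerance it is tested against.

## Known limitations

- The Laplace approximation is least accurate for Bernoulli responses
  with few observations per group (the field design); the AGQ check
  bounds the error on single-grouping fixtures only, and nested fits rely
  on the lme4 cross-check at moderate scale.
- Variance components are estimated by ML (not REML-like corrections), so
  σ̂² is biased slightly low with few groups; the bootstrap CI inherits
  this.
- `derive_speed` assigns displacement speed to the later fix; across data
  gaps this underestimates true speed, which is why generated
  ground-truth checks compare only regular-cadence fixes.
- The weather summary interpolates linearly between 6-hourly points;
  sub-6 h weather structure is invisible.
- Exact duplicate timestamps are resolved by keeping the first fix; with
  heavily corrupted logger data a smarter resolution would be needed.
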