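# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic-data tests do and do not establish about
real logger data.

## Data model and alignment

Loggers are ingested from CSV exports (`timestamp,temperature_c`),
timezone-naive local clock time.  Body loggers record hourly, ambient
loggers every 15 min; ambient readings are averaged onto half-open,
left-labelled hours [t, t+1h) and matched to the body timestamps.  Each
sample is taken to cover one cadence interval, so two loggers overlap if
their coverage intervals (first timestamp to last timestamp + cadence)
share at least one hour.  Duplicate timestamps are collapsed by mean
(symmetric and deterministic); gaps are kept as missing rows and never
interpolated — every downstream stage tolerates missing hours.  Logger
calibration is an OLS map of reference (water-bath) temperature on logger
temperature, applied pointwise.

Weekly body masses are carried forward within each week; the weekly mass
change ΔM_B is the difference between consecutive weekly values (zero in
the first week).  Daylength comes from the standard solar
declination/hour-angle formula at the site latitude (sunrise/sunset at
solar elevation 0°, no refraction).  At 39.65° S this gives a
seasonal daylength change of ≈ 4.5 h over an April–October season; because
published daylength figures rarely state their horizon convention, tests
treat that value as approximate (±0.5 h).

## Torpor classification and bout segmentation

No universal operational torpor criterion exists, so the classifier is a
configurable rule, with an explicit default rather than an implicit one:
torpid iff T_B < min(30 °C, rolling euthermic median − 5 °C), where the
euthermic median is computed over readings ≥ 30 °C in a 7-day window.  The
5 °C margin is wide enough that euthermic variation of a few degrees never
produces false bouts; an absolute-threshold mode exists for comparability
with fixed-cutoff studies.  Raising the threshold can only add torpid
hours (monotonicity, property-tested).

Maximal runs of equal labels become bouts (torpor or interbout euthermy);
the bout boundary is the first sample of the new state and durations count
one cadence interval per sample.  Missing gaps ≤ 2 h bridged by agreeing
labels inherit them; longer or disagreeing gaps split the record.  Runs
shorter than the configured minima (default 1 h each) that sit between two
runs of the opposite label are absorbed.  With minima at zero the
segmentation is exactly run-length encoding, which is what the brute-force
oracle test asserts.  The hibernation season of an individual spans its
first torpid sample to the end of its last torpor bout; IBE statistics use
only euthermic intervals strictly inside that span.  Multiday torpor is
flagged at > 24 h; a bout > 2 days marks the hibernation-capable phenotype.

Cohort torpor incidence mimics weekly spot checks: one census per period
(12:00 on the period's first day); an individual with no sample at the
census leaves the denominator for that period.

## Thermoregulatory polygon and T_Bmin

Torpid points are examined in the (T_A, T_DIFF) plane.  Thermoconformers
sit near a small constant differential MR/(C_min·M_B); below the critical
ambient region the defended floor produces the signature line
T_DIFF = T_Bmin − T_A with slope −1.  The edge selector operationalizes
the manual "take the bottom-left edge of the plot" procedure:

1. bin torpid points by T_A (default 1 °C bins, ≥ 3 points per bin);
2. locate the lower edge in each bin at the 5 % quantile of T_DIFF and keep
   points within a 1 °C tolerance band above it.  Keeping only points *at
   or below* the quantile would retain the lower tail of the measurement
   noise around the defended floor and bias T_Bmin downward by roughly two
   noise standard deviations; the band keeps the floor cluster roughly
   symmetric instead;
3. gate on slope: a rolling OLS over three consecutive bins must have
   slope ≤ −0.7 (the inverse-proportionality signature); only the maximal
   contiguous low-T_A run of gated bins survives;
4. drop the topmost bin of that run — it straddles the critical ambient
   region where defended and conforming differentials overlap, and its
   points contaminate the defended cluster.

An empty selection (with a warning) means the animal never thermoregulated
in torpor.  T_Bmin is the mean of T_DIFF + T_A over the selected points —
the mean defended body temperature — rather than the regression intercept,
which would conflate slope error whenever the fitted slope is not exactly
−1; the regression (slope, intercept, R²) is reported alongside.  The
estimator needs ≥ 5 points spanning ≥ 2 °C of T_A, and warns when the
fitted slope leaves [−1.3, −0.7].

On simulated winters with T_B measurement noise of 0.3 °C this recovers
defended floors of 1–5 °C with a median absolute error of ≈ 0.08 °C.  Note
a design consequence: a floor is only observable if the environment drops
well below it, so the floor-sweep test places the chamber mean 3 °C under
each floor.

RMR is reconstructed as C_min·M_B·(T_B − T_A) with the literature
conductance constant C_min = 3.4848 J g⁻¹ °C⁻¹ h⁻¹ (C_min is taken as
given, never estimated from the data).  The torpor-thermoregulation
regression uses *total* RMR in kJ h⁻¹ (mass folded in per record) so that
pooled fits across individuals of different mass are meaningful; for an
individual defending a constant T_B it satisfies slope = −C_min·M_B and
intercept = C_min·M_B·T_B to machine precision, which the tests use as an
analytic identity.

## Driver models and selection

The response is the thermal differential T_DIFF (a continuous proxy for
torpor depth; dichotomising torpor is avoided because such models converge
poorly).  Nine candidate Gaussian mixed models are fixed a priori: food;
food + T_A; food + T_A + photoperiod; those plus ΔM_B; and the two-way
interactions food×T_A, food×photoperiod, T_A×photoperiod, T_A×ΔM_B,
photoperiod×ΔM_B — each with independent crossed random intercepts for
individual, week and date (the food-only model carries individual and date
only).  The food factor is coded with *ad libitum* as the reference level,
and the reference is stated in every coefficient table.  Body mass and the
day-to-day photoperiod change are deliberately excluded as covariates
(redundant with photoperiod and ΔM_B).

Fitting is by maximum likelihood, not REML, because candidates differ in
fixed effects and their AICc values must be comparable; a `reml=True`
switch exists for variance-component reporting.  The solver profiles out
the fixed effects and the residual variance analytically and optimises
only the log variance ratios via the Woodbury identity, so each fit costs
a few Cholesky factorizations of a q×q matrix (q = total random-effect
levels) regardless of n.  L-BFGS-B runs from three starts (the profiled
surface can trap a single start at a variance-zero boundary) with a
Nelder-Mead polish when the line search ends abnormally.  ML and REML
log-likelihoods agree with statsmodels' `MixedLM` to < 1e−3 on reference
fits, which the test suite checks as an independent oracle.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = fixed effects (including the
intercept) + one variance per random term + the residual variance; this
counting convention is stated in the output manifest because "df" columns
in the literature are ambiguous.  Akaike weights are
exp(−Δᵢ/2)/Σ exp(−Δⱼ/2) over converged fits.  Collinearity is screened
per candidate by VIF_j = 1/(1−R²_j) of each fixed-design column on the
others (intercept excluded from the columns, included in the auxiliary
regressions); a single-column design has VIF 1 by convention, perfect
collinearity reports +inf, and VIF > 3 is flagged.  Fixed-effect p-values
are residual-df t tests; they are reported for orientation, not as exact
replications of finite-sample df corrections (e.g. Kenward–Roger), which
are estimator-specific and outside scope.

The selection-recovery test generates frames from the food×photoperiod
structure (photoperiod main effect +10 °C per unit z-scored daylength,
interaction −3, unit random SDs, residual SD 2, n = 5000) and requires the
generating candidate to win AICc in ≥ 80 % of 20 replicates with the
interaction sign recovered in ≥ 95 %.

## The simulator

The generator is a study-design twin, not a fitted model.  Body
temperature obeys c_body·M_B·dT_B/dt = MR − C_min·M_B·(T_B − T_A) with
tissue specific heat c_body = 3.47 J g⁻¹ °C⁻¹ (a typical mammalian value;
a simulator constant only).  Within each behavioural state the balance is
a linear ODE, so the integrator applies the exact exponential update per
hourly step (e-folding time c_body/C_min ≈ 1 h) instead of explicit Euler
sub-stepping — unconditionally stable, and the closed form *is* the test
oracle for cooling trajectories.  States:

- **euthermic** — T_B held at the 35 °C set point; MR = max(basal,
  C_min·(35 − T_A)) per gram, with basal 20 J g⁻¹ h⁻¹;
- **entering / torpid-conforming** — MR drops to 25 % of basal; T_B
  relaxes toward T_A + MR/(C_min·M_B) ("entering" while still > 1 °C above
  its target);
- **torpid-thermoregulating** — engaged when the passive update would
  cross the defended floor `t_bmin_true` (default 3.6 °C): T_B is clamped
  at the floor and MR rises to C_min·M_B·(floor − T_A) exactly;
- **arousing** — MR at a peak of 150 J g⁻¹ h⁻¹ until the set point is
  regained (rewarming from ~4 °C completes within ~1–2 h).

Records carry the state prevailing during the hour and T_B at the end of
it — what an implanted hourly logger samples — plus ground-truth bout ids.
Torpor entry is decided once per night (18:00; the species is nocturnal)
with hazard entry_rate·exp(0.35·(12 − daylength) + 0.7·[food restricted]);
arousal is an hourly hazard arousal_rate·exp(0.30·(daylength − 12)).  The
baselines (0.9 per night, 0.13 per hour) were set so that a full simulated
season reproduces the reported field conditions — on the order of 140–160
bouts per animal, mean bout duration in the teens of hours with a
multiday tail beyond 100 h, and interbout euthermy around a day.  Fasted
animals (the ramp protocol removes food entirely) are additionally forced
into torpor once T_A ≤ 1 °C and do not draw arousals below T_A = 0.5 °C:
rewarming at sub-freezing ambient is energetically prohibitive, and this
makes the ramp behaviour — torpid and floor-defending throughout the
sub-zero days — deterministic rather than merely likely.

The ramp protocol steps 1 °C per day from 5 °C down to the −2.4 °C
equipment floor (held two days), rests a week at 15 °C, then climbs
1 °C/day to 28 °C with food restored at the warm ramp.

The environment is annual-mean + seasonal sinusoid (minimum at the winter
solstice) + diel sinusoid (minimum at 05:00) + Gaussian noise; defaults
(mean 10 °C, amplitudes 7 and 3 °C, noise 1.5 °C) put April–October
monthly means in the 3–17 °C band at 39.65° S.  Cohorts draw masses
uniformly from 26–55 g, defended floors from N(3.85, 0.25²) °C, and split
food treatments evenly; weekly metadata masses drift down under
restriction and up ad libitum.

**What the simulator does not capture.**  Real records include logger
drift, behavioural thermoregulation (huddling, nest insulation),
evaporative water loss, digestion energetics, and drivers beyond
photoperiod/food/T_A.  Two consequences matter for interpreting tests.
First, simulated T_DIFF contains −T_A mechanically (euthermic T_DIFF =
35 − T_A), so on full-physics simulations the AICc winner among the driver
candidates is typically the T_A × photoperiod model; the selection-recovery
tests therefore generate frames from the candidate structure itself rather
than from the physics simulator.  Passing them shows the selection
machinery ranks correctly — not that photoperiod×food is identifiable from
any particular field season.  Second, detection agreement (≥ 95 % per-hour
against ground truth, ≥ 95 % of bout boundaries within ±1 h) is measured
under the generator's noise model; heavier-tailed sensor noise would
require widening the classifier margin.

## Determinism and degenerate inputs

All stochastic stages consume explicit integer seeds (cohorts spawn
per-individual seeds from one root), and a pipeline run is byte-identical
given the same configuration and seed.  Degenerate inputs fail loudly and
specifically: empty or >1 %-unparseable logger files, zero-variance
calibration, non-overlapping loggers, all-missing T_B, AICc with
n ≤ k + 1, polar latitudes.  Degenerate *analyses* degrade gracefully
instead: zero detected bouts yields an all-NaN summary (not an error),
an all-conforming animal yields an empty edge set with a warning,
single-level grouping factors are dropped with a warning, singular
variance components are retained but flagged, and non-converged candidates
are excluded from the ranking with a warning.
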