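# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the test suite does and does not establish.

## Data model and censoring

Measurements are air (µg/m³, expressed as µg NCO/m³ for cross-species
comparability) or urine (µg/L) records with an explicit LOQ and a censoring
flag. Values below the LOQ are substituted with LOQ/2 before any statistics
or reconstruction; the substitution is idempotent and rejects censored
records without a positive LOQ. Air concentrations of a diisocyanate are
converted to NCO mass by the species' NCO mass fraction
(2 × 42.017 / MW, with MW computed from the molecular formulas: MDI 250.25,
TDI 174.16, HDI 168.20, IPDI 222.28 g/mol).

Quantiles throughout use linear interpolation between order statistics at
plotting positions (k−1)/(n−1), so the empirical inverse CDF spans exactly
the observed range (min at p=0, max at p=1). The printed summaries the
package emulates do not determine the estimator uniquely; the convention is
a package-wide parameter (`method=` on the summary and fitting functions).
Exceedance counting against an exposure limit is strict (>), matching
compliance language. Display percentages round half away from zero to one
decimal; case counts round half away from zero to integers (this
reproduces, e.g., 81 cases from 80.6).

## Synthetic data

The registry behind the emulated datasets is not public, so the generator is
a first-class module. Urinary (and air) concentrations are drawn from a
two-component lognormal mixture: every record has a background component
(GM/GSD), and an `exposed_fraction` of records additionally receives an
occupational component (GM/GSD). A single lognormal cannot simultaneously
produce the observed 10–30% quantifiable fractions and the large max/P95
ratios; the mixture can. Creatinine is drawn lognormally with mean 1.36 g/L
(the population mean used for creatinine conversion) and GSD 1.4. All
randomness flows through one seeded `numpy.random.Generator`; truth values
are retained beside the censored view so reconstruction can be scored
against known inputs.

The packaged sector fixtures (`data/fixtures.yaml`) were calibrated once —
analytic mixture reasoning plus a small randomised search — so each
fixture's n, %≥LOQ and GM/P95 fall within the published sector bands, and
frozen with their seeds. Two caveats: (i) for two TDA groups the printed
combination GM ≈ LOQ/2 with P95 < LOQ is unattainable under a single LOQ
(the source laboratory LOQs spanned 0.1–0.6 µg/L), so those fixtures use a
lower representative LOQ within that span; (ii) the generator has a single
total-variance knob per component — it does not separate between-worker
from within-worker variance, which the emulated summaries cannot constrain.
Passing fixture tests therefore show the pipeline behaves correctly on data
with the right censoring structure and skew, not that it reproduces any
particular workplace.

## Kinetic model (MDI/TDI)

Reverse dosimetry for MDI and TDI uses a one-compartment linear model with
an exact piecewise-exponential solution. During a shift the body burden obeys
dB/dt = R − kB with intake R = absorbed_fraction × ventilation_rate × c_air
and k = ln2 / half-life; between shifts dB/dt = −kB. Composing the two
closed-form maps over the work schedule (default 12 weeks × 5 days × 8 h,
urine sampled post-shift on the last working day) gives the burden without
numerical integration; the urinary diamine concentration is the excretion
rate divided by urine flow, u = f_u · k · B / urine_flow. Everything is
linear in c_air, so the model is evaluated once at unit concentration and
scaled — the property the whole inversion relies on.

The model deliberately operates on NCO-expressed air concentration: with
linear kinetics the choice of DI-mass vs NCO-mass units is a pure rescaling
absorbed into the urinary-yield parameter, and keeping the whole
reconstruction in NCO units avoids a conversion round-trip.

Default parameters (`data/defaults.yaml`) are order-of-magnitude stand-ins,
not fitted values: absorbed fraction 0.2, ventilation 1.25 m³/h (light
work), urinary excretion fraction 0.1, urine flow 0.0625 L/h (≈1.5 L/day),
elimination half-life 24 h for MDI (slow MDA kinetics) and 6 h for TDI
(faster diamine elimination), observation-error GSD 1.5. They are
configurable per species; all correctness claims rest on oracle and
recovery properties that hold for any admissible parameter set, and the
per-draw outputs are exportable for audit. Parameter uncertainty of the
kinetic model itself is not propagated.

## Bayesian inversion

For one background-subtracted urinary level u > 0, the posterior over the
air concentration c has a lognormal likelihood
ln u ~ N(ln(A·c), ln²GSD_err) with A the unit response of the kinetic
model, and a half-normal prior (default scale 100 µg NCO/m³) supplying weak
information plus the positivity constraint. The Metropolis–Hastings sampler
uses a lognormal random-walk proposal (default log-scale SD 0.5, giving
20–50% acceptance on realistic inputs) with the multiplicative-walk Hastings
correction, initialised at the noise-free inverse u/A; burn-in (default 200
of 500 iterations) is discarded and degenerate acceptance rates (<1% or
>99%) raise a warning. Correctness is checked against an independent
dense-grid trapezoid-normalised posterior: MH quantiles agree within 3%
across the 5th–95th percentile band.

A known statistical property, documented rather than hidden: with an
(effectively) flat prior in c, the posterior mean of c is the noise-free
inverse times exp(1.5·ln²GSD_err) — ≈1.28 at GSD 1.5. Arithmetic-mean
recovery of a known truth is therefore only meaningful when the assumed
error GSD matches the data-generating noise, and the recovery tests use a
self-consistent moderate GSD of 1.25 (bias ≈ 8%), verifying the machinery
rather than cancelling the skew. On real data, where the error GSD is a
judgement call, reconstructed AMs inherit this conservative (upward) tilt.

## HDI calibration

No kinetic model is used for HDI. Urinary HDA is converted to µg/g
creatinine (using the record's creatinine where present — the sector mean of
available values — otherwise the default 1.36 g/L) and the log10–log10
regression HDA = f(HDI) with slope 0.4396 and intercept 0.4612 is inverted
algebraically, then converted to NCO mass. Inversions whose input or output
fall outside the calibration's validity ranges (1.36–27.7 µg HDA/g
creatinine; 0.3–97.7 µg HDI/m³) are flagged, and the flagged fraction is
reported per reconstruction; the round-trip forward∘inverse is exact to
1e-10 over the validity range.

## Sector Monte Carlo integration

Per sector/analyte: fit the empirical inverse CDF to the LOQ-substituted
values, then per MC iteration (default 10,000) sample one urinary level,
subtract the 0.2 µg/L background (clamped at zero), and invert. For MDI/TDI
the inversion runs one MH chain per iteration, vectorised across iterations,
and keeps the final post-burn-in state — a genuine posterior draw — so the
retained draws carry both population variability and inversion uncertainty.
Zero-clamped draws reconstruct to zero exposure: they enter the arithmetic
mean and P95 but are excluded from the geometric mean, which is undefined at
zero (an `include_zeros_in_gm` switch instead returns a zero GM whenever any
draw clamps, for users who prefer the degenerate-limit convention). In
heavily censored groups the conditional GM can therefore exceed the AM; the
reported `fraction_below_background` makes the conditioning explicit. A
sector whose sampled distribution lies entirely at or below background is
rejected with an explanatory error rather than reported as zero.

## Dose–response and HIA

The excess-BHR-risk relation is a table of risk bands from 0.1% (below
0.025 µg NCO/m³) to 5% (above 0.67 µg NCO/m³). Two evaluation modes:

- **Band lookup** returns the printed risk of the containing band; in gaps
  between bands the lower band's risk applies (risk never decreases with
  exposure), below the first band the lowest risk, above the last band's
  lower bound the highest tabulated risk.
- **Spline** interpolation: a shape-preserving cubic (PCHIP) through the
  band midpoints with a (0,0) anchor — midpoints being the
  minimal-assumption summary of each printed range — continued linearly
  above the last knot with the terminal PCHIP slope and capped at 7.5%, so
  the few very high reconstructed draws never extrapolate beyond the
  reported relation. The spline is monotone and bounded in [0, 7.5] by
  construction, and equals the band risks exactly at the midpoints.

Sector excess risk is the capped spline averaged over all reconstructed
draws; excess cases are the *unrounded* risk applied to the sector's mean
exposed-worker count (display rounds risk to one decimal). Worker counts for
new data take the midpoint of the available range estimates rounded to the
nearest hundred; the packaged per-group means are shipped as printed because
the source's own rounding of two midpoints (5750→5700, 9350→9300) follows no
recoverable rule. A task-split helper apportions one sector's workers across
analyte-specific tasks (fractions summing to ≤1) to correct the
double-counting that arises when every analyte's risk is applied to the
whole sector.

## Orchestration and reproducibility

The CLI (`dihia simulate|reconstruct|hia|report`) drives the chain from one
YAML config merged over packaged defaults; per-group seeds are derived from
the run seed via `numpy.random.SeedSequence`, so results are independent of
execution order, and a manifest (config snapshot, seeds, output digests,
version, timings) accompanies every run. Identical config + seed reproduces
byte-identical tables. Stage failures remove partial outputs and name the
failing stage.

## Problem sizes in the test suite

The suite runs in a few seconds by choosing sizes where the checked property
is already sharp: grid-oracle comparisons use single chains of 60,000
iterations against a 20,000-point grid; sector recovery uses 40 urine
samples and the full 10,000 MC iterations; sampler-convergence checks use
1e5 draws; the kinetic Euler oracle steps at 5 ms over the full 12-week
schedule (global error well below the 0.1% tolerance); the demo pipeline
uses 2,000 MC iterations per group.

## Known limitations

- The kinetic stand-in has one compartment and no dermal-route submodel;
  routes enter only implicitly through the biomarker.
- Kinetic parameter uncertainty is not propagated; only observation error
  and population variability are.
- The generator does not model between- vs within-worker variance
  components, multiple LOQs within a group, or temporal trends.
- The dose–response is used as published; no re-derivation from its source
  cohorts, no peak- or dermal-exposure axis, and BHR — not asthma — is the
  endpoint.
- Applying a sector's urinary distribution to all exposed workers in that
  sector can double-count when different tasks use different diisocyanates;
  the task-split helper exists precisely to explore that sensitivity.
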