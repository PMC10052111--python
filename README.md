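# dihia

Occupational diisocyanate (DI) exposure reconstruction and health impact
assessment (HIA) from urinary biomonitoring data.

Diisocyanates — MDI, TDI, HDI, IPDI — are respiratory sensitisers used in
polyurethane manufacture, industrial paints and glues. Their critical health
effect is bronchial hyperresponsiveness (BHR) and occupational asthma, for
which no safe threshold can be established. Air monitoring misses dermal
uptake and is collected outside respirators, so human biomonitoring of the
urinary diamine metabolites (MDA, TDA, HDA, IPDA) gives the more faithful
picture of what workers actually absorb. This package turns such
left-censored, highly skewed urinary datasets into sector-level estimates of
external exposure and excess BHR cases. It is written for occupational
hygienists, exposure scientists and risk assessors.

## The method

For a sector's urinary measurements `u` (µg/L, values below the limit of
quantitation substituted with LOQ/2):

1. **Empirical distribution.** The population distribution of urinary levels
   is the piecewise-linear inverse CDF through the empirical quantiles
   (skewed biomarker data are rarely compatible with a single parametric
   family).
2. **Background subtraction.** A non-occupational background of 0.2 µg/L is
   subtracted from each sampled level, clamped at zero.
3. **Reverse dosimetry.**
   - *MDI/TDI*: a one-compartment linear kinetic model predicts the post-shift
     urinary level after 12 weeks of exposure (5 days/week, 8 h/day) at a
     constant air concentration `C` (µg NCO/m³). The model is inverted with a
     Bayesian Metropolis–Hastings sampler: lognormal observation error around
     the kinetic prediction and a weakly informative half-normal prior that
     constrains `C > 0`.
   - *HDI*: the published log–log calibration
     `log10(HDA) = 0.4396·log10(HDI) + 0.4612` (HDA in µg/g creatinine) is
     inverted algebraically and converted to NCO mass.
4. **Monte Carlo integration.** Steps 1–3 are repeated (default 10,000
   iterations) and GM/AM/P95 are taken over the reconstructed draws.
5. **Dose–response.** Each draw is mapped to excess BHR risk over a working
   life through the regulatory risk-band table (0.1% below 0.025 µg NCO/m³ up
   to 5% above 0.67 µg NCO/m³), interpolated with a monotone cubic spline
   through the band midpoints and capped at 7.5% to avoid extrapolation.
6. **Case counts.** Sector mean risk × mean number of exposed workers.

Since the underlying national registry is not public, the package ships a
synthetic-data module: a seeded two-component lognormal mixture (background
vs. background + occupational) that reproduces the published censoring
fractions and GM/P95 summaries per sector, with uncensored truth values
retained for parameter-recovery testing.

## Worked example

Run the packaged demo pipeline (synthetic sector fixtures, reduced Monte
Carlo budget) from Python or the shell:

```
dihia report --seed 42 --out demo_out
```

`demo_out/summary.txt` then reads:

```
Excess BHR risk over a working life, by sector and diisocyanate

  assembly         HDI  risk  0.2%  -> 3 excess cases among 1500 exposed workers
  assembly         MDI  risk  1.7%  -> 25 excess cases among 1500 exposed workers
  assembly         TDI  risk  0.4%  -> 7 excess cases among 1500 exposed workers
  construction     MDI  risk  4.9%  -> 278 excess cases among 5700 exposed workers
  motor_vehicle    HDI  risk  0.6%  -> 54 excess cases among 9300 exposed workers
  motor_vehicle    MDI  risk  4.3%  -> 400 excess cases among 9300 exposed workers
  polyurethane     HDI  risk  0.6%  -> 11 excess cases among 1700 exposed workers
  polyurethane     MDI  risk  4.8%  -> 82 excess cases among 1700 exposed workers
  polyurethane     TDI  risk  0.8%  -> 13 excess cases among 1700 exposed workers

Excluded from assessment:
  construction / HDI: excluded: too few measurements above LOQ
  construction / TDI: excluded: too few measurements above LOQ
  motor_vehicle / TDI: excluded: too few measurements above LOQ

Total excess BHR cases across assessed pairs: 873
```

Each line is one sector/diisocyanate pair: the mean excess BHR risk over a
40-year working life obtained by averaging the capped dose–response over the
reconstructed exposure draws, and that risk applied to the sector's mean
exposed-worker count. Because the input fixtures are synthetic stand-ins for
the non-public registry, these numbers characterise the pipeline, not Finnish
workplaces. The output directory also contains `measurements.csv` (the
simulated input data), `reconstruction.csv` (GM/AM/P95 of reconstructed air
NCO per pair), `exclusions.csv` and a `manifest.yaml` recording the config
snapshot, seeds and digests; re-running with the same config and seed
reproduces byte-identical tables.

Pipelines on real data use the same command with `--config your.yaml`,
pointing each sector/analyte group at a measurement CSV
(`source: csv, path: ...`).

## Layout

- `src/dihia/species.py` — DI species registry, NCO-mass conversion
- `src/dihia/measurements.py` — records, LOQ rules, creatinine and
  exceedance arithmetic, summaries, CSV IO
- `src/dihia/simulate.py` — seeded lognormal-mixture generator and
  registry-like fixtures
- `src/dihia/quantiles.py` — piecewise-linear empirical inverse CDF
- `src/dihia/kinetics.py` — one-compartment kinetic closed form
- `src/dihia/reconstruct.py` — MH reverse dosimetry, HDI calibration,
  sector Monte Carlo integration
- `src/dihia/doseresponse.py`, `src/dihia/hia.py` — risk bands, spline,
  worker arithmetic, HIA driver
- `src/dihia/cli.py` — `dihia simulate|reconstruct|hia|report`

See `docs/methods.md` for the model assumptions, parameter defaults and known
limitations.
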