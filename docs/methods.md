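# Methods

This note records the models, conventions and judgment calls behind
`ednarisk`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Receptor data and units

The receptor is the soil bacterial community: a taxa × samples matrix of
16S relative abundances (fractions summing to one per sample; percent
only at presentation). Soil covariates follow the survey conventions:
pH (unitless), electrical conductivity EC (µS/cm), soil organic matter
SOM (% dry mass), total petroleum hydrocarbons TPH (mg/kg), and the 16 EPA
priority PAH congeners (mg/kg). Congener names are canonicalised through
an alias map ("BaP", "benzo(a)pyrene", … → `benzo[a]pyrene`); congeners
missing from an input vector are stored as explicit zeros with a
provenance flag. TPH and aging time are optional and excluded pairwise
from regressions.

## Toxic equivalents (TEQ)

`ΣTEQ_BaP = Σᵢ cᵢ·TEFᵢ` with TEF_BaP ≡ 1 — strictly additive, no
mixture-interaction modelling. The default TEF table is the Nisbet &
LaGoy-style set (Nap/Acy/Ace/Flu/Phe/Flt/Pyr 0.001; Ant/Chr/BghiP 0.01;
BaA/BbF/BkF/IcdP 0.1; BaP/DahA 1; column sum 2.437). TEF values vary
across the literature (DahA in particular is quoted as 1 or 5); the table
is treated as data, fully overridable via a two-column CSV. Survey
samples published only as aggregate ΣTEQ columns are carried through as
"as-reported" values so downstream stages still run.

## Screening of sensitive/tolerant taxa

Per taxon, relative abundance is regressed on the stressor by OLS on the
raw concentration scale (no transformation). Classification: *tolerant*
if slope > 0 and *p* < α, *sensitive* if slope < 0 and *p* < α (two-sided
t-test on the slope; α = 0.1 by default), else *unclassified*. Choices:

- No multiple-testing correction by default, matching the per-taxon
  screening convention of the source workflow; Benjamini–Hochberg is an
  opt-in (`bh_correct=True`).
- Taxa present in fewer than 3 samples are auto-unclassified (OLS
  undefined).
- A constant response is reported as slope 0, r = 0, *p* = 1 rather than
  an error.
- Key-stressor identification regresses community richness on each of pH,
  EC, SOM, TPH and ΣTEQ (α = 0.05), skipping candidates that are constant
  or mostly missing, and returns significant stressors sorted by *p*.

## Dose–response and EC50

The three-parameter logistic `y = y₀/(1 + exp(b(x − m)))` is fitted by
multi-start Levenberg–Marquardt least squares, with y the relative index
in percent of the control (CK) and **x the natural log** of ΣTEQ — the
model's `m` is defined as ln ECx, which pins the log base. Start points:
y₀ ∈ {100, max y}, b ∈ {±0.5, ±2}, m = median(x); the multi-start guards
against the logistic's slope-sign ambiguity. ECx for levels other than 50
follows from the model's symmetry, `ECx = exp(m + ln(x/(100−x))/b)`.

- CK is the sample with the lowest total toxicity unless designated
  explicitly; the field survey has no true blank.
- Field samples act as unpooled pseudo-doses; replicate pooling is not
  attempted.
- Failed fits are reported (non-converged or `None`), never dropped
  silently.
- In the pipeline, an endpoint is only *valid* if the fitted EC50 lies
  within the tested concentration range — the standard validity criterion;
  extrapolated EC50s (curves effectively flat over the window, typical for
  taxa that passed screening by chance) would otherwise contaminate the
  SSD.

## SSD and HC5

Location-scale SSDs are fitted on **log10** concentrations (log-normal and
log-logistic SSDs — the only scale on which a "normal" model can describe
endpoints spanning 0.06–55 mg/kg; base 10 is the ecotoxicology
convention and is distinct from the natural log inside the dose–response
model). The Burr III model `F(x) = (1 + (x/b)^−c)^−k` operates on the
concentration scale; its quantile is `HCq = b(q^(−1/k) − 1)^(−1/c)`.

Two objectives:

- `method="ls"` (default): nonlinear least squares of the model CDF
  against Weibull plotting positions `i/(n+1)` (Hazen `(i−0.5)/n`
  optional). Location-scale fits are performed in standardized log10
  coordinates with an analytic Jacobian and a Gauss–Newton polish, making
  HCq exactly scale-equivariant.
- `method="mle"`: maximum likelihood (normal: sample mean and SD with
  ddof = 1 of log10 endpoints; logistic: numerical ML).

RMSE is always evaluated between the fitted CDF and the plotting
positions, so minimum-RMSE model selection works under either objective;
ties resolve in model order (normal, logistic, burr3). A minimum of 5
endpoints is required (configurable) — below that, 5th-percentile
extrapolation is meaningless.

**Convention reconstruction.** The source workflow's fitting convention is
not stated, but its printed model-comparison RMSEs are reproduced to four
decimals by the ML objective with RMSE evaluated on Weibull positions
(calibrated endpoints: normal 0.0386, logistic 0.0416; raw endpoints:
logistic 0.0663), and the same convention reproduces both of its
model-selection decisions. Least-squares fits (any plotting-position
scheme) give materially lower HC5s and different RMSEs. The acceptance
computations therefore use `method="mle"` and log the convention. Residual
caveats: the published *calibrated* HC5 values coincide exactly with the
smallest calibrated EC50 of the corresponding endpoint tables, which no
smooth CDF fit reproduces, and the raw logistic HC5 is recovered only to
≈15%.

## DF/AF calibration

Distribution and aging effects are operationalised as dimensionless
multiplicative factors on the toxicity axis:

- `DF = calibrated/original` concentration. The partitioning side exposes
  the Karickhoff relation (log-linear `log10 Koc = log10 Kow − 0.21`
  default, proportional `Koc = 0.411·Kow` optional) and
  `Kd = Koc · foc` with `foc = SOM/100 × 0.58` (van Bemmelen carbon
  fraction, configurable). The full chemical chain from Kd to a
  "calibrated concentration" is not published for the reference workflow,
  so factors in practice come from ratios or from the shipped regression
  `DF = −1.132·SOM + 0.033·PAHs + 9.968` (R² 0.438).
- `AF = aged/original` equivalent toxicity, with the shipped regression
  `AF = 242.518·SOM + 1256.029·lg pH + 0.024·EC − 1415.447` (R² 0.995).
  **Known inconsistency:** on survey-scale inputs this model returns
  values in the hundreds while the observed EC50 fold changes are
  3.07–14.14; the scale of the published AF model cannot be reconciled
  from the available text. The pipeline therefore computes and reports AF
  but multiplies it into the toxicity data only when `apply_af=True`
  (default off).
- Both regressions explain only part of the variance and predict
  *non-positive* factors for high-SOM/low-PAH soils (6 of the 32
  reference samples under the DF model). A non-positive multiplicative
  factor is undefined; such samples are excluded pairwise from the
  calibrated refit and counted in the report, rather than clipped to an
  arbitrary floor.

## Risk classification

`RQ_NCs = c/C_QV(NCs)`, `RQ_MPCs = c/C_QV(MPCs)` (per-congener quotients
sum for Σ16 assessments). The two-condition decision table: level 1 for
RQ_NCs ∈ [1, 800) with RQ_MPCs < 1; level 2 for RQ_NCs ≥ 800 with
RQ_MPCs < 1; level 3 for RQ_NCs < 800 with RQ_MPCs ≥ 1; level 4 for both
high. The region with both quotients below 1 is undefined in the
published table and is assigned an explicit level 0 ("negligible");
boundaries are literal (exactly 1 falls in the ≥ 1 rows). Defaults:
C_QV(NCs) = 0.0028 mg/kg; C_QV(MPCs) = the pipeline's calibrated HC5.

Comparison indices, with configurable breakpoint tables because the
reference grading appendix is unavailable: PI = c/standard (grades 2–5 at
1/2/3), Igeo = log2(c/(1.5·background)) with the standard 7-class grading
(background is user-supplied, no default), and
NIPI = √((mean PI² + max PI²)/2) (grades 1–5 at 0.7/1/2/3). The packaged
per-sample reference risk table contains printed RQ/level combinations
that contradict its own decision table; the package recomputes levels and
*reports* the conflicts instead of reproducing them.

## Synthetic data (the stated world)

The generator emulates the survey the analysis assumes; its defaults are
the stated conditions, not tuning knobs:

- 32 samples, 200 taxa, 17 responder taxa.
- Covariates: pH ~ U(7.9, 8.9), SOM ~ U(3.7, 11.7)%, EC log-uniform on
  (700, 4800) µS/cm, TPH log-uniform up to 588 mg/kg (a zero lower bound
  is floored at 10⁻³ of the maximum for the log draw).
- Per-sample ΣTEQ targets are log-uniform over 0.003–1.1 mg/kg and
  distributed over congeners with lognormally jittered mass weights of
  8/4/1 for 2–3-ring / 4-ring / 5–6-ring congeners — petroleum PAH
  profiles are dominated by low-molecular-weight congeners, which also
  keeps the ΣPAH-to-TEQ ratio in the range the published DF regression
  was built for.
- Responders follow the same logistic dose–response the estimator fits,
  in x = ln ΣTEQ, with EC50s drawn from 10^N(−1.0, 0.5) (log10 mg/kg,
  centred inside the simulated dose range) and |b| ~ U(1, 3), alternating
  slope sign so half are sensitive and half tolerant. Non-responders are
  flat.
- Multiplicative lognormal noise (σ = 0.1 on the log scale, ≈10% relative
  — typical 16S profiling noise at moderate depth) is injected *before*
  column renormalisation, so planted curves are mildly distorted by
  compositionality exactly as real relative abundances would be. Recovery
  tolerances in the tests are calibrated to that distortion (planted EC50s
  recover to within ~10–20%, not to optimizer tolerance).
- All randomness flows from one integer seed through
  `numpy.random.default_rng([seed, stage])`.

What a green synthetic test does **not** establish: robustness to
sequencing depth variation, zero inflation, taxonomic misassignment,
spatially structured covariates, or non-logistic response shapes — none
of which the generator emulates.

## Numerical choices

- Dose–response: LM least squares, multi-start, tolerances 1e-12; fits
  with non-finite residuals discarded; overflow-guarded logistic.
- SSD LS fits: standardized coordinates, analytic Jacobian, Gauss–Newton
  polish to the stationary point (scale equivariance to ~1e-15).
- Degenerate inputs: constant stressors raise (or are skipped in
  multi-candidate scans); all-equal responses raise; EC50 endpoints must
  be strictly positive.
- The pipeline aborts with a clear message if the derived
  C_QV(MPCs) ≤ C_QV(NCs) rather than emitting an inconsistent risk table.

## Known limitations

- The eDNA-SSD endpoint is a relative-abundance response, not organism
  mortality; HC5s derived this way are site-specific and not comparable
  to laboratory-SSD regulatory values without care.
- The published AF model's scale pathology (above) means aging
  calibration is effectively descriptive here.
- BIOM support covers the v1 JSON dialect only (no HDF5).
- No bootstrap confidence intervals on HC5 in the core path; point
  estimates only, matching the reference workflow.
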