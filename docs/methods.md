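# Methods

This note documents the statistical model, the synthetic data generator,
the numerical choices, and the design decisions behind `fishssf`, in the
spirit of a package vignette. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The step-selection model

A fish's regularized track is a sequence of positions on an exact 20 s
grid. A *step* joins consecutive positions; its covariates are the
hydraulic raster values at the start and end points (flow velocity WV in
m/s, depth D in m, spatial velocity gradient SVG in 1/s), the cosines of
the angle between the step heading and the local flow / SVG directions
(DiffVang, DiffSVGang; 1 = moving with, −1 = against), the water
temperature nearest in time, the time-of-day category from nautical
twilight, log step length and the cosine of the turning angle. All
continuous covariates are z-scored with *global* statistics (all fish,
both species, true and random steps pooled, separately per column), so
coefficients are comparable across fish.

Each observed ("true") step is matched with k = 10 random steps sharing
its start point, start time and previous heading, drawn from gamma (step
length) and von Mises (turning angle) distributions fitted per fish to the
true steps: 100 draws, those ending off-river or off-raster removed, 10
sampled uniformly from the survivors (strata with fewer than 10 survivors
are dropped and logged). The conditional-logistic likelihood of the matched
set conditions the stratum intercept out:

    NLL(beta) = sum_s [ log sum_{j in s} exp(beta' x_j) − beta' x_case ].

This is convex; we minimize by damped Newton iteration from beta = 0 with
analytic gradient and Hessian, with log-sum-exp stabilization. The
covariance is the inverse Hessian at the optimum; AIC = 2k − 2logL with k
the number of estimated columns (stratum parameters are conditioned out).
Concordance is the fraction of within-stratum case–control pairs in which
the case has the higher linear predictor, ties counted one half.

The saturated per-fish model has 33 terms: 5 end-habitat main effects, 9
pairwise end-habitat interactions (DiffVang×DiffSVGang is not included), 5
TOD×end interactions, 5 same-covariate start×end interactions, log(SL),
cos(TA), and log(SL) interactions with the 5 start-habitat covariates,
temperature, and TOD. TOD and temperature are constant within a stratum
and therefore enter only via interactions; a fish whose data span a single
TOD category loses all TOD terms. Model selection is backward stepwise:
each round evaluates every single-term deletion, takes the lowest-AIC
candidate, and keeps the more complex current model (stopping) only when
its AIC is at least 2 units lower than that candidate. Ties between
deletions resolve toward removing the earlier-listed term. No marginality
constraint is enforced by default (interactions may outlive their mains),
matching the exploratory "test terms broadly" protocol; a flag enables
hierarchy. Coefficients beyond |beta| > 15 on the standardized scale are
flagged as possible separation but reported unpenalized, since extreme
coefficients are a documented feature of this analysis rather than a
failure.

## 2. Two-step population inference

Per species, per term: coefficients from individual final models are
pooled, with 0 for fish whose model dropped the term ("no effect"). The
summary reports mean, SD (n−1), SE = SD/√n, CV = SD/mean (signed), a 95%
t-interval and a one-sample t-test against zero; *cohesive* means the CI
excludes zero AND p < 0.05. Outliers (default: outside median ± 1.5·IQR)
are removed from all summary statistics of the term and recorded, so any
rule can be replayed from the audit trail; zero-filled entries participate
in outlier detection and the t-test. Per term, intercept-only, weight,
fork-length and total-length linear models of the coefficients are
compared by AIC; a size model is preferred only when it beats the null by
at least 2 AIC units (the same parsimony convention as the stepwise rule —
a plain argmin would pick a spurious size model in roughly 30% of
independent datasets, since P(chi²₁ > 2) ≈ 0.16 per measure).

Log relative selection strength for covariate v compares selection at v
against selection at the covariate mean with everything else at its mean:
for a linear model, log-RSS(v) = beta·z(v), so a one-unit standardized
increase equals the coefficient. Interaction panels fix the moderator at
its observed minimum, midpoint and maximum (pooled range over the analysed
steps of the species); the moderated slope is beta_focal +
beta_int·z(moderator). Grids span the observed min→max with 101 points.
TOD interactions are excluded from population panels because many fish
have single-TOD data.

## 3. Track processing

Approaches are extracted from raw detections by the documented thresholds:
the first detection within 10 m of the pass triggers a window of the
preceding 60 min unless any near-pass detection occurred in the previous
2 h; windows are rejected when over 90% of detections lie within 15 m of
the pass, when they span under 30 min (trigger minus first detection), or
hold fewer than 10 detections. "Near the pass" for the refractory test
reuses the 10 m radius (no second radius is defined). Windows are split at
inter-detection gaps over 60 s; segments with fewer than 10 detections are
dropped.

Each surviving segment is regularized to the 20 s grid by a continuous-time
correlated random walk: per coordinate, position integrates an
Ornstein–Uhlenbeck velocity (reversion b, noise s), observed with isotropic
Gaussian error tau; the two coordinates share (b, s, tau). Parameters are
estimated per segment by maximum likelihood through the Kalman
prediction-error decomposition (Nelder–Mead on log-parameters), with tau
floored at 0.1 m so noise-free input cannot collapse the filter. A
Rauch–Tung–Striebel smoother then predicts positions at the grid times;
non-convergence falls back to piecewise-linear interpolation and is logged.
Grid points outside the raster extent are removed.

Post filters keep tracks that (i) do not start within 50 m of the pass,
(ii) reduce their distance to the pass by at least 25% of the starting
distance, (iii) average at least 2 steps per minute over the track span,
and (iv) fall between the fish's tag date and the species season cut-off
(June 16 barbel, April 16 grayling). The directedness thresholds (25%,
50 m) are this package's explicit defaults — the original criteria are not
public — and are configurable.

## 4. The synthetic river and its limits

The generator stands in for the hydraulic model and the telemetry array.
Depth is a flattened parabolic cross-section (exponent 0.3) times a scour
pool near the pass entrance (Gaussian, amplitude 0.5 of local depth,
radius 12 m) times longitudinal dunes (relative amplitude 0.55, wavelength
9 m); the field is rescaled so the wetted-cell mean hits the target
(2.50 m at the 50 m³/s reference) and scales as Q^0.3. Velocity follows a
meandering thalweg (Gaussian lateral profile, width 7 m, meander 9 m ×
70 m) times cross-channel ripples (relative amplitude 0.45, wavelength
8 m), rescaled to a 0.35 m/s wetted mean and scaling as Q^0.7 — so higher
discharge gives pointwise non-decreasing velocity. SVG fields are central
finite differences of the velocity grid. Flow direction points downstream
with mild lateral variation. The depth dunes run along-channel and the
velocity ripples across-channel deliberately: the two fields then vary on
short scales in roughly orthogonal directions, keeping all pairwise
covariate correlations below 0.5 (the documented property of the study
reach) *and* making depth and velocity separately identifiable from
within-stratum contrast. These bedform scales were fixed once, at design
time, so that each recovery-study coefficient has a per-fish Wald |z| of
roughly 4 or more at 300 strata.

Movement uses a gamma(shape 3, scale 1.8 m) step length (mean 5.4 m per
20 s ≈ 0.27 m/s over ground) and von Mises(0, kappa 0.4) turning angles.
Tracks are generated by the exact mirror of the fitted model: M candidate
endpoints from the kernel, off-river candidates excluded, one selected
with probability ∝ exp(beta'x). M = 50 by default; the recovery studies
use M = 200, where the finite-M approximation error of this softmax
construction is far below the population CI width. An optional goal bias
(cosine alignment with the bearing to the pass) produces realistic
approaches for the end-to-end demo; it is *not* part of the covariate set,
and the demo shows the expected consequence — the unmodelled upstream
drive is absorbed by DiffVang as apparent against-flow selection. The
recovery studies therefore run goal-free.

Detections degrade the true path (piecewise linear between nodes) with
exponential ping intervals (default mean 1.2 s, the high-residency tag
interval), Bernoulli dropout (default 0.10) and isotropic Gaussian noise.
The positioning-noise SD (default 0.30 m) is a configurable assumption,
not a site measurement; positioning-error correlation in time is ignored.
Temperature is a smooth seasonal+diel curve at 15 min; fish biometry is
drawn from the species means (barbel TL 498 ± 73 mm, 1356 ± 592 g;
grayling 367 ± 56 mm, 630 ± 270 g; fork length 0.93·TL).

What passing tests therefore show: the estimator chain is correct under a
known generative model whose structure matches the fitted likelihood. What
they do not show: robustness to positioning-error autocorrelation,
behavioural-state switching, raster misregistration, or hydraulic fields
unlike the synthetic ones.

## 5. Validation studies and their settings

* **Coefficient recovery** — 50 replicates of 30 fish × ~300 strata with
  true coefficients {WV(end) 0.6, D(end) 0.4, DiffVang(end) 0.25, log(SL)
  1.0, log(SL):WV(start) −0.5} and five zero-coefficient "noise" terms in
  the candidate universe; full chain (simulate → random steps → stepwise
  clogit → two-step population); measured: per-term CI coverage, per-term
  retention, noise survival. Two identification choices are deliberate:
  the fitting proposal is the *generating* kernel (a proposal refitted to
  selection-tilted steps changes what log(SL) estimates — it would absorb
  the proposal correction, not the generative tilt), and one fixed global
  standardization (raster/kernel moments) is shared by generation and
  fitting so the true coefficients live on exactly the estimated scale.
  The per-fish refit path is validated separately in the pipeline tests.
* **Null calibration** — same design with all coefficients zero; measured:
  per-term cohesive-flag rate and mean concordance of selected models.
* **CI coverage** — 200 replicates of 30 fish × 150 strata with fish-level
  beta ~ Normal(0.4, 0.3²) on depth, single-term fits, no selection step.
* In the recovery and null studies the population summaries run **without**
  outlier trimming, as in the coverage study: per-fish estimates there are
  homogeneous, and median ± 1.5·IQR fences on a clean Gaussian sample
  remove ~8% of legitimate values, shrinking the t-interval ~12% below
  nominal. The trimming rule exists to guard against catastrophic outliers
  (real analyses of this kind report coefficients in the hundreds), which
  these simulations do not produce. The pipeline default keeps IQR
  trimming.

Problem sizes (30 fish, 300/150 strata, 50/200 replicates, M = 200/50)
are the studies' design settings, chosen to estimate the reported rates
with binomial noise of a few percentage points.

## 6. Numerical choices and degenerate inputs

* Newton line search halves the step until the NLL does not increase
  (convexity guarantees descent); convergence at gradient ∞-norm < 1e-8.
* Rank of the within-stratum-centered design is checked before the
  saturated fit; collinear columns are reported by name. During stepwise,
  column subsets of a full-rank design are fitted without re-checking.
  Terms collinear *within one fish's data* (e.g. log(SL):Temp with
  temperature constant over a single short approach) are pruned for that
  fish and logged, mirroring the single-TOD rule.
* Zero step lengths keep SL = 0, carry the previous heading forward and
  are flagged; log(SL) floors SL at 1e-3 m. Turning angles wrap to
  (−180°, 180°].
* Von Mises kappa uses the mean-resultant-length approximation plus one
  Newton refinement on A(kappa) = R̄, capped at 50 with a warning for
  degenerate (all-equal) angles.
* The empty model (all terms removed) is legal and flagged; its NLL is
  Σ log(stratum size) and its concordance 0.5 by the tie convention.
* Raster lookups use half-open cells [x0, x0+res) × (ytop−res, ytop], so
  boundary points belong to exactly one cell; the grid's top edge is
  included.
* Solar events come from the NOAA solar-position equations (equation of
  time + declination from the Julian century; −0.833° for sunrise/sunset,
  −12° for nautical twilight), iterated three times; polar no-event dates
  raise an explicit error. Calendars are keyed by UTC date, adequate for
  mid-latitude European sites where all events fall within the UTC day.
* All stochastic operations are pure functions of (inputs, seed); the
  pipeline derives per-stage streams from one root seed, and rerunning a
  configuration reproduces byte-identical CSV outputs.

## 7. Known limitations

* Two-dimensional only: no fish depth, no water-column structure.
* One raster discharge scenario is used per analysis run; matching each
  track to the prevailing discharge is left to the caller.
* The CTCRW shares parameters between the x and y coordinates and is
  refitted independently per segment; very short segments (10–15 detections) give
  noisy parameter estimates, mitigated by the measurement floor and the
  linear fallback.
* The two-step population summary is known to overstate between-individual
  variance relative to mixed-effects conditional models; no mixed-model
  alternative is provided.
* Temperature and TOD are assigned at the step start; the original
  assignment convention ("a fish position") is ambiguous.
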