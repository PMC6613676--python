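# Methods

## The biomarker family

During ventricular repolarization the heart's net electrical dipole traces a
3-D curve — the T-vector loop.  This package quantifies *when* the dipole
travels along that curve rather than only how long repolarization lasts.

From the eight independent leads of a 12-lead ECG (V1–V6, I, II) the
vectorcardiogram (x(t), y(t), z(t)) is reconstructed by the inverse Dower
transform (Edenbrandt–Pahlm coefficients; the matrix is configurable).  The
loop is the VCG restricted to the closed window [J + 20 ms, T_end].  The
T-vector velocity

    TVV(t) = sqrt(x'(t)^2 + y'(t)^2 + z'(t)^2)     [uV/ms]

is the speed of traversal; its integral is the arc length covered.  With
total arc length normalized to 1, the cumulated TVV c(t) is a distribution
function over the loop's time course, and the trajectory quantile

    TrX = min { t : c(t) >= X/100 },   X in {10, 20, ..., 100}

is the time (ms from loop start) at which X% of the trajectory has been
traversed.  Tr100 equals the window duration by construction.  A drug that
accelerates early repolarization lowers the early quantiles; one that
delays repolarization raises them — the vector (Tr10..Tr100) therefore
resolves *which phase* of repolarization a drug affects.

## Signal conditioning

Processing order: isoelectric correction → zero-phase low-pass → VCG.

* **Isoelectric baseline.**  Per lead, one knot per beat at the PQ
  midpoint, valued at the median amplitude over [P, Q]; a natural cubic
  spline through the knots (held constant beyond the first/last beat) is
  subtracted.  With fewer than two beats a constant median is subtracted.
  Natural boundary conditions were chosen over not-a-knot after measuring
  both on sinusoidal wander: the natural spline's edge-beat residual is
  several-fold smaller.  A caveat inherent to median baselines: a steep
  in-window trend reorders samples around the P deflection and can bias the
  median by ~1 uV; the generator keeps its P wave brief so the PQ segment
  dominates the median.
* **Low-pass filter.**  Analog-prototype Bessel, order 2 per pass, 36 Hz
  magnitude-normalized cutoff, applied forward and backward
  (``sosfiltfilt``): zero phase, squared magnitude response (measured
  bidirectional gain ~0.99 at 5 Hz, ~0.02 at 100 Hz), reflect padding of
  roughly three time constants.
* **Noisy leads** may be zeroed rather than dropping the record; the zeroed
  set is carried on the record and the lead contributes nothing to the
  dipole.
* **Beat selection.**  Only normal sinus beats with a usable repolarization
  window (at least 20 ms plus one derivative half-window) are used; fewer
  than three usable beats disqualifies the record, which is excluded from
  batch tables with a logged reason.

## Derivatives and quantile readout

Component derivatives use a Savitzky–Golay differentiation filter of
polynomial order 3 and window 31 samples at 500 Hz (the odd sample count
closest to 60 ms at other rates) — exact for locally cubic signals, strongly
noise-attenuating.  Derivatives are computed on the full-beat VCG and then
windowed to the loop, so no filter edge transient lies inside the loop.

Arc length is integrated trapezoidally, matching the linear interpolation
used to read out quantile crossings (earliest crossing on ties).  TrX is
referenced to the loop start (J + 20 ms).  A loop whose total arc length is
below 5 uV (two LSB of the 2.5 uV amplitude resolution) is degenerate: such
a trajectory is unmeasurable, and the residual the derivative filter leaves
in the window of a zero-amplitude T loop stays well under this threshold
while physiologic loops exceed it by three orders of magnitude.

A limitation worth knowing: the 60 ms derivative window cannot track a
traversal law with unbounded speed.  A warp like tau(q) = T q^2 (infinite
dipole speed at the loop start) is measured with a systematic early-quantile
bias of several ms; traversal laws whose speed tapers at the loop ends —
the physiologic case — are recovered to sub-ms accuracy.

## Heart-rate correction

Repolarization lengthens with the beat interval, so each parameter is
fitted on drug-free data (all placebo-arm records plus every arm's pre-dose
baselines) with the linear mixed model TrX ~ 1 + RR + (1 + RR | subject),
REML by default.  The fixed slope beta (ms per ms of RR) defines

    TrXc = TrX - beta * (RR - 1000),

the value expected at the 1000 ms anchor.  QT uses Fridericia's
QTcF = QT / (RR/1 s)^(1/3) instead, for comparability with standard
practice.  Internally RR is centred at the anchor and standardized before
the variance optimization — without this the profiled likelihood is poorly
scaled and the optimizer stalls on boundary solutions; estimates are
reported on the raw ms scale.  A non-converged or singular fit is refitted
with independent (diagonal-covariance) random effects and flagged.  Fitted
models serialize to JSON so correction is reproducible without refitting.

## Exposure-response and effect profiles

Replicate ECGs are averaged per subject × treatment × timepoint; the change
from the period's pre-dose baseline (ΔP) and its placebo correction within
subject and nominal time (ΔΔP) form the modelling endpoint.  Concentration
dependence is the no-intercept mixed model

    ΔΔP ~ 0 + C + (0 + C | subject)

for one drug and ΔΔP ~ 0 + C1 + C2 + C1:C2 + (0 + (C1 + C2) | subject) for
a combination (the interaction term is optional; combination models are
fitted on the pooled single-drug and combination periods).  The missing
intercept forces the fit through the origin: prediction at zero
concentration is exactly zero.  Concentrations are standardized internally
(slopes reported back on the raw scale) and units are never converted —
models are unit-consistent by construction.

The *effect profile* is the model prediction per quantile at a
representative concentration with a 95% CI from a subject-resampling
(cluster) bootstrap, refitting every model per replicate, percentile
intervals, default 2000 replicates.  Subject-level resampling was chosen
because the random-effect structure groups by subject; residual and
parametric bootstraps would understate between-subject slope uncertainty.
Bootstrap refits are warm-started from the full-data variance estimates; a
replicate whose fit lands on the random-effect variance boundary is a
legitimate estimate and is kept, while failed fits are dropped and counted
(a warning above 10%).  The reported interval is widened, if necessary, to
bracket the full-data point estimate.

## Discrimination of block types

Observations are subject × timepoint ΔΔ rows of post-dose timepoints:
group I from arms with pure outward-potassium (hERG/iKr) block, group II
from arms with an added inward-current blocker.  Features (single ddTrXc
columns, ddQTcF, or all ten quantiles) enter an unpenalized
maximum-likelihood logistic regression; in-sample predicted probabilities
are scored by the rank-sum AUC (ties get half credit), with a stratified
(within-class) bootstrap percentile 95% CI, default 2000 replicates.
In-sample evaluation is deliberate — the comparison between feature sets is
the object, and the 10-feature model's AUC is optimistic in the usual way;
cross-validation is available but not the default.  Complete separation is
reported with a warning rather than an error.

## The synthetic study generator

Ground truth is injected where the biomarker lives: in the arc-length/time
domain.  A beat's T loop is a smooth 3-D path traversed according to a
monotone warp

    tau(q) = T0 * h(q) + (C / C_ref) * delta(q) * (1 + b_subject),

so the true TrX = tau(X/100) is available in closed form for every beat.
Components:

* **Path**: magnitude A·sin(pi u)^1.5 times a direction rotating ~2.2 rad
  about an oblique axis — an open loop vanishing at both ends;
  re-parameterized by arc length numerically (2001-point grid).
* **Drug-free traversal** h: the inverse smoothstep, so dipole speed rises
  from zero, peaks mid-loop and decays to zero, as in a real T wave.  T0 is
  the drug-free duration: T_base (230 ms) + subject offset (SD 8 ms) +
  beta_subject·(RR − 1000) with beta ~ N(0.05, 0.01²) ms/ms, + a
  per-ECG biological jitter (SD 2 ms) that gives replicate ECGs the few-ms
  TrX variability real extractions show.
* **Effect shapes** delta(q), in ms at the reference concentration
  (default: the drug's single-dose Cmax): the outward-block shape rises
  monotonically from 0 to its amplitude (delay growing through
  repolarization); the inward-block shape falls to its (negative) plateau
  by q = 0.4 and stays flat (early acceleration, maintained).  Subjects
  carry a relative random effect slope b ~ N(0, 0.2²).
* **PK**: one-compartment oral kinetics C(t) = s·D·(e^(−ke t) − e^(−ka t)),
  ka = 1.5/h, ke = 0.35/h, superposed over dosing times, with log-normal
  (CV 15%) between-subject scaling.
* **Heart rate**: subject mean 1000 ± 70 ms, 60 ms circadian sine, 15 ms
  replicate jitter, clipped to [680, 1400] ms.
* **Noise**, added in lead space to the eight independent leads (limb leads
  derived afterwards, so Einthoven/Goldberger identities hold exactly):
  white Gaussian 10 uV plus 0.33 Hz sinusoidal wander up to 150 uV with
  random per-lead phase.
* **Records**: one rendered beat per record, tiled to 10 s at 500 Hz with
  per-beat annotations.  Default design: 22 subjects, 5 crossover periods,
  16 timepoints (0–24 h), triplicates.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about real ECGs: realistic P/QRS morphology beyond fiducial
plausibility, T-wave notching/flattening morphologies, beat-to-beat
variability within a record, annotation error, torso volume-conduction
effects, or non-linear (Emax/hysteresis) exposure-response.  The generator
validates the estimation machinery against known truth, not the physiology.

## Problem sizes

Tests and the metrics script run reduced designs — typically 8 subjects ×
8 timepoints × triplicates × 5 periods (≈960 records per study) — and
bootstrap sizes of 200–500; these sizes give stable pass/fail behaviour for
the seeded statistical checks.  Production-scale defaults (22 × 16 × 3 × 5,
2000 bootstrap replicates) remain the package defaults.

## Known limitations

* TrX cannot resolve traversal laws with unbounded speed (see above).
* The rate-correction slope is estimated once and frozen; drift of the
  RR-dependence over a long study is not modelled.
* The diagonal-random-effects fallback changes the estimand slightly when
  triggered; it is flagged on the results object.
* In-sample AUC of the all-quantile logistic model is optimistic for small
  studies; treat it as a comparison statistic, not a performance claim.
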