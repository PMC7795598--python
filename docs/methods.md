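# Methods

## Scope and model of the data

The package analyses multichannel unipolar intramyocardial electrograms
from an acute-ischemia protocol: 48 leads, 8 per region, across six
(wall, level) regions of the left ventricle and interventricular septum,
sampled at 4000 Hz at eleven time points (baseline plus 1, 2.5, 5, 10, 15,
20, 25, 30, 35, 40 min of occlusion). The occlusion site fixes the zone
map: LV apex, IVS apex and IVS middle are ischemic; LV middle and IVS base
are border; LV base is normal. Right-ventricular leads may be present in a
container but carry zone `excluded` and never enter the metrics.

All derived times are in milliseconds from QRS onset at the native
0.25 ms resolution; signals are in millivolts.

## Fiducial detection

AT is the instant of the smoothed-derivative minimum within the QRS search
window; RT the derivative maximum within the T-wave window (Wyatt rule,
polarity-independent); ARI = RT − AT. Numerical choices, all exposed in
`FiducialConfig`:

* **Derivative** — Savitzky–Golay order-2 least-squares first derivative,
  window 5 ms. It is exact for linear trends, so constant offsets and slow
  drift leave fiducials untouched, and it preserves extremum locations of
  symmetric peaks.
* **QRS window** — [onset, onset + 100 ms], widened automatically to
  150 ms when the minimum pins to the boundary; ischemic delays reach tens
  of ms past baseline.
* **T window** — [onset + 120 ms, onset + 0.9·RR] (fallback end 540 ms
  when RR is undefined). No standard exists for this window; it is a
  configuration default, not a claim.
* **QRS onset** — earliest instant of a sustained (1 ms) excursion of the
  rectified reference derivative above 30% of its peak, with a 250 ms
  refractory period between beats and an absolute floor of 0.05 mV/ms
  (below it: no-beat error). Onset detection uses a short 2 ms derivative
  window; a wide window smears the upstroke and drags the threshold
  crossing several ms early. Threshold crossing still precedes the
  upstroke centre by ~1 ms; this offset is common to all leads of a
  recording, so ARIs, dispersions and within-group time-course contrasts
  are unaffected, and group means inherit a ~1 ms positive bias that the
  calibration tolerances absorb.
* **RR** — median inter-onset interval; a single detected beat yields an
  undefined RR (NaN), flagged rather than guessed.
* **Tie-break** — equal extrema resolve to the earliest instant
  (determinism).
* **Quality rules** — a lead is flagged `excluded` (never silently
  dropped) when its peak-to-peak amplitude falls below 5% of the median
  lead amplitude, or when a fiducial sits on a window boundary after
  widening. A recording whose leads are all excluded is an error.
* **Beats** — recordings carry one analyzed QRS–T complex; detection runs
  on the first beat. The reference holds ≥ 3 beats so RR is defined.

## Metrics

Regional means are arithmetic means of AT and ARI over quality-passing
leads; a region whose eight leads all fail is reported missing, never
imputed. Global parameters span all analyzed (LV + IVS) ok leads:
DOR = max(RT) − min(RT), maximal AT, ARI extrema. DOR and AT_max are
permutation-invariant and can only shrink when leads are removed. VF
phases are inclusive windows, default 1A = [1, 5] and 1B = [15, 40] min;
the delayed window is a parameter (a [17, 40] convention also circulates)
and events between windows are flagged `intermediate` rather than forced
into a phase.

## Synthetic cohorts

The generator exists so that detection, metrics and inference can be
validated by parameter recovery. Its defaults *are* the study conditions:
13 control and 12 melatonin-treated animals, 48 leads, 4 kHz, the
eleven-minute schedule.

**Signal model.** Each lead has a phenomenological local action potential
made of two logistic edges — upstroke (10–90% width 2 ms) at the true AT,
repolarization (width 15 ms) at AT + APD — and the unipolar electrogram is
the remote-minus-local superposition
φ_i = Σ_j w_j·AP_j − AP_i + ST + noise, with weights summing to one.
Far-field terms use broadened edges (12 ms / 100 ms), standing for spatial
averaging over remote tissue. That broadening is also what makes the
Wyatt property exact on the grid: the shift a remote edge can impose on a
local derivative extremum is bounded by 0.77·s_local³/s_remote² (logistic
scales), ≈ 0.04 ms for the defaults — below the 0.25 ms sample. Injury
current is an additive baseline shift only, which moves no derivative
extremum, keeping the ground truth analytic. There is no electrotonic
coupling, no torso model, and no VF waveform — VF is an event label.

**Ischemia trajectories.** Region-level time courses prescribe added
activation delay, APD change and ST shift per minute. Ischemic regions get
a biphasic ("spike and dome") delay with maxima near 5 and 20 min and a
dip at 10 min, and monotone APD shortening to −55 ms; border regions a
rapid, persistent delay (control) or preservation at baseline through
20 min (melatonin); the normal region is flat. Border amplitudes are
rescaled at construction so the post-drug (minutes ≥ 1) group means equal
the calibration targets exactly at trajectory level: IVS base 35.4 ms
control / 23.0 ms melatonin, LV middle 24.6 / 17.5 ms. The two border
regions need different gains to hit their targets, which is why the
trajectory is stored per region rather than per zone. The APD time course
is shaped so that true DOR rises monotonically from 1 min to a peak in
the 20–30 min bin and declines slightly after — the dispersion dynamics
the delayed-VF phase is associated with.

**Heterogeneity.** Lead-level jitter (AT sd 2 ms, APD sd 5 ms) gives a
realistic nonzero baseline dispersion; animal-level effects (common AT
offset sd 1.5 ms, lognormal delay gain sd 0.15, RR sd 30 ms around
600 ms) create the between-animal covariate variation without which an
animal-level logistic association would be degenerate.

**VF hazard.** Per recording minute ≥ 1, VF is Bernoulli with logistic
probability linear in the animal's true covariates: ln(1.037)/ms on
IVS-base AT and ln(1.015)/ms on DOR by default (the association magnitudes
reinterpreted as generative effects), intercept calibrated by root-finding
so half of a jitter-free control cohort fibrillates within the protocol.
Recordings stop at the VF minute, inclusive — the animal is euthanised
immediately after VF, so the VF-minute recording exists but later ones do
not.

**What the generator does not emulate.** Real conduction physiology
(wavefront curvature, anisotropy), electrogram morphology beyond two
logistic edges, intermittent signal-quality loss, VT episodes preceding
VF, and any RR–DOR coupling (heart rate is generated independently of the
electrophysiology, so RR regressions on synthetic cohorts are null
checks). Passing tests therefore demonstrate correctness of the
*computational chain* under a model in which the dV/dt rules are exact —
not detector performance on recorded ischemic electrograms.

## Statistics

Implemented from first principles, with scipy used only for reference
distribution tails (χ², t, normal) and the optional Fisher-exact
alternative:

* **Univariate logistic regression** — Newton/IRLS on an internally
  standardized predictor, convergence on log-likelihood change < 1e-10,
  Wald SE from the inverse observed information; symmetric 95% CIs on the
  log-odds scale, reported per 1 ms. Complete separation and constant
  predictors raise explicit errors rather than drifting to infinity. On
  saturated binary data the fit reproduces the closed-form sample odds
  ratio.
* **2×2 incidence test** — Pearson chi-square without continuity
  correction. The choice is forced by arithmetic: it is the variant that
  reproduces both printed incidence p-values (0.016 and 0.456) from the
  printed counts; Fisher's exact is available behind a flag. With the
  study margins (12, 13) × (5, 20) the exact null rejection rate at
  α = 0.05 is 0.039 — conservative but inside the documented
  [0.03, 0.08] band.
* **Repeated measures** — paired contrasts of each minute against
  baseline with Bonferroni multiplication (capped at 1); subjects missing
  a minute are dropped per contrast. The two-time-point case reduces to a
  paired t-test.
* **KS normality** — Lilliefors variant: parameters estimated from the
  sample, p-value from a seeded Monte Carlo null (2000 samples), since the
  classical KS distribution does not apply with estimated parameters.

**Predictor summarization.** The analysis relates a per-animal scalar to a
binary VF outcome; the pipeline uses the mean over the occlusion minutes
(≥ 1) available before VF or censoring. This pooling rule is an assumption
of this package, surfaced as the documented default. A per-minute
generative hazard refit at animal level is not the same estimand — the
fitted OR carries a modest upward distortion at ~50% cumulative incidence,
partly offset by truncation — which is why recovery is asserted as CI
coverage of the generative value across replicates, not point equality.

**Incidence risk sets.** The 1B denominator excludes animals that
fibrillated in 1A (risk-set convention); excluding all earlier fibrillators,
including intermediate-phase ones, follows the same logic.

## Validation studies and problem sizes

`ischemap.validation` packages the recovery experiments run by the test
suite and `scripts/acceptance.py`:

* *Fiducial recovery* — one noiseless full-protocol animal (528 leads):
  max |AT|, |RT| error ≤ 0.25 ms against truth with known beat time; 500
  leads at noise sd 5% of QRS amplitude: AT RMS ≈ 0.2 ms, RT RMS ≈ 1.4 ms
  (bounds 2 and 5 ms).
* *Wyatt oracle* — the Savitzky–Golay detector agrees with a brute-force
  finite-difference extremum scan to one sample on every noiseless lead.
* *Occlusion dynamics* — one default cohort (25 animals) through the full
  waveform + detection chain: biphasic mean maximal AT (local maxima in
  the 3–5 and 15–30 min bins), mean DOR peak in the 20–30 min bin,
  melatonin IVS-base AT within 3 ms of baseline through 20 min against a
  > 10 ms control rise.
* *Odds-ratio recovery* — 100 replicates of 40 + 40 animals with the
  hazard acting only through IVS-base AT at OR 1.037/ms, fitted at
  truth-table level (waveform detection is validated separately and its
  sub-ms errors are negligible at this effect size); coverage of the
  generative OR by the 95% CI ≈ 0.93.

These sizes keep the full suite and the acceptance script at a few minutes
on a single CPU while leaving the stochastic margins comfortable.

## Known limitations

* The container format is package-specific; standard physiologic-record
  import is out of scope here.
* Beat averaging across multiple complexes is not implemented — one
  analyzed complex per recording is the generator's (and the analysis's)
  convention.
* The statistics layer is deliberately univariate and paired; there are no
  multivariable or mixed-effects models.
* QRS-onset threshold crossing biases absolute ATs by ~1 ms (see above);
  applications needing unbiased absolute latencies should calibrate the
  onset definition against their own reference convention.
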