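# Methods

## Behavioral model and statistics

A rat's nociceptive response is a vector of fifteen 3-minute face-rubbing
durations (seconds, each capped at 180 s). Phase 1 is the sum of bins
1–3 (0–9 min), phase 2 of bins 4–15 (9–45 min); the two phase totals
partition the total rubbing time exactly. Out-of-range bins are rejected
at ingestion, not clipped — a duration above 180 s in a 3-minute bin can
only be a recording error.

Antinociceptive activity is computed per rat as
`AA% = 100·(C − T)/C`, where `T` is the rat's phase total and `C` the
mean phase total of the concurrent vehicle (0.9% NaCl + formalin)
group. The control time exists only as a group quantity, so the group
mean is the denominator for every rat, controls included (control AA%
then scatters around zero). Negative AA% (pro-nociceptive response) is
preserved rather than truncated; line fits exclude non-positive effects
with a warning because the log/reciprocal machinery needs positive
values (a strict mode errors instead).

`%I = 100 − 100·AA_with/AA_without` quantifies the inhibition of one
drug's effect by a co-administered drug. Values above 100 (reversal)
are reported unclamped. The mast-cell analogue `I%` has the same
algebraic structure on degranulated-cell counts.

## Dose–response

Effects are regressed on log₁₀(dose) by (weight-aware) least squares;
base 10 is the pharmacological convention. Two ED50 conventions are
kept explicit through a `method_tag`:

* **direct** — for drugs reaching full efficacy, the dose at an
  absolute 50% effect, `10^((50 − a)/b)`; extrapolation beyond the
  fitted range is flagged, and a negative slope yields a value but a
  warning.
* **emax_rescaled** — for submaximal-efficacy drugs (alone-curve
  maximum below 60%), the maximal effect is first estimated from the
  double-reciprocal regression of 1/E on 1/D: `Emax = 1/intercept`,
  and the half-saturation dose `K = slope/intercept` is the ED50. For
  an exact hyperbola `E = Emax·D/(D + K)` the reciprocal plot is an
  exact line, so both parameters are recovered without error; this
  identity (not a 50%-crossing of a refitted line, which would be
  biased by the hyperbola's curvature in log-dose space) defines the
  ED50. Effects are additionally rescaled to percent-of-Emax and a
  log-dose line is fitted on them for downstream comparisons. A
  non-positive reciprocal intercept means no finite asymptote and is an
  error; in the orchestrated analysis the chain then falls back to the
  direct-line ED50 with a note in the report.

## Parallel-line interaction analysis

Alone and combination arms are compared as a classical parallel-line
bioassay:

1. **Parallelism** — extra-sum-of-squares F-test of the separate-slopes
   model against the common-slope model, F(1, n_a+n_b−4). Rejection at
   α = 0.05 (configurable) makes the potency ratio meaningless; the
   verdict is then *indeterminate-nonparallel* and the ratio is
   withheld.
2. **Relative potency** — under the common-slope model with slope `b`
   and intercepts `a_alone`, `a_combo`, the log₁₀ ratio is
   `M = (a_alone − a_combo)/b` and `R = 10^M = ED50_combo/ED50_alone`.
   `R > 1` means the combination needs more test drug for equal effect
   (rightward shift, antagonism direction). The identity
   `ED50_combo = R·ED50_alone` holds exactly under the fitted model.
3. **Confidence limits** — by Fieller's theorem on `M = d/b` with the
   pooled residual variance, t at n_a+n_b−3 df, and the full
   variance/covariance of `(d, b)` from the weighted design. With an
   imprecise slope the limits are strongly asymmetric; when Fieller's
   `g = t²·var(b)/b² ≥ 1` the interval is unbounded and no significance
   can be claimed. In the zero-noise limit the interval collapses to
   the point estimate.
4. **Verdict** — *additive* when the 95% CL includes 1.0 (no
   demonstrable departure), *antagonism*/*synergy* for a significant
   rightward/leftward shift. The point-estimate `shift_direction` is
   reported separately so a non-significant directional trend (e.g. a
   rightward shift whose wide CL spans 1) remains visible in reports.

### Variance-model weights

Per-rat AA% derived from multiplicative behavioral noise has residual
SD proportional to `100 − E`: rats near full suppression scatter far
less than weak responders. Unweighted OLS then feeds a heteroskedastic
error into the F and t reference distributions and inflates the
parallelism test's size well above its nominal level. The fixed-dose
analysis therefore weights each dose group by `1/(100 − mean effect)²`
(floored at 1/25² to avoid infinite weight at complete suppression),
the weighted parallel-line assay standard. Unweighted fits are
available with `variance_model="none"`. Monte-Carlo calibration under
the generator's null confirms the weighted test holds its ~5% size.

An isobologram proper is not constructible for this design — the
adjuvant is dose-independent and has no ED50 axis — so the interaction
analysis is exactly this line-shift comparison.

## Histomorphometry

Mast-cell counts are ingested as already-classified totals and
degranulated counts per high representative field (HRF; 400×,
0.95 mm²), three fields per rat, averaged arithmetically without
rounding. The ≥3-external-granules degranulation criterion is upstream
image interpretation and out of scope. Degranulation inhibition by a
pretreatment is `I%` of group means against the formalin group at each
time point (5 min, 25 min, 24 h). Degranulation–pain association uses
Pearson's r with the two-sided p from the t transform at n−2 df; at the
study's n = 6, |r| must exceed ≈0.811 for p < 0.05. Because behavior
and histology come from separate cohorts, rats are paired by position
within sorted ids; matching by identical ids is supported when one
cohort provides both measurements.

## Split-plot ANOVA and Tukey HSD

The design is one between-subjects factor (treatment, n rats nested per
group) crossed with one within-subjects factor (time bin or phase).
Sums of squares are computed in closed form for the balanced case:
subjects-within-groups is the error stratum for the between factor, the
subject×within residual for the within and interaction terms.
Unbalanced or incomplete designs raise an explicit error rather than
being silently approximated. Sphericity (Greenhouse–Geisser) correction
is off by default and, when enabled, both p-values are reported. Tukey
HSD uses the studentized-range distribution on the pooled within-group
variance (Tukey–Kramer standard error for unequal n). Results
cross-validate in the test suite against pingouin's mixed ANOVA and
scipy's `tukey_hsd`.

## Synthetic data generator

The generator emulates the study's structure, not its mechanisms:

* **Template** — the formalin+vehicle control time course is a phase-1
  burst (bins 55/40/8 s ≈ 103 s total) and a phase-2 plateau (12 × 30 s
  = 360 s). The absolute template is not empirically anchored (only
  figures exist for it); all calibrated quantities are on the AA%/ED50
  scales, which are invariant to the template's absolute seconds.
* **Cromoglycate** — per-phase hyperbolic effect
  `Emax·D^h/(D^h + ED50^h)`, defaults Emax 55% / ED50 2.35 mg/kg in
  phase 1 (submaximal, engaging the double-reciprocal route) and
  Emax 100% / ED50 7.0 mg/kg in phase 2, Hill coefficient 1.
* **Magnesium sulfate** — dose-independent additive effect at any
  positive dose: 10% in phase 1 (small, non-significant at n = 6), 40%
  in phase 2.
* **Interaction modes** — `null` leaves cromoglycate untouched;
  `inhibit`/`potentiate` divide/multiply its effective dose by
  (1 + magnitude), i.e. a pure horizontal shift of the log-dose curve.
* **Noise** — multiplicative lognormal per bin with CV 0.15, truncated
  to [0, 180] s: rubbing times are nonnegative and right-skewed, and
  the implied per-rat AA SDs (≈4–10 points depending on effect level)
  match the scale of group SDs such studies report. An additive-normal
  mode exists for calibration work where exact nominal test sizes are
  the benchmark.
* **Mast cells** — per-field totals Poisson around the group/time mean
  (naive 212/HRF; formalin-reduced, at 24 h by 43.9%), degranulated
  counts binomial within each field's total (naive mean 3/HRF; formalin
  multiplies degranulation ≈8×; magnesium inhibits it by 23% at 5 min,
  40% at 25 min, 0 at 24 h). Degranulated ≤ total holds by
  construction.
* **Determinism** — every rat's stream is keyed by
  (seed, purpose, group, rat index) through `numpy.random.SeedSequence`,
  so regeneration is byte-identical and adding a group never perturbs
  existing groups' draws.

What the generator does *not* emulate: between-rat random effects
(bins within a rat are independently noisy), pharmacokinetics, time-bin
autocorrelation, or any mechanistic mast-cell/neuron coupling — the
degranulation and behavior streams are statistically independent, which
is why the default-scenario degranulation–pain correlations scatter
around zero. Passing tests therefore demonstrate the statistical
machinery's correctness and calibration under the study's design and
realistic noise scales, not biological validity on real data.

## Numerical choices and edge cases

* All line fits go through `numpy.linalg.lstsq` on the weighted design;
  the test suite checks them against explicit normal-equations solvers
  at 1e-10 relative tolerance.
* Exactly collinear, noise-free inputs: the parallelism test reports
  F = 0, p = 1 when the pooled residual vanishes with equal slopes, and
  p = 0 with a degenerate-variance flag when slopes differ.
* A common slope numerically at zero makes the potency ratio undefined
  (error), not infinite.
* Fieller intervals with `g ≥ 1` are reported as (0, ∞) rather than as
  exploding finite numbers, and such comparisons are never significant.
* The split-plot F statistics for a constant response (zero error mean
  square with zero effect) are reported as F = 0, p = 1.

## Problem sizes

Simulation experiments run at the study's own scale — 6 rats per group,
3 dose groups per arm — with 200 replicates for parameter recovery and
1000 for coverage and type-I rates, putting Monte-Carlo error on rates
near ±0.7 percentage points; verdict distributions use 100–300
replicates. The full acceptance recomputation takes on the order of ten
seconds.
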