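# Methods

## The measurement problem

A blended-emotion perception study presents observers with brief expressions
that intentionally combine two of five emotion categories (anger, disgust,
fear, happiness, sadness) at one of three relative prominences. The
response format is a hybrid of forced choice and rating: the observer picks
scales — exactly two in the forced format, any number from one to five in
the free format — and rates each selected scale from 0 (not at all
prominent) to 10 (very prominent). Unselected scales are *missing*, not
zero: which scales were chosen is itself the categorical response, and the
package keeps selection first-class through every I/O cycle.

## Accuracy indices and their chance levels

Per trial, with target set T (|T| = 2) and selected set S:

- generous = 1{S ∩ T ≠ ∅}
- strict = 1{T ⊆ S} (superset policy; an exact-match policy
  `strict_policy="exact"` is available for sensitivity analysis)
- very strict = strict × 1{r(more) > r(less)}, defined only when the two
  targets have unequal intended prominence. Ties score 0 under the strict
  reading of "higher".

The superset policy is the default because the strict index must remain
meaningful in free-selection data, where the number of selections — and
hence the chance level — varies by trial; only a coverage definition lets
supersets count.

Chance levels assume uniform random selection of k of m = 5 scales and
exchangeable ratings. They are computed by exact enumeration of all C(m, k)
subsets (`chance.analytic_chance`) and equal the closed forms
1 − C(m−t, k)/C(m, k) and C(m−t, k−t)/C(m, k); the test suite asserts the
equality for all m ≤ 7. For k = 2: generous 0.70, strict 0.10, very strict
0.05 (the ordering factor 1/2 holds because under a continuous exchangeable
null the two target ratings tie with probability zero). For variable k the
level is the mixture Σ_k d(k)·p(index, k) over the observed
selection-count distribution d (`chance.mixture_chance`); by convention the
fixed k = 2 anchors are also reported as the general reference point for
free-selection data, since such observers select about two scales on
average.

The Monte-Carlo oracle (`chance.simulate_random_responder`) draws uniform
selections and *continuous* uniform ratings and scores them with the same
scorer functions applied to real data. Continuous ratings are the default
deliberately: rounding to the 0–10 grid makes target-rating ties possible
(probability ≈ 0.095 per strict trial for uniform integer ratings), which
the very-strict index scores 0, so an integer-rating null sits measurably
below 0.05. The integer variant is available (`ratings="integer"`) and is
conservative.

## Aggregation and intervals

Accuracy cells pool 0/1 trials across participants and actors; the reported
SD is the sample (n−1) SD of the binary scores, and the default 95% CI is
the Wald normal approximation on the pooled proportion (clipped to [0, 1]),
with the Wilson interval available via `ci_method="wilson"`. Pooled-trial
aggregation is the default because an overall proportion with SD ≈ 0.5 is
the natural summary of binary trials; a participant-level mode
(`unit="participant"`) averages per-participant proportions instead. A cell
is flagged above chance when its CI lower bound exceeds the chance level.

Cell mean ratings impute 0 for unselected scales (every response carries an
implicit 0 on scales it did not select); per-participant means are averaged
so each participant weighs equally in a cell.

## Rating-level inference

For each rating scale × proportion condition, participants' cell means over
the 10 combination conditions enter a one-way repeated-measures ANOVA,
implemented as the classical decomposition SS_total = SS_subject +
SS_condition + SS_error with F = MS_condition/MS_error on
((c−1), (c−1)(n−1)) df. The decomposition is written out in-package (rather
than delegated to a generic ANOVA backend) so the SS components are exposed
for the effect sizes and the conservation invariant; the test suite
cross-checks F, p, ε, Mauchly's W and both effect sizes against pingouin on
random fixtures.

Sphericity: Mauchly's W from the orthonormalized contrast covariance with
Box's chi-square series to second order; Greenhouse–Geisser
ε = tr(Σ̃)²/((c−1)·tr(Σ̃²)) from the same contrast covariance, bounded in
[1/(c−1), 1]. The GG-corrected p-value is the primary one, because
10-level rating designs essentially never satisfy sphericity. Effect sizes:
η²p = SS_c/(SS_c+SS_e) and η²G = SS_c/(SS_c+SS_s+SS_e); η²G ≤ η²p always.
Degenerate layouts (zero error variance) return a flagged result object
instead of raising, so pipelines cannot silently drop cells.

Post-hoc families are two-sided paired t-tests (scipy) on participant cell
means: the 4 target × 6 non-target contrasts per ANOVA at α = 0.05/24
(reported as 0.0021), and the 20 prominence-order tests (each combination ×
each unequal proportion, more-prominent target scale vs less-prominent) at
α = 0.05/20 = 0.0025. Order tests use participant-level means over actors,
consistent with their repeated-measures framing; directionality is read off
the sign of the mean difference.

## The synthetic rater model

`synthetic_raters` generates the fully crossed design (n_actors × 10
combinations × 3 proportions; 6 actors gives the canonical 180 stimuli) and
simulates judgments from:

- **gain A = 8** (default): peak expected rating of a fully expressed
  emotion — strong but below the 0–10 ceiling;
- **prominence weights** (0.3, 0.7)/(0.5, 0.5)/(0.7, 0.3): a convention
  encoding the intended ordering, exposed as free parameters because the
  prominence labels denote ordering, not exact percentages;
- **confusion kernel C** (unit diagonal): default leakage anger↔disgust
  0.25, fear↔sadness 0.30, minor leakage among other negative pairs
  (0.05–0.10), zero leakage to/from happiness — a qualitative encoding of
  same-valence confusability, not an empirical fit;
- **noise σ = 1** rating unit, additive Gaussian, comparable to the
  between-participant SDs such studies report (≈0.6–1.6);
- **selection**: `top2` (forced format; ties broken uniformly at random) or
  `threshold` with τ = 2 (free format; falls back to the single argmax so
  at least one rating is always given — with the defaults this yields a
  mean of roughly 1.9 selected scales per response, near the ≈2 that
  free-selection observers produce);
- **discretize** (default True): ratings are rounded to the integer grid,
  matching the response format. The continuous variant exists for
  null-calibration work: at zero gain, integer rounding (and clipping at 0)
  makes the two selected ratings tie on a large fraction of trials, which
  the very-strict index scores 0 — a property of discretization, not of the
  scorer. The continuous null retains only the clip-at-zero tie
  (≈3% of strict trials), putting the zero-signal very-strict level at
  ≈0.048 against the nominal 0.05.

A per-actor gain multiplier hook exists but defaults to 1; the default
generative model has no actor effects. The simulator returns the latent
means alongside the dataset so noise-free runs can be checked against the
generative values exactly.

**What the simulator does not emulate.** Real raters show response biases,
participant-level skill differences, stimulus-level idiosyncrasies beyond
the kernel, and sequential effects; none are modeled. Passing calibration
and recovery tests therefore demonstrates that the *pipeline* measures what
it claims under a known generative process — not that human data will show
any particular accuracy level.

**Calibration and recovery behavior** (computed by the test suite):

- zero-signal (A = 0) forced-format studies score at the analytic chance
  levels: strict is exact by selection symmetry; very strict matches the
  continuous null within Monte-Carlo error;
- accuracy rises monotonically with A at fixed σ;
- at A = 8, σ = 1 with an identity kernel and 40 participants, all 20
  prominence-order tests are significant in the correct direction. Cell
  very-strict accuracy under these settings sits around 0.80–0.87, not
  higher: with weights (0.3, 0.7) the less-prominent target's latent mean
  is 2.4 vs 0 for each of three non-targets, so each non-target displaces
  it from the top-two with probability 1 − Φ(2.4/√2) ≈ 0.045, bounding
  strict coverage by (1 − 0.045)³ ≈ 0.87 even before discretization ties.
  This ceiling is an intrinsic property of the top-two rule under these
  parameters.

## Numerical choices

- Ratings are stored internally as floats so the continuous simulator
  variant can be scored in memory; the CSV dialect enforces integers 0–10.
- Rounding in `perceive` uses numpy's round (banker's rounding at .5);
  default latent means never land on .5.
- Bonferroni alphas are reported at 4 decimals (0.0021, 0.0025), matching
  convention; significance is decided against the rounded value.
- Mauchly's W on singular contrast covariances (n ≤ c) degrades to W = 0
  with p = 0 rather than failing.
- Rendered report tables round to 2 decimals; machine-readable outputs keep
  full precision, and a manifest (config, seed, version) makes every
  rendered number recomputable.

## Problem sizes

The test suite simulates studies of up to 40 participants × 180 stimuli and
uses 20,000–100,000-trial Monte-Carlo runs; these sizes give standard
errors a few times smaller than the tolerances being checked while keeping
the suite fast.

## Known limitations

- No multilevel modeling: trials are nested in participants and stimuli,
  but inference follows the classical aggregate-then-ANOVA route.
- The very-strict chance extension to selections larger than two
  (strict(k) × 1/2) is a documented convention; other orderings of
  partially rated supersets could be defined.
- No response-bias-adjusted nulls (the null is uniform selection), no
  sensitivity-theoretic indices, and no fitting of the rater model to real
  data.
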