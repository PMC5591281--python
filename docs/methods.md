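# Methods

## Generative model and decision rules

A trial is a stimulus `(condition, s_m, s_f, c)` on the Laura(0)–Susan(1)
morph continuum. The old manipulation moves the physical form cue toward
the aged average face at form level 0.6: the effective form position is
`0.6c + (1−c)s_f` with `c ∈ {0, 0.35}`. The observer's internal
measurements are conditionally independent Gaussians,
`x_m ~ N(s_m, σ_m²)` and `x_f ~ N(0.6c + (1−c)s_f, σ_f(c)²)`, where
`σ_f(c)` is `σ_f` (old off) or `σ_f,old` (old on) — old faces may require
an extrapolation step that adds form noise, while motion is untouched.

Writing precisions `J = 1/σ²`, the optimal observer inverts the generative
model; the posterior over the underlying morph level is Gaussian with mean
`[J_m x_m + (1−c)J_f(x_f − 0.6c)] / [J_m + (1−c)²J_f]`, and the
accuracy-maximizing rule reports "Susan" when that mean exceeds the
boundary `b`. Because the decision variable is a linear-Gaussian function
of the measurements, the choice probability is a cumulative normal in the
stimulus; with a symmetric lapse process (probability λ of an unbiased
random guess) every model's prediction has the form
`p = λ/2 + (1−λ)Φ(z)` and is confined to `[λ/2, 1−λ/2]`.

The alternatives replace the fusion rule only: `BEST` thresholds the
single measurement with the smaller SD (comparing raw `σ_m` against the
condition-appropriate `σ_f(c)`; the measure-zero tie goes to form),
`AVG` thresholds the unweighted mean of the two measurements, and
`OPT_IB` fuses with full precision weights but without inverting the old
compression — an observer who believes old morphs are pure aged versions
of each identity. When `σ_m = σ_f` and `c = 0` the optimal and
simple-average rules coincide exactly; this equivalence point is flagged,
not treated as an error, by the recovery harness.

### Single-cue conditions

In form and motion blocks the observer is explicitly cued which feature to
judge, so by default all models use only the instructed cue
(`single_cue_rule="relevant_cue_only"`), making the three main models
share single-cue likelihoods: MOTION gives `Φ((s_m − b)/σ_m)` and FORM
gives `Φ((1−c)(s_f − b)/σ_f(c))`, the generative model inverted for the
instructed cue alone. `OPT_IB` keeps its uninverted form mean,
`Φ((0.6c + (1−c)s_f − b)/σ_f(c))`. The alternative of running the full
fusion rule in single-cue blocks (with the irrelevant cue at its neutral
0.5 level) is exposed as `single_cue_rule="full_rule"` for sensitivity
analysis.

## Trial design

The default grid is 11 equally spaced morph levels (0 to 1, step 0.1),
five conditions (form-only, motion-only, combined congruent, and the two
incongruent conditions at conflict Δ = 0.15), crossed with old on/off.
Under the adopted sign convention, +Δ means more form than motion
information (`s_f = s_m + Δ`); the switch `plus_is_form_greater` flips it,
since the two conventions are both defensible readings of the task
description. Incongruent pairs are anchored so the *mean* of `(s_m, s_f)`
lies on the level grid with symmetric ±Δ/2 offsets; pairs that would leave
[0,1] are dropped (and counted) rather than clipped, so the conflict is
always exactly Δ. Member-anchored alternatives (`incongruent_anchor =
"form"` or `"motion"`) offset the other cue by the full Δ instead. Motion
trials are generated at both old levels but marked poolable, because the
old manipulation does not affect motion reliability.

The default repetition count is `n_reps = 8` (816 trials/subject with the
full design), chosen so per-point binomial noise on a default synthetic
psychometric curve is comparable to published between-subject error bars;
the total trial budget of the original session is not public. Recovery
benchmarks use `n_reps = 20` to pin medians more tightly.

## Synthetic populations

A population is defined by its location parameters (defaulting to the
group-median estimates σ_f = 0.17, σ_f,old = 0.24, σ_m = 0.28, b = 0.51,
λ = 0.04) plus heterogeneity: noise SDs get a median-preserving log-normal
multiplicative spread (log-SD 0.33), `b` and λ get additive Gaussian
spread (SD 0.07 and 0.03) clipped to [0,1] and [0, 0.5]. The spreads were
back-solved once from the published across-subject IQRs under these
distributional forms (0.6745·spread ≈ half the IQR width). A "paper-like"
preset assigns 15 OPT / 3 BEST / 4 AVG subjects, mirroring the reported
per-subject posterior counts. Responses are independent Bernoulli draws
from the generating model's closed-form probability; a dataset is fully
determined by `(spec, seed)`.

What the simulator deliberately omits: sequential and learning effects,
reaction times, within-session drift, and any perceptual nonlinearity of
the morphing axis. Passing recovery tests therefore shows the *pipeline*
is consistent — that the fitting and selection machinery returns planted
truths under the model's own assumptions — not that real observers satisfy
those assumptions.

## Fitting

Per subject and model, all five parameters are estimated by maximizing the
Bernoulli likelihood with L-BFGS-B under bounds σ ∈ [0.01, 2] morph units,
b ∈ [−0.5, 1.5], λ ∈ [0, 0.5] (guessing cannot dominate behavior — a
standard psychophysics constraint). Ten restarts are drawn uniformly in
bounds, log-uniformly for the SDs; convergence is 1e-9 relative on the
objective (≈1e-6 absolute at typical NLLs); probabilities are floored at
1e-9 before logs, far below any effect at fitted λ > 0. The *joint*
variant fits all conditions; the *predictive* variant fits all five
parameters on single-cue trials only and evaluates the combined-cue log
likelihood without refitting, the total remaining the sum of the two
parts. The joint fit can only do better in-sample, and does on the
synthetic benchmarks.

## Model comparison

All candidate models have five parameters, so maximized log likelihoods
are compared directly. Pairwise: two-sided Wilcoxon signed-rank with zeros
dropped, averaged ranks, tie-corrected normal variance and no continuity
correction; for n ≤ 12 effective pairs an exact p by enumeration of all 2ⁿ
sign assignments is reported alongside. Group level: random-effects BMS
with a uniform Dirichlet prior (α₀ = 1), iterating per-subject
responsibilities `g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))` against
`α = α₀ + Σ_n g_n` to a 1e-8 step tolerance (cap 10⁴ iterations).
Exceedance probabilities come from 10⁶ Dirichlet Monte-Carlo draws; the
Bayes omnibus risk compares the converged variational free energy against
the null of equal frequencies, `F0 = Σ_n [logsumexp(L_n) − log K]`, via
`BOR = 1/(1 + exp(F1 − F0))`; protected exceedance probabilities are
`pxp = (1−BOR)·xp + BOR/K`. The whole procedure is invariant to adding
per-subject constants to all models' log evidences.

## Recovery harnesses

Parameter recovery simulates a cohort from planted parameters, refits
jointly, and scores bias, median absolute error and (when spread > 0) the
truth/estimate correlation per parameter. Model recovery simulates one
22-subject cohort per generating model at the default scale, fits all
candidates to every subject, and tabulates generating-versus-selected
confusion matrices under two selection rules: highest per-subject RFX-BMS
posterior (the primary criterion) and highest raw log likelihood. Runs at
documented equivalence points (no combined trials; σ_m = σ_f with old off)
are flagged rather than failed.

## Numerical and scale choices

Standard-normal CDFs use `scipy.special.ndtr`; likelihood evaluation is
vectorized over trials. Benchmarks in the test suite use 22 subjects at
`n_reps = 20` (parameter recovery) and `n_reps = 8` (model recovery) with
10 restarts — the study's own scale — while unit tests run scaled-down
cohorts (2–8 subjects, 2–12 repetitions) that exercise the same code
paths. Monte-Carlo oracle checks use 10⁵ decision-rule samples and a
3-binomial-SE band.

## Known limitations

* The exact supplementary equations of the incorrect-beliefs variant and
  the original study's fitting bounds are not public; the implementations
  here follow the stated generative model and standard practice, and are
  validated against this package's own Monte-Carlo oracles rather than the
  original code.
* The incongruent-condition x-axis for psychometric summaries (form,
  motion, or pair mean) is a presentation choice; the default is the pair
  mean, and the qualitative old-off/old-on curve-shift signature holds
  under any of the three.
* Published headline statistics (log-likelihood differences, pxp values,
  subject counts) depend on the non-redistributable human dataset; this
  package reproduces the analysis machinery and its recovery benchmarks,
  not those numbers.
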