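# Methods

This note documents the models, the estimation and inference procedures,
the synthetic-data generators, and the numerical and design choices behind
them. Empirical claims here are limited to what the test suite and
`scripts/acceptance.py` themselves compute.

## Task and learning models

The task presents four stimuli — AB, AC (two features) and B, C (one
feature) — with a go-target following AB/C on 70% and AC/B on 30% of
trials. Each run has 10 trials per stimulus (40 trials), shuffled; by
default target counts are exact per run (7/3), matching the printed design
proportions, with a Bernoulli mode available. Each feature alone predicts
the target at exactly 50%, so anticipation requires conjunctive knowledge.

Values code the stimulus–target association, never the monetary outcome:
the update signal is the binary target indicator `R_t`. All models use the
delta rule `V ← V + α (R_t − V)` over different state spaces:

| model | states | prediction | update |
|---|---|---|---|
| no_learning | — | constant v₀ | none |
| base_rate | 1 | shared V | shared V |
| feature | A, B, C | sum of present features | full α·δ to each present feature (no division) |
| conjunctive | AB, AC, B, C | V(stimulus) | presented stimulus only |
| value_spread | AB, AC, B, C | V(stimulus) | presented stimulus, plus α·δ·ω to every feature-sharing stimulus |

The overlap indicator O(s, s′) is 1 for (AB, AC), (AB, B), (AC, C) and 0
for (AB, C), (AC, B), (B, C) and for s′ = s. Spread crosses target classes
(an AB trial updates both AC and B). Values are not clipped for the
feature and spread models; conjunctive values with v₀ ∈ [0, 1] stay in
[0, 1] by construction. State resets to v₀ at every run boundary because
the feature-to-image mappings change between runs and carry-over learning
is meaningless; a no-reset flag exists for sensitivity checks. The design
was genuinely open on whether outcomes were exactly or stochastically
proportioned per run and on the reset; exact proportions and reset are the
defaults, both switchable.

## Fitting and cross-validation

Log RTs of responded trials are modelled as
`log rt_t ~ Normal(β₀ + β₁ v_t, σ²)`; misses have no RT and are excluded
(the inclusion rule is an option). For *fixed* learning parameters the ML
regression weights are the OLS solution and the ML σ is the RMS residual,
so the optimiser (bounded L-BFGS-B, 20 seeded restarts by default, ties to
first-found) searches only the 1–3-dimensional box of learning parameters
— α, ω ∈ [0, 1], optional v₀ ∈ [0, 1] — with the regression profiled
analytically at each evaluation. This is the exact MLE of the joint
problem, just better conditioned than searching over (α, ω, β₀, β₁, σ)
directly. σ is floored at 1e-4 log-units so noiseless synthetic data do
not produce an unbounded likelihood; the no-learning model is an
intercept-only Gaussian fit computed in closed form.

Cross-validation is leave-one-run-out: all parameters including σ are
refit on the remaining runs and the Gaussian likelihood is evaluated on
the held-out run's responded trials; the total is divided by the number of
included held-out trials so subjects with different response counts are
comparable. Runs are the natural CV unit because category mappings remap
per run, making runs approximately exchangeable learning episodes.

## Model comparison

Per-subject total cross-validated predictive log-likelihoods serve as the
log model evidences (the evidence proxy was an open choice; CV likelihood
is the default because it penalises complexity without a prior).

`group_bms` implements the variational random-effects scheme: model
frequencies r follow a Dirichlet prior (α₀ = 1), responsibilities
`g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))` and concentrations
`α = α₀ + Σ_n g_n` iterate to a 1e-6 fixed point. Exceedance
probabilities come from Monte-Carlo sampling of the posterior Dirichlet
(1e6 samples by default; tolerance scales as 3/√n). The Bayesian omnibus
risk compares the variational free energy of the random-effects model with
the null of equal frequencies, `F₀ = Σ_n log mean_k exp(L_nk)`, giving
`BOR = 1/(1 + exp(F₁ − F₀))` and `pEP_k = xp_k (1 − BOR) + BOR/K`.

**Known property:** the variational posterior concentration is α₀ + N
regardless of how informative the evidence is, so for *ambiguous* evidence
the scheme is sharper (more confident) than the exact posterior; its
exceedance probabilities then deviate from a brute-force
importance-sampling estimate by up to ~0.1–0.3. Under decisive evidence
(a consistent advantage of a couple of nats per subject) or exact
symmetry, the two agree to well under 0.02, and the tests check agreement
in those regimes.

On synthetic cohorts generated from the value-spread model at ω = .44 the
four-model comparison selects value_spread decisively, while the
three-model comparison (no_learning / feature / conjunctive) tends to
prefer *feature*: which pure model best approximates a spread mixture
depends on ω, and results on real subjects need not match this synthetic
ordering.

Pairwise comparisons use two-sided Wilcoxon signed-rank tests on
per-subject per-trial CV likelihoods (exact enumeration for n ≤ 25 without
ties, normal approximation otherwise; all-zero differences are flagged
degenerate rather than tested). The per-run conjunctive-learning index is
LL(conjunctive) − LL(value_spread), each evaluated per run at that model's
subject-level ML parameters; it is ≤ 0 in sample by nesting, values nearer
0 meaning more purely conjunctive behavior, and the engagement nuisance is
LL(value_spread) − LL(no_learning) computed the same way.

## Prediction-error regressors and the striatal decomposition

The feature-model PE trace is z-scored directly; the conjunctive regressor
is the z-scored per-trial *difference* of the feature and conjunctive PE
traces (default feature − conjunctive, with the convention stamped in the
output — both orders are supported because the source descriptions of the
subtraction order conflict, and the choice only flips the coefficient
sign). Differencing removes most of the variance the two learning systems
share; the residual correlation between the two regressors is reported,
not assumed. Regressor-construction parameters default to group-median
fitted values so regressors are identical across subjects.

Group inference is two-stage: per-subject OLS of per-trial betas on
(intercept, target, feature-PE, conjunctive-PE), then one-sample t-tests
across subjects — the exact equivalent of a random-intercept model for
balanced designs, which these are by construction. Rank-deficient
per-subject designs are excluded and reported. The run-level
brain–behavior coupling mirrors a random-slope model the same way:
within-subject centering, per-subject slope of conjunctive-PE coefficient
on overlap coefficient across runs, group t on the slopes; single-run or
zero-variance subjects are dropped and reported.

## Pattern-similarity analysis

The dependent variable is the Fisher-transformed Pearson correlation of
every trial pair's activation patterns, with |r| clipped to 1 − 1e-7 so
identical patterns stay finite; zero-variance trial patterns invalidate
their pairs, which are excluded from regression. All pairs enter, within
and across runs, with both-in-run indicator columns and linear/quadratic
elapsed-time columns (global trial-index difference) absorbing session
structure; whether the original analysis excluded within-run pairs was
unstated, so all-pairs-with-nuisance is the documented default.

Design columns (all z-scored; intercept added at fit time):
within-stimulus (1 identical stimulus), overlap (+1 share / −1 no-share /
0 same-stimulus, optionally split into separate share and no-share
indicators for visualization models), PE- and value-similarity (negated
absolute differences of trial PEs / post-update values, so positive
coefficients mean similarity coding), response (+1 same response demanded,
−1 otherwise), target (+1 both-target / −1 both-non-target / 0 mixed), and
time × within-stimulus. The value and PE columns are residualized against
(intercept, response, target) *before* z-scoring, assigning shared
variance to the outcome columns. The optional learning-epoch interaction
codes +1 for pairs both late in their run, −1 both early (median split on
within-run position), 0 mixed, and multiplies the orthogonalized value
column.

Inference shuffles the vector of pair similarities uniformly (default
10,000 shuffles), refits, and reports one-sided
`p = (1 + #{null ≥ obs})/(1 + n_perm)` in the tested direction (the +1
keeps p > 0); the tested sign is configurable per column (e.g. −1 for the
epoch interaction). Between-region contrasts shuffle each region's vector
independently and use the per-shuffle coefficient difference as the null —
identical regions then give p ≈ .5 rather than a degenerate null. A
permutation of *trial labels* applied identically to two regions leaves
the observed difference unchanged (paired construction).

## Pattern content

Templates are per-category means over localizer miniblocks (all localizer
runs pooled; matched-run templating was an open choice). Each task trial
is correlated with the template of the category its diagnostic feature
maps to in that run — B and AB score against B's category, C and AC
against C's — so single- and two-feature conditions are template-matched
within run and any difference reflects the task representation.
Similarity is the same clipped Fisher-z correlation as the PSA. Condition
nulls shuffle condition labels within run, independently per region for
the region-difference null. A mean-pattern-removal toggle exists
(default off) in place of the out-of-scope stimulus-general-activation
control.

## Synthetic-data generators

**Behavior.** Latent `log rt = log(0.4 s) + β₁ v_t + ε`,
`ε ~ Normal(0, σ_gen)`, with β₁ = −0.4 and σ_gen = 0.15 as the default
study conditions. Target trials always draw a response; the trial is a hit
(+25¢) if rt beats the adaptive threshold, else a slow miss (0¢). On
non-target trials the subject anticipates (false alarm, −25¢) with
probability `sigmoid(−2 + 3 v_t)` — the generative anticipation rule is a
package choice (instructions encouraged anticipatory responding but no
rule exists to copy); its logistic form and parameters were picked so
false alarms are rare at zero value (~12%) and rise steeply with value
(toward ~50% for strongly target-predictive stimuli), and they are config
fields. The threshold starts from
a calibration phase with 30 ms steps (converging on the median baseline
RT, hence ~50% hits) and moves ±10 ms per target trial during the task.
Trial timing fields (600 ms target onset, Poisson ITI) are carried as
metadata only; nothing downstream consumes them.

**Patterns.** `pattern_t = a·prototype(stim) + b·Σ_f component(f) +
c·(cos θ_t e₁ + sin θ_t e₂) + noise` with fixed seeded unit-norm vectors
and `θ_t = v_t π + d·progress_t·φ(stim)`. The value term is a *direction*
rotating with value inside a fixed 2-plane rather than a scaled axis:
correlation-based similarity measures alignment, not proximity, so only a
rotating code makes value-similar trials genuinely similar — the structure
the value-similarity regressor tests. The epoch-drift term d adds a
stimulus-specific rotation growing over the run, so value-similar trials
of different stimuli drift apart late in learning (the mechanism behind a
negative value × epoch coefficient). Default SNR (unit-strength signals,
60 units, noise SD 0.5 per unit) yields pair correlations and regression
coefficients of a few hundredths — the scale typical of event-level
pattern similarity — while keeping planted effects detectable in a
120-trial design. Prototype sampling noise (random cross-prototype
correlations ~n_units^{-1/2}) adds instance-to-instance coefficient
variability; analyses that need single-run coefficient estimates (the
coupling stage) therefore use more units (120) and lower noise, mimicking
a well-measured ROI.

**Striatal betas.** `β_t = w_target·target + w_feature·z_feature_pe +
w_conj·z_conj_diff + noise`; defaults (1.0, 0.25, 0.12, noise SD 0.5)
keep the target effect dominant and the conjunctive component the
smallest, as in the motivating decomposition. The coupling study gives
each subject's three runs low/medium/high overlap strengths
(0.05/0.4/0.75, shuffled, jittered) and sets
`w_conj(run) = 0.12 − 0.5·b(run) + jitter`, guaranteeing within-subject
predictor variance for the two-stage slope.

**Localizer / content modes.** Localizer blocks are category prototypes
plus noise; prototypes are deterministic in the seed and shared with the
task-pattern generator so task/template analyses interlock. Conjunctive
mode draws each two-feature stimulus's pattern from a dedicated prototype
orthogonalized against both feature templates (pattern separation);
additive mode sums the two feature templates with a gain of 1.5, modelling
the stronger cortical drive of compound stimuli (without the gain, adding
an orthogonal second template can only *dilute* the correlation with the
scored template, and two-feature similarity could never reach or exceed
single-feature similarity as the feature-mixing hypothesis expects).

**What the generators do not emulate:** hemodynamics and temporal
autocorrelation, spatial noise structure, run-level scanner drifts beyond
the planted epoch effects, attention fluctuations, and any systematic
relation between behavioral learning and pattern structure other than the
explicitly planted coupling. Passing round-trip tests therefore validates
the *estimators* — that each analysis recovers the structure it targets at
realistic SNR — not claims about real neural data.

## Numerical choices

- σ floor 1e-4 log-units; correlation clip 1 − 1e-7 before arctanh.
- Optimiser: L-BFGS-B within bounds, 20 restarts (first start at
  α = 0.3, ω/v₀ = 0.5; the rest uniform in the box), ties to first-found.
- BMS: variational tolerance 1e-6, 10,000 iteration cap, 1e6 Dirichlet
  samples drawn in 1e5-sample blocks.
- Permutations: dependent-vector shuffles in blocks of 1000 with a
  precomputed pseudoinverse; p-values use the +1 correction.
- All randomness flows from explicit integer seeds; generators use named
  substreams of a master seed (`default_rng([seed, substream])`).
- Exact Wilcoxon enumeration only for n ≤ 25 with untied non-zero
  differences, otherwise the normal approximation.

## Problem sizes

The default study is 30 subjects × 3 runs × 40 trials — the task's own
design size — with 60-unit pattern regions; the full pipeline runs in
~2 minutes on one CPU and `scripts/acceptance.py` (which adds a 30-subject
recovery sweep) in ~3. Calibration tests (permutation type-I error,
striatal null) use a few hundred replicates at reduced design sizes, which
bounds their binomial resolution to a few percentage points around the
nominal level.

## Limitations

- Per-subject ML fits only; no hierarchical shrinkage of α or ω.
- The two-stage group analyses are exact analogs of mixed models only for
  balanced designs; unbalanced real data would need the full likelihood.
- The variational BMS overconfidence under ambiguous evidence (above)
  is inherited by design from the standard procedure.
- The sign conventions for the difference regressor and the value/PE
  similarity columns are choices between two readings of the source
  analyses; both are implemented and the active convention is recorded in
  every output.
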