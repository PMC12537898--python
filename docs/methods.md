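# Methods

This note documents the models, the synthetic-data generators, and the
numerical and design choices behind `twostep_ema`.

## The two-step task environment

One first-stage state offers actions a ∈ {0, 1}; action a leads to
second-stage state a with probability `p_common` (default 0.7) and to the
other state otherwise (`p_common` is only constrained to (0.5, 1]; 0.7 is
the convention of the task family this environment models). Each
second-stage action pays a nonzero integer in {−5…−1, +1…+5}. Payoffs
drift as Gaussian random walks (default step SD 2.0 points) on a latent
continuous scale with reflecting boundaries at ±5; the delivered value is
the latent value rounded to the nearest allowed integer, with the zero gap
resolved away from zero toward the latent sign (exact zero by a fair
coin). Both walk SD and the boundary rule are configurable because the
task family varies on them; the defaults are the gamified-variant
convention. Trials are 1-based in files, 0-based in memory.

## The hybrid reinforcement-learning model

Seven parameters: stage-specific learning rates α₁, α₂ ∈ [0, 1], trace
weight λ ∈ [0, 1], inverse temperatures β₁, β₂ ≥ 0, model-based weight
ω ∈ [0, 1], and a first-stage choice-repetition bonus *rep* (logit units).
Second-stage values Q₂(s, a) learn by δ₂ = r − Q₂; first-stage model-free
values learn by δ₁ = Q₂(s₂, a₂) − Q_MF(a₁) plus the λ-weighted carry-back
of δ₂ (SARSA(λ)). Model-based first-stage values are recomputed each trial
from the transition structure,
Q_MB(a) = p·max_{a′} Q₂(common(a), a′) + (1−p)·max_{a′} Q₂(other(a), a′).
First-stage choice is a softmax over β₁·[ω·Q_MB + (1−ω)·Q_MF] plus *rep*
for the previously chosen action; second stage a softmax over β₂·Q₂. All
values start at 0; softmaxes use log-sum-exp and are exact for arbitrarily
large β. Ties in the max over second-stage actions cannot affect the value
(the max is unique by value); where an argmax must be named the lower
index wins.

Payoffs enter the likelihood unscaled (±1…5 points). Inverse temperatures
therefore live on a smaller numeric scale than in binary-reward tasks:
β = 2 here corresponds to a logit difference of up to 20 between actions.

### MAP estimation

Per-subject maximum a posteriori estimation replaces hierarchical sampling
to keep fits deterministic and desk-scale. The objective NLL − log prior
is minimized by L-BFGS-B in unconstrained coordinates (logit for
unit-interval parameters, log for β, identity for *rep*) from 10
prior-sampled restarts; the best converged restart wins and a fit where no
restart converged is returned flagged. Priors: Beta(1.1, 1.1) on
unit-interval parameters, Normal(0, 1) on *rep*, Gamma(shape 1.2,
rate 1.0) on β₁, β₂. The Gamma rate is matched to the unscaled payoff
range: with a mode of 0.2 and mean 1.2 it is weakly informative over the
plausible β range (≈0.3–4) and shrinks β toward 0 on the α → 0
identifiability ridge, where the likelihood carries no information about β
(a rate borrowed from binary-reward conventions would instead pull
unidentified temperatures toward 1). Reduced variants (shared α, shared β)
are available as fit flags and serve as the AIC/BIC model-comparison set.

A numerical Hessian of the penalized objective is checked for positive
definiteness at the optimum (`hessian_ok`).

### RPE decomposition

Two events per trial. At second-stage onset the model-free RPE is
Q₂(s₂, a₂) − Q_MF(a₁) and the model-based RPE is Q₂(s₂, a₂) − Q_MB(a₁),
both evaluated at pre-update values; their difference is the unique
model-based component. At outcome both systems share r − Q₂(s₂, a₂), so
the unique component is identically zero there — this is a structural
contract, not an empirical finding. Exports concatenate both event
streams per trial.

### Parameter recovery

Generating distributions for the recovery experiment: α₁, α₂, λ ~
Beta(2, 2); β₁, β₂ ~ Gamma(3, scale 2/3) (mean 2, SD ≈ 1.15 on the
point scale); ω ~ Beta(2.4, 1.4), i.e. cohort mean 0.63 and SD 0.22;
*rep* ~ Normal(0.2, 0.3). At 67 agents × 201 trials the Pearson
correlation between generating and recovered ω is typically 0.7–0.85;
it rises with trial count, as recovery is information-limited at this
session length. Undefined correlations (zero generating spread) are
reported as such rather than propagated as NaN.

## The stay/switch MB score

Lag-1 logistic mixed-effects regression of repeating the first-stage
choice on previous outcome (reward vs punishment by the sign of the
points, +0.5/−0.5), previous transition (common/rare, +0.5/−0.5) and
their product, with per-subject random intercepts and uncorrelated random
slopes for all three terms. The per-subject MB score is the fixed
interaction plus the subject's shrunken (posterior-mean) interaction
slope. Estimation is variational Bayes (`statsmodels`
`BinomialBayesMixedGLM`); posterior SDs are known to be somewhat
anti-conservative, which matters for declaring effects *absent* but not
for the detection and scoring uses here.

Two optional covariates implement corrections to the lag-1 regression: a
standardized trial-number term (drift/fatigue) and a standardized
previous-points magnitude term. The magnitude term exists because the
binary reward/punishment coding discards payoff size in a task whose
payoffs are graded: a purely model-free agent's stay probability tracks
the full magnitude, and the part the sign coding misses correlates with
transition type through the payoff walks, producing a spurious
"model-based" interaction of around 0.2–0.8 logits in pure model-free
cohorts. Consequently, "model-free agents show no interaction" holds here
as a magnitude statement (the off-target coefficient is a small fraction
of the on-target one), not as a z-threshold statement — with tens of
thousands of trials any systematic artifact is "significant".

## The EMA generator

The generator emulates a year-long smartphone protocol: a three-category
drinking-intention item ("none", "no_more", "less") every 8 days, valid
for the query day plus 7 following days, and a consumption item every 2
days reporting grams of ethanol for each of the two preceding days
separately. Intentions follow a sticky Markov chain over 8-day blocks
(persistence 0.4, stationary distribution 0.45/0.30/0.25) whose
stationary law is exact by construction. Subject traits are ω ~
Beta(2.4, 1.4) and three regional neural-signature means (hippocampus,
ventral striatum, vmPFC) drawn jointly standard normal with pairwise
correlation 0.5, independent of ω by default.

Daily grams come from one of two families:

* **hurdle** (default, realistic): a logistic drinking indicator followed
  by a log-normal amount, each with its own subject random intercept and
  shared random intention slopes, and trait × intention interactions on
  both parts. ω enters interactions uncentered (it is bounded in [0, 1]);
  signatures are standardized. Fixed-effect defaults are the coefficient
  pattern of the motivating cohort (log-gram estimates for the amount
  part, log odds-ratios for the indicator part); intercepts and variance
  components were calibrated once so the defaults reproduce the anchor
  statistics — mean intake ≈ 32 g/day, ICC of log(g+1) ≈ 0.16, "less"
  intention on ≈ 25% of days, ≈ 45% abstinent days.
* **loglinear**: the analysis-scale model itself, log(g+1) = Xβ + u₀ +
  u_less·less + u_no_more·no_more + ε with grams = max(exp(y) − 1, 0).
  This family makes the downstream linear mixed model correctly specified
  (up to the small truncation at zero), which is what simulation-based
  calibration of coverage and type-I error requires. Coverage and ICC
  experiments use a raised intercept (4.0 log-grams) so that truncation
  affects well under 1% of days; with the realistic intercept (2.37) the
  truncation itself produces the zero-inflation.

Missingness is MCAR at the whole-rating/whole-report level. The single
`p_miss` parameter is the target share of invalid days; it is split evenly
across the two streams (per-stream rate 1 − √(1 − p_miss)), because an
intention rating invalidates 8 days and a consumption report 2. With the
default 0.24 the mean number of valid days per subject is ≈ 273 of 359.

What the generator does **not** emulate: staggered enrollment and dropout
(so the between-subject SD of valid days is far smaller than in real
cohorts), informative (MAR/MNAR) missingness — hooks exist but no
mechanism is shipped — beverage-type composition, weekday/seasonal
structure, and any feedback from drinking to later intentions. Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated data-generating process, not robustness to these real-data
features.

### Restructuring

Raw ratings and reports are merged to day-level records: each rating
covers its query day plus the following 7 (window configurable); where
windows overlap, the later rating wins (recency rule). Each report
contributes grams to the two days preceding its query day; consistent
duplicates are idempotent, conflicting duplicates raise an error listing
subject and day. A day is valid only when both grams and intention are
defined. With the default schedules the operation is order-independent.

## Moderation analysis

Linear mixed models on log(grams + 1) are fitted by maximum likelihood
(`statsmodels` `MixedLM`); the logistic counterpart on the drinking
indicator (grams > 0) by variational Bayes. Intention is dummy-coded with
"none" as reference. Fixed effects: both contrasts, all requested traits
(ω and MB score uncentered, signatures and cognitive covariates
z-standardized), and every trait × contrast interaction. Random
structures: subject intercept; plus uncorrelated contrast slopes; plus
their correlations — compared by sequential likelihood-ratio tests
(χ² with df = parameter difference; boundary nulls make these
conservative, which is logged, not corrected). The GLMM backend cannot
estimate random-effect correlations; requesting the correlated structure
there falls back to uncorrelated slopes with a note.

p-values use Wald degrees of freedom (n_obs − n_fixed) for the LMM and
normal z for the GLMM. Confidence intervals are Wald throughout; the
backend does not profile fixed effects, and every fit records this in its
notes. Estimated marginal means evaluate the fixed-effect predictor at
specified trait values per intention category and back-transform via
exp(m) − 1 (CI endpoints transformed, gram-scale SE by the delta method);
requesting trait values outside the observed range warns. The
unconditional ICC is between-subject variance over total variance from an
intercept-only LMM and is reported as undefined (not an error) for
degenerate data. No multiplicity correction is applied across the
trait × contrast interactions, matching the analysis style the package
reproduces; robust re-estimation is out of scope and an influence check
(residual inspection, subject-level leverage via the exported random
effects) is left to the user.

Numerical details: the default MixedLM optimizer is used with Powell and
conjugate-gradient fallbacks, and a fit is treated as failed when the
optimizer reports non-convergence or a non-finite likelihood; LMM failures
trigger a flagged refit with the next simpler random structure. The
variational GLMM initializer draws from NumPy's global legacy RNG; it is
pinned locally (and the caller's state restored) so identical inputs give
identical fits. Complete separation in the GLMM (constant outcome or
runaway coefficients) is flagged, never silently returned.

## Problem sizes in the shipped experiments

Simulation experiments use the cohort sizes of the emulated study design:
67 subjects × 201 trials for recovery, 40 × 500 for cohort signature
checks, and 67 subjects × 270 valid days for moderation-recovery
(100 replicates for CI coverage, 200 for type-I error) and ICC
experiments. These sizes are the study conditions being emulated, and at
them the whole suite runs on a single desktop core.

## Known limitations

* Per-subject MAP underestimates between-subject shrinkage relative to a
  hierarchical fit; recovery correlations are interpreted accordingly.
* Variational posterior SDs in the logistic mixed models are
  anti-conservative; decisions about *absent* effects should not ride on
  their z-values alone.
* The exact variant of the lag-1 correction used in the literature this
  package mirrors is not public; the shipped trial-number and magnitude
  covariates are this package's interpretation.
* The loglinear generator truncates at zero grams; with low intercepts
  this censoring attenuates coefficients of the corresponding LMM, which
  is why calibration experiments raise the intercept.
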