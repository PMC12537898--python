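# twostep-ema

Computational-psychiatry toolkit linking laboratory model-based control to
real-life drinking regulation. It implements, as one tested pipeline:

1. the **two-step sequential decision task** (stochastic common/rare
   transitions, Gaussian-random-walk payoffs of ±1…5 points);
2. the **hybrid model-free/model-based reinforcement-learning model** with
   SARSA(λ) updates, simulation, exact likelihood, per-subject MAP fitting,
   decomposition of reward prediction errors (RPEs) into model-free and
   unique model-based components, and parameter-recovery experiments;
3. the regression-based **MB score**: a logistic mixed model of stay/switch
   behaviour whose previous-outcome × previous-transition interaction
   indexes model-based control per subject;
4. a **synthetic EMA generator** for year-long smartphone data — weekly
   drinking intentions ("none" / "drink no more than usual" / "drink less
   than usual", queried every 8 days) and daily alcohol intake in grams
   (reported every 2 days for the two past days) — with zero-inflated,
   right-skewed consumption and subject random effects;
5. the **moderation analysis**: linear mixed models on log(grams + 1) and
   logistic mixed models on drinking vs abstinence with cross-level
   trait × intention interactions, random-structure selection by
   likelihood-ratio test, intra-class correlation, and estimated marginal
   means back-transformed to grams.

It is written for researchers who want to prototype, power, or sanity-check
this class of design — RL phenotyping at baseline, intensive-longitudinal
outcomes, cross-level moderation — on fully synthetic data with known
ground truth.

## The model in brief

First-stage choice follows a softmax over
β₁·[ω·Q_MB(a) + (1 − ω)·Q_MF(a)] + rep·1[a = a_prev], where
Q_MB(a) = p·max Q₂(common(a), ·) + (1 − p)·max Q₂(other(a), ·) is computed
prospectively from the transition structure and Q_MF learns by SARSA(λ).
ω ∈ [0, 1] is the model-based weight: ω = 1 pure model-based, ω = 0 pure
model-free. At second-stage onset the unique model-based RPE component is
the difference between model-based and model-free RPEs; at outcome both
systems share r − Q₂, so the unique component is zero. Daily drinking is
analysed as log(grams + 1) (LMM, maximum likelihood) and as a drinking
indicator (logistic GLMM), with intention dummy-coded against "no specific
intention" and trait × intention interactions quantifying how well a
subject's behaviour tracks their stated intention. See
[docs/methods.md](docs/methods.md) for the full specification.

## Worked example

```python
import numpy as np
from twostep_ema import (TaskConfig, HybridParams, simulate_agent,
                         fit_subject, EMAGenConfig, simulate_cohort,
                         restructure, summarize, ModerationSpec,
                         fit_moderation, icc)

rng = np.random.default_rng(1)

# a moderately model-based agent plays 201 trials and is refitted by MAP
truth = HybridParams(alpha1=0.5, alpha2=0.5, lam=0.6, beta1=2.0,
                     beta2=2.0, omega=0.8, rep=0.2)
trials = simulate_agent(truth, TaskConfig(), rng)
fit = fit_subject(trials, rng=rng)
print(f"omega true 0.80, recovered {fit.params.omega:.2f}, "
      f"NLL {fit.nll:.1f}")

# a synthetic EMA cohort at study scale, restructured to daily records
traits, ratings, reports = simulate_cohort(EMAGenConfig(seed=1))
daily = restructure(ratings, reports)
s = summarize(daily, traits)
print(f"valid days/subject {s.valid_days_mean:.0f}, "
      f"mean intake {s.mean_grams:.1f} g/day, "
      f"'less' days {s.pct_intention['less']:.1f}%")
print(f"ICC(log g+1) = {icc(daily).icc:.2f}")

# does omega moderate the effect of the 'drink less' intention?
mod = fit_moderation(daily, traits, ModerationSpec(traits=("omega",)))
est, p = mod.coef("omega_x_less"), mod.p("omega_x_less")
print(f"omega x 'less' interaction: {est:.2f} (p = {p:.4f})")
```

prints

```
omega true 0.80, recovered 0.80, NLL 97.2
valid days/subject 272, mean intake 29.9 g/day, 'less' days 26.3%
ICC(log g+1) = 0.14
omega x 'less' interaction: -1.42 (p = 0.0217)
```

The recovered ω tracks the generating value; the cohort reproduces the
target descriptive statistics (≈272 valid days, ≈30 g/day, "less"
intention on ≈25% of days, ICC ≈ 0.16); and the negative ω × "less"
interaction means subjects with more model-based behaviour drink less,
relative to their own no-intention baseline, in periods where they intend
to cut down — the generator's built-in moderation effect, recovered by
the mixed model.

The same chain is available from the shell:

```sh
twostep-ema run --seed 1 --out runs/demo          # full pipeline
twostep-ema simulate-task --subjects 67 --out trials.csv
twostep-ema recover --seed 1 --subjects 67 --out recovery.csv
```

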