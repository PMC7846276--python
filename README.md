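# lapsekit

Perceptual decision-makers — rats, mice, humans — make a small, stubborn
fraction of errors even on the easiest stimuli.  These *lapses* are usually
brushed aside as inattention or motor slips.  `lapsekit` implements, fits and
simulates a family of generative choice models in which lapses are instead
**uncertainty-guided exploration**: when an observer is uncertain about the
values of its actions, softmax/Thompson-style exploration produces asymptotic
error rates that depend on each action's reward, and on nothing else.

The package targets a two-alternative rate-discrimination task: a 1 s stream
of auditory clicks and/or visual flashes at 9–16 events/s is judged against an
abstract category boundary of 12.5 Hz (high → right port, low → left port,
24 μL water per correct choice; visual, auditory and matched multisensory
trials interleaved 40/40/20, plus "neutral" multisensory trials whose visual
stream sits at 12 Hz, and 6% zero-uncertainty "sure-bet" trials).

## Models

The descriptive psychometric curve is

ψ(x) = γ + (1 − γ − λ) Φ((x − μ)/σ),

with lapse parameters γ (low-rate) and λ (high-rate).  The generative
families explain γ and λ mechanistically:

| family | choice rule | asymptotes |
| --- | --- | --- |
| ideal observer | pick argmax of Q(a) = ρ·q(High,a) + (1−ρ)·q(Low,a) | γ = λ = 0 |
| inattention | ideal with prob. p_attend, else guess p_bias | γ+λ = 1−p_attend, γ/(γ+λ) = p_bias |
| ε-greedy / motor error | ideal with prob. 1−ε, else guess | γ+λ = ε |
| exploration | p(R) = softmax(β(Q_R − Q_L)), marginalized over the belief state ρ | γ = 1/(1+e^{β r_L}), λ = 1/(1+e^{β r_R}) |

Here ρ = Φ((x_combined − μ₀)/σ_post) is the posterior belief that the rate is
high, with multisensory noise optimally combined,
σ_M = (σ_A⁻² + σ_V⁻²)^(−1/2).  Only the exploration model predicts that a
one-sided reward change moves one lapse and leaves the other untouched —
which is what the package's manipulation and inactivation machinery tests.

Modules:

- `lapsekit.models` — pure choice-probability functions (the exploration
  marginal is evaluated by criterion-refined Gauss–Legendre quadrature,
  accurate uniformly in β).
- `lapsekit.fitting` — maximum-likelihood fits on trial tables with
  cross-condition constraints, the four lapse-variant psychometric models,
  AIC/BIC comparison, Hessian and bootstrap confidence intervals,
  multisensory-optimality checks, and a constrained exploration model whose
  lapse is linear in each condition's sensory noise.
- `lapsekit.perturbations` — one-sided reward-magnitude/probability
  manipulations, and one-parameter inactivation deficits (biased evidence /
  biased value / biased effort) with joint control+perturbed fits.
- `lapsekit.synthetic` — task-structured trial generator, forward sampling
  of any model family, and a Thompson-sampling learning agent with
  belief-state credit assignment.
- `lapsekit.io`, `lapsekit.cli` — CSV/JSON interchange and a CLI
  (`simulate`, `fit`, `compare`, `perturb`, `agent`, `report`).

## Worked example

```python
from lapsekit import fitting as F, synthetic as S

trials = S.generate_trials(n_trials=30000, seed=1)
data = S.simulate_choices(trials, "exploration",
                          S.default_generative_params(), seed=2)

fit = F.fit_model(data, F.ModelSpec(family="psychometric",
                                    lapse_variant="variable"), seed=0)
for cond, (gamma, lam) in F.lapse_rates(fit).items():
    print(f"{cond:>13}: gamma={gamma:.3f} lam={lam:.3f} total={gamma+lam:.3f}")
```

prints

```
       visual: gamma=0.092 lam=0.098 total=0.190
     auditory: gamma=0.112 lam=0.110 total=0.222
 multisensory: gamma=0.020 lam=0.024 total=0.045
```

i.e. the fitted lapse probability is smallest on multisensory trials and
largest on auditory trials, tracking each condition's sensory noise — the
signature of uncertainty-guided exploration (a fixed-error or inattention
observer would produce equal totals in all three conditions).  Comparing the
four psychometric lapse variants ranks them by BIC:

```python
table, fits = F.lapse_variant_comparison(data, seed=0)
print(table[["model", "k", "loglik", "d_bic"]].to_string(index=False))
```

```
           model  k        loglik     d_bic
  variable_lapse 12 -13314.610530  0.000000
     fixed_lapse  8 -13343.562401 16.915290
restricted_lapse 12 -13331.622150 34.023240
      none_lapse  6 -13382.356532 74.009327
```

so condition-specific lapses are warranted on these data, and a model with
no lapses at all is strongly rejected.

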