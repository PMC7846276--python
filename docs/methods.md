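# Methods

## Task and decision variable

All models describe two-alternative rate discrimination: a 1 s stimulus
carries an integer nominal event rate on the 9–16 Hz grid (eight levels), the
category boundary is 12.5 Hz, and high rates are rewarded at the right port
under the standard contingency (the reversed contingency swaps the
category→action map, never the stimulus axis).  The nominal rate is the
decision variable everywhere; the generator also builds per-trial event
streams from 50 ms and 100 ms inter-event intervals (9 Hz = all long,
16 Hz = all short, intermediate rates a shuffled mixture, so the event count
over 1 s equals the nominal rate) and truncated-exponential pre-stimulus
delays (scale 30 ms on [10, 200] ms), but these are cosmetic realism: no
model consumes them.  Reward magnitudes are carried in μL and converted to
value units of one baseline reward (24 μL ≡ 1).

## Observer models

A trial's sensory evidence is a Gaussian-corrupted observation of the true
rate, with per-modality noise σ_A, σ_V (Hz) and the multisensory noise at the
inverse-variance combination σ_M = (σ_A⁻² + σ_V⁻²)^(−1/2).  The belief state
ρ = Φ((x − μ₀)/σ_post) is the posterior probability of the high category
under flat priors; deviations from flat priors or from the true boundary are
absorbed into the fitted subjective boundary μ, so the exploration model
fixes priors at 0.5/0.5 by design.  Expected action values are linear in ρ,
Q_a(ρ) = ρ·q(High,a) + (1−ρ)·q(Low,a) (+ an additive effort offset), with a
trained observer holding q(High,R) = r_R, q(Low,L) = r_L and zero
off-diagonal values.

The families differ only in the decision rule applied to Q: strict
maximization (ideal observer, with the reward/prior criterion
1/(1 + p_High r_R / (p_Low r_L)) on the posterior), attention-gated
maximization (inattention), fixed-rate random choice (ε-greedy / motor
error), a softmax in value space (exploration), or a softmax in
log-value space (probability matching, which provably produces no lapses and
is included only as a contrast).

## Evaluating the exploration marginal

The exploration choice probability is the marginal of
softmax(β(Q_R(ρ(x)) − Q_L(ρ(x)))) over the observation x ~ N(s, σ_post).
Because Q_R − Q_L is linear in ρ, the integrand contains a single logistic
transition at the decision criterion whose width scales as 1/(β·reward);
a fixed Gauss–Hermite rule under-resolves it once β is large.  The integral
is therefore evaluated in standardized observation coordinates with
composite 8-point Gauss–Legendre panels over [−8, 8] plus panels
geometrically refined around the criterion (16 doublings of the transition
width).  This is accurate to ~1e-10 against the belief-space density-ratio
form of the same integral and to ~1e-8 against the closed-form
ideal-observer limit at β = 10⁴, at ~0.3 ms per 8-point rate grid.  The
belief-space density-ratio integral is kept only as a test oracle (evaluated
with log-space density ratios and analytic endpoint slivers, since the ratio
is numerically unstable near ρ ∈ {0, 1}).

## Fitting

Likelihoods are Bernoulli in the rightward choice, computed on
(condition × nominal rate) bins — identical to the trial-wise sum because
every model predicts one probability per bin — with probabilities clipped to
[1e-9, 1−1e-9] inside the likelihood only.  Optimization is bounded L-BFGS-B
from the best of n_starts = 10 starts (a data-informed default plus
Latin-hypercube draws inside the bounds, seed-controlled and therefore
bit-reproducible).  Default bounds: μ ∈ [rate_min − 2, rate_max + 2] Hz,
σ ∈ [0.1, 10] Hz, γ, λ ∈ [0, 0.5], β ∈ [0, 50], rewards ∈ [0.01, 10].
Psychometric variants without cross-condition sharing (none / restricted /
variable lapses) are fit one condition at a time and recombined; the
restricted variant is reparameterized as (total, fraction) with
total ≤ 0.1 so the constraint is a box.  Model comparison uses
AIC = 2k − 2ℓ and BIC = k ln n − 2ℓ, re-zeroed at each subject's best model;
ties within 1e-6 break toward fewer parameters.

The multisensory σ is constrained to the optimal combination for all
theoretical-model fits and left free for the descriptive psychometric family
— which is what the optimality check needs, since it compares the measured
multisensory σ to the prediction from the unisensory fits.  Ignoring lapses
inflates the unisensory σ estimates much more than the multisensory one and
makes integration look supra-optimal; the variable-lapse fit removes the
artifact.

Confidence intervals: Hessian (Wald) intervals use numerical curvature of
the negative log-likelihood (`statsmodels.tools.numdiff`), stepping 1e-5
inside the bounds; singular curvature falls back to the bootstrap with a
warning.  Bootstrap intervals resample trials with replacement (an exact
multinomial over bin × outcome cells), refit warm-started from the point
estimate, and report percentiles; default 1000 resamples.

### Identifiability caveat

With σ ≳ 2 Hz the 9–16 Hz range barely reaches the curve asymptotes, and
(σ, lapse) — or (σ, β) in the exploration family — trade off along a flat
likelihood ridge.  Point estimates of lapse parameters are then noisy (and
per-condition β fits can even prefer a no-lapse/large-σ mode on a given
sample), while the infinite-data estimates remain essentially unbiased
(pseudo-true fitted lapse within ~0.006 of the generative asymptote across
σ ∈ [1, 2.8]).  Consequences adopted throughout: cohort summaries average
fits across subjects; recovery is assessed by bootstrap-CI coverage rather
than point error; and the manipulation/inactivation analyses use *joint*
control+perturbed fits that share σ and β across blocks so the ridge
cancels out of the contrast.

## Perturbations

Reward manipulations act on single stimulus–action values: a magnitude
factor scales the named action's values (36/24 = 1.5, 16/24 = 2/3), and
probabilistic reward on the incorrect side sets that (category, action)
value to p·r (expected value; the generator still delivers stochastic
rewards).  Inactivation deficits attach to the action contralateral to the
infused hemisphere: biased evidence shifts the effective rate by K·σ_c away
from that action, biased value scales its values by K ∈ (0.01, 1]
(enhancement K > 1 behind an explicit option, default off), biased effort
adds a cost K ≤ 0.  Joint fits share every baseline parameter between
control and perturbed blocks and add exactly one free parameter (K, or the
manipulated value difference); the one-sidedness analysis optionally frees
both of the manipulated block's value differences
(d_high = q(High,R) − q(High,L), d_low = q(Low,L) − q(Low,R)) so the data,
not the parameterization, decide whether the un-manipulated side moved.

Sure-bet trials are modeled as the zero-uncertainty limit: the observer
exploits, choosing the cued action whenever its (possibly scaled) value
exceeds the alternative's — hence exact immunity to any multiplicative value
change, and to effort costs smaller than the reward.  The generator adds a
0.5% motor slip so simulated sure-bet accuracy is ~0.995 rather than 1.

## Synthetic cohort

The generator's operating point is the study population it emulates:
condition-average total lapse probabilities 0.17 (visual), 0.21 (auditory,
also used for neutral trials) and 0.06 (multisensory), converted to
per-condition inverse temperatures through the exploration asymptotes with
unit rewards.  Sensory noises default to σ_A = 1.5 Hz, σ_V = 1.3 Hz
(auditory noisier than visual, consistent with its higher lapse rate;
σ_M optimal ≈ 0.98 Hz), chosen so the extreme rates sit on the flat part of
the curve as the observed curves do — at noticeably larger σ an
exploration-generated curve is mimicked by a lapse-free cumulative Gaussian
with inflated σ, and the lapse parameters that the study demonstrably
measures would not be identifiable in the synthetic data.  A cohort holds
17 rats, 20,000 trials each (≈340k trials, matching the scale of the
behavioral dataset): 14 "explorer" rats whose exploration level is one
shared mean-one lognormal factor per rat (sd 0.25 in log space) times a
small per-condition factor (sd 0.08) — so lapses keep tracking condition
uncertainty within each rat — plus 10% jitter on σ, and 3 near-ideal
"exploiter" rats (total lapse 0.01) mirroring the minority of animals the
ideal observer fits adequately.  Explorer targets are scaled up so the
17-rat average equals the stated condition averages.

One known emulation gap: exploration-generated curves approach their
asymptotes more softly than a true four-parameter psychometric curve, so on
this synthetic cohort the fixed-lapse variant absorbs part of the
between-condition lapse differences into σ and the variable-lapse variant
wins the BIC comparison in fewer animals than it does on real data (the
no-lapse rejection counts are unaffected).

What the generator does **not** emulate: sequential (trial-history) value
updating in the static families, within-stimulus evidence-accumulation
dynamics, event-count biases, session-level nonstationarity, reaction times
and movement kinematics.  Passing tests therefore certify the inferential
machinery on data that satisfy the models' own assumptions, not the models'
adequacy for any real animal.

## Learning agent

The Thompson agent holds independent Normal beliefs over the four
stimulus–action values (prior mean 0.5, prior sd 1.0) with known observation
noise 0.5 (the scale of Bernoulli reward noise), samples one value per pair,
acts greedily on the sampled expected action values, and updates the chosen
action's beliefs for both categories with Kalman gains scaled by the belief
state (ρ for High, 1−ρ for Low) — the simplest conjugate form of
belief-state credit assignment; the rule is a design choice, since only the
policy family is specified by the science.  Ambiguous beliefs make rewards
bleed into the counterfactual category's value (its fixed point is
Σ(1−ρ)r / Σ(1−ρ), well above zero at high sensory noise), which is the
mechanism that keeps value uncertainty and hence exploration alive when
perception is noisy.  Regret accumulates against an oracle that always takes
the truly rewarded action, so perceptual errors burden all policies equally.

Without forgetting, value uncertainty — and exploration — collapses as
learning converges, at a rate set by the sensory noise.  The lapse–noise
study therefore uses the steady-state configuration: a per-trial belief-
variance inflation of 1e-4 (the agent's built-in forgetting option, default
off elsewhere), 4,000 trials, with the asymptotic lapse measured by a
variable-lapse psychometric fit to the final 25% of trials (a fit, rather
than a raw error rate, so perceptual errors at high σ are not mistaken for
lapses).  Under this configuration the mean asymptotic lapse rises
approximately linearly from ~0.02 at σ = 0.5 Hz to ~0.14 at σ = 3 Hz, and
collapses below 0.01 at σ = 0; regret comparisons (Thompson < ε-greedy with
ε = 0.2 < random at 10,000 trials) run with forgetting off.

## Problem sizes

Defaults used by the test suite and the acceptance script: 10,000 trials
per condition for recovery studies (20 seeded replicates, 200-resample
bootstrap CIs), 25,000–36,000 trials per block for manipulation and
inactivation fits, 17 × 20,000 trials for the cohort, and 4 noise levels ×
10 seeds for the agent sweep.  These sizes make every stochastic check
well-resolved while keeping a full run in the minutes range on one core.

## Known limitations

* Wald (Hessian) intervals ignore parameter bounds and can extend below 0
  for small lapse estimates; bootstrap percentile intervals respect bounds.
* The σ/lapse ridge above means single-subject exploration fits with
  per-condition β should be treated as descriptive unless paired with CIs
  or a constraint (shared β, the noise-linear lapse model, or a joint fit).
* The agent's learning rule is one reasonable conjugate choice; its
  quantitative lapse levels (not the qualitative noise scaling or regret
  ordering) depend on the prior and observation-noise hyperparameters.
* Probabilistic reward enters static-model fits as an expected-value change
  (q = p·r); only the generator delivers stochastic outcomes.
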