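"""Synthetic task data and learning-agent simulation.

Generates trial tables with the statistical structure of the multisensory
rate-discrimination task — integer event rates 9–16 Hz around a 12.5 Hz
category boundary, interleaved visual/auditory/multisensory trials
(40/40/20), neutral multisensory trials whose visual stream sits at 12 Hz,
6% sure-bet trials, 24 uL rewards with magnitude/probability manipulations —
and fills in choices by forward-sampling any of the generative model
families.  A Thompson-sampling learning agent provides trajectories linking
sensory noise to exploratory lapses and regret.

Default generative parameters are the task's reported operating point:
condition-average total lapse rates of 0.17 (visual), 0.21 (auditory) and
0.06 (multisensory), converted to inverse temperatures via the exploration
asymptotes with equal unit rewards, and sensory noises sigma_auditory = 3.0,
sigma_visual = 2.6 Hz (auditory noisier, consistent with its higher lapse
rate) with the multisensory noise at the optimal combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .models import TaskConfig, ValueParams, combined_sigma, trained_values
from .perturbations import Deficit, Manipulation, apply_inactivation, \
    apply_value_manipulation, deficit_rate_shift, surebet_prob_correct

__all__ = [
    "TRIAL_COLUMNS",
    "StimulusStream",
    "AgentState",
    "AgentTrajectory",
    "default_generative_params",
    "generate_trials",
    "generate_event_stream",
    "simulate_choices",
    "run_learning_agent",
    "asymptotic_lapse",
    "simulate_rat",
    "simulate_cohort",
]

TRIAL_COLUMNS = [
    "subject_id", "session_id", "trial_index", "condition", "rate_nominal",
    "rate_auditory", "rate_visual", "choice", "rewarded", "reward_left",
    "reward_right", "manipulation", "contingency", "prev_choice", "prev_rewarded",
]

BASELINE_REWARD_UL = 24.0

# reported condition-average total lapse rates used as the generator's
# operating point; neutral trials behave like auditory ones
DEFAULT_LAPSE_TOTALS = {
    "visual": 0.17, "auditory": 0.21, "multisensory": 0.06, "neutral": 0.21,
}
# sensory noises chosen so the extreme rates sit on the flat part of the
# psychometric curve (the observed curves visibly saturate by 9-10 and
# 15-16 Hz, which is what makes their lapse parameters identifiable);
# auditory is noisier than visual, consistent with its higher lapse rate,
# and the multisensory noise is the optimal combination
DEFAULT_SIGMAS = {
    "visual": 1.3, "auditory": 1.5,
    "multisensory": combined_sigma(1.5, 1.3), "neutral": 1.5,
}

SUREBET_ERROR = 0.005  # residual motor slip on sure-bet trials (generator only)


def beta_for_total_lapse(total: float, r_right: float = 1.0, r_left: float = 1.0) -> float:
    """Inverse temperature giving a requested total lapse gamma + lam.

    With equal unit rewards total = 2 / (1 + exp(beta)); general rewards are
    solved numerically.
    """
    if not 0.0 < total < 1.0:
        raise ValueError("total lapse must lie in (0, 1)")
    if r_right == r_left == 1.0:
        return math.log(2.0 / total - 1.0)
    from scipy.optimize import brentq
    return brentq(lambda b: sum(models.exploration_asymptotes(b, r_right, r_left)) - total,
                  0.0, 200.0)


def default_generative_params() -> dict:
    """Per-condition (sigma, beta) of the default exploration generator."""
    return {
        "sigma": dict(DEFAULT_SIGMAS),
        "beta": {c: beta_for_total_lapse(t) for c, t in DEFAULT_LAPSE_TOTALS.items()},
    }


# ---------------------------------------------------------------------------
# stimulus streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusStream:
    """Event times of one 1 s stimulus built from 50/100 ms intervals."""

    event_times: tuple
    interval_sequence: tuple  # values in {0.05, 0.1} s

    @property
    def n_events(self) -> int:
        return len(self.event_times)


def generate_event_stream(rate: int, seed: int = 0) -> StimulusStream:
    """Build a 1 s event stream at the nominal rate.

    Events are separated by short (50 ms) or long (100 ms) intervals; nine
    events per second uses all long intervals and sixteen all short ones,
    with intermediate rates mixing the two (order shuffled by ``seed``).
    """
    if rate != int(rate) or not 9 <= rate <= 16:
        raise ValueError("rate must be an integer in [9, 16]")
    rate = int(rate)
    n_intervals = rate - 1
    n_short = round(n_intervals * (rate - 9) / 7.0)
    intervals = np.array([0.05] * n_short + [0.1] * (n_intervals - n_short))
    rng = np.random.default_rng(seed)
    rng.shuffle(intervals)
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    assert times[-1] <= 1.0
    return StimulusStream(tuple(np.round(times, 10)), tuple(intervals))


def sample_prestimulus_delay(rng: np.random.Generator, scale: float = 0.030,
                             lo: float = 0.010, hi: float = 0.200) -> float:
    """Truncated-exponential pre-stimulus delay (cosmetic; unused by models)."""
    u = rng.uniform()
    # inverse-CDF of the exponential truncated to [lo, hi]
    a, b = math.expm1(-lo / scale), math.expm1(-hi / scale)
    return -scale * math.log1p(a + u * (b - a))


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def generate_trials(config: TaskConfig | None = None, n_trials: int = 10000,
                    seed: int = 0, subject_id: str = "sim",
                    manipulation: str = "none", session_length: int = 500
                    ) -> pd.DataFrame:
    """Generate a trial table (choices unfilled) with the task's trial mix.

    Rates are drawn uniformly from the integer grid 9–16 Hz; neutral trials
    carry an informative auditory rate with the visual stream fixed at 12 Hz;
    sure-bet trials are flagged with a cued side and carry no rate.  Reward
    magnitude columns reflect the requested manipulation (36/16 uL on the
    right for reward_up_right / reward_down_right).  Reproducible given seed.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)

    labels, probs = [], []
    mix_sum = sum(config.modality_mix.values())
    for cond, frac in config.modality_mix.items():
        if frac > 0:
            labels.append(cond)
            probs.append(frac / mix_sum * (1.0 - config.surebet_fraction))
    if config.surebet_fraction > 0:
        labels += ["surebet_left", "surebet_right"]
        probs += [config.surebet_fraction / 2.0] * 2
    probs = np.asarray(probs) / np.sum(probs)
    condition = rng.choice(labels, size=n_trials, p=probs)

    grid = np.arange(int(config.rate_min), int(config.rate_max) + 1)
    rate = rng.choice(grid, size=n_trials).astype(float)
    is_surebet = np.char.startswith(condition.astype(str), "surebet")
    rate[is_surebet] = np.nan

    rate_auditory = np.where(np.isin(condition, ["auditory", "multisensory", "neutral"]),
                             rate, np.nan)
    rate_visual = np.where(np.isin(condition, ["visual", "multisensory"]), rate, np.nan)
    rate_visual = np.where(condition == "neutral", 12.0, rate_visual)

    reward_right = np.full(n_trials, config.reward_right_ul)
    reward_left = np.full(n_trials, config.reward_left_ul)
    if manipulation == "reward_up_right":
        reward_right[:] = 1.5 * BASELINE_REWARD_UL
    elif manipulation == "reward_down_right":
        reward_right[:] = BASELINE_REWARD_UL / 1.5
    elif manipulation not in ("none", "prob_reward_left_on_high",
                              "inactivation_left", "inactivation_right", "saline"):
        raise ValueError(f"unknown manipulation label {manipulation!r}")

    session = np.arange(n_trials) // session_length
    trial_index = np.arange(n_trials) % session_length

    return pd.DataFrame({
        "subject_id": subject_id,
        "session_id": [f"{subject_id}_s{int(s):03d}" for s in session],
        "trial_index": trial_index,
        "condition": condition,
        "rate_nominal": rate,
        "rate_auditory": rate_auditory,
        "rate_visual": rate_visual,
        "choice": np.nan,
        "rewarded": np.nan,
        "reward_left": reward_left,
        "reward_right": reward_right,
        "manipulation": manipulation,
        "contingency": config.contingency,
        "prev_choice": np.nan,
        "prev_rewarded": np.nan,
    }, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# forward-sampling choices
# ---------------------------------------------------------------------------

def _discrimination_probs(trials: pd.DataFrame, family: str, params: dict,
                          config: TaskConfig, deficit: Deficit | None) -> np.ndarray:
    """Rightward probability for every discrimination trial."""
    p = np.full(len(trials), np.nan)
    rates = trials["rate_nominal"].to_numpy(float)
    mu0 = params.get("mu", config.boundary_mu0)

    for cond in trials["condition"].unique():
        if str(cond).startswith("surebet"):
            continue
        m = (trials["condition"] == cond).to_numpy()
        r = rates[m]
        if family == "psychometric":
            p[m] = models.psychometric_prob(r, params["params"][cond])
            continue
        sigma = params["sigma"][cond]
        if family == "ideal":
            p[m] = models.ideal_observer_prob(r, sigma, mu0)
        elif family == "inattention":
            p[m] = models.inattention_prob(r, sigma, mu0,
                                           params["p_attend"], params["p_bias"])
        elif family == "eps_greedy":
            p[m] = models.epsilon_greedy_prob(r, sigma, mu0,
                                              params["eps"], params["p_bias"])
        elif family == "exploration":
            values = _condition_values(cond, params, trials, config)
            shift = deficit_rate_shift(deficit, sigma) if deficit is not None else 0.0
            if deficit is not None:
                values = apply_inactivation(values, deficit)
            uniq, inv = np.unique(r, return_inverse=True)
            p[m] = models.exploration_prob_values(uniq + shift, sigma, mu0, values)[inv]
        else:
            raise ValueError(f"unknown family {family!r}")
    return p


def _condition_values(cond: str, params: dict, trials: pd.DataFrame,
                      config: TaskConfig) -> ValueParams:
    """Trained stimulus–action values for one condition, reflecting reward
    magnitudes and any probabilistic-reward manipulation in the table."""
    if "values" in params:
        v = params["values"]
        return v[cond] if isinstance(v, dict) else v
    beta = params["beta"][cond]
    r_right = float(trials["reward_right"].iloc[0]) / BASELINE_REWARD_UL
    r_left = float(trials["reward_left"].iloc[0]) / BASELINE_REWARD_UL
    values = trained_values(r_right=r_right, r_left=r_left, beta=beta,
                            contingency=config.contingency)
    manip = str(trials["manipulation"].iloc[0])
    if manip == "prob_reward_left_on_high":
        values = apply_value_manipulation(
            values, Manipulation(kind="reward_probability", side="left", factor=0.5))
    return values


def simulate_choices(trials: pd.DataFrame, family: str, params: dict,
                     seed: int = 0, config: TaskConfig | None = None,
                     deficit: Deficit | None = None,
                     surebet_error: float = SUREBET_ERROR) -> pd.DataFrame:
    """Fill in choices and rewards by forward-sampling a model family.

    ``params`` is family-specific: per-condition ``sigma``/``beta`` dicts for
    the exploration family (plus optional explicit ``values``), per-condition
    :class:`~lapsekit.models.PsychometricParams` under ``params['params']``
    for the descriptive family, and so on.  Sure-bet trials are exploitative
    (the cued side's perturbed value decides) up to a small motor slip.
    Rewards follow the contingency and any probabilistic-reward manipulation;
    lagged history columns are filled per session.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    cond = out["condition"].astype(str).to_numpy(dtype=str)
    is_surebet = np.char.startswith(cond, "surebet")

    p_right = np.full(n, np.nan)
    if (~is_surebet).any():
        p_right[~is_surebet] = _discrimination_probs(
            out[~is_surebet], family, params, config, deficit)

    if is_surebet.any():
        sb_values = params.get("values_surebet")
        if sb_values is None:
            r_right = float(out["reward_right"].iloc[0]) / BASELINE_REWARD_UL
            r_left = float(out["reward_left"].iloc[0]) / BASELINE_REWARD_UL
            sb_values = trained_values(r_right=r_right, r_left=r_left,
                                       contingency=config.contingency)
        if deficit is not None:
            sb_values = apply_inactivation(sb_values, deficit)
        for side in ("left", "right"):
            m = cond == f"surebet_{side}"
            if not m.any():
                continue
            correct = surebet_prob_correct(sb_values, side)
            p_corr = correct * (1.0 - surebet_error) + (1.0 - correct) * surebet_error
            p_right[m] = p_corr if side == "right" else 1.0 - p_corr

    choice = (rng.uniform(size=n) < p_right).astype(float)
    out["choice"] = choice

    # outcome: correct side per category / cue, probabilistic reward manipulation
    high = out["rate_nominal"].to_numpy(float) > config.boundary_mu0
    if config.contingency == "standard":
        correct_side = np.where(high, 1.0, 0.0)
    else:
        correct_side = np.where(high, 0.0, 1.0)
    correct_side[cond == "surebet_right"] = 1.0
    correct_side[cond == "surebet_left"] = 0.0
    rewarded = (choice == correct_side).astype(float)

    manip = out["manipulation"].astype(str).to_numpy()
    prob_left = (manip == "prob_reward_left_on_high") & high & (choice == 0.0) & ~is_surebet
    if prob_left.any():
        rewarded[prob_left] = (rng.uniform(size=int(prob_left.sum())) < 0.5).astype(float)
    out["rewarded"] = rewarded

    # lagged history columns within session
    g = out.groupby("session_id", sort=False)
    out["prev_choice"] = g["choice"].shift(1)
    out["prev_rewarded"] = g["rewarded"].shift(1)
    return out


# ---------------------------------------------------------------------------
# Thompson-sampling learning agent
# ---------------------------------------------------------------------------

@dataclass
class AgentState:
    """Normal value beliefs per (category, action) pair with Kalman-style
    precision-weighted updates whose effective learning rate is scaled by the
    belief state (credit cannot be assigned to a single stimulus–action pair
    when the category is uncertain)."""

    mean: np.ndarray  # shape (2 categories: 0=Low 1=High, 2 actions: 0=L 1=R)
    var: np.ndarray
    obs_noise: float
    forgetting: float = 0.0

    def update(self, action: int, rho: float, reward: float) -> None:
        if self.forgetting > 0:
            self.var += self.forgetting
        s2 = self.obs_noise**2
        for cat, w in ((1, rho), (0, 1.0 - rho)):
            if w <= 0:
                continue
            v = self.var[cat, action]
            new_v = 1.0 / (1.0 / v + w / s2)
            self.mean[cat, action] = new_v * (self.mean[cat, action] / v + w * reward / s2)
            self.var[cat, action] = new_v


@dataclass
class AgentTrajectory:
    """Per-trial record of a simulated learning agent."""

    rates: np.ndarray
    rho: np.ndarray
    choice: np.ndarray
    reward: np.ndarray
    regret: np.ndarray  # per-trial expected regret increment
    policy: str
    sigma_sensory: float
    seed: int
    final_state: AgentState
    config: TaskConfig = field(default_factory=TaskConfig)

    @property
    def cumulative_regret(self) -> np.ndarray:
        return np.cumsum(self.regret)

    def lapse_timecourse(self, n_blocks: int = 10) -> np.ndarray:
        """Error rate on the easiest rates (grid extremes) per trial block."""
        lo = self.config.rate_min
        hi = self.config.rate_max
        easy = (self.rates == lo) | (self.rates == hi)
        correct = self.choice == (self.rates > self.config.boundary_mu0)
        edges = np.linspace(0, len(self.rates), n_blocks + 1).astype(int)
        out = np.empty(n_blocks)
        for b in range(n_blocks):
            m = easy[edges[b]:edges[b + 1]]
            c = correct[edges[b]:edges[b + 1]]
            out[b] = 1.0 - c[m].mean() if m.any() else np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rate": self.rates, "rho": self.rho, "choice": self.choice,
            "reward": self.reward, "regret": self.regret,
        })


def run_learning_agent(sigma_sensory: float, n_trials: int = 5000,
                       policy: str = "thompson", seed: int = 0,
                       config: TaskConfig | None = None,
                       prior_mean: float = 0.5, prior_sd: float = 1.0,
                       obs_noise: float = 0.5, forgetting: float = 0.0,
                       eps: float = 0.2) -> AgentTrajectory:
    """Simulate a value-learning agent on the rate-discrimination task.

    Each trial the agent observes a noisy rate, forms the belief state rho,
    turns sampled (thompson) or mean (greedy / eps_greedy / random) values
    into expected action values via rho, acts, and updates the chosen
    action's value beliefs for both categories with weights (rho, 1 - rho).
    Regret is accumulated against an oracle that always takes the truly
    rewarded action.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if policy not in ("thompson", "eps_greedy", "greedy", "random"):
        raise ValueError(f"unknown policy {policy!r}")
    if sigma_sensory < 0 or obs_noise <= 0 or prior_sd <= 0 or forgetting < 0:
        raise ValueError("invalid agent hyperparameters")
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)

    r_right = config.reward_right_ul / BASELINE_REWARD_UL
    r_left = config.reward_left_ul / BASELINE_REWARD_UL
    if config.contingency == "standard":
        true_q = np.array([[r_left, 0.0], [0.0, r_right]])  # [cat(Low,High), action(L,R)]
    else:
        true_q = np.array([[0.0, r_right], [r_left, 0.0]])

    state = AgentState(mean=np.full((2, 2), prior_mean),
                       var=np.full((2, 2), prior_sd**2),
                       obs_noise=obs_noise, forgetting=forgetting)

    grid = np.arange(int(config.rate_min), int(config.rate_max) + 1)
    rates = rng.choice(grid, size=n_trials).astype(float)
    noise = rng.standard_normal(n_trials)
    mu0 = config.boundary_mu0
    inv = 1.0 / (sigma_sensory * math.sqrt(2.0)) if sigma_sensory > 0 else None

    rho_arr = np.empty(n_trials)
    choice_arr = np.empty(n_trials)
    reward_arr = np.empty(n_trials)
    regret_arr = np.empty(n_trials)
    unif = rng.uniform(size=n_trials)
    coins = rng.integers(0, 2, size=n_trials)
    z = rng.standard_normal((n_trials, 2, 2))

    for t in range(n_trials):
        s = rates[t]
        if inv is None:
            rho = 1.0 if s > mu0 else 0.0
        else:
            x = s + sigma_sensory * noise[t]
            rho = 0.5 * (1.0 + math.erf((x - mu0) * inv))
        if policy == "thompson":
            q = state.mean + np.sqrt(state.var) * z[t]
        else:
            q = state.mean
        q_l = rho * q[1, 0] + (1.0 - rho) * q[0, 0]
        q_r = rho * q[1, 1] + (1.0 - rho) * q[0, 1]
        if policy == "random" or (policy == "eps_greedy" and unif[t] < eps):
            action = int(coins[t])
        else:
            action = 1 if q_r > q_l else 0 if q_l > q_r else int(coins[t])
        cat = 1 if s > mu0 else 0
        reward = true_q[cat, action]
        state.update(action, rho, reward)
        rho_arr[t] = rho
        choice_arr[t] = action
        reward_arr[t] = reward
        regret_arr[t] = true_q[cat].max() - reward

    return AgentTrajectory(rates=rates, rho=rho_arr, choice=choice_arr,
                           reward=reward_arr, regret=regret_arr, policy=policy,
                           sigma_sensory=sigma_sensory, seed=seed,
                           final_state=state, config=config)


def agent_trial_table(traj: AgentTrajectory, subject_id: str = "agent",
                      session_length: int = 500) -> pd.DataFrame:
    """Convert an agent trajectory to a trial table (with history columns),
    so the history-conditioned and other fitting operations apply to
    learning-agent data."""
    n = len(traj.rates)
    session = np.arange(n) // session_length
    cfg = traj.config
    rr, rl = cfg.reward_right_ul, cfg.reward_left_ul
    df = pd.DataFrame({
        "subject_id": subject_id,
        "session_id": [f"{subject_id}_s{int(s):03d}" for s in session],
        "trial_index": np.arange(n) % session_length,
        "condition": "multisensory",
        "rate_nominal": traj.rates,
        "rate_auditory": traj.rates,
        "rate_visual": traj.rates,
        "choice": traj.choice,
        "rewarded": (traj.reward > 0).astype(float),
        "reward_left": rl,
        "reward_right": rr,
        "manipulation": "none",
        "contingency": cfg.contingency,
        "prev_choice": np.nan,
        "prev_rewarded": np.nan,
    }, columns=TRIAL_COLUMNS)
    g = df.groupby("session_id", sort=False)
    df["prev_choice"] = g["choice"].shift(1)
    df["prev_rewarded"] = g["rewarded"].shift(1)
    return df


def asymptotic_lapse(traj: AgentTrajectory, final_frac: float = 0.25) -> float:
    """Total lapse (gamma + lam) of a psychometric fit to the trajectory's
    terminal trials — the agent's residual exploration after learning."""
    from .fitting import ModelSpec, fit_model, lapse_rates

    start = int(len(traj.rates) * (1.0 - final_frac))
    df = pd.DataFrame({
        "subject_id": "agent", "session_id": "agent_s0",
        "trial_index": np.arange(len(traj.rates) - start),
        "condition": "multisensory",
        "rate_nominal": traj.rates[start:],
        "choice": traj.choice[start:],
    })
    spec = ModelSpec(family="psychometric", lapse_variant="variable",
                     conditions=("multisensory",))
    fit = fit_model(df, spec, n_starts=5, seed=traj.seed)
    g, l = lapse_rates(fit)["multisensory"]
    return g + l


# ---------------------------------------------------------------------------
# cohort generation (synthetic stand-in for the study's rat dataset)
# ---------------------------------------------------------------------------

EXPLOITER_LAPSE = 0.01  # near-ideal rats: negligible exploratory lapse


def simulate_rat(subject_id: str, seed: int, n_trials: int = 20000,
                 explorer: bool = True, config: TaskConfig | None = None,
                 manipulation: str = "none", deficit: Deficit | None = None,
                 lapse_targets: dict | None = None,
                 jitter_sd: float = 0.25) -> pd.DataFrame:
    """One synthetic rat: exploration-model choices with rat-specific
    parameter jitter around a lapse operating point.

    ``explorer=False`` produces a near-exploiter rat with negligible lapses
    (a minority of real animals are close to the ideal observer).  The
    multiplicative lapse jitter is mean-one, so a cohort's average lapse
    matches its targets.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(seed)
    sigma_a = DEFAULT_SIGMAS["auditory"] * rng.lognormal(-0.005, 0.10)
    sigma_v = DEFAULT_SIGMAS["visual"] * rng.lognormal(-0.005, 0.10)
    sigma = {"visual": sigma_v, "auditory": sigma_a,
             "multisensory": combined_sigma(sigma_a, sigma_v), "neutral": sigma_a}
    if lapse_targets is None:
        lapse_targets = dict(DEFAULT_LAPSE_TOTALS) if explorer else \
            {c: EXPLOITER_LAPSE for c in DEFAULT_LAPSE_TOTALS}
    # one exploration level per rat (shared across conditions, mean-one
    # lognormal) plus small condition-level jitter: lapses keep tracking each
    # condition's uncertainty within a rat, as the constrained noise-lapse
    # relation implies
    cond_sd = 0.08
    rat_factor = rng.lognormal(-0.5 * jitter_sd**2, jitter_sd)
    beta = {}
    for c, target in lapse_targets.items():
        jitter = rat_factor * rng.lognormal(-0.5 * cond_sd**2, cond_sd)
        total = float(np.clip(target * jitter, 5e-3, 0.6))
        beta[c] = beta_for_total_lapse(total)
    trials = generate_trials(config, n_trials=n_trials, seed=seed + 1,
                             subject_id=subject_id, manipulation=manipulation)
    return simulate_choices(trials, "exploration", {"sigma": sigma, "beta": beta},
                            seed=seed + 2, config=config, deficit=deficit)


def simulate_cohort(n_rats: int = 17, n_explorers: int = 14,
                    n_trials: int = 20000, seed: int = 0,
                    config: TaskConfig | None = None) -> pd.DataFrame:
    """Synthetic cohort: ``n_explorers`` rats with sizable exploratory lapses
    and the remainder near-ideal exploiters, one table for all.

    Explorer lapse targets are scaled up so that the cohort-average lapse
    per condition equals the reported condition averages (the exploiters
    pull the mean down, exactly as the near-ideal animals do in the study
    population)."""
    if not 0 < n_explorers <= n_rats:
        raise ValueError("n_explorers must lie in (0, n_rats]")
    n_expl = n_rats - n_explorers
    explorer_targets = {
        c: (n_rats * L - n_expl * EXPLOITER_LAPSE) / n_explorers
        for c, L in DEFAULT_LAPSE_TOTALS.items()}
    tables = []
    for i in range(n_rats):
        explorer = i < n_explorers
        tables.append(simulate_rat(
            f"rat{i:02d}", seed=seed + 1000 * i, n_trials=n_trials,
            explorer=explorer, config=config,
            lapse_targets=explorer_targets if explorer else None))
    return pd.concat(tables, ignore_index=True)
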