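"""Maximum-likelihood fitting of choice models on trial tables.

Fits operate on a *trial table* (pandas DataFrame, one row per trial; see
:mod:`lapsekit.io` for the schema) and a :class:`ModelSpec` naming the model
family and its cross-condition constraints.  Because every model predicts a
single rightward probability per (condition, nominal rate) cell, likelihoods
are evaluated on binned counts — identical to the trial-wise Bernoulli sum,
but hundreds of times faster, which is what makes bootstrap confidence
intervals and large recovery studies tractable.

Families
--------
``psychometric``
    Descriptive four-parameter curve per condition with a lapse variant
    (``none`` / ``fixed`` / ``restricted`` / ``variable``) controlling how the
    lapse parameters are shared or bounded across conditions.
``ideal``
    Reward-maximizing Bayesian observer: shared subjective boundary mu, one
    sensory noise per condition, no lapses.
``inattention``
    Ideal observer that on 1 - p_attend of trials ignores the stimulus and
    guesses with probability p_bias.
``eps_greedy``
    Ideal observer with a fixed exploration/motor-error fraction eps.
``exploration``
    Softmax exploration over belief-state action values; lapses emerge from
    the inverse temperature beta and the reward magnitudes.
``exploration_constrained``
    Exploration model whose total lapse per condition is a linear function of
    that condition's sensory noise (slope, intercept), replacing the
    per-condition betas.

Multisensory sigma is constrained to the optimal combination
``combined_sigma(sigma_auditory, sigma_visual)`` for the theoretical
families (switchable), and always free for the descriptive psychometric
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc, ttest_rel

from . import models
from .models import combined_sigma, ideal_observer_prob, exploration_prob, _logistic

__all__ = [
    "ModelSpec",
    "FitResult",
    "BinnedChoices",
    "bin_trials",
    "negative_log_likelihood",
    "fit_model",
    "lapse_rates",
    "lapse_variant_comparison",
    "model_comparison_table",
    "optimality_check",
    "constrained_exploration_fit",
    "confidence_intervals",
    "history_conditioned_fit",
    "FitError",
]

DISCRIMINATION_CONDITIONS = ("visual", "auditory", "multisensory", "neutral")

P_CLIP = 1e-9  # likelihood-only clipping; model outputs are never clipped

_LAPSE_VARIANTS = ("none", "fixed", "restricted", "variable")
_FAMILIES = ("psychometric", "ideal", "inattention", "eps_greedy",
             "exploration", "exploration_constrained")


class FitError(RuntimeError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """What to fit: a model family plus its cross-condition constraints."""

    family: str = "psychometric"
    lapse_variant: str = "variable"  # psychometric family only
    conditions: tuple[str, ...] | None = None  # None -> inferred from data
    constrain_multisensory_sigma: bool = True  # theoretical families only
    exploration_parameterization: str = "fix_rL_fit_beta"  # or fix_beta_fit_rewards
    share_beta: bool = False
    restricted_total: float = 0.1
    boundary: float = 12.5
    rate_min: float = 9.0
    rate_max: float = 16.0
    bounds_overrides: dict = field(default_factory=dict, hash=False)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.lapse_variant not in _LAPSE_VARIANTS:
            raise ValueError(f"unknown lapse_variant {self.lapse_variant!r}")
        if self.exploration_parameterization not in ("fix_rL_fit_beta", "fix_beta_fit_rewards"):
            raise ValueError("unknown exploration_parameterization")

    # -- parameter layout ---------------------------------------------------

    def layout(self, conditions: tuple[str, ...]) -> "_Layout":
        return _build_layout(self, tuple(conditions))


@dataclass
class _Layout:
    """Named free-parameter vector with bounds, defaults and a predictor."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    x0: np.ndarray
    spec: ModelSpec
    conditions: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.names)

    def unpack(self, theta) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(theta, dtype=float)))

    def clip(self, theta) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lower, self.upper)

    def predict(self, theta, rates, cond_idx) -> np.ndarray:
        """Rightward probability per bin; cond_idx indexes self.conditions."""
        return _predict(self.spec, self, np.asarray(theta, float),
                        np.asarray(rates, float), np.asarray(cond_idx))


_DEFAULT_BOUNDS = {
    "mu": (None, None),  # filled from rate range
    "sigma": (0.1, 10.0),
    "gamma": (0.0, 0.5),
    "lam": (0.0, 0.5),
    "total": (0.0, None),  # restricted-variant total lapse
    "frac": (0.0, 1.0),
    "beta": (0.0, 50.0),
    "reward": (0.01, 10.0),
    "prob": (0.0, 1.0),
    "slope": (-0.5, 0.5),
    "intercept": (-1.0, 1.0),  # negative allowed: predicted totals are floored
}

_DEFAULT_X0 = {
    "mu": None, "sigma": 2.0, "gamma": 0.05, "lam": 0.05, "total": 0.05,
    "frac": 0.5, "beta": 2.0, "reward": 1.0, "prob": 0.5,
    "slope": 0.05, "intercept": 0.02,
}


def _bound(spec: ModelSpec, name: str, kind: str) -> tuple[float, float]:
    if name in spec.bounds_overrides:
        return spec.bounds_overrides[name]
    lo, hi = _DEFAULT_BOUNDS[kind]
    if kind == "mu":
        lo, hi = spec.rate_min - 2.0, spec.rate_max + 2.0
    if kind == "total":
        hi = spec.restricted_total
    return lo, hi


def _sigma_is_derived(spec: ModelSpec, conditions: tuple[str, ...], cond: str) -> bool:
    """sigma_multisensory is derived from the unisensory sigmas when the
    optimality constraint is on (theoretical families only)."""
    return (
        cond == "multisensory"
        and spec.family != "psychometric"
        and spec.constrain_multisensory_sigma
        and "visual" in conditions
        and "auditory" in conditions
    )


def _build_layout(spec: ModelSpec, conditions: tuple[str, ...]) -> _Layout:
    names: list[str] = []
    kinds: list[str] = []

    def add(name: str, kind: str) -> None:
        names.append(name)
        kinds.append(kind)

    fam = spec.family
    if fam == "psychometric":
        for c in conditions:
            add(f"mu_{c}", "mu")
            add(f"sigma_{c}", "sigma")
        v = spec.lapse_variant
        if v == "fixed":
            add("gamma", "gamma")
            add("lam", "lam")
        elif v == "restricted":
            for c in conditions:
                add(f"total_{c}", "total")
                add(f"frac_{c}", "frac")
        elif v == "variable":
            for c in conditions:
                add(f"gamma_{c}", "gamma")
                add(f"lam_{c}", "lam")
    else:
        add("mu", "mu")
        for c in conditions:
            if not _sigma_is_derived(spec, conditions, c):
                add(f"sigma_{c}", "sigma")
        if fam == "inattention":
            add("p_attend", "prob")
            add("p_bias", "prob")
        elif fam == "eps_greedy":
            add("eps", "prob")
            add("p_bias", "prob")
        elif fam == "exploration":
            if spec.exploration_parameterization == "fix_rL_fit_beta":
                if spec.share_beta:
                    add("beta", "beta")
                else:
                    for c in conditions:
                        add(f"beta_{c}", "beta")
                add("r_right", "reward")
            else:  # fix_beta_fit_rewards: beta = 1
                add("r_right", "reward")
                add("r_left", "reward")
        elif fam == "exploration_constrained":
            add("lapse_intercept", "intercept")
            add("lapse_slope", "slope")
            add("r_right", "reward")

    lower = np.empty(len(names))
    upper = np.empty(len(names))
    x0 = np.empty(len(names))
    for i, (name, kind) in enumerate(zip(names, kinds)):
        lo, hi = _bound(spec, name, kind)
        lower[i], upper[i] = lo, hi
        guess = _DEFAULT_X0[kind]
        x0[i] = spec.boundary if kind == "mu" else guess
    return _Layout(names, lower, upper, x0, spec, conditions)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _condition_sigmas(spec, layout, p: dict) -> dict[str, float]:
    sig = {}
    for c in layout.conditions:
        if _sigma_is_derived(spec, layout.conditions, c):
            sig[c] = combined_sigma(p["sigma_auditory"], p["sigma_visual"])
        else:
            sig[c] = p[f"sigma_{c}"]
    return sig


def _constrained_beta(total_lapse: float, r_right: float) -> float:
    """Invert total lapse 1/(1+e^b) + 1/(1+e^{b rR}) = L for beta (rL = 1)."""

    def g(b):
        return _logistic(-b) + _logistic(-b * r_right) - total_lapse

    if g(0.0) <= 0:  # even beta = 0 cannot produce that much lapse
        return 0.0
    if g(50.0) >= 0:
        return 50.0
    return optimize.brentq(g, 0.0, 50.0, xtol=1e-10)


def _predict(spec, layout, theta, rates, cond_idx) -> np.ndarray:
    p = layout.unpack(theta)
    fam = spec.family
    out = np.empty(len(rates))

    if fam == "psychometric":
        for i, c in enumerate(layout.conditions):
            m = cond_idx == i
            if not m.any():
                continue
            if spec.lapse_variant == "none":
                g, l = 0.0, 0.0
            elif spec.lapse_variant == "fixed":
                g, l = p["gamma"], p["lam"]
            elif spec.lapse_variant == "restricted":
                g = p[f"total_{c}"] * p[f"frac_{c}"]
                l = p[f"total_{c}"] * (1.0 - p[f"frac_{c}"])
            else:
                g, l = p[f"gamma_{c}"], p[f"lam_{c}"]
            z = (rates[m] - p[f"mu_{c}"]) / p[f"sigma_{c}"]
            out[m] = g + (1.0 - g - l) * models._phi(z)
        return out

    sig = _condition_sigmas(spec, layout, p)
    mu = p["mu"]
    for i, c in enumerate(layout.conditions):
        m = cond_idx == i
        if not m.any():
            continue
        r = rates[m]
        if fam == "ideal":
            out[m] = ideal_observer_prob(r, sig[c], mu)
        elif fam == "inattention":
            base = ideal_observer_prob(r, sig[c], mu)
            out[m] = p["p_attend"] * base + (1.0 - p["p_attend"]) * p["p_bias"]
        elif fam == "eps_greedy":
            base = ideal_observer_prob(r, sig[c], mu)
            out[m] = (1.0 - p["eps"]) * base + p["eps"] * p["p_bias"]
        elif fam == "exploration":
            if spec.exploration_parameterization == "fix_rL_fit_beta":
                beta = p["beta"] if spec.share_beta else p[f"beta_{c}"]
                rr, rl = p["r_right"], 1.0
            else:
                beta, rr, rl = 1.0, p["r_right"], p["r_left"]
            out[m] = exploration_prob(r, sig[c], mu, beta, rr, rl)
        elif fam == "exploration_constrained":
            total = float(np.clip(p["lapse_intercept"] + p["lapse_slope"] * sig[c],
                                  1e-4, 0.98))
            beta = _constrained_beta(total, p["r_right"])
            out[m] = exploration_prob(r, sig[c], mu, beta, p["r_right"], 1.0)
    return out


# ---------------------------------------------------------------------------
# binning and likelihood
# ---------------------------------------------------------------------------

@dataclass
class BinnedChoices:
    """Rightward-choice counts per (condition, nominal rate) cell."""

    rates: np.ndarray       # bin rate (Hz)
    cond_idx: np.ndarray    # index into conditions
    n: np.ndarray           # trials per bin
    n_right: np.ndarray     # rightward choices per bin
    conditions: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return int(self.n.sum())

    def resampled(self, rng: np.random.Generator) -> "BinnedChoices":
        """Resample trials with replacement (multinomial over bin x outcome)."""
        cells = np.concatenate([self.n_right, self.n - self.n_right]).astype(float)
        total = cells.sum()
        draw = rng.multinomial(int(total), cells / total)
        nb = len(self.n)
        k = draw[:nb].astype(float)
        n = k + draw[nb:]
        return BinnedChoices(self.rates, self.cond_idx, n, k, self.conditions)


def infer_conditions(trials: pd.DataFrame) -> tuple[str, ...]:
    present = set(trials["condition"].unique())
    ordered = [c for c in DISCRIMINATION_CONDITIONS if c in present]
    unknown = present - set(DISCRIMINATION_CONDITIONS) - {"surebet_left", "surebet_right"}
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    if not ordered:
        raise ValueError("no discrimination trials in table")
    return tuple(ordered)


def bin_trials(trials: pd.DataFrame, conditions: tuple[str, ...] | None = None
               ) -> BinnedChoices:
    if conditions is None:
        conditions = infer_conditions(trials)
    disc = trials[trials["condition"].isin(conditions)]
    if disc.empty:
        raise ValueError("no trials in the requested conditions")
    if disc["choice"].isna().any():
        raise ValueError("trials contain missing choices; simulate or drop first")
    cmap = {c: i for i, c in enumerate(conditions)}
    ci = disc["condition"].map(cmap).to_numpy()
    g = pd.DataFrame({
        "ci": ci,
        "rate": disc["rate_nominal"].to_numpy(float),
        "choice": disc["choice"].to_numpy(float),
    }).groupby(["ci", "rate"])["choice"].agg(["count", "sum"]).reset_index()
    return BinnedChoices(
        rates=g["rate"].to_numpy(),
        cond_idx=g["ci"].to_numpy(),
        n=g["count"].to_numpy(float),
        n_right=g["sum"].to_numpy(float),
        conditions=tuple(conditions),
    )


def _binned_nll(p: np.ndarray, data: BinnedChoices) -> float:
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    return float(-(data.n_right * np.log(p)
                   + (data.n - data.n_right) * np.log1p(-p)).sum())


def negative_log_likelihood(trials: pd.DataFrame, spec: ModelSpec, theta) -> float:
    """Bernoulli negative log-likelihood (nats) of the rightward choices.

    ``theta`` may be a vector in the spec's parameter order or a name->value
    mapping.  Probabilities are clipped to [1e-9, 1 - 1e-9] inside the
    likelihood only.
    """
    data = bin_trials(trials, spec.conditions)
    layout = spec.layout(data.conditions)
    if isinstance(theta, dict):
        missing = [n for n in layout.names if n not in theta]
        if missing:
            raise ValueError(f"theta missing parameters: {missing}")
        theta = np.array([theta[n] for n in layout.names], dtype=float)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (layout.k,):
        raise ValueError(f"theta must have {layout.k} entries {layout.names}")
    if np.any(theta < layout.lower - 1e-12) or np.any(theta > layout.upper + 1e-12):
        bad = [layout.names[i] for i in range(layout.k)
               if not layout.lower[i] - 1e-12 <= theta[i] <= layout.upper[i] + 1e-12]
        raise ValueError(f"theta outside bounds for: {bad}")
    return _binned_nll(layout.predict(theta, data.rates, data.cond_idx), data)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Parameter estimates with likelihood, information criteria and
    convergence metadata.  ``aic = 2k - 2 loglik``; ``bic = k ln n - 2 loglik``.
    """

    params: dict[str, float]
    loglik: float
    k: int
    n: int
    aic: float
    bic: float
    spec: ModelSpec
    conditions: tuple[str, ...]
    names: list[str]
    theta: np.ndarray
    converged: bool
    n_starts: int
    seed: int
    diagnostics: list = field(default_factory=list)
    ci: dict | None = None
    label: str = ""

    def to_dict(self) -> dict:
        out = {
            "label": self.label or self.spec.family,
            "family": self.spec.family,
            "lapse_variant": self.spec.lapse_variant,
            "conditions": list(self.conditions),
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": float(self.loglik),
            "k": self.k,
            "n": self.n,
            "aic": float(self.aic),
            "bic": float(self.bic),
            "converged": bool(self.converged),
            "n_starts": self.n_starts,
            "seed": self.seed,
        }
        if self.ci is not None:
            out["ci"] = {k: [float(v[0]), float(v[1])] for k, v in self.ci["intervals"].items()}
            out["ci_method"] = self.ci["method"]
        return out


def _multistart_minimize(objective, lower, upper, x0, n_starts: int, seed: int,
                         tol: float = 1e-10):
    """Best-of-n bounded L-BFGS-B with Latin-hypercube restarts.

    Returns (theta, fun, diagnostics); raises FitError when every start
    produces a non-finite objective.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    starts = [np.clip(np.asarray(x0, float), lower, upper)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(lower), seed=seed)
        unit = sampler.random(n_starts - 1)
        span = upper - lower
        # keep random starts off the very edges of the box
        starts.extend(lower + (0.05 + 0.9 * unit) * span)

    best = None
    diagnostics = []
    bounds = list(zip(lower, upper))
    for s in starts:
        res = optimize.minimize(objective, np.clip(s, lower, upper),
                                method="L-BFGS-B", bounds=bounds,
                                options={"ftol": tol, "gtol": 1e-8, "maxiter": 500})
        diagnostics.append({"x0": np.asarray(s).tolist(), "fun": float(res.fun),
                            "success": bool(res.success), "message": str(res.message)})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("no optimizer start produced a finite likelihood", diagnostics)
    return np.clip(best.x, lower, upper), float(best.fun), diagnostics


def _fit_binned(data: BinnedChoices, spec: ModelSpec, n_starts: int = 10,
                seed: int = 0, x0=None, tol: float = 1e-10) -> FitResult:
    layout = spec.layout(data.conditions)

    def objective(theta):
        return _binned_nll(layout.predict(theta, data.rates, data.cond_idx), data)

    theta, fun, diagnostics = _multistart_minimize(
        objective, layout.lower, layout.upper,
        layout.x0 if x0 is None else x0, n_starts, seed, tol)
    loglik = -fun
    k, n = layout.k, data.n_trials
    return FitResult(
        params=layout.unpack(theta), loglik=loglik, k=k, n=n,
        aic=2 * k - 2 * loglik, bic=k * np.log(n) - 2 * loglik,
        spec=spec, conditions=data.conditions, names=layout.names,
        theta=theta, converged=any(d["success"] for d in diagnostics),
        n_starts=n_starts, seed=seed, diagnostics=diagnostics,
    )


def _separable(spec: ModelSpec) -> bool:
    """Psychometric variants with no cross-condition coupling can be fit one
    condition at a time, which is both faster and far more reliable than a
    joint high-dimensional search."""
    return spec.family == "psychometric" and spec.lapse_variant != "fixed"


def _fit_separable(data: BinnedChoices, spec: ModelSpec, n_starts: int,
                   seed: int, warm_params: dict | None = None,
                   tol: float = 1e-10) -> FitResult:
    params: dict[str, float] = {}
    names: list[str] = []
    theta_parts = []
    loglik = 0.0
    k = 0
    converged = True
    diagnostics = []
    for i, c in enumerate(data.conditions):
        m = data.cond_idx == i
        sub = BinnedChoices(data.rates[m], np.zeros(m.sum(), dtype=int),
                            data.n[m], data.n_right[m], (c,))
        subspec = replace(spec, conditions=(c,))
        x0 = None
        if warm_params is not None:
            x0 = [warm_params[n] for n in subspec.layout((c,)).names]
        fit = _fit_binned(sub, subspec, n_starts=n_starts, seed=seed, x0=x0,
                          tol=tol)
        params.update(fit.params)
        names.extend(fit.names)
        theta_parts.append(fit.theta)
        loglik += fit.loglik
        k += fit.k
        converged &= fit.converged
        diagnostics.extend(fit.diagnostics)
    n = data.n_trials
    return FitResult(
        params=params, loglik=loglik, k=k, n=n,
        aic=2 * k - 2 * loglik, bic=k * np.log(n) - 2 * loglik,
        spec=spec, conditions=data.conditions, names=names,
        theta=np.concatenate(theta_parts), converged=converged,
        n_starts=n_starts, seed=seed, diagnostics=diagnostics,
    )


def fit_model(trials: pd.DataFrame, spec: ModelSpec, n_starts: int = 10,
              seed: int = 0, min_trials_per_condition: int = 50,
              x0=None) -> FitResult:
    """Best-of-``n_starts`` bounded maximum-likelihood fit.

    Starts are the layout default plus Latin-hypercube draws within bounds
    (seed-controlled, so refits on identical data are bit-identical).
    Psychometric variants without cross-condition parameter sharing are fit
    per condition and combined.
    """
    data = bin_trials(trials, spec.conditions)
    per_cond = np.bincount(data.cond_idx.astype(int), weights=data.n,
                           minlength=len(data.conditions))
    thin = [c for c, m in zip(data.conditions, per_cond) if m < min_trials_per_condition]
    if thin:
        raise ValueError(
            f"fewer than {min_trials_per_condition} trials in conditions {thin}")
    if spec.family == "exploration_constrained" and len(data.conditions) < 3:
        raise ValueError("constrained exploration fit needs >= 3 conditions")
    if _separable(spec) and len(data.conditions) > 1 and x0 is None:
        return _fit_separable(data, spec, n_starts=n_starts, seed=seed)
    return _fit_binned(data, spec, n_starts=n_starts, seed=seed, x0=x0)


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def lapse_rates(fit: FitResult) -> dict[str, tuple[float, float]]:
    """Per-condition (gamma, lam) implied by a fit, whatever the family."""
    p, spec = fit.params, fit.spec
    out = {}
    for c in fit.conditions:
        if spec.family == "psychometric":
            if spec.lapse_variant == "none":
                gl = (0.0, 0.0)
            elif spec.lapse_variant == "fixed":
                gl = (p["gamma"], p["lam"])
            elif spec.lapse_variant == "restricted":
                gl = (p[f"total_{c}"] * p[f"frac_{c}"],
                      p[f"total_{c}"] * (1.0 - p[f"frac_{c}"]))
            else:
                gl = (p[f"gamma_{c}"], p[f"lam_{c}"])
        elif spec.family == "ideal":
            gl = (0.0, 0.0)
        elif spec.family == "inattention":
            gl = models.inattention_asymptotes(p["p_attend"], p["p_bias"])
        elif spec.family == "eps_greedy":
            gl = models.epsilon_greedy_asymptotes(p["eps"], p["p_bias"])
        elif spec.family == "exploration":
            if spec.exploration_parameterization == "fix_rL_fit_beta":
                beta = p["beta"] if spec.share_beta else p[f"beta_{c}"]
                gl = models.exploration_asymptotes(beta, p["r_right"], 1.0)
            else:
                gl = models.exploration_asymptotes(1.0, p["r_right"], p["r_left"])
        else:  # exploration_constrained
            layout = spec.layout(fit.conditions)
            sig = _condition_sigmas(spec, layout, p)
            total = float(np.clip(p["lapse_intercept"] + p["lapse_slope"] * sig[c],
                                  1e-4, 0.98))
            beta = _constrained_beta(total, p["r_right"])
            gl = models.exploration_asymptotes(beta, p["r_right"], 1.0)
        out[c] = (float(gl[0]), float(gl[1]))
    return out


def fitted_sigmas(fit: FitResult) -> dict[str, float]:
    """Per-condition sensory noise implied by a fit (resolving the optimality
    constraint for derived multisensory sigma)."""
    if fit.spec.family == "psychometric":
        return {c: fit.params[f"sigma_{c}"] for c in fit.conditions}
    layout = fit.spec.layout(fit.conditions)
    return _condition_sigmas(fit.spec, layout, fit.params)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def model_comparison_table(fits: dict[str, FitResult], subject_id: str = "",
                           tie_tol: float = 1e-6) -> pd.DataFrame:
    """Tidy comparison table with d_aic/d_bic re-zeroed at the best model.

    Ties within ``tie_tol`` are broken toward fewer parameters (parsimony).
    """
    rows = []
    for name, f in fits.items():
        rows.append({"subject_id": subject_id, "model": name, "k": f.k, "n": f.n,
                     "loglik": f.loglik, "aic": f.aic, "bic": f.bic})
    df = pd.DataFrame(rows)
    for col in ("aic", "bic"):
        best = df[col].min()
        near = df[df[col] <= best + tie_tol]
        winner = near.sort_values(["k", "model"]).iloc[0]
        df[f"d_{col}"] = df[col] - winner[col]
        df.loc[df["model"] == winner["model"], f"d_{col}"] = 0.0
    return df


def lapse_variant_comparison(trials: pd.DataFrame, subject_id: str = "",
                             n_starts: int = 10, seed: int = 0,
                             base_spec: ModelSpec | None = None
                             ) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit the four psychometric lapse variants and rank them by AIC/BIC."""
    base = base_spec or ModelSpec(family="psychometric")
    fits = {}
    for variant in _LAPSE_VARIANTS:
        spec = replace(base, family="psychometric", lapse_variant=variant)
        fit = fit_model(trials, spec, n_starts=n_starts, seed=seed)
        fit.label = f"{variant}_lapse"
        fits[f"{variant}_lapse"] = fit
    table = model_comparison_table(fits, subject_id=subject_id)
    return table.sort_values("bic").reset_index(drop=True), fits


def optimality_check(per_subject_fits: dict[str, dict[str, models.PsychometricParams]]
                     ) -> tuple[pd.DataFrame, dict]:
    """Compare measured multisensory sigma to the optimal-combination
    prediction from the unisensory fits, per subject, with a paired test.

    Input: subject -> {"visual": PsychometricParams, "auditory": ...,
    "multisensory": ...}.
    """
    rows = []
    for subject, fits in per_subject_fits.items():
        for cond in ("visual", "auditory", "multisensory"):
            if cond not in fits:
                raise ValueError(f"subject {subject!r} missing condition {cond!r}")
        predicted = combined_sigma(fits["auditory"].sigma, fits["visual"].sigma)
        rows.append({"subject_id": subject, "sigma_visual": fits["visual"].sigma,
                     "sigma_auditory": fits["auditory"].sigma,
                     "predicted_sigma_m": predicted,
                     "measured_sigma_m": fits["multisensory"].sigma})
    df = pd.DataFrame(rows)
    diff = df["measured_sigma_m"] - df["predicted_sigma_m"]
    if len(df) > 1:
        t, pval = ttest_rel(df["measured_sigma_m"], df["predicted_sigma_m"])
    else:
        t, pval = np.nan, np.nan
    summary = {"mean_diff": float(diff.mean()), "sd_diff": float(diff.std(ddof=1))
               if len(df) > 1 else np.nan, "t": float(t), "p": float(pval),
               "n_subjects": len(df)}
    return df, summary


def constrained_exploration_fit(trials: pd.DataFrame, n_starts: int = 10,
                                seed: int = 0, **kw) -> FitResult:
    """Exploration fit with total lapse linear in the condition's sensory
    noise (slope, intercept replace the per-condition betas)."""
    spec = ModelSpec(family="exploration_constrained", **kw)
    return fit_model(trials, spec, n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def _layout_theta(fit: FitResult, layout: _Layout) -> np.ndarray:
    """fit parameters re-ordered into the layout's canonical order."""
    return np.array([fit.params[n] for n in layout.names], dtype=float)


def _hessian_ci(fit: FitResult, data: BinnedChoices, alpha: float) -> dict | None:
    from statsmodels.tools.numdiff import approx_hess1

    layout = fit.spec.layout(fit.conditions)
    theta_hat = _layout_theta(fit, layout)

    def nll(theta):
        return _binned_nll(layout.predict(theta, data.rates, data.cond_idx), data)

    # step back from bound edges so finite differences stay inside the box
    theta = np.clip(theta_hat, layout.lower + 1e-5, layout.upper - 1e-5)
    try:
        hess = approx_hess1(theta, nll)
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var <= 0) or np.any(~np.isfinite(var)):
        return None
    from scipy.stats import norm as _norm
    zc = _norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(var)
    return {
        "method": "hessian", "alpha": alpha,
        "intervals": {n: (theta_hat[i] - zc * se[i], theta_hat[i] + zc * se[i])
                      for i, n in enumerate(layout.names)},
        "se": dict(zip(layout.names, se)),
    }


def _bootstrap_ci(fit: FitResult, data: BinnedChoices, n_boot: int, seed: int,
                  alpha: float) -> dict:
    layout = fit.spec.layout(fit.conditions)
    theta_hat = _layout_theta(fit, layout)
    separable = _separable(fit.spec) and len(fit.conditions) > 1
    rng = np.random.default_rng(seed)
    thetas = np.empty((n_boot, fit.k))
    for b in range(n_boot):
        resampled = data.resampled(rng)
        # warm-started single refit per resample
        if separable:
            refit = _fit_separable(resampled, fit.spec, n_starts=1, seed=seed,
                                   warm_params=fit.params, tol=1e-9)
            thetas[b] = [refit.params[n] for n in layout.names]
        else:
            refit = _fit_binned(resampled, fit.spec, n_starts=1, seed=seed,
                                x0=theta_hat, tol=1e-9)
            thetas[b] = refit.theta
    lo = np.percentile(thetas, 100 * alpha / 2.0, axis=0)
    hi = np.percentile(thetas, 100 * (1.0 - alpha / 2.0), axis=0)
    return {
        "method": "bootstrap", "alpha": alpha, "n_boot": n_boot, "seed": seed,
        "intervals": {n: (lo[i], hi[i]) for i, n in enumerate(layout.names)},
        "samples": thetas, "names": list(layout.names),
    }


def confidence_intervals(fit: FitResult, trials: pd.DataFrame,
                         method: str = "hessian", n_boot: int = 1000,
                         seed: int = 0, alpha: float = 0.05) -> dict:
    """Per-parameter confidence intervals.

    ``hessian`` uses the local curvature of the negative log-likelihood at
    the optimum (falling back to bootstrap with a warning when the curvature
    is singular); ``bootstrap`` resamples trials with replacement ``n_boot``
    times and refits, reporting percentile intervals.  Deterministic given
    ``seed``.  The result is also attached to ``fit.ci``.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    data = bin_trials(trials, fit.conditions)
    if method == "hessian":
        ci = _hessian_ci(fit, data, alpha)
        if ci is None:
            warnings.warn("singular curvature; falling back to bootstrap CIs")
            ci = _bootstrap_ci(fit, data, n_boot, seed, alpha)
    elif method == "bootstrap":
        ci = _bootstrap_ci(fit, data, n_boot, seed, alpha)
    else:
        raise ValueError("method must be 'hessian' or 'bootstrap'")
    fit.ci = ci
    return ci


# ---------------------------------------------------------------------------
# history-conditioned fits
# ---------------------------------------------------------------------------

def history_conditioned_fit(trials: pd.DataFrame, spec: ModelSpec | None = None,
                            n_starts: int = 10, seed: int = 0) -> dict:
    """Fit the exploration model separately to trials following rightward
    successes vs. rightward failures (equal-reward trials only).

    A learning observer updates action values from outcomes, so the
    post-success split should show a lower high-rate lapse than the
    post-failure split; a static observer shows no difference.
    """
    spec = spec or ModelSpec(family="exploration")
    eligible = trials[(trials["manipulation"] == "none")
                      & (trials["prev_choice"] == 1)
                      & trials["prev_rewarded"].isin([0, 1])]
    splits = {
        "post_success": eligible[eligible["prev_rewarded"] == 1],
        "post_failure": eligible[eligible["prev_rewarded"] == 0],
    }
    out = {"n_eligible": len(eligible)}
    for name, sub in splits.items():
        if sub.empty:
            raise ValueError(f"empty split: {name}")
        fit = fit_model(sub, spec, n_starts=n_starts, seed=seed)
        fit.label = name
        out[name] = fit
        out[f"{name}_n"] = len(sub)
        out[f"{name}_lapses"] = lapse_rates(fit)
    return out
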