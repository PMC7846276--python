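"""Reward manipulations and unilateral-inactivation deficit models.

Two perturbation classes enter the static exploration model:

* :class:`Manipulation` — experimenter-controlled changes of reward magnitude
  (e.g. 36 or 16 uL against a 24 uL baseline, i.e. factors 1.5 / 0.667) or
  reward probability (e.g. rewarding the incorrect left port on high-rate
  trials with probability 0.5).  These act on a single stimulus-action value
  and therefore, under exploration, move only the lapse rate on the
  corresponding side of the psychometric curve.

* :class:`Deficit` — one-parameter models of a unilateral inactivation:
  ``biased_evidence`` (a rate shift of K*sigma_condition), ``biased_value``
  (contralateral action values scaled by K < 1), ``biased_effort`` (an
  additive cost K < 0 on the contralateral action).  Deficits attach to
  actions, never to stimulus categories, so reversed-contingency animals are
  handled by the contingency-aware value map.

Joint fits share every baseline parameter between the control and perturbed
trial tables and add exactly one free parameter for the perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import fitting, models
from .fitting import (BinnedChoices, FitResult, ModelSpec, _binned_nll,
                      _multistart_minimize, bin_trials, model_comparison_table)
from .models import ValueParams, exploration_prob_values, trained_values

__all__ = [
    "Manipulation",
    "Deficit",
    "apply_value_manipulation",
    "apply_inactivation",
    "surebet_prob_correct",
    "fit_manipulation_pair",
    "fit_inactivation_pair",
    "deficit_model_comparison",
]

DEFICIT_TYPES = ("biased_evidence", "biased_value", "biased_effort")


@dataclass(frozen=True)
class Manipulation:
    """A one-sided reward change.

    kind='reward_magnitude': the named side's water amount is multiplied by
    ``factor`` (> 0).  kind='reward_probability': the named side's *incorrect*
    choice is rewarded with probability ``factor`` on trials of the other
    category (the classic case: left choices on high-rate trials at p=0.5).
    """

    kind: str
    side: str
    factor: float

    def __post_init__(self):
        if self.kind not in ("reward_magnitude", "reward_probability"):
            raise ValueError(f"unknown manipulation kind {self.kind!r}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.kind == "reward_magnitude" and not self.factor > 0:
            raise ValueError("magnitude factor must be > 0")
        if self.kind == "reward_probability" and not 0.0 <= self.factor <= 1.0:
            raise ValueError("reward probability must lie in [0, 1]")


@dataclass(frozen=True)
class Deficit:
    """A one-parameter unilateral deficit attached to the ``side`` action
    (the action contralateral to the inactivated hemisphere)."""

    type: str
    K: float
    side: str

    def __post_init__(self):
        if self.type not in DEFICIT_TYPES:
            raise ValueError(f"unknown deficit type {self.type!r}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.type == "biased_value" and not 0.0 < self.K <= 1.0:
            raise ValueError("biased_value requires K in (0, 1]")
        if self.type == "biased_effort" and self.K > 0:
            raise ValueError("biased_effort requires K <= 0")
        if self.type == "biased_evidence" and self.K < 0:
            raise ValueError("biased_evidence requires K >= 0")


# ---------------------------------------------------------------------------
# applying perturbations to value parameters
# ---------------------------------------------------------------------------

def apply_value_manipulation(values: ValueParams, m: Manipulation) -> ValueParams:
    """Return the stimulus–action values after a reward manipulation.

    Magnitude changes scale both values of the named action; a probabilistic
    reward on the incorrect side sets that side's off-diagonal value to
    factor * (its correct-side counterpart's scale), e.g. q(High, Left) =
    0.5 * rL for the left-on-high manipulation.
    """
    if m.kind == "reward_magnitude":
        if m.side == "right":
            return replace(values,
                           q_high_right=values.q_high_right * m.factor,
                           q_low_right=values.q_low_right * m.factor)
        return replace(values,
                       q_high_left=values.q_high_left * m.factor,
                       q_low_left=values.q_low_left * m.factor)
    # reward_probability: expected-value change q = p * r on the incorrect
    # (category, action) pair
    if m.side == "left":
        return replace(values, q_high_left=m.factor * values.q_low_left)
    return replace(values, q_low_right=m.factor * values.q_high_right)


def apply_inactivation(values: ValueParams, d: Deficit) -> ValueParams:
    """Return the action values after a value or effort deficit.

    ``biased_evidence`` does not change values (it shifts the effective
    stimulus; see :func:`deficit_rate_shift`).
    """
    if d.type == "biased_evidence":
        return values
    if d.type == "biased_value":
        if d.side == "right":
            return replace(values, q_high_right=values.q_high_right * d.K,
                           q_low_right=values.q_low_right * d.K)
        return replace(values, q_high_left=values.q_high_left * d.K,
                       q_low_left=values.q_low_left * d.K)
    # biased_effort: additive cost on the affected action
    if d.side == "right":
        return replace(values, effort_right=values.effort_right + d.K)
    return replace(values, effort_left=values.effort_left + d.K)


def deficit_rate_shift(d: Deficit, sigma_condition: float) -> float:
    """Additive shift of the effective stimulus rate under biased_evidence:
    evidence is biased *away* from the affected action by K * sigma of the
    condition (larger shifts for noisier conditions)."""
    if d.type != "biased_evidence":
        return 0.0
    sign = -1.0 if d.side == "right" else 1.0
    return sign * d.K * sigma_condition


def surebet_prob_correct(values: ValueParams, cued_side: str) -> float:
    """Choice accuracy on a sure-bet trial in the zero-uncertainty limit.

    With no perceptual or value uncertainty the observer exploits: it picks
    the cued side iff that action's (possibly perturbed) value exceeds the
    other action's.  Any multiplicative value scaling K > 0 or modest effort
    cost leaves the argmax unchanged, which is why sure-bet performance is
    immune to manipulations and value deficits.
    """
    if cued_side not in ("left", "right"):
        raise ValueError("cued_side must be 'left' or 'right'")
    # the cued action carries its (possibly scaled) reward value; the other
    # action carries zero reward — only additive effort can move the argmax
    if cued_side == "right":
        q_cued = max(values.q_high_right, values.q_low_right) + values.effort_right
        q_other = values.effort_left
    else:
        q_cued = max(values.q_high_left, values.q_low_left) + values.effort_left
        q_other = values.effort_right
    if q_cued > q_other:
        return 1.0
    if q_cued < q_other:
        return 0.0
    return 0.5


# ---------------------------------------------------------------------------
# joint control + perturbed fitting
# ---------------------------------------------------------------------------

def _exploration_base_layout(conditions, spec: ModelSpec):
    """Names/bounds/x0 of the shared exploration baseline (fix rL = 1)."""
    layout = spec.layout(conditions)
    return layout


def _block_predict_exploration(p: dict, spec, layout, conditions, rates, cond_idx,
                               values_for_condition):
    """Predict per-bin p(R) with per-condition ValueParams supplied by a
    callback (condition, beta) -> ValueParams, plus an optional rate shift."""
    out = np.empty(len(rates))
    sig = fitting._condition_sigmas(spec, layout, p)
    for i, c in enumerate(conditions):
        m = cond_idx == i
        if not m.any():
            continue
        beta = p["beta"] if spec.share_beta else p[f"beta_{c}"]
        values, shift = values_for_condition(c, beta, sig[c])
        out[m] = exploration_prob_values(rates[m] + shift, sig[c], p["mu"], values)
    return out


def _joint_fit(control: BinnedChoices, perturbed: BinnedChoices,
               spec: ModelSpec, extra_names: list[str], extra_bounds: list,
               extra_x0: list, predict_control, predict_perturbed,
               n_starts: int, seed: int, label: str,
               with_ci: bool = False) -> FitResult:
    if control.conditions != perturbed.conditions:
        raise ValueError("control and perturbed tables must span the same conditions")
    layout = spec.layout(control.conditions)
    n_extra = len(extra_names)
    names = layout.names + list(extra_names)
    lower = np.append(layout.lower, [b[0] for b in extra_bounds])
    upper = np.append(layout.upper, [b[1] for b in extra_bounds])
    x0 = np.append(layout.x0, extra_x0)

    def objective(theta):
        p = dict(zip(layout.names, theta[:-n_extra]))
        extras = theta[-n_extra:]
        pc = predict_control(p, layout)
        pp = predict_perturbed(p, layout, extras)
        return _binned_nll(pc, control) + _binned_nll(pp, perturbed)

    theta, fun, diagnostics = _multistart_minimize(objective, lower, upper, x0,
                                                   n_starts, seed)
    loglik = -fun
    k = len(names)
    n = control.n_trials + perturbed.n_trials
    fit = FitResult(
        params=dict(zip(names, theta)), loglik=loglik, k=k, n=n,
        aic=2 * k - 2 * loglik, bic=k * np.log(n) - 2 * loglik,
        spec=spec, conditions=control.conditions, names=names,
        theta=np.asarray(theta), converged=any(d["success"] for d in diagnostics),
        n_starts=n_starts, seed=seed, diagnostics=diagnostics, label=label,
    )
    if with_ci:
        fit.ci = _joint_hessian_ci(objective, fit, lower, upper)
    return fit


def _joint_hessian_ci(objective, fit: FitResult, lower, upper,
                      alpha: float = 0.05) -> dict | None:
    """Wald intervals from the curvature of the joint objective."""
    from scipy.stats import norm as _norm
    from statsmodels.tools.numdiff import approx_hess1

    theta = np.clip(fit.theta, lower + 1e-5, upper - 1e-5)
    try:
        cov = np.linalg.inv(approx_hess1(theta, objective))
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var <= 0) or np.any(~np.isfinite(var)):
        return None
    se = np.sqrt(var)
    zc = _norm.ppf(1.0 - alpha / 2.0)
    return {"method": "hessian", "alpha": alpha,
            "intervals": {n: (fit.theta[i] - zc * se[i], fit.theta[i] + zc * se[i])
                          for i, n in enumerate(fit.names)},
            "se": dict(zip(fit.names, se))}


def fit_manipulation_pair(control: pd.DataFrame, manipulated: pd.DataFrame,
                          manipulation: Manipulation, family: str = "exploration",
                          n_starts: int = 10, seed: int = 0, conditions=None,
                          free_both_sides: bool = False,
                          with_ci: bool = False) -> FitResult:
    """Joint fit of control + reward-manipulated data, sharing every
    baseline parameter and freeing only the manipulated block's value.

    Under exploration, the manipulated block's lapse-controlling quantities
    are the effective value differences d_high = q(High,R) - q(High,L) and
    d_low = q(Low,L) - q(Low,R) (the control block has d_high = rR,
    d_low = rL = 1).  A manipulation touching one stimulus category frees
    only that category's difference (``value_high_manip`` for rightward
    magnitude changes and for probabilistic left reward on high rates), so
    k_joint = k_control + 1.  With ``free_both_sides`` both differences are
    free (k + 2) and the un-manipulated side's estimate, with its CI, tests
    one-sidedness empirically.

    ``inattention``: (mu, sigmas, p_attend) shared and p_bias free per
    block — the inattention observer's only way to move lapses, which
    necessarily moves both asymptotes together.
    """
    cb = bin_trials(control, conditions)
    mb = bin_trials(manipulated, cb.conditions)

    if family == "exploration":
        spec = ModelSpec(family="exploration", conditions=cb.conditions)
        high_side = ((manipulation.kind == "reward_magnitude" and manipulation.side == "right")
                     or (manipulation.kind == "reward_probability" and manipulation.side == "left"))

        def predict_control(p, layout):
            return _block_predict_exploration(
                p, spec, layout, cb.conditions, cb.rates, cb.cond_idx,
                lambda c, beta, s: (trained_values(r_right=p["r_right"],
                                                   r_left=1.0, beta=beta), 0.0))

        def predict_perturbed(p, layout, extras):
            if free_both_sides:
                d_high, d_low = extras
            elif high_side:
                d_high, d_low = extras[0], 1.0
            else:
                d_high, d_low = p["r_right"], extras[0]

            def vals(c, beta, s):
                return trained_values(r_right=d_high, r_left=d_low,
                                      beta=beta), 0.0
            return _block_predict_exploration(
                p, spec, layout, mb.conditions, mb.rates, mb.cond_idx, vals)

        if free_both_sides:
            extras = (["value_high_manip", "value_low_manip"],
                      [(0.0, 10.0), (0.0, 10.0)], [1.0, 1.0])
        elif high_side:
            extras = (["value_high_manip"], [(0.0, 10.0)], [1.0])
        else:
            extras = (["value_low_manip"], [(0.0, 10.0)], [1.0])
        return _joint_fit(cb, mb, spec, *extras,
                          predict_control, predict_perturbed, n_starts, seed,
                          label=f"exploration+{manipulation.kind}",
                          with_ci=with_ci)

    if family == "inattention":
        spec = ModelSpec(family="inattention", conditions=cb.conditions)

        def predict_block(p, layout, block, p_bias):
            out = np.empty(len(block.rates))
            sig = fitting._condition_sigmas(spec, layout, p)
            for i, c in enumerate(block.conditions):
                m = block.cond_idx == i
                if not m.any():
                    continue
                base = models.ideal_observer_prob(block.rates[m], sig[c], p["mu"])
                out[m] = p["p_attend"] * base + (1.0 - p["p_attend"]) * p_bias
            return out

        return _joint_fit(
            cb, mb, spec, ["p_bias_manip"], [(0.0, 1.0)], [0.5],
            lambda p, layout: predict_block(p, layout, cb, p["p_bias"]),
            lambda p, layout, extras: predict_block(p, layout, mb, extras[0]),
            n_starts, seed, label=f"inattention+{manipulation.kind}",
            with_ci=with_ci)

    raise ValueError("family must be 'exploration' or 'inattention'")


def fit_inactivation_pair(control: pd.DataFrame, perturbed: pd.DataFrame,
                          deficit_type: str, side: str = "right",
                          contingency: str = "standard",
                          n_starts: int = 10, seed: int = 0,
                          conditions=None, allow_enhancement: bool = False,
                          with_ci: bool = False) -> FitResult:
    """Joint fit of control + inactivation data: all baseline exploration
    parameters shared, plus exactly one deficit parameter K applied only to
    the perturbed block (k_joint = k_control + 1).

    ``side`` names the affected (contralateral) action; with a reversed
    contingency the stimulus-category mapping is resolved through the value
    map, so the deficit still attaches to the action.
    """
    if deficit_type not in DEFICIT_TYPES:
        raise ValueError(f"unknown deficit type {deficit_type!r}")
    cb = bin_trials(control, conditions)
    pb = bin_trials(perturbed, cb.conditions)
    spec = ModelSpec(family="exploration", conditions=cb.conditions)

    def base_values(beta, p):
        return trained_values(r_right=p["r_right"], r_left=1.0, beta=beta,
                              contingency=contingency)

    def predict_control(p, layout):
        return _block_predict_exploration(
            p, spec, layout, cb.conditions, cb.rates, cb.cond_idx,
            lambda c, beta, s: (base_values(beta, p), 0.0))

    def predict_perturbed(p, layout, extras):
        d = Deficit(type=deficit_type, K=float(extras[0]), side=side)
        def vals(c, beta, s):
            return apply_inactivation(base_values(beta, p), d), \
                deficit_rate_shift(d, s)
        return _block_predict_exploration(
            p, spec, layout, pb.conditions, pb.rates, pb.cond_idx, vals)

    if deficit_type == "biased_value":
        bounds, x0 = (0.01, 2.0 if allow_enhancement else 1.0), 0.8
    elif deficit_type == "biased_evidence":
        bounds, x0 = (0.0, 5.0), 0.5
    else:
        bounds, x0 = (-10.0, 0.0), -0.3
    return _joint_fit(cb, pb, spec, ["K"], [bounds], [x0],
                      predict_control, predict_perturbed, n_starts, seed,
                      label=deficit_type, with_ci=with_ci)


def deficit_model_comparison(control: pd.DataFrame, perturbed: pd.DataFrame,
                             side: str = "right", contingency: str = "standard",
                             n_starts: int = 10, seed: int = 0,
                             subject_id: str = "") -> tuple[pd.DataFrame, dict]:
    """Fit all three deficit types jointly and rank them by AIC/BIC.

    All three have the same k, so AIC and BIC rankings coincide.
    """
    fits = {}
    for dt in DEFICIT_TYPES:
        fits[dt] = fit_inactivation_pair(control, perturbed, dt, side=side,
                                         contingency=contingency,
                                         n_starts=n_starts, seed=seed)
    table = model_comparison_table(fits, subject_id=subject_id)
    return table.sort_values("bic").reset_index(drop=True), fits
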