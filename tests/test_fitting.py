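"""Maximum-likelihood fitting: likelihood oracle, recovery, comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from lapsekit import fitting as F, models as M, synthetic as S


def _psy_table(params_by_cond: dict, n_per_cond: int, seed: int) -> pd.DataFrame:
    mix = {c: 1.0 / len(params_by_cond) for c in params_by_cond}
    cfg = M.TaskConfig(modality_mix=mix, surebet_fraction=0.0)
    trials = S.generate_trials(cfg, n_trials=n_per_cond * len(params_by_cond),
                               seed=seed)
    return S.simulate_choices(trials, "psychometric", {"params": params_by_cond},
                              seed=seed + 1, config=cfg)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_nll_matches_bernoulli_product_oracle(rng):
    """Binned likelihood equals an independently coded trial-by-trial
    Bernoulli product to 1e-10."""
    n = 50
    rates = rng.integers(9, 17, n).astype(float)
    choices = rng.integers(0, 2, n).astype(float)
    df = pd.DataFrame({"subject_id": "x", "session_id": "s", "trial_index": range(n),
                       "condition": "visual", "rate_nominal": rates, "choice": choices})
    params = M.PsychometricParams(12.2, 1.7, 0.08, 0.12)
    spec = F.ModelSpec(family="psychometric", lapse_variant="variable",
                       conditions=("visual",))
    theta = {"mu_visual": 12.2, "sigma_visual": 1.7, "gamma_visual": 0.08,
             "lam_visual": 0.12}
    nll = F.negative_log_likelihood(df, spec, theta)
    oracle = 0.0
    for r, c in zip(rates, choices):  # plain python product, no vectorization
        p = M.psychometric_prob(float(r), params)
        oracle -= math.log(p) if c == 1.0 else math.log(1.0 - p)
    assert nll == pytest.approx(oracle, abs=1e-10)


def test_nll_of_coin_flip_model_is_n_ln2(rng):
    n = 64
    df = pd.DataFrame({"subject_id": "x", "session_id": "s", "trial_index": range(n),
                       "condition": "visual",
                       "rate_nominal": rng.integers(9, 17, n).astype(float),
                       "choice": rng.integers(0, 2, n).astype(float)})
    spec = F.ModelSpec(family="psychometric", lapse_variant="variable",
                       conditions=("visual",))
    theta = {"mu_visual": 12.5, "sigma_visual": 2.0, "gamma_visual": 0.5,
             "lam_visual": 0.5}  # forces p = 0.5 everywhere
    assert F.negative_log_likelihood(df, spec, theta) == pytest.approx(n * math.log(2))


def test_nll_validates_theta():
    df = _psy_table({"visual": M.PsychometricParams(12.5, 1.5)}, 200, 3)
    spec = F.ModelSpec(family="psychometric", lapse_variant="variable",
                       conditions=("visual",))
    with pytest.raises(ValueError, match="outside bounds"):
        F.negative_log_likelihood(df, spec, [12.5, -1.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="missing"):
        F.negative_log_likelihood(df, spec, {"mu_visual": 12.5})


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_psychometric_recovery_and_information_criteria():
    truth = M.PsychometricParams(12.5, 1.5, 0.1, 0.05)
    df = _psy_table({"visual": truth}, 10000, seed=11)
    spec = F.ModelSpec(family="psychometric", lapse_variant="variable",
                       conditions=("visual",))
    fit = F.fit_model(df, spec, seed=0)
    assert fit.params["mu_visual"] == pytest.approx(truth.mu, abs=0.15)
    assert fit.params["sigma_visual"] == pytest.approx(truth.sigma, abs=0.15)
    assert fit.params["gamma_visual"] == pytest.approx(truth.gamma, abs=0.02)
    assert fit.params["lam_visual"] == pytest.approx(truth.lam, abs=0.02)
    # information-criterion identities hold exactly
    assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=1e-9)
    assert fit.bic == pytest.approx(fit.k * np.log(fit.n) - 2 * fit.loglik, abs=1e-9)
    # likelihood at the optimum beats the generating parameters
    nll_truth = F.negative_log_likelihood(df, spec, {
        "mu_visual": truth.mu, "sigma_visual": truth.sigma,
        "gamma_visual": truth.gamma, "lam_visual": truth.lam})
    assert -fit.loglik <= nll_truth + 1e-6


def test_fit_is_deterministic_given_seed():
    df = _psy_table({"visual": M.PsychometricParams(12.5, 1.5, 0.1, 0.05)}, 2000, 5)
    spec = F.ModelSpec(family="psychometric", lapse_variant="variable",
                       conditions=("visual",))
    f1 = F.fit_model(df, spec, seed=9)
    f2 = F.fit_model(df, spec, seed=9)
    np.testing.assert_array_equal(f1.theta, f2.theta)


def test_exploration_recovery_shared_beta():
    """Simulate-then-fit under the exploration model with a shared inverse
    temperature and the optimal multisensory-sigma constraint: beta comes
    back within 15% and the lapse asymptotes within 0.02 at 10k
    trials/condition."""
    cfg = M.TaskConfig(modality_mix={"visual": 1 / 3, "auditory": 1 / 3,
                                     "multisensory": 1 / 3}, surebet_fraction=0.0)
    sig = {"visual": 2.5, "auditory": 3.0,
           "multisensory": M.combined_sigma(3.0, 2.5)}
    beta = {c: 2.0 for c in sig}
    trials = S.generate_trials(cfg, n_trials=30000, seed=500)
    sim = S.simulate_choices(trials, "exploration", {"sigma": sig, "beta": beta},
                             seed=600, config=cfg)
    spec = F.ModelSpec(family="exploration", share_beta=True,
                       conditions=("visual", "auditory", "multisensory"))
    fit = F.fit_model(sim, spec, seed=0)
    assert fit.params["beta"] == pytest.approx(2.0, rel=0.15)
    g, l = M.exploration_asymptotes(fit.params["beta"], fit.params["r_right"], 1.0)
    tg, tl = M.exploration_asymptotes(2.0, 1.0, 1.0)
    assert g == pytest.approx(tg, abs=0.02)
    assert l == pytest.approx(tl, abs=0.02)
    # the optimizer never does worse than the generating parameters
    nll_truth = F.negative_log_likelihood(sim, spec, {
        "mu": 12.5, "sigma_visual": 2.5, "sigma_auditory": 3.0,
        "beta": 2.0, "r_right": 1.0})
    assert -fit.loglik <= nll_truth + 1e-6


def test_min_trials_guard():
    df = _psy_table({"visual": M.PsychometricParams(12.5, 1.5)}, 30, 2)
    with pytest.raises(ValueError, match="fewer than"):
        F.fit_model(df, F.ModelSpec(family="psychometric"), seed=0)


# ---------------------------------------------------------------------------
# nesting and variant comparison
# ---------------------------------------------------------------------------

def test_lapse_variant_nesting_and_selection():
    """Variable >= fixed >= none in log-likelihood on any data; BIC picks
    the generating variant."""
    params = {
        "visual": M.PsychometricParams(12.4, 1.5, 0.12, 0.03),
        "auditory": M.PsychometricParams(12.6, 1.9, 0.05, 0.15),
        "multisensory": M.PsychometricParams(12.5, 1.1, 0.01, 0.02),
    }
    df = _psy_table(params, 5000, seed=21)
    table, fits = F.lapse_variant_comparison(df, seed=0)
    ll = {v: fits[f"{v}_lapse"].loglik for v in ("none", "fixed", "variable")}
    assert ll["variable"] >= ll["fixed"] - 1e-6
    assert ll["fixed"] >= ll["none"] - 1e-6
    assert table.iloc[0]["model"] == "variable_lapse"
    assert table.iloc[0]["d_bic"] == 0.0
    assert (table["d_bic"] >= 0).all() and (table["d_aic"] >= 0).all()


def test_no_lapse_data_selects_no_lapse_variant():
    params = {
        "visual": M.PsychometricParams(12.4, 1.5),
        "auditory": M.PsychometricParams(12.6, 1.9),
    }
    df = _psy_table(params, 5000, seed=31)
    table, _ = F.lapse_variant_comparison(df, seed=0)
    assert table.iloc[0]["model"] == "none_lapse"


# ---------------------------------------------------------------------------
# multisensory optimality check
# ---------------------------------------------------------------------------

def test_optimality_check_identity_and_lapse_artifact():
    """With variable lapses the measured multisensory sigma sits on the
    optimal prediction; ignoring lapses makes integration look
    supra-optimal (measured below predicted)."""
    gen = S.default_generative_params()
    fits_var, fits_none = {}, {}
    for i in range(4):
        trials = S.generate_trials(n_trials=15000, seed=300 + 10 * i)
        df = S.simulate_choices(trials, "exploration", gen, seed=301 + 10 * i)
        for variant, store in (("variable", fits_var), ("none", fits_none)):
            fit = F.fit_model(df, F.ModelSpec(family="psychometric",
                                              lapse_variant=variant), seed=0)
            store[f"s{i}"] = {
                c: M.PsychometricParams(
                    fit.params[f"mu_{c}"], fit.params[f"sigma_{c}"])
                for c in ("visual", "auditory", "multisensory")}
    _, summary_var = F.optimality_check(fits_var)
    _, summary_none = F.optimality_check(fits_none)
    # unbiased when lapses modeled; clearly "supra-optimal" when not
    assert abs(summary_var["mean_diff"]) < 0.25
    assert summary_none["mean_diff"] < -0.25


def test_optimality_check_exact_identity():
    fits = {"a": {"visual": M.PsychometricParams(12.5, 2.0),
                  "auditory": M.PsychometricParams(12.5, 1.5),
                  "multisensory": M.PsychometricParams(12.5, M.combined_sigma(1.5, 2.0))}}
    df, summary = F.optimality_check(fits)
    assert summary["mean_diff"] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="missing condition"):
        F.optimality_check({"a": {"visual": M.PsychometricParams(12.5, 2.0)}})


# ---------------------------------------------------------------------------
# constrained exploration fit
# ---------------------------------------------------------------------------

def test_constrained_exploration_beats_unconstrained_on_linear_data(
        exploration_dataset):
    cfit = F.constrained_exploration_fit(exploration_dataset, seed=0)
    efit = F.fit_model(exploration_dataset, F.ModelSpec(family="exploration"), seed=0)
    assert cfit.k == efit.k - 1
    assert cfit.bic < efit.bic
    # implied lapse totals increase with condition noise
    totals = {c: sum(gl) for c, gl in F.lapse_rates(cfit).items()}
    assert totals["multisensory"] < totals["visual"] <= totals["auditory"] + 0.02


def test_constrained_fit_needs_three_conditions():
    df = _psy_table({"visual": M.PsychometricParams(12.5, 1.5)}, 500, 2)
    with pytest.raises(ValueError, match="3 conditions"):
        F.constrained_exploration_fit(df, seed=0)


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def well_conditioned_fit():
    truth = M.PsychometricParams(12.5, 1.2, 0.10, 0.06)
    df = _psy_table({"visual": truth}, 20000, seed=41)
    spec = F.ModelSpec(family="psychometric", lapse_variant="variable",
                       conditions=("visual",))
    return df, F.fit_model(df, spec, seed=0)


def test_ci_brackets_estimate_and_methods_agree(well_conditioned_fit):
    df, fit = well_conditioned_fit
    ci_h = F.confidence_intervals(fit, df, method="hessian")
    ci_b = F.confidence_intervals(fit, df, method="bootstrap", n_boot=200, seed=2)
    for name in fit.names:
        lo, hi = ci_b["intervals"][name]
        assert lo <= fit.params[name] <= hi
        wh = ci_h["intervals"][name][1] - ci_h["intervals"][name][0]
        wb = hi - lo
        assert 0.5 < wh / wb < 2.0  # curvature and resampling agree on scale


def test_bootstrap_single_resample_is_degenerate(well_conditioned_fit):
    df, fit = well_conditioned_fit
    ci = F.confidence_intervals(fit, df, method="bootstrap", n_boot=1, seed=5)
    for lo, hi in ci["intervals"].values():
        assert lo == hi


def test_bootstrap_ci_deterministic(well_conditioned_fit):
    df, fit = well_conditioned_fit
    a = F.confidence_intervals(fit, df, method="bootstrap", n_boot=25, seed=3)
    b = F.confidence_intervals(fit, df, method="bootstrap", n_boot=25, seed=3)
    assert a["intervals"] == b["intervals"]


# ---------------------------------------------------------------------------
# history-conditioned fits
# ---------------------------------------------------------------------------

def test_history_split_partitions_eligible_trials(exploration_dataset):
    h = F.history_conditioned_fit(
        exploration_dataset, spec=F.ModelSpec(family="exploration"), seed=0)
    assert h["post_success_n"] + h["post_failure_n"] == h["n_eligible"]


def test_static_generator_shows_no_history_effect(exploration_dataset):
    """A non-learning observer's post-success and post-failure lapses are
    statistically indistinguishable.  The splits are small, so the fit
    shares one inverse temperature across conditions."""
    h = F.history_conditioned_fit(
        exploration_dataset,
        spec=F.ModelSpec(family="exploration", share_beta=True), seed=0)
    ls = h["post_success_lapses"]
    lf = h["post_failure_lapses"]
    for c in ls:
        assert ls[c][1] == pytest.approx(lf[c][1], abs=0.06)
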