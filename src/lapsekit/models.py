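"""Choice-probability models for two-alternative rate discrimination.

All functions compute the probability of a rightward (high-rate) choice as a
function of the stimulus event rate ``s`` (Hz), under one of the generative
model families used to explain lapses:

* a descriptive four-parameter psychometric curve,
* a Bayesian ideal observer with optimal multisensory cue combination,
* an inattention observer that guesses on a fraction of trials,
* a motor-error / epsilon-greedy observer,
* an uncertainty-guided exploration observer (softmax / Thompson-style) whose
  lapses arise from finite inverse temperature beta,
* a log-posterior matching rule, included only as a contrast (it produces no
  lapses).

Everything is a pure function of scalars or aligned numpy arrays; no fitting
or trial bookkeeping lives here.  Probability clipping is deliberately NOT
applied in this module — likelihood code clips, model outputs do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.stats import norm

__all__ = [
    "TaskConfig",
    "PsychometricParams",
    "SensoryParams",
    "BeliefState",
    "ValueParams",
    "psychometric_prob",
    "combined_sigma",
    "belief_state",
    "action_values",
    "ideal_observer_prob",
    "inattention_prob",
    "inattention_asymptotes",
    "epsilon_greedy_prob",
    "epsilon_greedy_asymptotes",
    "exploration_prob",
    "exploration_prob_values",
    "exploration_asymptotes",
    "exploration_asymptotes_values",
    "matching_rule_prob",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskConfig:
    """Static description of the rate-discrimination task.

    Defaults are the standard task: rates on the integer grid 9–16 Hz around
    a 12.5 Hz category boundary, 40/40/20 visual/auditory/multisensory mix,
    6% sure-bet trials, 24 uL reward on both sides.  Reward magnitudes are
    carried in uL; models work in value units of one baseline reward
    (24 uL == 1).
    """

    boundary_mu0: float = 12.5
    rate_min: float = 9.0
    rate_max: float = 16.0
    prior_high: float = 0.5
    reward_right_ul: float = 24.0
    reward_left_ul: float = 24.0
    modality_mix: dict = field(
        default_factory=lambda: {
            "visual": 0.40,
            "auditory": 0.40,
            "multisensory": 0.20,
            "neutral": 0.0,
        }
    )
    surebet_fraction: float = 0.06
    contingency: str = "standard"  # high-rate rewarded right

    @property
    def prior_low(self) -> float:
        return 1.0 - self.prior_high

    def __post_init__(self) -> None:
        if not 0.0 <= self.prior_high <= 1.0:
            raise ValueError("prior_high must lie in [0, 1]")
        if not self.rate_min < self.boundary_mu0 < self.rate_max:
            raise ValueError("boundary_mu0 must lie strictly inside [rate_min, rate_max]")
        if self.reward_right_ul < 0 or self.reward_left_ul < 0:
            raise ValueError("reward magnitudes must be >= 0")
        if self.contingency not in ("standard", "reversed"):
            raise ValueError("contingency must be 'standard' or 'reversed'")
        if not 0.0 <= self.surebet_fraction < 1.0:
            raise ValueError("surebet_fraction must lie in [0, 1)")
        if any(not 0.0 <= v <= 1.0 for v in self.modality_mix.values()):
            raise ValueError("modality_mix proportions must lie in [0, 1]")
        mix = sum(self.modality_mix.values())
        # the mix may be given within discrimination trials (sums to 1) or as
        # absolute proportions (sums to 1 - surebet_fraction)
        if not (np.isclose(mix, 1.0, atol=1e-8)
                or np.isclose(mix + self.surebet_fraction, 1.0, atol=1e-8)):
            raise ValueError(
                f"modality_mix must sum to 1 or to 1 - surebet_fraction (got {mix:g})"
            )


@dataclass(frozen=True)
class PsychometricParams:
    """Four-parameter descriptive curve: midpoint mu (Hz), inverse slope
    sigma (Hz), lower asymptote gamma (low-rate lapse) and upper-asymptote
    complement lam (high-rate lapse)."""

    mu: float
    sigma: float
    gamma: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        for name in ("gamma", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.gamma + self.lam > 1.0:
            raise ValueError("gamma + lam must not exceed 1")

    @property
    def total_lapse(self) -> float:
        return self.gamma + self.lam


@dataclass(frozen=True)
class SensoryParams:
    """Per-modality sensory noise.  sigma_m doubles as the posterior width of
    the combined estimate when it equals the optimal combination."""

    sigma_a: float
    sigma_v: float
    sigma_m: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        if self.sigma_a <= 0 or self.sigma_v <= 0:
            raise ValueError("sigma_a and sigma_v must be > 0")
        if self.sigma_m is None:
            object.__setattr__(self, "sigma_m", combined_sigma(self.sigma_a, self.sigma_v))
        elif self.sigma_m <= 0:
            raise ValueError("sigma_m must be > 0")

    @property
    def w_a(self) -> float:
        return self.sigma_m**2 / self.sigma_a**2

    @property
    def w_v(self) -> float:
        return self.sigma_m**2 / self.sigma_v**2


@dataclass(frozen=True)
class BeliefState:
    """Posterior belief rho that the category is High, given the combined
    noisy observation x_combined."""

    x_combined: float
    rho: float
    s_true: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass(frozen=True)
class ValueParams:
    """Learnt stimulus–action values and decision-rule parameters.

    q_high_right etc. are the values q(c, a) of taking action a when the
    category is c, in units where the baseline reward is 1.  A fully trained
    observer under the standard contingency has q_high_right = rR,
    q_low_left = rL and zero off-diagonal values.  ``effort_right`` /
    ``effort_left`` are additive offsets on the expected action values (used
    by the biased-effort deficit; <= 0 for a cost).
    """

    beta: float = 1.0
    q_high_right: float = 1.0
    q_high_left: float = 0.0
    q_low_right: float = 0.0
    q_low_left: float = 1.0
    effort_right: float = 0.0
    effort_left: float = 0.0
    eps: float = 0.0
    p_attend: float = 1.0
    p_bias: float = 0.5

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        for name in ("eps", "p_attend", "p_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("q_high_right", "q_high_left", "q_low_right", "q_low_left"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def expected_values(self, rho):
        """Expected action values (Q_R, Q_L) at belief state rho."""
        rho = np.asarray(rho, dtype=float)
        q_r = rho * self.q_high_right + (1.0 - rho) * self.q_low_right + self.effort_right
        q_l = rho * self.q_high_left + (1.0 - rho) * self.q_low_left + self.effort_left
        return q_r, q_l


# fully trained values for given rewards / contingency ----------------------

def trained_values(r_right: float = 1.0, r_left: float = 1.0, beta: float = 1.0,
                   contingency: str = "standard", **kw) -> ValueParams:
    """ValueParams of an observer that has fully learnt the contingency."""
    if contingency == "standard":
        return ValueParams(beta=beta, q_high_right=r_right, q_low_left=r_left,
                           q_high_left=0.0, q_low_right=0.0, **kw)
    if contingency == "reversed":
        return ValueParams(beta=beta, q_high_left=r_left, q_low_right=r_right,
                           q_high_right=0.0, q_low_left=0.0, **kw)
    raise ValueError("contingency must be 'standard' or 'reversed'")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_SQRT2 = np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _phi(z):
    """Standard normal CDF, vectorized, without scipy.stats overhead."""
    return 0.5 * (1.0 + special.erf(np.asarray(z, dtype=float) / _SQRT2))


def _phi_pdf(z):
    """Standard normal density, vectorized, without scipy.stats overhead."""
    z = np.asarray(z, dtype=float)
    return _INV_SQRT2PI * np.exp(-0.5 * z * z)


def _check_prob(name: str, value) -> None:
    v = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


def _logistic(z):
    z = np.asarray(z, dtype=float)
    return special.expit(z)


# ---------------------------------------------------------------------------
# descriptive psychometric curve
# ---------------------------------------------------------------------------

def psychometric_prob(x, params: PsychometricParams):
    """P(rightward | rate x) under the four-parameter psychometric curve

        psi(x) = gamma + (1 - gamma - lam) * Phi((x - mu) / sigma).

    gamma and lam are the low- and high-rate lapse rates (the curve's lower
    asymptote and upper-asymptote complement).
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("x must be finite")
    p = params.gamma + (1.0 - params.gamma - params.lam) * _phi((x - params.mu) / params.sigma)
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# ideal observer and cue combination
# ---------------------------------------------------------------------------

def combined_sigma(sigma_a, sigma_v):
    """Optimal (inverse-variance) combined noise (sigma_a^-2 + sigma_v^-2)^-1/2."""
    sigma_a = np.asarray(sigma_a, dtype=float)
    sigma_v = np.asarray(sigma_v, dtype=float)
    if np.any(sigma_a <= 0) or np.any(sigma_v <= 0):
        raise ValueError("sigma_a and sigma_v must be > 0")
    out = 1.0 / np.sqrt(sigma_a**-2 + sigma_v**-2)
    return out if out.ndim else float(out)


def belief_state(x_combined, mu0: float, sigma_post: float):
    """Posterior belief rho = P(category High | combined observation) under
    flat category priors: Phi((x - mu0) / sigma_post)."""
    if sigma_post <= 0:
        raise ValueError("sigma_post must be > 0")
    rho = _phi((np.asarray(x_combined, dtype=float) - mu0) / sigma_post)
    return rho if rho.ndim else float(rho)


def action_values(rho, r_right: float, r_left: float, contingency: str = "standard"):
    """Expected action values (Q_R, Q_L) = (rho*rR, (1-rho)*rL) for a trained
    observer; the category->action map is swapped under reversed contingency."""
    _check_prob("rho", rho)
    if r_right < 0 or r_left < 0:
        raise ValueError("rewards must be >= 0")
    rho = np.asarray(rho, dtype=float)
    if contingency == "standard":
        q_r, q_l = rho * r_right, (1.0 - rho) * r_left
    elif contingency == "reversed":
        q_r, q_l = (1.0 - rho) * r_right, rho * r_left
    else:
        raise ValueError("contingency must be 'standard' or 'reversed'")
    if q_r.ndim:
        return q_r, q_l
    return float(q_r), float(q_l)


def ideal_observer_prob(s, sigma: float, mu0: float, prior_high: float = 0.5,
                        r_right: float = 1.0, r_left: float = 1.0):
    """P(rightward | true rate s) for the reward-maximizing ideal observer.

    The observer chooses right whenever its posterior belief exceeds the
    reward/prior-adjusted criterion 1 / (1 + pHigh*rR / (pLow*rL)); with the
    combined observation Gaussian around s this is a shifted cumulative
    Gaussian in s.  With equal rewards and flat priors it reduces to
    Phi((s - mu0) / sigma) and asymptotes exactly at 0 and 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    _check_prob("prior_high", prior_high)
    if r_right < 0 or r_left < 0:
        raise ValueError("rewards must be >= 0")
    s = np.asarray(s, dtype=float)
    prior_low = 1.0 - prior_high
    num = prior_high * r_right
    den = prior_low * r_left
    if num == 0 and den == 0:
        raise ValueError("at least one of prior*reward products must be positive")
    if num == 0:  # rightward never worth it
        p = np.zeros_like(s)
        return p if p.ndim else 0.0
    if den == 0:
        p = np.ones_like(s)
        return p if p.ndim else 1.0
    threshold = 1.0 / (1.0 + num / den)
    p = _phi((s - mu0) / sigma - norm.ppf(threshold))
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# inattention and epsilon-greedy families
# ---------------------------------------------------------------------------

def inattention_prob(s, sigma: float, mu0: float, p_attend: float, p_bias: float,
                     prior_high: float = 0.5, r_right: float = 1.0, r_left: float = 1.0):
    """Inattention observer: with probability p_attend behaves like the ideal
    observer, otherwise guesses rightward with probability p_bias.  The
    asymptotes satisfy gamma + lam = 1 - p_attend and gamma/(gamma+lam) = p_bias.
    """
    _check_prob("p_attend", p_attend)
    _check_prob("p_bias", p_bias)
    base = ideal_observer_prob(s, sigma, mu0, prior_high, r_right, r_left)
    return p_attend * np.asarray(base) + (1.0 - p_attend) * p_bias if np.ndim(base) \
        else p_attend * base + (1.0 - p_attend) * p_bias


def inattention_asymptotes(p_attend: float, p_bias: float) -> tuple[float, float]:
    """Closed-form lapse rates (gamma, lam) of the inattention observer."""
    _check_prob("p_attend", p_attend)
    _check_prob("p_bias", p_bias)
    return (1.0 - p_attend) * p_bias, (1.0 - p_attend) * (1.0 - p_bias)


def epsilon_greedy_prob(s, sigma: float, mu0: float, eps: float, p_bias: float,
                        prior_high: float = 0.5, r_right: float = 1.0, r_left: float = 1.0):
    """Motor-error / epsilon-greedy observer: random (biased) choice on an eps
    fraction of trials, ideal otherwise.  gamma + lam = eps."""
    _check_prob("eps", eps)
    _check_prob("p_bias", p_bias)
    base = ideal_observer_prob(s, sigma, mu0, prior_high, r_right, r_left)
    return (1.0 - eps) * np.asarray(base) + eps * p_bias if np.ndim(base) \
        else (1.0 - eps) * base + eps * p_bias


def epsilon_greedy_asymptotes(eps: float, p_bias: float) -> tuple[float, float]:
    """Closed-form lapse rates (gamma, lam) = (eps*p_bias, eps*(1-p_bias))."""
    _check_prob("eps", eps)
    _check_prob("p_bias", p_bias)
    return eps * p_bias, eps * (1.0 - p_bias)


# ---------------------------------------------------------------------------
# uncertainty-guided exploration (softmax over belief-state action values)
# ---------------------------------------------------------------------------

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GH_CACHE:
        z, w = np.polynomial.hermite.hermgauss(n)
        _GH_CACHE[n] = (z, w / np.sqrt(np.pi))
    return _GH_CACHE[n]


_GL_NODES = np.polynomial.legendre.leggauss(8)
_REFINE_LEVELS = 2.0 ** np.arange(16)  # geometric panels around the criterion


def exploration_prob_values(s, sigma_post: float, mu0: float, values: ValueParams,
                            n_nodes: int = 129):
    """P(rightward | s) under the softmax-exploration observer with arbitrary
    stimulus–action values.

    Marginalizes the softmax over the latent belief state: the combined
    observation x is Gaussian around s with width sigma_post, the belief is
    rho(x) = Phi((x - mu0)/sigma_post), the expected action values are
    Q_a(rho), and the choice is softmax(beta * (Q_R - Q_L)).

    Because Q_R - Q_L is linear in rho, the integrand has a single logistic
    transition at the decision criterion; its width shrinks like
    1/(beta * reward scale), so a fixed Gauss–Hermite rule under-resolves it
    at large beta.  The integral is therefore evaluated in standardized
    observation coordinates z = (x - s)/sigma_post with composite
    Gauss–Legendre panels over [-8, 8] plus panels geometrically refined
    around the criterion, which stays accurate uniformly in beta (including
    the ideal-observer limit).  A plain Gauss–Hermite rule with ``n_nodes``
    nodes is used when the criterion lies outside the belief range.  The
    equivalent rho-space density-ratio form is kept as a test cross-check
    only.
    """
    if sigma_post <= 0:
        raise ValueError("sigma_post must be > 0")
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    s_in = np.asarray(s, dtype=float)
    s = np.atleast_1d(s_in)
    beta = values.beta

    # Q_R(rho) - Q_L(rho) = a*rho + b
    a = (values.q_high_right - values.q_high_left
         - values.q_low_right + values.q_low_left)
    b = (values.q_low_right - values.q_low_left
         + values.effort_right - values.effort_left)

    rho_star = -b / a if a != 0.0 else np.nan
    refined = beta > 0 and a != 0.0 and 1e-9 < rho_star < 1.0 - 1e-9

    if not refined:
        # no interior criterion: integrand varies on the sigma scale only
        z, w = _gh_nodes(n_nodes)
        x = s[:, None] + _SQRT2 * sigma_post * z
        rho = _phi((x - mu0) / sigma_post)
        p = _logistic(beta * (a * rho + b)) @ w
    else:
        z_star = float(special.ndtri(rho_star))  # criterion in belief coordinates
        x_star = mu0 + sigma_post * z_star
        z_c = (x_star - s) / sigma_post      # criterion per stimulus, z units
        # logistic transition width in z units
        slope = beta * abs(a) * float(_phi_pdf(z_star))
        width = 1.0 / slope if slope > 1e-290 else 16.0
        offsets = width * _REFINE_LEVELS
        coarse = np.linspace(-8.0, 8.0, 17)
        zc = np.clip(z_c[:, None], -8.0, 8.0)
        edges = np.concatenate([
            np.broadcast_to(coarse, (len(s), coarse.size)),
            zc,
            np.clip(zc + offsets, -8.0, 8.0),
            np.clip(zc - offsets, -8.0, 8.0),
        ], axis=1)
        edges.sort(axis=1)
        lo, hi = edges[:, :-1], edges[:, 1:]
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        xi, wxi = _GL_NODES
        zq = mid[:, :, None] + half[:, :, None] * xi      # (n_s, panels, 8)
        wt = half[:, :, None] * wxi * _phi_pdf(zq)
        rho = _phi((s[:, None, None] + sigma_post * zq - mu0) / sigma_post)
        p = (_logistic(beta * (a * rho + b)) * wt).sum(axis=(1, 2))

    if not np.all(np.isfinite(p)):
        raise ArithmeticError("exploration quadrature produced non-finite values")
    return p if s_in.ndim else float(p[0])


def exploration_prob(s, sigma_post: float, mu0: float, beta: float,
                     r_right: float = 1.0, r_left: float = 1.0,
                     n_nodes: int = 129):
    """P(rightward | s) for a trained softmax-exploration observer, i.e. the
    marginal of softmax(beta * (rho*(rR+rL) - rL)) over the belief state.

    Asymptotes at gamma = 1/(1+exp(beta*rL)) and 1 - lam with
    lam = 1/(1+exp(beta*rR)); beta -> infinity recovers the ideal observer.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if r_right < 0 or r_left < 0:
        raise ValueError("rewards must be >= 0")
    vals = trained_values(r_right=r_right, r_left=r_left, beta=beta)
    return exploration_prob_values(s, sigma_post, mu0, vals, n_nodes=n_nodes)


def _exploration_prob_rho_space(s: float, sigma_post: float, mu0: float, beta: float,
                                r_right: float = 1.0, r_left: float = 1.0,
                                eps: float = 1e-9) -> float:
    """Direct rho-space integral (density-ratio form) — slow reference
    implementation used only to cross-check the quadrature.

    The density ratio is evaluated in log space and the integrable endpoint
    singularities are handled analytically: over [0, eps] and [1 - eps, 1]
    the softmax is constant to O(beta * reward * eps), so those slivers
    contribute f(0) * P(rho < eps) and f(1) * P(rho > 1 - eps) exactly.
    """
    from scipy.integrate import quad

    def integrand(rho: float) -> float:
        u = sigma_post * norm.ppf(1.0 - rho)  # quantile of N(0, sigma_post)
        log_ratio = (norm.logpdf(u, loc=mu0 - s, scale=sigma_post)
                     - norm.logpdf(u, loc=0.0, scale=sigma_post))
        f = float(_logistic(beta * (rho * (r_right + r_left) - r_left)))
        return f * float(np.exp(log_ratio))

    # help the adaptive rule at the softmax transition and wherever the
    # observation distribution puts mass (its quantiles mapped into rho)
    points = {r_left / (r_right + r_left)}
    for k in np.arange(-6.0, 6.5, 0.5):
        points.add(float(_phi((s + k * sigma_post - mu0) / sigma_post)))
    points = sorted(min(max(p, eps), 1 - eps) for p in points)
    val, _ = quad(integrand, eps, 1.0 - eps, limit=800, points=points,
                  epsabs=1e-12, epsrel=1e-12)
    # analytic tail slivers: rho < eps <=> x below the eps-quantile of belief
    x_lo = mu0 + sigma_post * norm.ppf(eps)
    x_hi = mu0 + sigma_post * norm.ppf(1.0 - eps)
    f0 = float(_logistic(-beta * r_left))
    f1 = float(_logistic(beta * r_right))
    val += f0 * float(_phi((x_lo - s) / sigma_post))
    val += f1 * float(1.0 - _phi((x_hi - s) / sigma_post))
    return val


def exploration_asymptotes(beta: float, r_right: float = 1.0, r_left: float = 1.0
                           ) -> tuple[float, float]:
    """Closed-form lapse rates of the exploration observer:

        gamma = 1 / (1 + exp(beta * rL)),   lam = 1 / (1 + exp(beta * rR)).

    gamma depends only on the leftward reward, lam only on the rightward one —
    the dissociation that one-sided reward manipulations exploit.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if r_right < 0 or r_left < 0:
        raise ValueError("rewards must be >= 0")
    return float(_logistic(-beta * r_left)), float(_logistic(-beta * r_right))


def exploration_asymptotes_values(values: ValueParams) -> tuple[float, float]:
    """Lapse rates for arbitrary stimulus–action values, from the rho -> 0/1
    limits of the softmax."""
    q_r0, q_l0 = values.expected_values(0.0)
    q_r1, q_l1 = values.expected_values(1.0)
    gamma = float(_logistic(values.beta * (q_r0 - q_l0)))
    lam = 1.0 - float(_logistic(values.beta * (q_r1 - q_l1)))
    return gamma, lam


# ---------------------------------------------------------------------------
# matching rule (contrast case: produces no lapses)
# ---------------------------------------------------------------------------

def matching_rule_prob(q_right, q_left, beta: float):
    """Generalized probability matching: softmax on log-values,
    Q_R^beta / (Q_R^beta + Q_L^beta).  As one value goes to zero the choice
    probability saturates at 0/1 — no lapses; included to demonstrate the
    contrast with the value-space softmax."""
    q_right = np.asarray(q_right, dtype=float)
    q_left = np.asarray(q_left, dtype=float)
    if np.any(q_right <= 0) or np.any(q_left <= 0):
        raise ValueError("q_right and q_left must be > 0")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    p = _logistic(beta * (np.log(q_right) - np.log(q_left)))
    return p if p.ndim else float(p)
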