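"""Hierarchical estimation of PoP-ORL parameters, one assessment wave at a time.

Subjects at a wave share a population: each subject's parameters are modelled
as draws from normal distributions on an unconstrained scale (learning rates
mapped through the standard-normal CDF link, so their unconstrained values
are probits; beta_f and beta_b identity-linked).  The default backend
(``map_eb``) is a penalized-likelihood empirical-Bayes scheme: it alternates
subject-level MAP estimation under the current group prior with group
moment updates (posterior means and variances via a diagonal Laplace
approximation), which shrinks noisy subject estimates toward the group mean
exactly as a full hierarchical sampler would, at desk scale.  An optional
``mcmc`` backend draws per-subject posteriors with an affine-invariant
ensemble sampler under the converged group prior and reports posterior
means; it approximates (not replicates) a fully joint hierarchical sampler.

Downstream growth models consume the resulting point estimates, with the
learning rates normalized through the inverse standard-normal CDF.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .igt_task import SessionLog, TaskConfig, default_task_config
from .pop_orl import (
    DECK_INDEX,
    ModelConfig,
    ORLParams,
    _loglik_core,
    _schedule_tables,
    _simulate_core,
    session_arrays,
    simulate_agent,
)

PARAM_NAMES = ("A_rew", "A_pun", "beta_f", "beta_b")
RATE_CLIP = 1e-6

#: unconstrained-scale starting group prior: rates centred at 0.5
#: (probit 0), betas at 0; unit SDs except a wider one for beta_f.
INIT_GROUP_MEANS = np.zeros(4)
INIT_GROUP_SDS = np.array([1.0, 1.0, 2.0, 1.0])

_BOUNDS = [(-6.0, 6.0), (-6.0, 6.0), (-25.0, 25.0), (-25.0, 25.0)]


class DegenerateGeneratorError(ValueError):
    """Generator with zero between-subject variance: recovery r is undefined."""


def probit_transform(a: float | np.ndarray) -> float | np.ndarray:
    """Inverse standard-normal CDF of a rate in (0, 1).

    Values are clipped to [1e-6, 1 - 1e-6] first so boundary estimates map
    to large finite probits instead of infinities.
    """
    arr = np.asarray(a, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("rates must lie in [0, 1]")
    out = ndtri(np.clip(arr, RATE_CLIP, 1.0 - RATE_CLIP))
    return float(out) if np.isscalar(a) or arr.ndim == 0 else out


def theta_to_params(theta: np.ndarray) -> ORLParams:
    """Unconstrained 4-vector (probit rates, betas) -> natural parameters."""
    return ORLParams(
        float(ndtr(theta[0])), float(ndtr(theta[1])),
        float(theta[2]), float(theta[3]),
    )


@dataclass(frozen=True)
class FitConfig:
    backend: str = "map_eb"
    tolerance: float = 1e-3
    max_iterations: int = 30
    n_starts: int = 3
    start_jitter: float = 0.5  # in units of group SD
    seed: int = 0
    # mcmc backend only
    walkers: int = 16
    warmup: int = 200
    samples: int = 300

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.backend not in ("map_eb", "mcmc"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class GroupPosterior:
    means: np.ndarray  # unconstrained scale, order PARAM_NAMES
    sds: np.ndarray
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            raise ValueError("group SDs must be positive")


def flat_prior(sd: float = 10.0) -> GroupPosterior:
    return GroupPosterior(INIT_GROUP_MEANS.copy(), np.full(4, sd))


@dataclass(frozen=True)
class SubjectEstimate:
    subject_id: str
    wave: int
    A_rew: float
    A_pun: float
    beta_f: float
    beta_b: float
    A_rew_z: float
    A_pun_z: float
    converged: bool = True

    @classmethod
    def from_theta(cls, subject_id, wave, theta, converged=True):
        p = theta_to_params(theta)
        return cls(
            subject_id, wave, p.A_rew, p.A_pun, p.beta_f, p.beta_b,
            probit_transform(p.A_rew), probit_transform(p.A_pun), converged,
        )

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.A_rew_z, self.A_pun_z, self.beta_f, self.beta_b])


def estimates_to_df(estimates) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "subject_id": e.subject_id, "wave": e.wave,
            "A_rew": e.A_rew, "A_pun": e.A_pun,
            "beta_f": e.beta_f, "beta_b": e.beta_b,
            "A_rew_z": e.A_rew_z, "A_pun_z": e.A_pun_z,
            "converged": e.converged,
        }
        for e in estimates
    ])


# ---------------------------------------------------------------------------
# subject-level MAP


@njit(cache=False)
def _negll_theta(deck_idx, played, outcomes, theta, scale, fictive, atten):
    # Phi(z) via erf; keeps the whole objective inside the jit
    a_rew = 0.5 * (1.0 + math.erf(theta[0] / math.sqrt(2.0)))
    a_pun = 0.5 * (1.0 + math.erf(theta[1] / math.sqrt(2.0)))
    return -_loglik_core(deck_idx, played, outcomes, a_rew, a_pun,
                         theta[2], theta[3], scale, fictive, atten)


@njit(cache=False)
def _negll_and_grad(deck_idx, played, outcomes, theta, scale, fictive, atten):
    """Objective with a central-difference gradient, fused in one jit call."""
    f0 = _negll_theta(deck_idx, played, outcomes, theta, scale, fictive, atten)
    grad = np.empty(4)
    for i in range(4):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        fp = _negll_theta(deck_idx, played, outcomes, tp, scale, fictive, atten)
        fm = _negll_theta(deck_idx, played, outcomes, tm, scale, fictive, atten)
        grad[i] = (fp - fm) / (2.0 * h)
    return f0, grad


def _make_objective(session: SessionLog, prior: GroupPosterior,
                    model_config: ModelConfig, with_grad: bool = False):
    deck_idx, played, outcomes = session_arrays(session)
    mu, sd = prior.means, prior.sds
    scale = model_config.outcome_scale
    fictive = model_config.fictive_updating
    atten = model_config.fictive_attenuation

    if with_grad:
        def neg_log_post_grad(theta: np.ndarray):
            f, g = _negll_and_grad(deck_idx, played, outcomes, theta,
                                   scale, fictive, atten)
            z = (theta - mu) / sd
            return f + 0.5 * float(np.sum(z**2)), g + z / sd

        return neg_log_post_grad

    def neg_log_post(theta: np.ndarray) -> float:
        a_rew = ndtr(theta[0])
        a_pun = ndtr(theta[1])
        ll = _loglik_core(deck_idx, played, outcomes, a_rew, a_pun,
                          theta[2], theta[3], scale, fictive, atten)
        lp = -0.5 * np.sum(((theta - mu) / sd) ** 2)
        return -(ll + lp)

    return neg_log_post


def _map_fit_theta(
    session: SessionLog,
    prior: GroupPosterior,
    fit_config: FitConfig,
    model_config: ModelConfig,
    warm_start: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Multi-start quasi-Newton MAP on the unconstrained scale."""
    obj = _make_objective(session, prior, model_config, with_grad=True)
    # start jitter keyed to session *content*, so identical data always gets
    # identical starts (exchangeability) while subjects still differ
    content = ",".join(f"{t.deck}{t.choice[0]}" for t in session.trials)
    rng = np.random.default_rng(fit_config.seed + zlib.crc32(content.encode()) % 10007)
    if warm_start is not None:
        starts = [warm_start]
    else:
        starts = [prior.means.copy()]
        jitter_sd = fit_config.start_jitter * np.minimum(prior.sds, 2.0)
        for _ in range(fit_config.n_starts - 1):
            starts.append(prior.means + rng.normal(0.0, jitter_sd))
    best = None
    best_ok = False
    for x0 in starts:
        res = minimize(obj, np.clip(x0, [b[0] for b in _BOUNDS],
                                    [b[1] for b in _BOUNDS]),
                       method="L-BFGS-B", bounds=_BOUNDS, jac=True,
                       options={"maxiter": 200, "ftol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
            best_ok = bool(res.success)
    return best.x, best_ok


def fit_subject_map(
    session: SessionLog,
    group_posterior: GroupPosterior | None = None,
    fit_config: FitConfig = FitConfig(),
    model_config: ModelConfig = ModelConfig(),
) -> SubjectEstimate:
    """MAP estimate of one subject's parameters under a group prior.

    With no group posterior supplied, a wide (effectively flat) prior is
    used, giving a lightly regularized maximum-likelihood estimate.
    Nonconvergence is flagged on the returned estimate, never silent.
    """
    if not session.trials:
        raise ValueError("cannot fit an empty session")
    prior = group_posterior or flat_prior()
    theta, ok = _map_fit_theta(session, prior, fit_config, model_config)
    return SubjectEstimate.from_theta(session.subject_id, session.wave, theta, ok)


def _likelihood_se2(session: SessionLog, theta: np.ndarray,
                    model_config: ModelConfig) -> np.ndarray:
    """Per-coordinate sampling variances from the *likelihood-only*
    curvature (diagonal Laplace) at an estimate.  Flat directions get a
    large but finite variance, so uninformative data is downweighted
    rather than discarded."""
    obj = _make_objective(session, flat_prior(1e6), model_config)
    f0 = obj(theta)
    var = np.empty(4)
    for i in range(4):
        h = 5e-3 * max(1.0, abs(theta[i]))
        e = np.zeros(4)
        e[i] = h
        hess = (obj(theta + e) - 2.0 * f0 + obj(theta - e)) / h**2
        var[i] = 1.0 / hess if hess > 2.5e-3 else 400.0
    return np.clip(var, 1e-4, 400.0)


def _marginal_ml_group(mles: np.ndarray, se2: np.ndarray,
                       tau_floor: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Random-effects deconvolution, one coordinate at a time.

    Treats flat-prior estimates as theta_i + noise with known variances
    se2_i and maximizes the marginal normal likelihood
    prod_i N(mle_i; mu, tau^2 + se2_i) over (mu, tau) with mu profiled out.
    """
    from scipy.optimize import minimize_scalar

    mu = np.empty(4)
    tau = np.empty(4)
    for k in range(4):
        x, v = mles[:, k], se2[:, k]

        def nll(log_tau):
            t2 = np.exp(2.0 * log_tau)
            w = 1.0 / (t2 + v)
            m = np.sum(w * x) / np.sum(w)
            return 0.5 * np.sum(np.log(t2 + v) + w * (x - m) ** 2)

        res = minimize_scalar(nll, bounds=(np.log(tau_floor), np.log(20.0)),
                              method="bounded",
                              options={"xatol": 1e-4})
        t2 = float(np.exp(2.0 * res.x))
        w = 1.0 / (t2 + v)
        mu[k] = float(np.sum(w * x) / np.sum(w))
        tau[k] = max(np.sqrt(t2), tau_floor)
    return mu, tau


def _mc_marginal_ml_group(
    sessions: list[SessionLog],
    mles: np.ndarray,
    se2: np.ndarray,
    init_mu: np.ndarray,
    init_sd: np.ndarray,
    model_config: ModelConfig,
    seed: int,
    n_draws: int = 256,
    tau_floor: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo marginal maximum likelihood for the group parameters.

    For each subject, parameter draws come from a defensive mixture of a
    local proposal (around the flat-prior estimate, curvature-scaled) and a
    population proposal (the deconvolution estimate), with the likelihood
    evaluated once per draw.  The group-level normal's mean and SD are then
    fit by maximizing the self-normalized importance-sampling estimate of
    the marginal likelihood — the same integral a full hierarchical sampler
    targets, so weakly identified subjects contribute their whole
    likelihood surface rather than a point estimate.
    """
    n = len(sessions)
    rng = np.random.default_rng(seed)
    loc_sd = np.sqrt(np.clip(se2, 0.04, 9.0)) * 1.5
    pop_sd = np.maximum(init_sd, 0.2) * 1.5
    half = n_draws // 2
    draws = np.empty((n, n_draws, 4))
    logq = np.empty((n, n_draws))
    loglik = np.empty((n, n_draws))
    for i, s in enumerate(sessions):
        m_i = np.clip(mles[i], [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS])
        local = m_i + rng.standard_normal((half, 4)) * loc_sd[i]
        pop = init_mu + rng.standard_normal((n_draws - half, 4)) * pop_sd
        th = np.vstack((local, pop))
        draws[i] = th
        # mixture density 0.5 local + 0.5 population
        lq_loc = -0.5 * np.sum(((th - m_i) / loc_sd[i]) ** 2, axis=1) \
            - np.sum(np.log(loc_sd[i]))
        lq_pop = -0.5 * np.sum(((th - init_mu) / pop_sd) ** 2, axis=1) \
            - np.sum(np.log(pop_sd))
        logq[i] = np.logaddexp(lq_loc, lq_pop) + math.log(0.5)
        deck_idx, played, outcomes = session_arrays(s)
        for j in range(n_draws):
            loglik[i, j] = -_negll_theta(
                deck_idx, played, outcomes, th[j],
                model_config.outcome_scale, model_config.fictive_updating,
                model_config.fictive_attenuation,
            )
    base = loglik - logq  # (n, S)

    def nll(pars):
        mu = pars[:4]
        sd = np.exp(pars[4:])
        lp = -0.5 * np.sum(((draws - mu) / sd) ** 2, axis=2) \
            - np.sum(np.log(sd))
        a = base + lp
        amax = a.max(axis=1, keepdims=True)
        return -float(np.sum(amax[:, 0] + np.log(
            np.exp(a - amax).mean(axis=1))))

    x0 = np.concatenate((init_mu, np.log(np.maximum(init_sd, tau_floor))))
    bounds = [(-4, 4)] * 2 + [(-15, 15)] * 2 + [(np.log(tau_floor), np.log(10.0))] * 4
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 300})
    mu = res.x[:4]
    sd = np.maximum(np.exp(res.x[4:]), tau_floor)
    return mu, sd


def fit_wave(
    sessions: list[SessionLog],
    fit_config: FitConfig = FitConfig(),
    model_config: ModelConfig = ModelConfig(),
) -> tuple[list[SubjectEstimate], GroupPosterior]:
    """Hierarchical fit of all subjects observed at one wave.

    The ``map_eb`` backend alternates subject-level estimation with group
    updates: subjects are first fit under an effectively flat prior (with
    likelihood-curvature standard errors), the group mean and SD of each
    unconstrained parameter are then estimated by marginal maximum
    likelihood (a random-effects deconvolution, so estimation noise does
    not inflate — nor iterative shrinkage collapse — the group SD), and
    subjects are refit by MAP under the resulting normal prior.  The loop
    repeats until group means move less than ``tolerance`` or
    ``max_iterations`` is reached.  ``mcmc`` refines the converged solution
    with per-subject ensemble sampling and returns posterior means in the
    same schema.
    """
    if len(sessions) < 2:
        raise ValueError("hierarchical fit needs >= 2 subjects; "
                         "use fit_subject_map for a single session")
    n = len(sessions)
    wide = flat_prior()
    mles = np.empty((n, 4))
    se2 = np.empty((n, 4))
    ok = np.ones(n, dtype=bool)
    for i, s in enumerate(sessions):
        mles[i], ok[i] = _map_fit_theta(s, wide, fit_config, model_config)
        se2[i] = _likelihood_se2(s, mles[i], model_config)

    init_mu, init_sd = _marginal_ml_group(mles, se2)
    mu, sd = _mc_marginal_ml_group(
        sessions, mles, se2, init_mu, init_sd, model_config, fit_config.seed
    )
    thetas = mles.copy()
    converged = False
    iteration = 0
    prior = GroupPosterior(mu, sd)
    for iteration in range(1, fit_config.max_iterations + 1):
        shift = 0.0
        for i, s in enumerate(sessions):
            theta_i, ok_i = _map_fit_theta(
                s, prior, fit_config, model_config, warm_start=thetas[i]
            )
            shift = max(shift, float(np.max(np.abs(theta_i - thetas[i]))))
            thetas[i] = theta_i
            ok[i] = ok[i] and ok_i
        if shift < fit_config.tolerance:
            converged = True
            break

    group = GroupPosterior(mu, sd, converged, iteration)
    if fit_config.backend == "mcmc":
        thetas, ok = _mcmc_refine(sessions, group, fit_config, model_config,
                                  thetas)
    estimates = [
        SubjectEstimate.from_theta(s.subject_id, s.wave, thetas[i], bool(ok[i]))
        for i, s in enumerate(sessions)
    ]
    return estimates, group


def _mcmc_refine(sessions, group, fit_config, model_config, map_thetas):
    """Per-subject posterior means via emcee under the group prior."""
    import emcee  # optional backend dependency

    thetas = np.empty_like(map_thetas)
    ok = np.ones(len(sessions), dtype=bool)
    rng = np.random.default_rng(fit_config.seed)
    for i, s in enumerate(sessions):
        obj = _make_objective(s, group, model_config)

        def log_post(theta):
            if np.any(theta < [b[0] for b in _BOUNDS]) or \
               np.any(theta > [b[1] for b in _BOUNDS]):
                return -np.inf
            return -obj(theta)

        p0 = map_thetas[i] + 0.05 * rng.standard_normal((fit_config.walkers, 4))
        sampler = emcee.EnsembleSampler(fit_config.walkers, 4, log_post)
        state = sampler.run_mcmc(p0, fit_config.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, fit_config.samples, progress=False)
        thetas[i] = sampler.get_chain(flat=True).mean(axis=0)
        ok[i] = np.all(sampler.acceptance_fraction > 0.05)
    return thetas, ok


# ---------------------------------------------------------------------------
# validation harnesses


@dataclass(frozen=True)
class GeneratorDistributions:
    """Group-level normal distributions of the unconstrained parameters.

    Defaults describe a plausible adolescent population for this task:
    low reward learning rates (probit mean -1.55, i.e. A_rew around 0.06),
    somewhat higher punishment learning rates, a broad positive spread of
    frequency sensitivity, and a positive go bias around 1.25.
    """

    means: tuple[float, float, float, float] = (-1.55, -0.9, 3.0, 1.25)
    sds: tuple[float, float, float, float] = (0.6, 0.6, 2.0, 0.8)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.means, self.sds, size=(n, 4))


def parameter_recovery(
    n_subjects: int = 100,
    generator_distributions: GeneratorDistributions = GeneratorDistributions(),
    task_config: TaskConfig | None = None,
    fit_config: FitConfig = FitConfig(),
    model_config: ModelConfig = ModelConfig(),
    seed: int = 0,
) -> dict:
    """Simulate-and-refit study: Pearson r between true and recovered values.

    Correlations are computed on the estimation (unconstrained) scale.
    Returns per-parameter r plus the true/recovered scatter arrays.
    """
    if n_subjects < 20:
        raise ValueError("parameter recovery needs >= 20 subjects")
    if any(s <= 0 for s in generator_distributions.sds):
        raise DegenerateGeneratorError(
            "between-subject SDs must be positive for recovery correlations"
        )
    task_config = task_config or default_task_config()
    rng = np.random.default_rng(seed)
    true_thetas = generator_distributions.sample(n_subjects, rng)
    sessions = []
    for i in range(n_subjects):
        params = theta_to_params(true_thetas[i])
        sessions.append(simulate_agent(
            params, task_config, model_config,
            seed=int(rng.integers(2**31)), subject_id=f"s{i:04d}",
        ))
    estimates, group = fit_wave(sessions, fit_config, model_config)
    rec = np.array([e.theta for e in estimates])
    correlations = {
        name: float(np.corrcoef(true_thetas[:, k], rec[:, k])[0, 1])
        for k, name in enumerate(PARAM_NAMES)
    }
    return {
        "correlations": correlations,
        "true": true_thetas,
        "recovered": rec,
        "group": group,
        "estimates": estimates,
        "sessions": sessions,
    }


def posterior_predictive_check(
    estimates: list[SubjectEstimate],
    sessions: list[SessionLog],
    model_config: ModelConfig = ModelConfig(),
    n_reps: int = 50,
    seed: int = 0,
    block_length: int = 30,
    task_config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Observed vs model-simulated play proportions per deck per trial block.

    For each subject, ``n_reps`` sessions are simulated at the subject's
    estimate on that subject's own deck schedule; per deck x block cells we
    report the observed mean play proportion across subjects, the simulated
    mean, and the simulated 95% interval over replicate datasets.
    """
    by_key = {(e.subject_id, e.wave): e for e in estimates}
    aligned = [(by_key[(s.subject_id, s.wave)], s) for s in sessions]
    task_config = task_config or default_task_config()
    wins, loss_add = _schedule_tables(task_config)
    rng = np.random.default_rng(seed)

    n_trials = len(sessions[0].trials)
    n_blocks = int(np.ceil(n_trials / block_length))
    blocks = np.arange(n_trials) // block_length
    obs_sum = np.zeros((4, n_blocks))
    cell_n = np.zeros((4, n_blocks))
    sim_props = np.zeros((n_reps, 4, n_blocks))
    sim_n = np.zeros((4, n_blocks))
    for est, sess in aligned:
        deck_idx, played, _ = session_arrays(sess)
        for j in range(4):
            for b in range(n_blocks):
                m = (deck_idx == j) & (blocks == b)
                k = int(m.sum())
                if k:
                    obs_sum[j, b] += played[m].sum() / k
                    cell_n[j, b] += 1
        for r in range(n_reps):
            choices, _ = _simulate_core(
                deck_idx, rng.random(n_trials),
                est.A_rew, est.A_pun, est.beta_f, est.beta_b,
                model_config.outcome_scale, model_config.fictive_updating,
                model_config.fictive_attenuation, wins, loss_add,
            )
            for j in range(4):
                for b in range(n_blocks):
                    m = (deck_idx == j) & (blocks == b)
                    k = int(m.sum())
                    if k:
                        sim_props[r, j, b] += choices[m].sum() / k
    sim_props /= max(len(aligned), 1)
    rows = []
    for j, deck in enumerate(DECK_INDEX):
        for b in range(n_blocks):
            if cell_n[j, b] == 0:
                continue
            dist = sim_props[:, j, b]
            rows.append({
                "deck": deck, "block": b + 1,
                "observed": obs_sum[j, b] / cell_n[j, b],
                "simulated_mean": float(dist.mean()),
                "simulated_lo": float(np.quantile(dist, 0.025)),
                "simulated_hi": float(np.quantile(dist, 0.975)),
            })
    return pd.DataFrame(rows)
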