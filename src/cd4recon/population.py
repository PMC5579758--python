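"""Mixed-effects layer of the reconstitution model.

Individual parameters are lognormal about covariate-adjusted typical values,

    param_i = theta * prod(1 + theta_cov) * exp(eta_i),   eta_i ~ MVN(0, Omega)

with a full 6x6 random-effect covariance Omega and an additive Gaussian
residual on log-transformed CD4 counts (variance sigma2).  Estimation uses a
Monte-Carlo (importance sampling) EM algorithm: the E-step evaluates each
subject's posterior moments of eta by self-normalized importance sampling
with a heavy-tailed proposal that adapts across iterations, and the M-step
updates typical values, covariate coefficients, Omega and sigma2 in closed
form from those moments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import gammaln, logsumexp

from . import _batch
from .kinetics import StructuralParameters
from .reference import AgeReferenceConstants, DEFAULT_CONSTANTS

__all__ = [
    "PARAM_NAMES",
    "PopulationParameters",
    "CovariateEffect",
    "SubjectRecord",
    "Dataset",
    "IndividualEstimate",
    "FitSettings",
    "FitResult",
    "individual_parameters",
    "observation_loglik",
    "marginal_neg2ll_is",
    "empirical_bayes",
    "evaluate_objective",
    "evaluate_objectives",
    "fit_population",
    "bootstrap_se",
]

log = logging.getLogger(__name__)

#: The six structural parameters that carry fixed and random effects.
PARAM_NAMES = ("lambda0", "d0", "p0", "x0", "lambda_h", "lambda_r")

_NP = len(PARAM_NAMES)


def nearest_psd(a: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    a = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(a)
    if w.min() >= floor:
        return a
    w = np.maximum(w, floor)
    return (v * w) @ v.T


@dataclass
class PopulationParameters:
    """Typical values, random-effect covariance and residual variance."""

    theta: np.ndarray
    omega: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, float)
        self.omega = np.asarray(self.omega, float)
        if self.theta.shape != (_NP,):
            raise ValueError(f"theta must have {_NP} entries {PARAM_NAMES}")
        if np.any(self.theta <= 0):
            raise ValueError("typical values must be strictly positive")
        if self.omega.shape != (_NP, _NP):
            raise ValueError("omega must be 6x6")
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        if np.linalg.eigvalsh(self.omega).min() < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    def theta_as_dict(self) -> dict:
        return dict(zip(PARAM_NAMES, self.theta.tolist()))


@dataclass(frozen=True)
class CovariateEffect:
    """Multiplicative covariate effect: typical value x (1 + value)."""

    covariate: str
    parameter: str
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not 1.0 + self.value > 0:
            raise ValueError("1 + effect size must stay positive")


@dataclass
class SubjectRecord:
    """One subject: age at transplant, covariate flags and observations."""

    subject_id: str
    age_at_hsct: float
    covariates: dict
    times: np.ndarray
    cd4: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.cd4 = np.asarray(self.cd4, float)
        if self.times.shape != self.cd4.shape:
            raise ValueError("times and cd4 must have equal length")
        if len(self.times) and (np.any(np.diff(self.times) < 0) or self.times[0] < 0):
            raise ValueError("observation times must be nondecreasing and >= 0")
        if np.any(self.cd4 <= 0):
            raise ValueError("CD4 concentrations must be strictly positive")
        if not self.age_at_hsct >= 0:
            raise ValueError("age_at_hsct must be non-negative")

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass
class Dataset:
    """A cohort of subjects plus the declared covariate column order."""

    subjects: list
    covariate_names: tuple = ()

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)


@dataclass
class IndividualEstimate:
    """Posterior summary of one subject's random effects (log scale)."""

    eta_mean: np.ndarray
    eta_cov: np.ndarray
    neg2ll: float
    proposal_fallback: bool = False

    def __post_init__(self) -> None:
        self.eta_mean = np.asarray(self.eta_mean, float)
        self.eta_cov = nearest_psd(np.asarray(self.eta_cov, float), floor=0.0)


@dataclass
class FitSettings:
    """Tuning knobs of the importance-sampling EM fitter.

    n_samples      -- importance samples per subject per E-step
    max_iter       -- EM iteration cap
    tol, streak    -- stop when |objective change| < tol for `streak`
                      consecutive iterations
    proposal_df    -- degrees of freedom of the multivariate-t proposal
    accelerate     -- quadratic (SQUAREM-style) extrapolation along the EM
                      path; plain EM steps when disabled
    omega_structure-- "full" (estimate the whole covariance) or "diagonal"
                      (variances only; off-diagonals forced to zero)
    """

    n_samples: int = 300
    max_iter: int = 200
    tol: float = 0.5
    streak: int = 5
    proposal_df: float = 3.0
    accelerate: bool = True
    omega_structure: str = "full"


@dataclass
class FitResult:
    pop: PopulationParameters
    effects: list
    objective: float
    trace: list
    converged: bool
    seed: int
    n_iter: int


# ---------------------------------------------------------------------------
# parameter assembly


def _effect_design(effects, subject) -> np.ndarray:
    """Additive log-scale shift of the typical values for one subject."""
    shift = np.zeros(_NP)
    for e in effects:
        flag = subject.covariates.get(e.covariate)
        if flag is None:
            raise KeyError(f"subject {subject.subject_id!r} lacks covariate {e.covariate!r}")
        if flag:
            shift[PARAM_NAMES.index(e.parameter)] += math.log1p(e.value)
    return shift


def individual_parameters(theta, effects, flags: dict, eta) -> StructuralParameters:
    """Assemble one individual's structural parameters.

    param_i = theta_i * prod(1 + theta_cov, active effects) * exp(eta_i),
    with the competition strengths cp = cd = 1 appended (fixed, never
    estimated).
    """
    if isinstance(theta, PopulationParameters):
        theta = theta.theta
    theta = np.asarray(theta, float)
    eta = np.asarray(eta, float)
    subject = SubjectRecord("_", 0.0, dict(flags), [], [])
    logp = np.log(theta) + _effect_design(effects, subject) + eta
    values = np.exp(logp)
    return StructuralParameters(**dict(zip(PARAM_NAMES, values)))


def observation_loglik(subject: SubjectRecord, params: StructuralParameters,
                       sigma2: float,
                       consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> float:
    """Gaussian log-density of the log CD4 counts about the model curve."""
    if subject.n_obs == 0:
        return 0.0
    arrays = {name: np.array([getattr(params, name)]) for name in _batch.PARAM_ORDER}
    pred = _batch.solve_blocks(arrays, [subject.age_at_hsct], [subject.times], [1],
                               consts)[0][:, 0]
    resid = np.log(subject.cd4) - np.log(pred)
    n = subject.n_obs
    return float(-0.5 * n * math.log(2.0 * math.pi * sigma2)
                 - 0.5 * np.sum(resid ** 2) / sigma2)


# ---------------------------------------------------------------------------
# importance sampling internals


def _mvt_rvs(mean, chol_lower, df, size, rng):
    z = rng.standard_normal((_NP, size))
    g = rng.chisquare(df, size) / df
    return mean[:, None] + (chol_lower @ z) / np.sqrt(g)[None, :]


def _mvt_logpdf(x, mean, chol_lower, df):
    dev = solve_triangular(chol_lower, x - mean[:, None], lower=True)
    quad = np.sum(dev ** 2, axis=0)
    logdet = np.sum(np.log(np.diag(chol_lower)))
    d = _NP
    return (gammaln(0.5 * (df + d)) - gammaln(0.5 * df)
            - 0.5 * d * math.log(df * math.pi) - logdet
            - 0.5 * (df + d) * np.log1p(quad / df))


def _mvn_logpdf(x, chol_lower):
    dev = solve_triangular(chol_lower, x, lower=True)
    quad = np.sum(dev ** 2, axis=0)
    logdet = np.sum(np.log(np.diag(chol_lower)))
    return -0.5 * quad - logdet - 0.5 * _NP * math.log(2.0 * math.pi)


def _truncate_logw(logw: np.ndarray) -> np.ndarray:
    """Truncated importance sampling: cap weights at sqrt(K) times the mean
    raw weight.  Bounds the variance contributed by a single draw (at a
    small, K-vanishing bias), which keeps objective evaluations stable for
    subjects whose posteriors sit in far tails of the random-effect prior."""
    K = logw.size
    cap = (logsumexp(logw) - math.log(K)) + 0.5 * math.log(K)
    return np.minimum(logw, cap)


def _safe_chol(a, jitter=1e-8):
    a = 0.5 * (a + a.T)
    for k in range(6):
        try:
            return cholesky(a + (jitter * 10 ** k) * np.eye(_NP), lower=True)
        except np.linalg.LinAlgError:
            continue
    return cholesky(nearest_psd(a, 1e-6) + 1e-6 * np.eye(_NP), lower=True)


def _loglik_batch(subject, log_mean, eta, sigma2, consts):
    """Log-likelihood of one subject's observations for K eta draws."""
    K = eta.shape[1]
    if subject.n_obs == 0:
        return np.zeros(K)
    logp = log_mean[:, None] + eta
    values = np.exp(logp)
    arrays = {name: values[i] for i, name in enumerate(PARAM_NAMES)}
    arrays["cp"] = np.ones(K)
    arrays["cd"] = np.ones(K)
    pred = _batch.solve_blocks(arrays, [subject.age_at_hsct], [subject.times], [K],
                               consts)[0]
    resid = np.log(subject.cd4)[:, None] - np.log(pred)
    n = subject.n_obs
    return (-0.5 * n * math.log(2.0 * math.pi * sigma2)
            - 0.5 * np.sum(resid ** 2, axis=0) / sigma2)


def _estep(dataset, log_theta, beta_shifts, omega, sigma2, proposals, K, df,
           rng, consts):
    """One importance-sampling pass over all subjects (batched ODE solves).

    proposals  -- per subject (mean, cov) of the t proposal on eta
    beta_shifts-- per subject additive log-scale covariate shift (6,)
    Returns per-subject contributions, posterior moments, residual moments.
    """
    S = len(dataset.subjects)
    omega_chol = _safe_chol(omega)
    etas, logq, logprior, chols = [], [], [], []
    for s, subject in enumerate(dataset.subjects):
        m, C = proposals[s]
        L = _safe_chol(C)
        eta = _mvt_rvs(m, L, df, K, rng)
        etas.append(eta)
        logq.append(_mvt_logpdf(eta, m, L, df))
        logprior.append(_mvn_logpdf(eta, omega_chol))
        chols.append(L)

    # one big batched solve across all subjects and samples
    values = []
    arrays = {name: [] for name in _batch.PARAM_ORDER}
    with_obs = [s for s in range(S) if dataset.subjects[s].n_obs > 0]
    for s in with_obs:
        logp = (log_theta + beta_shifts[s])[:, None] + etas[s]
        vals = np.exp(logp)
        for i, name in enumerate(PARAM_NAMES):
            arrays[name].append(vals[i])
        arrays["cp"].append(np.ones(K))
        arrays["cd"].append(np.ones(K))
    loglik = [np.zeros(K) for _ in range(S)]
    if with_obs:
        cat = {name: np.concatenate(arrays[name]) for name in _batch.PARAM_ORDER}
        preds = _batch.solve_blocks(
            cat,
            [dataset.subjects[s].age_at_hsct for s in with_obs],
            [dataset.subjects[s].times for s in with_obs],
            [K] * len(with_obs),
            consts,
        )
        for s, pred in zip(with_obs, preds):
            subject = dataset.subjects[s]
            resid = np.log(subject.cd4)[:, None] - np.log(pred)
            n = subject.n_obs
            loglik[s] = (-0.5 * n * math.log(2.0 * math.pi * sigma2)
                         - 0.5 * np.sum(resid ** 2, axis=0) / sigma2)

    contrib = np.empty(S)
    means = np.empty((S, _NP))
    covs = np.empty((S, _NP, _NP))
    r2 = np.empty(S)
    ess = np.empty(S)
    for s in range(S):
        logw = _truncate_logw(loglik[s] + logprior[s] - logq[s])
        a = logsumexp(logw)
        contrib[s] = -2.0 * (a - math.log(K))
        w = np.exp(logw - a)
        ess[s] = 1.0 / np.sum(w ** 2)
        m = etas[s] @ w
        dev = etas[s] - m[:, None]
        means[s] = m
        covs[s] = (dev * w) @ dev.T
        # weighted mean squared log residual, for the sigma2 update
        if dataset.subjects[s].n_obs:
            n = dataset.subjects[s].n_obs
            ss = -2.0 * (loglik[s] + 0.5 * n * math.log(2.0 * math.pi * sigma2)) * sigma2
            r2[s] = ss @ w
        else:
            r2[s] = 0.0
    return contrib, means, covs, r2, ess


def _gls_update(means, designs, omega):
    """Generalized least squares for the mean-shift (d_mu, d_beta).

    means[s] is the posterior mean deviation of subject s from the current
    mean structure; designs[s] maps the free coefficients onto the six log
    parameters.
    """
    S, E = len(means), designs[0].shape[1]
    oi = np.linalg.inv(nearest_psd(omega, 1e-8) + 1e-10 * np.eye(_NP))
    lhs = np.zeros((E, E))
    rhs = np.zeros(E)
    for s in range(S):
        A = designs[s]
        lhs += A.T @ oi @ A
        rhs += A.T @ oi @ means[s]
    return np.linalg.solve(lhs + 1e-12 * np.eye(E), rhs)


def fit_population(dataset: Dataset, init: PopulationParameters,
                   effects=(), settings: FitSettings | None = None,
                   seed: int = 0,
                   consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> FitResult:
    """Fit the population model by importance-sampling EM.

    ``effects`` lists the covariate-parameter pairs whose coefficients are
    estimated (their ``value`` fields are the initial guesses).  The E-step
    proposal for each subject is a multivariate t centered at the previous
    iteration's posterior moments (the prior on the first iteration); the
    M-step updates the log-typical values and covariate coefficients by
    generalized least squares, Omega from posterior second moments, and
    sigma2 from mean squared log residuals.
    """
    if len(dataset.subjects) < 2:
        raise ValueError("need at least 2 subjects to fit a population model")
    settings = settings or FitSettings()
    effects = [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
               for e in effects]
    rng = np.random.default_rng(seed)
    S = len(dataset.subjects)
    E = len(effects)
    n_obs_total = max(dataset.n_obs, 1)

    # per-subject design: columns = 6 mean shifts + E covariate coefficients
    designs = []
    for subject in dataset.subjects:
        A = np.zeros((_NP, _NP + E))
        A[:, :_NP] = np.eye(_NP)
        for j, e in enumerate(effects):
            if subject.covariates.get(e.covariate, 0):
                A[PARAM_NAMES.index(e.parameter), _NP + j] = 1.0
        designs.append(A)

    tril = np.tril_indices(_NP, -1)

    def pack(log_theta, beta, omega, sigma2):
        L = _safe_chol(omega)
        return np.concatenate([log_theta, beta, np.log(np.diag(L)),
                               L[tril], [math.log(sigma2)]])

    def unpack(psi):
        log_theta = psi[:_NP]
        beta = psi[_NP:_NP + E]
        L = np.zeros((_NP, _NP))
        np.fill_diagonal(L, np.exp(psi[_NP + E:2 * _NP + E]))
        L[tril] = psi[2 * _NP + E:-1]
        return log_theta, beta, L @ L.T, math.exp(psi[-1])

    def mean_structure(psi):
        log_theta, beta, _, _ = unpack(psi)
        coef = np.concatenate([log_theta, beta])
        return [designs[s] @ coef for s in range(S)]

    def shift_proposals(proposals, psi_from, psi_to):
        """Re-express proposal means relative to a new mean structure."""
        old = mean_structure(psi_from)
        new = mean_structure(psi_to)
        return [(m - (new[s] - old[s]), C)
                for s, (m, C) in enumerate(proposals)]

    def em_step(psi, proposals):
        """One importance-sampling E-step + closed-form M-step."""
        log_theta, beta, omega, sigma2 = unpack(psi)
        omega = nearest_psd(omega, 1e-6)
        shifts = [designs[s][:, _NP:] @ beta for s in range(S)]
        contrib, means, covs, r2, _ = _estep(
            dataset, log_theta, shifts, omega, sigma2, proposals,
            settings.n_samples, settings.proposal_df, rng, consts)
        objective = float(np.sum(contrib))
        delta = _gls_update(means, designs, omega)
        resid_means = [means[s] - designs[s] @ delta for s in range(S)]
        omega_new = np.zeros((_NP, _NP))
        for s in range(S):
            omega_new += covs[s] + np.outer(resid_means[s], resid_means[s])
        omega_new = omega_new / S
        if settings.omega_structure == "diagonal":
            omega_new = np.diag(np.diag(omega_new))
        psi_new = pack(log_theta + delta[:_NP], beta + delta[_NP:],
                       nearest_psd(omega_new, 1e-6),
                       max(float(np.sum(r2)) / n_obs_total, 1e-8))
        proposals_new = [(resid_means[s], nearest_psd(covs[s], 1e-6))
                         for s in range(S)]
        return psi_new, proposals_new, objective

    psi = pack(np.log(init.theta), np.array([math.log1p(e.value) for e in effects]),
               nearest_psd(init.omega, 1e-6), float(init.sigma2))
    proposals = [(np.zeros(_NP), nearest_psd(init.omega, 1e-6)) for _ in range(S)]
    # warm-up adaptation: one expectation-only pass so the first M-step sees
    # posterior moments from an adapted proposal rather than the raw prior
    log_theta, beta, omega, sigma2 = unpack(psi)
    _, m0, c0, _, _ = _estep(dataset, log_theta,
                             [designs[s][:, _NP:] @ beta for s in range(S)],
                             nearest_psd(omega, 1e-6), sigma2, proposals,
                             settings.n_samples, settings.proposal_df, rng,
                             consts)
    proposals = [(m0[s], nearest_psd(c0[s], 1e-6)) for s in range(S)]

    trace: list[float] = []
    converged = False
    run = 0

    def check(trace):
        nonlocal run, converged
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < settings.tol:
            run += 1
            if run >= settings.streak:
                converged = True
        else:
            run = 0

    while len(trace) < settings.max_iter and not converged:
        if settings.accelerate and settings.max_iter - len(trace) >= 3:
            # SQUAREM cycle: two EM steps, quadratic extrapolation along the
            # EM path, then one stabilizing EM step from the extrapolant.
            psi0, prop0 = psi, proposals
            psi1, prop1, obj0 = em_step(psi0, prop0)
            trace.append(obj0)
            check(trace)
            psi2, prop2, obj1 = em_step(psi1, prop1)
            trace.append(obj1)
            check(trace)
            if converged:
                psi, proposals = psi2, prop2
                break
            r = psi1 - psi0
            v = psi2 - 2.0 * psi1 + psi0
            nv = float(np.linalg.norm(v))
            if nv < 1e-12:
                psi, proposals = psi2, prop2
                continue
            alpha = -max(1.0, min(float(np.linalg.norm(r)) / nv, 16.0))
            psi_acc = psi0 - 2.0 * alpha * r + alpha * alpha * v
            prop_acc = shift_proposals(prop2, psi2, psi_acc)
            psi3, prop3, obj2 = em_step(psi_acc, prop_acc)
            if not np.isfinite(obj2) or obj2 > obj0 + 10.0 * settings.tol:
                # extrapolation overshot; keep the plain EM progress
                psi, proposals = psi2, prop2
                log.debug("SQUAREM step rejected (objective %.2f > %.2f)",
                          obj2, obj0)
                continue
            trace.append(obj2)
            check(trace)
            psi, proposals = psi3, prop3
        else:
            psi, proposals, objective = em_step(psi, proposals)
            trace.append(objective)
            check(trace)

    log_theta, beta, omega, sigma2 = unpack(psi)
    pop = PopulationParameters(np.exp(log_theta), nearest_psd(omega, 1e-8),
                               sigma2)
    fitted = [replace(e, value=float(np.expm1(b))) for e, b in zip(effects, beta)]
    return FitResult(pop, fitted, trace[-1], trace, converged, seed, len(trace))


def evaluate_objective(dataset: Dataset, pop: PopulationParameters,
                       effects=(), n_samples: int = 500, seed: int = 0,
                       consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> float:
    """-2 log marginal likelihood at fixed population parameters.

    A dedicated fixed-sample evaluation pass (never the EM trace): each
    subject's contribution comes from importance sampling with a proposal
    centered at that subject's posterior mode (see
    :func:`marginal_neg2ll_is`).  Each subject's random stream is derived
    from ``seed`` and the subject's position, so competing models are
    evaluated on common random numbers and likelihood-ratio differences are
    far more stable than the individual objectives.
    """
    effects = [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
               for e in effects]
    subjects = dataset.subjects
    children = np.random.SeedSequence([seed, 97]).spawn(max(len(subjects), 1))
    seeds = [int(ch.generate_state(1)[0] % (2 ** 31)) for ch in children]
    shifts = [_effect_design(effects, s) for s in subjects]
    out = _map_batch(subjects, pop, shifts, consts, max_iter=15)
    contribs, _, _ = _mixture_eval(subjects, pop, shifts, out["modes"],
                                   out["covs"], n_samples, seeds, consts)
    return float(np.sum(contribs))


def evaluate_objectives(dataset: Dataset, models, n_samples: int = 500,
                        seed: int = 0,
                        consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """-2 log marginal likelihoods of several models on shared draws.

    ``models`` is a sequence of (PopulationParameters, effects) pairs, the
    first being the reference model.  The integral is evaluated in
    log-parameter space, where nested covariate models differ only through
    the (lognormal) prior density: each subject's trajectories are solved
    ONCE for a shared set of log-parameter draws, and every model reweights
    the same likelihood values by its own prior.  Objective DIFFERENCES
    between the models are therefore far more precise than the objectives
    themselves, which is what likelihood-ratio testing needs.  The proposal
    is a defensive mixture over the reference model's posterior mode and
    every model's prior.  Returns a list with one total per model.
    """
    models = [(pop, [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
                     for e in effects]) for pop, effects in models]
    subjects = dataset.subjects
    S = len(subjects)
    M = len(models)
    children = np.random.SeedSequence([seed, 97]).spawn(max(S, 1))
    seeds = [int(ch.generate_state(1)[0] % (2 ** 31)) for ch in children]

    ref_pop, ref_effects = models[0]
    ref_shifts = [_effect_design(ref_effects, s) for s in subjects]
    mapfit = _map_batch(subjects, ref_pop, ref_shifts, consts, max_iter=15)

    # per-model prior means (log-parameter scale) and covariance factors
    means = [[np.log(pop.theta) + _effect_design(effects, subj)
              for subj in subjects] for pop, effects in models]
    omega_chols = [_safe_chol(pop.omega) for pop, _ in models]

    # mixture proposal per subject: reference posterior + every model's prior
    w_mode = 0.85
    w_prior = (1.0 - w_mode) / M
    n_mode = max(n_samples - M * max(int(round(w_prior * n_samples)), 1), M)
    n_each_prior = (n_samples - n_mode) // M
    n_mode = n_samples - M * n_each_prior

    us, logqs = [], []
    for s in range(S):
        rng = np.random.default_rng(seeds[s])
        u_mode = means[0][s] + mapfit["modes"][s]
        L = _safe_chol(1.5 * mapfit["covs"][s])
        pieces = [_mvt_rvs(u_mode, L, 3.0, n_mode, rng)]
        for m in range(M):
            pieces.append(_mvt_rvs(means[m][s], omega_chols[m], 3.0,
                                   n_each_prior, rng))
        u = np.concatenate(pieces, axis=1)
        comps = [math.log(n_mode / n_samples) + _mvt_logpdf(u, u_mode, L, 3.0)]
        for m in range(M):
            comps.append(math.log(n_each_prior / n_samples)
                         + _mvt_logpdf(u, means[m][s], omega_chols[m], 3.0))
        logqs.append(logsumexp(np.stack(comps), axis=0))
        us.append(u)

    # one batched likelihood solve shared by all models
    with_obs = [s for s in range(S) if subjects[s].n_obs > 0]
    loglik = [np.zeros(n_samples) for _ in range(S)]
    sigma2_ref = models[0][0].sigma2
    if with_obs:
        arrays = {name: [] for name in _batch.PARAM_ORDER}
        for s in with_obs:
            values = np.exp(us[s])
            for i, name in enumerate(PARAM_NAMES):
                arrays[name].append(values[i])
            arrays["cp"].append(np.ones(n_samples))
            arrays["cd"].append(np.ones(n_samples))
        cat = {name: np.concatenate(arrays[name]) for name in _batch.PARAM_ORDER}
        preds = _batch.solve_blocks(
            cat, [subjects[s].age_at_hsct for s in with_obs],
            [subjects[s].times for s in with_obs],
            [n_samples] * len(with_obs), consts)
        rss = [None] * S
        for s, pred in zip(with_obs, preds):
            resid = np.log(subjects[s].cd4)[:, None] - np.log(pred)
            rss[s] = np.sum(resid ** 2, axis=0)

    totals = []
    for m, (pop, effects) in enumerate(models):
        total = 0.0
        for s in range(S):
            n = subjects[s].n_obs
            if n:
                ll = (-0.5 * n * math.log(2.0 * math.pi * pop.sigma2)
                      - 0.5 * rss[s] / pop.sigma2)
            else:
                ll = 0.0
            logprior = _mvn_logpdf(us[s] - means[m][s][:, None], omega_chols[m])
            logw = _truncate_logw(ll + logprior - logqs[s])
            total += -2.0 * (logsumexp(logw) - math.log(n_samples))
        totals.append(float(total))
    return totals


# ---------------------------------------------------------------------------
# single-subject machinery


def _map_estimate(subject, pop, shift, consts, max_iter: int = 60,
                  fd_step: float = 1e-4):
    """Posterior mode of eta and its Gauss-Newton curvature.

    Thin wrapper over :func:`_map_batch` for a single subject.  Returns
    (mode, covariance = inverse Gauss-Newton Hessian, fallback flag).
    """
    out = _map_batch([subject], pop, [shift], consts, max_iter=max_iter,
                     fd_step=fd_step)
    return out["modes"][0], out["covs"][0], out["fallback"][0]


def _map_batch(subjects, pop, shifts, consts, max_iter: int = 25,
               fd_step: float = 1e-4, tol: float = 1e-4):
    """Posterior modes of eta for many subjects simultaneously.

    Damped Gauss-Newton on the penalized log-scale least-squares problem.
    Every iteration evaluates all active subjects' trajectories (and their 6
    forward perturbations) in one batched solve, which is what makes
    whole-dataset objective evaluation affordable.  Returns modes,
    Gauss-Newton covariances, log-prediction Jacobians at the mode and
    per-subject fallback flags (degenerate curvature -> prior covariance).
    """
    S = len(subjects)
    omega_chol = _safe_chol(pop.omega)
    prior_rows = solve_triangular(omega_chol, np.eye(_NP), lower=True)
    sigma = math.sqrt(pop.sigma2)
    log_means = [np.log(pop.theta) + shifts[s] for s in range(S)]
    with_obs = [s for s in range(S) if subjects[s].n_obs > 0]

    def predict(cols):
        """cols: {s: (6, k)} -> {s: (n_obs_s, k) log-predictions}."""
        order = sorted(cols)
        arrays = {name: [] for name in _batch.PARAM_ORDER}
        for s in order:
            values = np.exp(log_means[s][:, None] + cols[s])
            for i, name in enumerate(PARAM_NAMES):
                arrays[name].append(values[i])
            k = cols[s].shape[1]
            arrays["cp"].append(np.ones(k))
            arrays["cd"].append(np.ones(k))
        cat = {name: np.concatenate(arrays[name]) for name in _batch.PARAM_ORDER}
        preds = _batch.solve_blocks(
            cat, [subjects[s].age_at_hsct for s in order],
            [subjects[s].times for s in order],
            [cols[s].shape[1] for s in order], consts)
        return {s: np.log(p) for s, p in zip(order, preds)}

    def cost_of(s, eta_s, f_s):
        data = (np.log(subjects[s].cd4) - f_s) / sigma
        prior = prior_rows @ eta_s
        return 0.5 * (data @ data + prior @ prior)

    eta = np.zeros((S, _NP))
    damp = np.full(S, 1e-3)
    cost = np.zeros(S)
    if with_obs:
        f0 = predict({s: eta[s][:, None] for s in with_obs})
        for s in with_obs:
            cost[s] = cost_of(s, eta[s], f0[s][:, 0])
    active = set(with_obs)
    for _ in range(max_iter):
        if not active:
            break
        eye_cols = fd_step * np.eye(_NP)
        fs = predict({s: np.concatenate([eta[s][:, None],
                                         eta[s][:, None] + eye_cols], axis=1)
                      for s in active})
        trial, deltas = {}, {}
        for s in active:
            f = fs[s]
            G = (f[:, 1:] - f[:, :1]) / fd_step
            J = np.concatenate([-G / sigma, prior_rows])
            res = np.concatenate([(np.log(subjects[s].cd4) - f[:, 0]) / sigma,
                                  prior_rows @ eta[s]])
            Hs = J.T @ J
            g = J.T @ res
            try:
                delta = np.linalg.solve(Hs + damp[s] * np.diag(np.diag(Hs)), -g)
            except np.linalg.LinAlgError:
                delta = -g / (np.diag(Hs) + damp[s] + 1e-12)
            trial[s] = (eta[s] + delta)[:, None]
            deltas[s] = delta
        ft = predict(trial)
        for s in list(active):
            eta_try = trial[s][:, 0]
            cost_try = cost_of(s, eta_try, ft[s][:, 0])
            if np.isfinite(cost_try) and cost_try <= cost[s]:
                eta[s], cost[s] = eta_try, cost_try
                damp[s] = max(damp[s] / 10.0, 1e-7)
                if np.max(np.abs(deltas[s])) < tol:
                    active.discard(s)
            else:
                damp[s] *= 10.0
                if damp[s] > 1e7:
                    active.discard(s)

    # final curvature pass at the modes
    modes = eta
    covs = np.tile(nearest_psd(pop.omega, 1e-10), (S, 1, 1))
    jacobians = [None] * S
    logpreds = [None] * S
    fallback = np.zeros(S, dtype=bool)
    if with_obs:
        eye_cols = fd_step * np.eye(_NP)
        fs = predict({s: np.concatenate([eta[s][:, None],
                                         eta[s][:, None] + eye_cols], axis=1)
                      for s in with_obs})
        for s in with_obs:
            f = fs[s]
            G = (f[:, 1:] - f[:, :1]) / fd_step
            jacobians[s] = G
            logpreds[s] = f[:, 0]
            J = np.concatenate([-G / sigma, prior_rows])
            Hs = J.T @ J
            try:
                cov = np.linalg.inv(Hs)
                if not np.all(np.isfinite(cov)) or np.linalg.cond(Hs) > 1e10:
                    raise np.linalg.LinAlgError
                covs[s] = nearest_psd(cov, 1e-10)
            except np.linalg.LinAlgError:
                fallback[s] = True
                log.warning("degenerate curvature for subject %s; prior "
                            "covariance used as proposal",
                            subjects[s].subject_id)
    return {"modes": modes, "covs": covs, "jacobians": jacobians,
            "logpreds": logpreds, "fallback": fallback}


def _mixture_eval(subjects, pop, shifts, modes, covs, n_samples, seeds, consts):
    """Batched defensive-mixture importance sampling at fixed parameters.

    For each subject, draws 90% of the samples from an inflated t(3) about
    the posterior mode and 10% from a prior-shaped t(3); all trajectory
    solves go through one batched call.  Returns per-subject -2 log marginal
    contributions and self-normalized posterior moments.
    """
    S = len(subjects)
    L0 = _safe_chol(pop.omega)
    zero = np.zeros(_NP)
    n_prior = max(int(round(0.1 * n_samples)), 1)
    w_mode = math.log(1.0 - n_prior / n_samples)
    w_prior = math.log(n_prior / n_samples)

    etas, logqs, logpriors = [], [], []
    for s in range(S):
        rng = np.random.default_rng(seeds[s])
        L = _safe_chol(1.5 * covs[s])
        eta = np.concatenate([
            _mvt_rvs(modes[s], L, 3.0, n_samples - n_prior, rng),
            _mvt_rvs(zero, L0, 3.0, n_prior, rng),
        ], axis=1)
        logq = np.logaddexp(
            w_mode + _mvt_logpdf(eta, modes[s], L, 3.0),
            w_prior + _mvt_logpdf(eta, zero, L0, 3.0))
        etas.append(eta)
        logqs.append(logq)
        logpriors.append(_mvn_logpdf(eta, L0))

    with_obs = [s for s in range(S) if subjects[s].n_obs > 0]
    loglik = [np.zeros(n_samples) for _ in range(S)]
    if with_obs:
        arrays = {name: [] for name in _batch.PARAM_ORDER}
        for s in with_obs:
            log_mean = np.log(pop.theta) + shifts[s]
            values = np.exp(log_mean[:, None] + etas[s])
            for i, name in enumerate(PARAM_NAMES):
                arrays[name].append(values[i])
            arrays["cp"].append(np.ones(n_samples))
            arrays["cd"].append(np.ones(n_samples))
        cat = {name: np.concatenate(arrays[name]) for name in _batch.PARAM_ORDER}
        preds = _batch.solve_blocks(
            cat, [subjects[s].age_at_hsct for s in with_obs],
            [subjects[s].times for s in with_obs],
            [n_samples] * len(with_obs), consts)
        for s, pred in zip(with_obs, preds):
            subject = subjects[s]
            resid = np.log(subject.cd4)[:, None] - np.log(pred)
            loglik[s] = (-0.5 * subject.n_obs * math.log(2.0 * math.pi * pop.sigma2)
                         - 0.5 * np.sum(resid ** 2, axis=0) / pop.sigma2)

    contribs = np.empty(S)
    post_means = np.empty((S, _NP))
    post_covs = np.empty((S, _NP, _NP))
    for s in range(S):
        logw = _truncate_logw(loglik[s] + logpriors[s] - logqs[s])
        a = logsumexp(logw)
        contribs[s] = -2.0 * (a - math.log(n_samples))
        w = np.exp(logw - a)
        m = etas[s] @ w
        dev = etas[s] - m[:, None]
        post_means[s] = m
        post_covs[s] = (dev * w) @ dev.T
    return contribs, post_means, post_covs


def marginal_neg2ll_is(subject: SubjectRecord, pop: PopulationParameters,
                       effects=(), n_samples: int = 300, seed: int = 0,
                       consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Importance-sampling estimate of a subject's -2 log marginal likelihood.

    The proposal is a multivariate t (3 df) centered at the posterior mode
    with spread from the mode's Gauss-Newton curvature; if the curvature is
    degenerate the prior covariance is used instead and the result is
    flagged.  Also returns the self-normalized posterior mean and covariance
    of the random effects.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    effects = [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
               for e in effects]
    if subject.n_obs == 0:
        return 0.0, IndividualEstimate(np.zeros(_NP), pop.omega.copy(), 0.0)
    shift = _effect_design(effects, subject)
    out = _map_batch([subject], pop, [shift], consts)
    contribs, means, covs = _mixture_eval(
        [subject], pop, [shift], out["modes"], out["covs"], n_samples, [seed],
        consts)
    est = IndividualEstimate(means[0], covs[0], float(contribs[0]),
                             bool(out["fallback"][0]))
    return float(contribs[0]), est


def empirical_bayes(subject: SubjectRecord, pop: PopulationParameters,
                    effects=(), n_samples: int = 300, seed: int = 0,
                    consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> IndividualEstimate:
    """Posterior moments of one subject's random effects at fixed population
    parameters (expectation-only importance sampling; no population update)."""
    _, est = marginal_neg2ll_is(subject, pop, effects, n_samples, seed, consts)
    return est


def bootstrap_se(dataset: Dataset, pop: PopulationParameters, effects=(),
                 n_boot: int = 200, seed: int = 0,
                 settings: FitSettings | None = None,
                 consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> dict:
    """Nonparametric bootstrap standard errors by subject resampling.

    Each replicate resamples subjects with replacement and refits with a
    reduced iteration budget, warm-started at the point estimates.
    Replicates failing numerically are dropped and counted.  Returns SDs
    across replicates for theta, the covariate effects, Omega and sigma2.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    settings = settings or FitSettings(n_samples=100, max_iter=10, streak=3)
    rng = np.random.default_rng(seed)
    thetas, betas, omegas, sigmas = [], [], [], []
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, len(dataset.subjects), len(dataset.subjects))
        subjects = [replace(dataset.subjects[i],
                            subject_id=f"{dataset.subjects[i].subject_id}#{k}")
                    for k, i in enumerate(idx)]
        rep = Dataset(subjects, dataset.covariate_names)
        try:
            fit = fit_population(rep, pop, effects, settings,
                                 seed=int(rng.integers(2 ** 31)), consts=consts)
            if not np.isfinite(fit.objective):
                raise RuntimeError("non-finite objective")
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            failures += 1
            log.warning("bootstrap replicate %d dropped: %s", b, exc)
            continue
        thetas.append(fit.pop.theta)
        betas.append([e.value for e in fit.effects])
        omegas.append(fit.pop.omega)
        sigmas.append(fit.pop.sigma2)
    if len(thetas) < 2:
        raise RuntimeError("too few successful bootstrap replicates")
    return {
        "theta_se": np.std(np.array(thetas), axis=0, ddof=1),
        "effect_se": np.std(np.array(betas), axis=0, ddof=1) if effects else np.array([]),
        "omega_se": np.std(np.array(omegas), axis=0, ddof=1),
        "sigma2_se": float(np.std(sigmas, ddof=1)),
        "n_failed": failures,
        "n_used": len(thetas),
    }
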