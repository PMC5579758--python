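"""Goodness-of-fit machinery: conditional weighted residuals and the VPC.

CWRES are computed by linearizing the log-scale model about each subject's
conditional (posterior-mode) random-effect estimate and whitening the
per-subject residual vector with the implied first-order covariance
G Omega G' + sigma2 I.  Under the true model they are approximately standard
normal and independent of time.  The visual predictive check simulates many
replicate datasets at the observed design and compares the observed median
and outer percentiles per time bin with their simulation distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from . import _batch
from .population import (
    PARAM_NAMES,
    CovariateEffect,
    Dataset,
    PopulationParameters,
    _effect_design,
    _map_batch,
)
from .reference import AgeReferenceConstants, DEFAULT_CONSTANTS

__all__ = ["cwres", "vpc", "VPCResult"]

log = logging.getLogger(__name__)

_NP = len(PARAM_NAMES)


def cwres(dataset: Dataset, pop: PopulationParameters, effects=(),
          consts: AgeReferenceConstants = DEFAULT_CONSTANTS,
          fd_step: float = 1e-4):
    """Conditional weighted residuals for every observation.

    Returns a flat array ordered as the observations appear in the dataset.
    Singular per-subject covariances are ridge-stabilized and logged.
    """
    effects = [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
               for e in effects]
    subjects = [s for s in dataset.subjects if s.n_obs > 0]
    shifts = [_effect_design(effects, s) for s in subjects]
    fit = _map_batch(subjects, pop, shifts, consts, fd_step=fd_step)
    out = []
    for s, subject in enumerate(subjects):
        eta_hat = fit["modes"][s]
        G = fit["jacobians"][s]
        f0 = fit["logpreds"][s]
        cov = G @ pop.omega @ G.T + pop.sigma2 * np.eye(subject.n_obs)
        try:
            L = cholesky(cov, lower=True)
        except np.linalg.LinAlgError:
            log.warning("singular residual covariance for subject %s; "
                        "ridge added", subject.subject_id)
            L = cholesky(cov + 1e-6 * np.eye(subject.n_obs), lower=True)
        mean = f0 - G @ eta_hat  # first-order population prediction at eta=0
        res = np.log(subject.cd4) - mean
        out.append(solve_triangular(L, res, lower=True))
    return np.concatenate(out) if out else np.array([])


@dataclass
class VPCResult:
    """Binned observed statistics with simulated confidence bands."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: dict    # {"median": ..., "p2.5": ..., "p97.5": ...} per bin
    sim_lower: dict   # 2.5% of each statistic across replicates
    sim_upper: dict   # 97.5% of each statistic across replicates
    n_replicates: int
    seed: int

    def to_frame(self):
        import pandas as pd

        data = {"bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
                "bin_mid": self.bin_mid}
        for key in self.observed:
            data[f"obs_{key}"] = self.observed[key]
            data[f"sim_lo_{key}"] = self.sim_lower[key]
            data[f"sim_hi_{key}"] = self.sim_upper[key]
        return pd.DataFrame(data)


def vpc(dataset: Dataset, pop: PopulationParameters, effects=(),
        n_replicates: int = 600, bins: int = 8, seed: int = 0,
        include_parameter_uncertainty: bool = False, theta_cov=None,
        consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> VPCResult:
    """Visual predictive check at the observed design.

    Simulates ``n_replicates`` datasets with the subjects' ages, covariates
    and sampling times, then compares the observed median and 2.5/97.5
    percentiles per time bin with the 95% range of the same statistics
    across replicates.  By default only inter-individual variability and
    residual error are simulated; ``include_parameter_uncertainty`` adds a
    draw of the typical values from ``theta_cov`` per replicate.  Bins are
    quantile-spaced in time and bins with fewer than 5 observations are
    merged with a neighbour (logged).
    """
    effects = [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
               for e in effects]
    subjects = [s for s in dataset.subjects if s.n_obs > 0]
    all_times = np.concatenate([s.times for s in subjects])
    all_obs = np.concatenate([s.cd4 for s in subjects])

    edges = np.unique(np.quantile(all_times, np.linspace(0, 1, bins + 1)))
    edges[0] -= 1e-9
    which = np.searchsorted(edges, all_times, side="right") - 1
    which = np.clip(which, 0, len(edges) - 2)
    # merge under-filled bins with their left neighbour
    counts = np.bincount(which, minlength=len(edges) - 1)
    while len(edges) > 2 and counts.min() < 5:
        j = int(np.argmin(counts))
        drop = j if j > 0 else 1
        log.info("VPC bin %d under-filled (%d obs); merged", j, counts.min())
        edges = np.delete(edges, drop)
        which = np.clip(np.searchsorted(edges, all_times, side="right") - 1,
                        0, len(edges) - 2)
        counts = np.bincount(which, minlength=len(edges) - 1)

    ss = np.random.SeedSequence([seed, 67])
    rng_eta, rng_eps, rng_theta = (np.random.default_rng(s) for s in ss.spawn(3))
    S = len(subjects)
    R = n_replicates

    # one batched solve: block = subject, columns = replicates
    eta = rng_eta.multivariate_normal(np.zeros(_NP), pop.omega, (S, R),
                                      method="eigh")  # (S, R, 6)
    log_theta = np.log(pop.theta)
    if include_parameter_uncertainty:
        if theta_cov is None:
            raise ValueError("theta_cov required for parameter uncertainty")
        draws = rng_theta.multivariate_normal(log_theta, np.asarray(theta_cov),
                                              R, method="eigh")  # (R, 6)
    arrays = {name: [] for name in _batch.PARAM_ORDER}
    for s, subject in enumerate(subjects):
        shift = _effect_design(effects, subject)
        base = (draws if include_parameter_uncertainty else log_theta[None, :])
        logp = base + shift[None, :] + eta[s]  # (R, 6)
        vals = np.exp(logp).T
        for i, name in enumerate(PARAM_NAMES):
            arrays[name].append(vals[i])
        arrays["cp"].append(np.ones(R))
        arrays["cd"].append(np.ones(R))
    cat = {name: np.concatenate(arrays[name]) for name in _batch.PARAM_ORDER}
    preds = _batch.solve_blocks(cat, [s.age_at_hsct for s in subjects],
                                [s.times for s in subjects], [R] * S, consts)
    sim = np.concatenate(preds, axis=0)  # (n_obs_total, R)
    eps = rng_eps.normal(0.0, np.sqrt(pop.sigma2), sim.shape)
    sim = np.exp(np.log(sim) + eps)

    stats = ("median", "p2.5", "p97.5")
    qs = {"median": 50.0, "p2.5": 2.5, "p97.5": 97.5}
    n_bins = len(edges) - 1
    observed = {k: np.empty(n_bins) for k in stats}
    sim_lower = {k: np.empty(n_bins) for k in stats}
    sim_upper = {k: np.empty(n_bins) for k in stats}
    for b in range(n_bins):
        mask = which == b
        for k in stats:
            observed[k][b] = np.percentile(all_obs[mask], qs[k])
            rep_stat = np.percentile(sim[mask], qs[k], axis=0)
            sim_lower[k][b] = np.percentile(rep_stat, 2.5)
            sim_upper[k][b] = np.percentile(rep_stat, 97.5)
    mid = 0.5 * (edges[:-1] + edges[1:])
    return VPCResult(edges, mid, observed, sim_lower, sim_upper, R, seed)
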