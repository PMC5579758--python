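"""Stepwise covariate model building by likelihood-ratio testing.

Dichotomous covariates enter the model as multiplicative shifts of a typical
parameter value, typical x (1 + theta_cov), one degree of freedom each.
The forward search adds, one at a time, the candidate with the smallest
likelihood-ratio p-value below the inclusion threshold (default P < 0.01);
backward elimination then removes effects whose deletion is not significant
at the stricter threshold (default P < 0.005).  Objective values for the
tests come from a dedicated fixed-sample evaluation pass with common random
numbers so that Monte-Carlo noise is far below the test statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .population import (
    CovariateEffect,
    Dataset,
    FitResult,
    FitSettings,
    PopulationParameters,
    evaluate_objectives,
    fit_population,
)
from .reference import AgeReferenceConstants, DEFAULT_CONSTANTS

__all__ = ["SCMStep", "SCMResult", "lrt_pvalue", "scm"]

log = logging.getLogger(__name__)


def lrt_pvalue(delta_objective: float, df: int) -> float:
    """Upper-tail chi-square probability of a -2 log-likelihood difference.

    Negative differences (the larger model fits worse, possible only through
    Monte-Carlo noise) give p = 1.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    if delta_objective <= 0:
        return 1.0
    return float(chi2.sf(delta_objective, df))


@dataclass(frozen=True)
class SCMStep:
    phase: str  # "forward" | "backward"
    covariate: str
    parameter: str
    delta_objective: float
    df: int
    p_value: float
    accepted: bool


@dataclass
class SCMResult:
    steps: list
    effects: list
    fit: FitResult

    def step_table(self):
        import pandas as pd

        return pd.DataFrame([vars(s) for s in self.steps])


def scm(dataset: Dataset, candidates, init: PopulationParameters,
        forward_alpha: float = 0.01, backward_alpha: float = 0.005,
        settings: FitSettings | None = None, eval_samples: int = 500,
        seed: int = 0,
        consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> SCMResult:
    """Forward-inclusion / backward-elimination covariate search.

    ``candidates`` is a sequence of (covariate, parameter) pairs.  Ties in
    p-value are broken by larger objective drop, then lexicographically.
    Candidate fits that fail numerically are skipped for that round and
    logged.  All fits and objective evaluations share one seed so the
    likelihood-ratio differences are computed on common random numbers.
    """
    settings = settings or FitSettings()
    candidates = [tuple(c) for c in candidates]
    steps: list[SCMStep] = []

    current_fit = fit_population(dataset, init, [], settings, seed=seed,
                                 consts=consts)
    current: list[CovariateEffect] = []
    current_obj = float("nan")
    remaining = list(candidates)

    while remaining:
        # refit the current model and every candidate from the SAME starting
        # point with the same budget, so the likelihood-ratio differences
        # measure the covariate rather than extra convergence of the shared
        # parameters; then evaluate all the round's models on shared
        # importance-sampling draws so the Monte-Carlo noise cancels in the
        # differences
        start_pop = current_fit.pop
        current_fit = fit_population(dataset, start_pop, current, settings,
                                     seed=seed, consts=consts)
        current = list(current_fit.effects)
        fits, pairs = [], []
        for cov, par in remaining:
            trial = current + [CovariateEffect(cov, par)]
            try:
                fits.append(fit_population(dataset, start_pop, trial, settings,
                                           seed=seed, consts=consts))
                pairs.append((cov, par))
            except Exception as exc:  # noqa: BLE001 - skip failed candidates
                log.warning("forward candidate %s on %s skipped: %s", cov, par, exc)
        if not fits:
            break
        objs = evaluate_objectives(
            dataset,
            [(current_fit.pop, current)] + [(f.pop, f.effects) for f in fits],
            n_samples=eval_samples, seed=seed, consts=consts)
        current_obj = objs[0]
        results = []
        for (cov, par), fit, obj in zip(pairs, fits, objs[1:]):
            delta = current_obj - obj
            results.append(((cov, par), fit, obj, delta, lrt_pvalue(delta, 1)))
        results.sort(key=lambda r: (r[4], -r[3], r[0]))
        (cov, par), fit, obj, delta, p = results[0]
        accepted = p < forward_alpha
        for (c, pr), _f, _o, d, pv in results[1:]:
            steps.append(SCMStep("forward", c, pr, d, 1, pv, False))
        steps.append(SCMStep("forward", cov, par, delta, 1, p, accepted))
        if not accepted:
            break
        current = [e for e in fit.effects]
        current_fit, current_obj = fit, obj
        remaining.remove((cov, par))

    # backward elimination at the stricter threshold
    while current:
        start_pop = current_fit.pop
        current_fit = fit_population(dataset, start_pop, current, settings,
                                     seed=seed, consts=consts)
        current = list(current_fit.effects)
        fits, dropped = [], []
        for e in current:
            reduced = [x for x in current if x is not e]
            try:
                fits.append(fit_population(dataset, start_pop, reduced,
                                           settings, seed=seed, consts=consts))
                dropped.append(e)
            except Exception as exc:  # noqa: BLE001
                log.warning("backward removal of %s on %s skipped: %s",
                            e.covariate, e.parameter, exc)
        if not fits:
            break
        objs = evaluate_objectives(
            dataset,
            [(current_fit.pop, current)] + [(f.pop, f.effects) for f in fits],
            n_samples=eval_samples, seed=seed, consts=consts)
        current_obj = objs[0]
        results = []
        for e, fit, obj in zip(dropped, fits, objs[1:]):
            delta = obj - current_obj  # loss of fit when the effect is removed
            results.append((e, fit, obj, delta, lrt_pvalue(delta, 1)))
        # least significant effect = largest removal p-value
        results.sort(key=lambda r: (-r[4], r[3], (r[0].covariate, r[0].parameter)))
        e, fit, obj, delta, p = results[0]
        keep = p < backward_alpha
        steps.append(SCMStep("backward", e.covariate, e.parameter, delta, 1, p,
                             not keep))
        if keep:
            break
        current = [x for x in fit.effects]
        current_fit, current_obj = fit, obj

    return SCMResult(steps, current, current_fit)
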