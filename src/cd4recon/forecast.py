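"""Bayesian forecasting of an individual's long-term reconstitution.

Given fitted population parameters and a subject's observations from the
first months after transplant, the posterior of the subject's random effects
is summarized by empirical Bayes; sampling parameter sets from that
posterior (on the log scale, so parameters stay positive) and solving one
trajectory per draw yields a median predicted curve with a 90% band
(5th-95th pointwise percentiles).  A prediction is classified "good" when
strictly more than 75% of the held-out observations fall inside the band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _batch
from .population import (
    PARAM_NAMES,
    CovariateEffect,
    Dataset,
    PopulationParameters,
    SubjectRecord,
    _effect_design,
    _map_batch,
    _mixture_eval,
)
from .reference import AgeReferenceConstants, DEFAULT_CONSTANTS

__all__ = ["TrajectoryPrediction", "forecast", "forecast_cohort",
           "classify_prediction"]

log = logging.getLogger(__name__)

_NP = len(PARAM_NAMES)


@dataclass
class TrajectoryPrediction:
    """Median forecast with a pointwise 90% band (cells/uL)."""

    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_samples: int
    cutoff_days: float
    seed: int
    prior_only: bool = False

    def __post_init__(self) -> None:
        for name in ("times", "median", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if not (np.all(self.lower <= self.median + 1e-9)
                and np.all(self.median <= self.upper + 1e-9)):
            raise ValueError("bands must be ordered lower <= median <= upper")
        if np.any(self.lower <= 0):
            raise ValueError("concentrations must be positive")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_days": self.times, "lower": self.lower,
                             "median": self.median, "upper": self.upper})


def forecast_cohort(subjects, pop: PopulationParameters, effects=(),
                    cutoff_days: float = 183.0, n_samples: int = 500,
                    horizon_days: float = 1095.0, grid=None, seed: int = 0,
                    ebe_samples: int = 300, include_residual: bool = False,
                    consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Forecast many subjects at once (one batched solve per stage).

    For each subject: empirical-Bayes posterior from the pre-cutoff
    observations, ``n_samples`` random-effect draws from a multivariate
    normal with the posterior mean and covariance, one trajectory per draw,
    and pointwise 5/50/95 percentile bands.  Observations after the cutoff
    never influence the result.  Returns a list of
    :class:`TrajectoryPrediction`.

    By default the band is a confidence band for the latent concentration
    curve.  With ``include_residual=True`` each sampled curve also receives
    log-additive residual noise, giving a prediction band for observed
    counts -- the right yardstick when classifying held-out measurements.
    """
    effects = [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
               for e in effects]
    if grid is None:
        grid = np.arange(0.0, float(horizon_days) + 3.5, 7.0)
    grid = np.asarray(grid, float)
    subjects = list(subjects)
    S = len(subjects)

    early, prior_only = [], []
    for s in subjects:
        keep = s.times <= cutoff_days
        early.append(replace(s, times=s.times[keep], cd4=s.cd4[keep]))
        prior_only.append(early[-1].n_obs == 0)
        if prior_only[-1]:
            warnings.warn(
                f"subject {s.subject_id!r} has no observations before day "
                f"{cutoff_days:g}; returning a prior-only forecast",
                stacklevel=2,
            )

    shifts = [_effect_design(effects, s) for s in subjects]
    ss = np.random.SeedSequence([seed, 53])
    children = ss.spawn(S + 1)
    ebe_seeds = [int(ch.generate_state(1)[0] % (2 ** 31)) for ch in children[:S]]
    fit = _map_batch(early, pop, shifts, consts)
    _, post_mean, post_cov = _mixture_eval(early, pop, shifts, fit["modes"],
                                           fit["covs"], ebe_samples, ebe_seeds,
                                           consts)

    rng = np.random.default_rng(children[S])
    arrays = {name: [] for name in _batch.PARAM_ORDER}
    for s in range(S):
        mean = post_mean[s] if not prior_only[s] else np.zeros(_NP)
        cov = post_cov[s] if not prior_only[s] else pop.omega
        eta = rng.multivariate_normal(mean, cov, n_samples, method="eigh").T
        values = np.exp((np.log(pop.theta) + shifts[s])[:, None] + eta)
        for i, name in enumerate(PARAM_NAMES):
            arrays[name].append(values[i])
        arrays["cp"].append(np.ones(n_samples))
        arrays["cd"].append(np.ones(n_samples))
    cat = {name: np.concatenate(arrays[name]) for name in _batch.PARAM_ORDER}
    curves = _batch.solve_blocks(cat, [s.age_at_hsct for s in subjects],
                                 [grid] * S, [n_samples] * S, consts)

    out = []
    for s in range(S):
        sampled = curves[s]
        if include_residual:
            eps = rng.normal(0.0, np.sqrt(pop.sigma2), sampled.shape)
            sampled = np.exp(np.log(sampled) + eps)
        lower, median, upper = np.percentile(sampled, [5.0, 50.0, 95.0], axis=1)
        out.append(TrajectoryPrediction(grid, median, lower, upper, n_samples,
                                        float(cutoff_days), seed,
                                        prior_only[s]))
    return out


def forecast(subject: SubjectRecord, pop: PopulationParameters, effects=(),
             cutoff_days: float = 183.0, n_samples: int = 500,
             horizon_days: float = 1095.0, grid=None, seed: int = 0,
             ebe_samples: int = 300, include_residual: bool = False,
             consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> TrajectoryPrediction:
    """Forecast one subject's trajectory from observations up to a cutoff.

    Only observations at t <= cutoff inform the posterior; later rows never
    influence the result.  With no usable observation the forecast falls
    back to the population prior and is flagged ``prior_only``.
    """
    return forecast_cohort([subject], pop, effects, cutoff_days, n_samples,
                           horizon_days, grid, seed, ebe_samples,
                           include_residual, consts)[0]


def classify_prediction(pred: TrajectoryPrediction, times, cd4) -> dict:
    """Classify a forecast against held-out observations.

    "good" means strictly more than 75% of the held-out points lie within
    the band at their times (bands linearly interpolated between grid
    points).  The auxiliary trend flag compares the sign of the observed and
    predicted change from the cutoff to the last held-out observation; it is
    reported but never alters the classification.
    """
    times = np.asarray(times, float)
    cd4 = np.asarray(cd4, float)
    if len(times) == 0:
        raise ValueError("classification requires at least one held-out observation")
    lo = np.interp(times, pred.times, pred.lower)
    hi = np.interp(times, pred.times, pred.upper)
    inside = (cd4 >= lo) & (cd4 <= hi)
    fraction = float(np.mean(inside))
    ref = float(np.interp(pred.cutoff_days, pred.times, pred.median))
    observed_change = cd4[np.argmax(times)] - ref
    predicted_change = float(np.interp(times.max(), pred.times, pred.median)) - ref
    return {
        "classification": "good" if fraction > 0.75 else "poor",
        "fraction_inside": fraction,
        "trend_agrees": bool(np.sign(observed_change) == np.sign(predicted_change)),
    }
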