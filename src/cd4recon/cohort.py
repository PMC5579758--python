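"""Synthetic cohorts with the statistical structure of the transplant study.

The real hospital datasets are not public, so every stage of the pipeline is
exercised on simulated cohorts that emulate their printed structure: the age
distribution at transplant (five bands), the prevalence of the dichotomous
covariates, a right-skewed number of samples per subject (median 8, range
1-43) over up to seven years of follow-up with denser early sampling,
lognormal inter-individual variability and a log-additive residual.
Demographics, schedules, random effects and noise are drawn from independent
seeded substreams, so every stage is separately reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _batch
from .population import (
    PARAM_NAMES,
    CovariateEffect,
    Dataset,
    PopulationParameters,
    SubjectRecord,
    _effect_design,
)
from .reference import AgeReferenceConstants, DEFAULT_CONSTANTS

__all__ = ["CohortSpec", "sample_demographics", "sample_schedule", "simulate_dataset"]

#: Age bands at transplant (days) with cohort weights; the open top band is
#: capped at 18 years and the first band starts at 30 days so that ages can
#: be drawn log-uniformly within each band.
DEFAULT_AGE_BANDS = (
    (30.0, 365.0, 0.16),
    (365.0, 730.0, 0.21),
    (730.0, 1825.0, 0.23),
    (1825.0, 3650.0, 0.24),
    (3650.0, 6570.0, 0.16),
)

#: Cohort prevalences of the dichotomous covariate flags.
DEFAULT_PREVALENCES = {
    "alemtuzumab": 0.50,
    "atg": 0.03,
    "gvhd": 0.32,
    "leukemia": 0.30,
    "fludarabine": 0.21,
    "no_conditioning": 0.13,
}


@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    The samples-per-subject distribution is a discretized lognormal with
    median ``samples_median`` clipped to ``samples_range``; observation
    times are log-uniform between day 14 and the follow-up horizon, which
    concentrates sampling in the first year the way transplant follow-up
    schedules do.
    """

    n_subjects: int = 100
    age_bands: tuple = DEFAULT_AGE_BANDS
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    samples_median: float = 8.0
    samples_log_sd: float = 0.55
    samples_range: tuple = (1, 43)
    horizon_days: float = 7 * 365.25
    min_spacing_days: float = 3.0

    def __post_init__(self) -> None:
        weights = [w for *_edges, w in self.age_bands]
        if abs(sum(weights) - 1.0) > 1e-6:
            raise ValueError("age band weights must sum to 1")
        for p in self.prevalences.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")
        if not self.horizon_days > 0:
            raise ValueError("horizon must be positive")


def sample_demographics(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Draw subject skeletons: age at transplant and covariate flags.

    Ages are drawn by band (per the cohort weights) and log-uniformly within
    a band; flags are independent Bernoulli draws at the stated prevalences.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    lo = np.array([b[0] for b in spec.age_bands])
    hi = np.array([b[1] for b in spec.age_bands])
    w = np.array([b[2] for b in spec.age_bands])
    band = rng.choice(len(w), size=spec.n_subjects, p=w / w.sum())
    u = rng.uniform(size=spec.n_subjects)
    age = np.exp(np.log(lo[band]) + u * (np.log(hi[band]) - np.log(lo[band])))
    data = {"subject_id": [f"S{i:04d}" for i in range(spec.n_subjects)],
            "age_at_hsct": age}
    for name, p in spec.prevalences.items():
        data[name] = (rng.uniform(size=spec.n_subjects) < p).astype(int)
    return pd.DataFrame(data)


def sample_schedule(spec: CohortSpec, n: int, seed: int = 0) -> list:
    """Draw per-subject observation times (days post-transplant).

    Counts come from a discretized lognormal (median ~8, clipped to 1-43);
    times are log-uniform on [14, horizon], sorted, and thinned to at least
    the minimum spacing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    lo_n, hi_n = spec.samples_range
    counts = np.clip(
        np.rint(np.exp(rng.normal(math.log(spec.samples_median),
                                  spec.samples_log_sd, n))).astype(int),
        lo_n, hi_n)
    schedules = []
    log_lo, log_hi = math.log(14.0), math.log(spec.horizon_days)
    for c in counts:
        t = np.sort(np.exp(rng.uniform(log_lo, log_hi, int(c))))
        keep = [0]
        for j in range(1, len(t)):
            if t[j] - t[keep[-1]] >= spec.min_spacing_days:
                keep.append(j)
        schedules.append(t[keep])
    return schedules


def simulate_dataset(pop: PopulationParameters, effects, skeletons: pd.DataFrame,
                     schedules: list, seed: int = 0,
                     consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Simulate CD4 observations for a cohort.

    Per subject: draw eta ~ MVN(0, Omega), assemble individual parameters
    from the covariate-adjusted typical values, solve the trajectory at the
    scheduled times, and report DV = exp(log X(t) + eps) with
    eps ~ N(0, sigma2).  Returns the :class:`Dataset` together with a truth
    table (true eta and structural parameters per subject) for recovery
    experiments.
    """
    if len(schedules) != len(skeletons):
        raise ValueError("skeletons and schedules must have equal length")
    effects = [e if isinstance(e, CovariateEffect) else CovariateEffect(*e)
               for e in effects]
    ss = np.random.SeedSequence([seed, 37])
    rng_eta = np.random.default_rng(ss.spawn(2)[0])
    rng_eps = np.random.default_rng(ss.spawn(2)[1])
    S = len(skeletons)
    cov_names = [c for c in skeletons.columns if c not in ("subject_id", "age_at_hsct")]

    eta = rng_eta.multivariate_normal(np.zeros(len(PARAM_NAMES)), pop.omega, S,
                                      method="eigh")
    subjects, truth_rows = [], []
    arrays = {name: [] for name in _batch.PARAM_ORDER}
    stubs = []
    for i in range(S):
        row = skeletons.iloc[i]
        flags = {c: int(row[c]) for c in cov_names}
        stub = SubjectRecord(str(row["subject_id"]), float(row["age_at_hsct"]),
                             flags, [], [])
        logp = np.log(pop.theta) + _effect_design(effects, stub) + eta[i]
        values = np.exp(logp)
        for j, name in enumerate(PARAM_NAMES):
            arrays[name].append(values[j])
        arrays["cp"].append(1.0)
        arrays["cd"].append(1.0)
        stubs.append((stub, flags, values))
    cat = {name: np.asarray(arrays[name]) for name in _batch.PARAM_ORDER}
    preds = _batch.solve_blocks(
        cat,
        [s.age_at_hsct for s, _, _ in stubs],
        [np.asarray(t, float) for t in schedules],
        [1] * S,
        consts,
    )
    for i, (stub, flags, values) in enumerate(stubs):
        times = np.asarray(schedules[i], float)
        x = preds[i][:, 0]
        if np.any(~np.isfinite(x)) or np.any(x <= 0):
            # resample this subject's random effects once, then give up
            eta[i] = rng_eta.multivariate_normal(np.zeros(len(PARAM_NAMES)),
                                                 pop.omega, method="eigh")
            logp = np.log(pop.theta) + _effect_design(effects, stub) + eta[i]
            values = np.exp(logp)
            retry = {n: np.array([values[j]]) for j, n in enumerate(PARAM_NAMES)}
            retry["cp"] = np.ones(1)
            retry["cd"] = np.ones(1)
            x = _batch.solve_blocks(retry, [stub.age_at_hsct], [times], [1],
                                    consts)[0][:, 0]
            if np.any(~np.isfinite(x)) or np.any(x <= 0):
                raise RuntimeError(
                    f"trajectory failure for subject {stub.subject_id}")
        eps = rng_eps.normal(0.0, math.sqrt(pop.sigma2), len(times))
        dv = np.exp(np.log(x) + eps)
        subjects.append(SubjectRecord(stub.subject_id, stub.age_at_hsct, flags,
                                      times, dv))
        rec = {"subject_id": stub.subject_id, "age_at_hsct": stub.age_at_hsct}
        rec.update({f"eta_{n}": eta[i][j] for j, n in enumerate(PARAM_NAMES)})
        rec.update({n: values[j] for j, n in enumerate(PARAM_NAMES)})
        truth_rows.append(rec)
    dataset = Dataset(subjects, tuple(cov_names))
    return dataset, pd.DataFrame(truth_rows)
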