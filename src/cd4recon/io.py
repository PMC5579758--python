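"""Plain-text formats: observation tables, run configuration, fit results.

The observation table is a comma-delimited file with a header row and
columns SUBJID, AGE0_DAYS, TIME_DAYS, CD4 followed by 0/1 covariate columns;
"." marks a missing value.  Units are fixed by the format: days and
cells/uL.  The run configuration is a YAML file with sections ``reference``,
``parameters``, ``covariates``, ``estimation``, ``forecast`` and ``seeds``;
unknown keys are rejected.  Fitted parameters are written back in the same
``parameters`` schema so a fit's output feeds prediction and VPC directly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .population import (
    PARAM_NAMES,
    CovariateEffect,
    Dataset,
    FitResult,
    PopulationParameters,
    SubjectRecord,
)
from .reference import AgeReferenceConstants

__all__ = [
    "read_dataset",
    "write_dataset",
    "load_config",
    "save_config",
    "pop_to_config",
    "pop_from_config",
    "save_fit_result",
]

log = logging.getLogger(__name__)

_MANDATORY = ("SUBJID", "AGE0_DAYS", "TIME_DAYS", "CD4")

_CONFIG_SECTIONS = ("reference", "parameters", "covariates", "estimation",
                    "forecast", "seeds")


def read_dataset(path) -> Dataset:
    """Read an observation table into a typed :class:`Dataset`.

    Rows with missing or non-positive CD4 are dropped (with a logged count);
    inconsistent AGE0_DAYS within a subject is an error.
    """
    frame = pd.read_csv(path, na_values=["."], dtype={"SUBJID": str})
    for col in _MANDATORY:
        if col not in frame.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    cov_names = [c for c in frame.columns if c not in _MANDATORY]
    for col in ("AGE0_DAYS", "TIME_DAYS", "CD4"):
        bad = frame.index[frame[col].map(
            lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.number))))]
        if len(bad):
            raise ValueError(f"unparseable number in column {col}, row {bad[0]}")
    dropped = int(((frame["CD4"].isna()) | (frame["CD4"] <= 0)).sum())
    if dropped:
        log.info("%s: dropped %d rows with missing/non-positive CD4", path, dropped)
    frame = frame[(frame["CD4"].notna()) & (frame["CD4"] > 0)]
    subjects = []
    for sid, g in frame.groupby("SUBJID", sort=False):
        ages = g["AGE0_DAYS"].unique()
        if len(ages) != 1:
            raise ValueError(f"inconsistent AGE0_DAYS for subject {sid!r}")
        g = g.sort_values("TIME_DAYS", kind="stable")
        flags = {c: int(g[c].iloc[0]) for c in cov_names}
        subjects.append(SubjectRecord(str(sid), float(ages[0]), flags,
                                      g["TIME_DAYS"].to_numpy(float),
                                      g["CD4"].to_numpy(float)))
    return Dataset(subjects, tuple(cov_names))


def write_dataset(dataset: Dataset, path) -> None:
    """Write an observation table (CD4 rounded to 0.01 cells/uL)."""
    rows = []
    for s in dataset.subjects:
        for t, v in zip(s.times, s.cd4):
            row = {"SUBJID": s.subject_id, "AGE0_DAYS": s.age_at_hsct,
                   "TIME_DAYS": t, "CD4": round(float(v), 2)}
            for c in dataset.covariate_names:
                row[c] = s.covariates.get(c, 0)
            rows.append(row)
    columns = list(_MANDATORY) + list(dataset.covariate_names)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


def pop_to_config(pop: PopulationParameters, effects=()) -> dict:
    """Serialize population parameters to the config ``parameters`` schema."""
    return {
        "theta": pop.theta_as_dict(),
        "omega": [[float(v) for v in row] for row in pop.omega],
        "sigma2": float(pop.sigma2),
        "effects": [
            {"covariate": e.covariate, "parameter": e.parameter,
             "value": float(e.value)} for e in effects
        ],
    }


def pop_from_config(section: dict):
    """Parse a ``parameters`` section back into typed objects."""
    theta = np.array([section["theta"][n] for n in PARAM_NAMES])
    pop = PopulationParameters(theta, np.array(section["omega"], float),
                               float(section["sigma2"]))
    effects = [CovariateEffect(e["covariate"], e["parameter"], float(e["value"]))
               for e in section.get("effects", [])]
    return pop, effects


def load_config(path) -> dict:
    """Load and validate a run configuration; unknown sections/keys error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = dict(raw)
    if "reference" in raw:
        ref = dict(raw["reference"])
        valid = set(AgeReferenceConstants.__dataclass_fields__)
        unknown = set(ref) - valid
        if unknown:
            raise ValueError(f"unknown reference keys: {sorted(unknown)}")
        out["reference"] = AgeReferenceConstants(**ref)
    if "parameters" in raw:
        out["parameters"] = pop_from_config(raw["parameters"])
    return out


def save_config(config: dict, path) -> None:
    """Write a run configuration; typed objects are serialized back."""
    out = {}
    for key, value in config.items():
        if key not in _CONFIG_SECTIONS:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(value, AgeReferenceConstants):
            value = asdict(value)
        elif key == "parameters" and isinstance(value, tuple):
            value = pop_to_config(*value)
        out[key] = value
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def save_fit_result(fit: FitResult, path) -> None:
    """Write a fit as a config file whose ``parameters`` section feeds
    forecasting and VPC directly; the objective trace and seed ride along
    in an ``estimation`` section."""
    save_config(
        {
            "parameters": (fit.pop, fit.effects),
            "estimation": {
                "objective": float(fit.objective),
                "converged": bool(fit.converged),
                "n_iter": int(fit.n_iter),
                "trace": [float(v) for v in fit.trace],
            },
            "seeds": {"fit": int(fit.seed)},
        },
        path,
    )
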