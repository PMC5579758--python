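"""Healthy-child reference curves and age-scaling functions.

Every rate in the transplant model is scaled to what is expected for a
healthy child of the same age: the total CD4 concentration ``N(tau)``, the
naive CD4 concentration ``Nn(tau)``, the fraction of CD4 cells expressing
the proliferation marker Ki67 ``y(tau)``, and the theoretical thymic-output
curve assembled from TREC (T-cell receptor excision circle) constants.
Ages are in days throughout; concentrations in cells/uL of blood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgeReferenceConstants",
    "DAYS_PER_MONTH",
    "expected_total_cd4",
    "expected_naive_cd4",
    "ki67_fraction",
    "thymic_output_for_age",
    "thymic_output_multiplier",
]

#: Calendar-average month length used whenever results are reported in months.
DAYS_PER_MONTH = 30.4375

#: Algebraically plausible readings of how the TREC constants combine into the
#: age-independent multiplier of the thymic-output curve.  "pool" is the
#: calibrated default (see docs/methods.md); the others are retained so the
#: calibration experiment stays reproducible.
GROUPINGS = ("pool", "inverse", "duration")


@dataclass(frozen=True)
class AgeReferenceConstants:
    """Published coefficients of the healthy-child reference functions.

    The defaults are the printed values for N(tau), Nn(tau) and y(tau)
    together with the TREC constants: ``ki67_duration`` is the mean duration
    of Ki67 expression (days), ``trec_thymus`` the average TREC content of
    naive cells leaving the thymus and ``trec_pool`` that of the circulating
    naive pool.
    """

    n_total_asymptote: float = 924.0
    n_total_amplitude: float = 2354.0
    n_total_rate: float = 0.001012
    n_naive_asymptote: float = 496.5
    n_naive_amplitude: float = 2074.0
    n_naive_rate: float = 0.000869
    ki67_at_birth: float = 0.02
    ki67_decay_rate: float = 0.00027
    ki67_duration: float = 0.52
    trec_thymus: float = 0.25
    trec_pool: float = 0.08
    lambda_age_grouping: str = "pool"

    def __post_init__(self) -> None:
        positive = (
            "n_total_asymptote", "n_total_amplitude", "n_total_rate",
            "n_naive_asymptote", "n_naive_amplitude", "n_naive_rate",
            "ki67_decay_rate", "ki67_duration", "trec_thymus", "trec_pool",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.ki67_at_birth < 1:
            raise ValueError("ki67_at_birth must lie in (0, 1)")
        if not self.trec_thymus > self.trec_pool:
            raise ValueError(
                "trec_thymus (c) must exceed trec_pool (gamma); the thymic "
                "output formula changes sign otherwise"
            )
        if self.lambda_age_grouping not in GROUPINGS:
            raise ValueError(
                f"unknown lambda_age_grouping {self.lambda_age_grouping!r}; "
                f"choose one of {GROUPINGS}"
            )


DEFAULT_CONSTANTS = AgeReferenceConstants()


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be non-negative (days since birth)")
    return age


def expected_total_cd4(age, consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Expected total CD4 concentration N(tau) for a healthy child (cells/uL)."""
    age = _check_age(age)
    return consts.n_total_asymptote + consts.n_total_amplitude * np.exp(
        -consts.n_total_rate * age
    )


def expected_naive_cd4(age, consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Expected naive CD4 concentration Nn(tau) for a healthy child (cells/uL)."""
    age = _check_age(age)
    return consts.n_naive_asymptote + consts.n_naive_amplitude * np.exp(
        -consts.n_naive_rate * age
    )


def ki67_fraction(age, consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Fraction y(tau) of CD4 cells expressing Ki67 at a given age."""
    age = _check_age(age)
    return consts.ki67_at_birth * np.exp(-consts.ki67_decay_rate * age)


def thymic_output_multiplier(consts: AgeReferenceConstants = DEFAULT_CONSTANTS) -> float:
    """Age-independent multiplier combining the TREC constants.

    The thymic-output curve is proportional to ``y(tau) * Nn(tau)``; the
    proportionality constant is assembled from gamma (TREC content of the
    naive pool), the Ki67 birth fraction, the Ki67 expression duration and
    ``c - gamma``.  The printed formula is typographically ambiguous in how
    these combine, so the grouping is an explicit, calibrated choice:

    - ``"pool"``     : gamma * (c - gamma) / (ki67_at_birth * duration)
    - ``"inverse"``  : gamma / (ki67_at_birth * duration * (c - gamma))
    - ``"duration"`` : gamma * duration * (c - gamma) / ki67_at_birth
    """
    g = consts.trec_pool
    c = consts.trec_thymus
    k0 = consts.ki67_at_birth
    eta = consts.ki67_duration
    if not c > g:
        raise ValueError("trec_thymus must exceed trec_pool")
    tag = consts.lambda_age_grouping
    if tag == "pool":
        return g * (c - g) / (k0 * eta)
    if tag == "inverse":
        return g / (k0 * eta * (c - g))
    if tag == "duration":
        return g * eta * (c - g) / k0
    raise ValueError(f"unknown grouping {tag!r}")


def thymic_output_for_age(age, consts: AgeReferenceConstants = DEFAULT_CONSTANTS):
    """Theoretical thymic output for a healthy child of a given age.

    Returns the age-dependent zero-order production rate (cells/uL/day)
    before any transplant scaling: multiplier * y(tau) * Nn(tau).  Strictly
    decreasing in age because both factors decay.
    """
    age = _check_age(age)
    return (
        thymic_output_multiplier(consts)
        * ki67_fraction(age, consts)
        * expected_naive_cd4(age, consts)
    )
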