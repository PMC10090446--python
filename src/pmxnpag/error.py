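"""Multiplicative polynomial residual-error model and observation likelihood.

The assay standard deviation is a polynomial in the *observed* concentration,

    SD(c_obs) = C0 + C1*c_obs + C2*c_obs^2 + C3*c_obs^3,

and the effective observation SD is gamma * SD(c_obs), with gamma a
dimensionless process-noise multiplier (mis-specified sampling times, dose
records, model error).  Observations are weighted by 1/(gamma*SD)^2, i.e.
the observation density is Gaussian with that SD.  Computing SD from the
observed rather than the model-predicted concentration is deliberate and
matches the fitting convention this pipeline reproduces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Subject

__all__ = ["ErrorSpec", "sd_of_observation", "log_likelihood_subject"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ErrorSpec:
    """Error-polynomial coefficients and the gamma multiplier.

    Defaults: C = (0.1, 0.15, 0, 0) mg/L-scale coefficients; gamma starts
    at 5 and is re-optimized during fitting (a fitted value near 0.7 is
    typical for this drug/assay).
    """

    c0: float = 0.1
    c1: float = 0.15
    c2: float = 0.0
    c3: float = 0.0
    gamma: float = 5.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    def with_gamma(self, gamma: float) -> "ErrorSpec":
        return ErrorSpec(self.c0, self.c1, self.c2, self.c3, gamma)


def sd_of_observation(c_obs, spec: ErrorSpec):
    """Assay SD at observed concentration(s), before gamma scaling (mg/L)."""
    c = np.asarray(c_obs, dtype=float)
    if np.any(c < 0):
        raise ValueError("observed concentration must be >= 0")
    sd = spec.c0 + spec.c1 * c + spec.c2 * c**2 + spec.c3 * c**3
    if np.any(sd <= 0):
        raise ValueError("error polynomial yields non-positive SD; "
                         "check coefficients")
    return sd if sd.shape else float(sd)


def log_likelihood_subject(params, subject: Subject, spec: ErrorSpec) -> float:
    """Gaussian log-likelihood of a subject's quantified observations.

    Mean = model prediction at the observation time, SD = gamma * SD(c_obs).
    BLQ observations are excluded.  Returns 0.0 (with a warning) when the
    subject has no quantified observations.
    """
    from .pk import predict_concentrations, predict_one_compartment

    obs = [o for o in subject.observations if not o.blq]
    if not obs:
        warnings.warn(f"subject {subject.id!r} has no quantified observations; "
                      "log-likelihood is 0", stacklevel=2)
        return 0.0
    times = np.array([o.time for o in obs])
    y = np.array([o.concentration for o in obs])
    if params.n_compartments == 2:
        pred = predict_concentrations(params, subject.doses, times)
    else:
        pred = predict_one_compartment(params, subject.doses, times)
    sigma = spec.gamma * np.asarray(sd_of_observation(y, spec))
    z = (y - pred) / sigma
    return float(np.sum(-0.5 * z**2 - np.log(sigma) - 0.5 * _LOG_2PI))
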