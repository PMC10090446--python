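"""Monte Carlo probability-of-target-attainment (PTA) dosing simulation.

Efficacy target: total-drug AUC_ss,24h / MIC >= 50, derived from the
consensus free-drug target fAUC/MIC ~ 20 and an unbound fraction of 0.42
(20 / 0.42 = 47.6, rounded up to the nearest ten).  Toxicity limit:
AUC_ss,24h > 100 mg·h/L.  Because the PK is linear, AUC_ss,24h depends
only on clearance: (24 / interval) * maintenance_dose / CL.

Virtual patients are sampled either from a fitted nonparametric support
(points with replacement by weight) or, in "published-table" mode, from
independent lognormals parameterized by the reported mean and % CV of each
parameter.  Albumin is drawn uniformly within the scenario stratum, age is
fixed at the scenario value, and the final covariate model (ALB on CL,
age on V) is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateModel, final_covariate_model
from .pk import Regimen

__all__ = [
    "PdTargets",
    "Scenario",
    "PublishedModel",
    "ALB_STRATA",
    "AGE_PERCENTILES",
    "REGIMENS",
    "MIC_GRID",
    "efficacy_threshold_from_fauc",
    "all_scenarios",
    "sample_virtual_population",
    "pta_efficacy",
    "pta_toxicity",
    "dosing_report",
]

#: albumin strata, g/L
ALB_STRATA = {"ultra-low": (21.3, 24.9), "low": (25.0, 34.9),
              "normal": (35.0, 41.5)}
#: simulated ages: cohort 5th percentile, median, 95th percentile (years)
AGE_PERCENTILES = {"p5": 34.0, "median": 68.0, "p95": 93.0}
#: maintenance regimens I-V, mg q12h
REGIMENS = {"I": 100.0, "II": 75.0, "III": 60.0, "IV": 50.0, "V": 40.0}
#: MIC doubling series, mg/L
MIC_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def efficacy_threshold_from_fauc(fauc_mic_target: float = 20.0,
                                 unbound_fraction: float = 0.42) -> float:
    """Total-drug AUC/MIC threshold: free target / unbound fraction,
    rounded up to the nearest ten (20 / 0.42 -> 47.6 -> 50)."""
    if not (fauc_mic_target > 0 and 0 < unbound_fraction <= 1):
        raise ValueError("need fauc_mic_target > 0 and 0 < unbound_fraction <= 1")
    return 10.0 * math.ceil(fauc_mic_target / unbound_fraction / 10.0)


@dataclass(frozen=True)
class PdTargets:
    """PK/PD targets for efficacy and toxicity."""

    fauc_mic_target: float = 20.0
    unbound_fraction: float = 0.42
    auc_mic_threshold: float = 50.0
    toxicity_auc: float = 100.0
    attainment_threshold: float = 0.9

    def __post_init__(self) -> None:
        implied = efficacy_threshold_from_fauc(self.fauc_mic_target,
                                               self.unbound_fraction)
        if self.auc_mic_threshold < implied:
            raise ValueError(
                f"auc_mic_threshold {self.auc_mic_threshold} below the value "
                f"implied by the free-drug target ({implied})")
        if not (self.toxicity_auc > 0 and 0 < self.attainment_threshold <= 1):
            raise ValueError("invalid toxicity/attainment settings")


@dataclass(frozen=True)
class Scenario:
    """One simulated stratum: an albumin interval (g/L) and a fixed age."""

    alb_lo: float
    alb_hi: float
    age: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.alb_lo < self.alb_hi):
            raise ValueError("need 0 < alb_lo < alb_hi")
        if not self.age > 0:
            raise ValueError("age must be > 0")


def all_scenarios() -> list[Scenario]:
    """The full 3 (albumin) x 3 (age) factorial."""
    out = []
    for aname, (lo, hi) in ALB_STRATA.items():
        for pname, age in AGE_PERCENTILES.items():
            out.append(Scenario(lo, hi, age, label=f"{aname}/{pname}"))
    return out


@dataclass(frozen=True)
class PublishedModel:
    """Reported population parameter table: mean and % CV per parameter,
    with lognormal between-subject variability, plus the covariate model."""

    means: dict = field(default_factory=lambda: {
        "CL": 1.24, "Vc": 16.64, "Q": 3.04, "Vp": 66.2})
    cv_pct: dict = field(default_factory=lambda: {
        "CL": 30.48, "Vc": 76.55, "Q": 74.78, "Vp": 54.76})
    covariates: CovariateModel = field(default_factory=final_covariate_model)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cv_pct.values()):
            raise ValueError("CV% values must be > 0")


def _apply_scenario_covariates(theta: np.ndarray, alb: np.ndarray, age: float,
                               model: CovariateModel) -> np.ndarray:
    values = {"alb": alb, "age": np.full(len(alb), age)}
    out = theta.copy()
    for e in model.effects:
        if e.covariate not in values:
            raise KeyError(f"scenario provides no covariate {e.covariate!r}")
        col = 0 if e.target == "CL" else 1
        out[:, col] *= (values[e.covariate] / e.reference) ** e.exponent
    return out


def sample_virtual_population(model, scenario: Scenario, n: int = 1000,
                              seed: int = 0) -> np.ndarray:
    """Sample n virtual patients; returns an (n, d) array of individual
    parameters (columns CL, Vc[, Q, Vp]).

    ``model`` is either a fitted :class:`~pmxnpag.npag.NPAGResult` (base
    parameters resampled from the support by weight; its ModelSpec's
    covariate model applied) or a :class:`PublishedModel` (independent
    mean/CV-parameterized lognormals).
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, PublishedModel):
        names = list(model.means)
        cols = []
        for nm in names:
            sigma2 = np.log1p((model.cv_pct[nm] / 100.0) ** 2)
            mu = np.log(model.means[nm]) - 0.5 * sigma2
            cols.append(rng.lognormal(mu, np.sqrt(sigma2), size=n))
        theta = np.column_stack(cols)
        cm = model.covariates
    else:                                   # fitted NPAGResult
        support = model.support
        idx = rng.choice(support.K, size=n, p=support.weights)
        theta = support.points[idx].copy()
        cm = model.model.covariates
    alb = rng.uniform(scenario.alb_lo, scenario.alb_hi, size=n)
    return _apply_scenario_covariates(theta, alb, scenario.age, cm)


def _auc24(pop: np.ndarray, regimen: Regimen) -> np.ndarray:
    cl = pop[:, 0]
    return (24.0 / regimen.interval) * regimen.maintenance_dose / cl


def pta_efficacy(pop: np.ndarray, regimen: Regimen,
                 targets: PdTargets = PdTargets(),
                 mic_grid=MIC_GRID) -> pd.Series:
    """Fraction of the population with AUC_ss,24h / MIC >= the efficacy
    threshold, per MIC."""
    if len(pop) == 0:
        raise ValueError("empty population")
    mics = np.asarray(mic_grid, dtype=float)
    if np.any(mics <= 0):
        raise ValueError("MIC values must be > 0")
    auc = _auc24(pop, regimen)
    frac = [(auc / mic >= targets.auc_mic_threshold).mean() for mic in mics]
    return pd.Series(frac, index=mics, name="pta_efficacy")


def pta_toxicity(pop: np.ndarray, regimen: Regimen,
                 targets: PdTargets = PdTargets()) -> float:
    """Fraction of the population with AUC_ss,24h above the toxicity limit."""
    if len(pop) == 0:
        raise ValueError("empty population")
    return float((_auc24(pop, regimen) > targets.toxicity_auc).mean())


def dosing_report(model, targets: PdTargets = PdTargets(), n: int = 1000,
                  seed: int = 0, mic: float = 1.0,
                  scenarios: list[Scenario] | None = None,
                  regimens: dict | None = None,
                  mic_grid=MIC_GRID):
    """Full factorial PTA table plus a recommendation per scenario.

    One virtual population is sampled per scenario (shared across regimens,
    which makes efficacy PTA exactly non-decreasing in dose).  The
    recommended regimen is the smallest maintenance dose whose efficacy PTA
    at ``mic`` reaches the attainment threshold while the toxicity PTA
    stays below it; a scenario where no regimen qualifies is flagged
    ``"none attainable"``.
    """
    scenarios = scenarios if scenarios is not None else all_scenarios()
    regimens = regimens if regimens is not None else REGIMENS
    ss = np.random.SeedSequence(seed)
    rows = []
    recommendations = {}
    for scen, child in zip(scenarios, ss.spawn(len(scenarios))):
        pop = sample_virtual_population(model, scen, n=n,
                                        seed=int(child.generate_state(1)[0] % (2**31)))
        best = None
        for label, dose in sorted(regimens.items(), key=lambda kv: kv[1]):
            reg = Regimen(maintenance_dose=dose)
            eff = pta_efficacy(pop, reg, targets, mic_grid)
            tox = pta_toxicity(pop, reg, targets)
            for m, p in eff.items():
                rows.append({"scenario": scen.label, "alb_lo": scen.alb_lo,
                             "alb_hi": scen.alb_hi, "age": scen.age,
                             "regimen": label, "dose": dose, "mic": m,
                             "pta_eff": p, "pta_tox": tox})
            at_mic = eff.loc[mic] if mic in eff.index else \
                pta_efficacy(pop, reg, targets, [mic]).iloc[0]
            if (best is None and at_mic >= targets.attainment_threshold
                    and tox < targets.attainment_threshold):
                best = label
        recommendations[scen.label] = best if best is not None else "none attainable"
    return pd.DataFrame(rows), recommendations
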