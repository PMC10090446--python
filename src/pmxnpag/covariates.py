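"""Covariate derivation, power-law covariate models, and stepwise selection.

Covariates enter the structural model multiplicatively as centered power
laws, e.g. ``CL = CL0 * (ALB/31.45)**(-0.95)`` and
``V = V0 * (age/68)**0.95``: albumin binding drives clearance (lower ALB,
higher free fraction, higher CL of total drug) and age drives the central
volume.  Selection follows a likelihood-ratio / population-fit rule: an
effect is kept when it drops -2LL by more than the df=1, p<0.01 chi-square
critical value (6.63) or improves the population R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, CovariateSet
from .pk import PKParameters

__all__ = [
    "CHI2_1DF_P01",
    "ALB_REFERENCE",
    "AGE_REFERENCE",
    "APACHE2_REFERENCE",
    "CovariateEffect",
    "CovariateModel",
    "final_covariate_model",
    "cockcroft_gault",
    "apply_covariates",
    "apply_covariates_theta",
    "screen_covariates",
    "stepwise_select",
]

#: chi-square critical value, df=1, p=0.01 — the -2LL drop an effect must
#: beat for inclusion (strict inequality).
CHI2_1DF_P01 = 6.63

# centering constants: cohort medians of albumin (g/L), age (y), APACHE-II
ALB_REFERENCE = 31.45
AGE_REFERENCE = 68.0
APACHE2_REFERENCE = 21.5


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative power-law effect: ``target *= (cov/reference)**exponent``.

    ``target`` is "CL" or "V"; ``covariate`` one of age/wt/alb/scr/apache2/ccr.
    """

    target: str
    covariate: str
    reference: float
    exponent: float

    def __post_init__(self) -> None:
        if self.target not in ("CL", "V"):
            raise ValueError(f"target must be 'CL' or 'V', got {self.target!r}")
        if not self.reference > 0:
            raise ValueError("reference must be > 0")
        if not np.isfinite(self.exponent):
            raise ValueError("exponent must be finite")

    def factor(self, cov: CovariateSet) -> float:
        value = getattr(cov, self.covariate, None)
        if value is None:
            raise KeyError(f"covariate {self.covariate!r} missing")
        return (value / self.reference) ** self.exponent


@dataclass(frozen=True)
class CovariateModel:
    """A set of effects, at most one per (target, covariate) pair."""

    effects: tuple[CovariateEffect, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        pairs = [(e.target, e.covariate) for e in self.effects]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (target, covariate) effect")

    def __bool__(self) -> bool:
        return bool(self.effects)

    def with_effect(self, effect: CovariateEffect) -> "CovariateModel":
        return CovariateModel(self.effects + (effect,))

    def label(self) -> str:
        if not self.effects:
            return "base"
        return " * ".join(
            f"{e.target}0*({e.covariate}/{e.reference:g})^{e.exponent:g}"
            for e in self.effects)


def final_covariate_model() -> CovariateModel:
    """The fitted final covariate model: ALB on CL (exponent -0.95) and
    age on V (exponent +0.95), centered at the cohort medians."""
    return CovariateModel((
        CovariateEffect("V", "age", AGE_REFERENCE, 0.95),
        CovariateEffect("CL", "alb", ALB_REFERENCE, -0.95),
    ))


def cockcroft_gault(age: float, wt: float, scr: float, sex: str) -> float:
    """Cockcroft–Gault creatinine clearance, mL/min.

    ``scr`` in µmol/L (divided by 88.4 to convert to mg/dL); result
    multiplied by 0.85 for females.
    """
    if not (age > 0 and wt > 0 and scr > 0):
        raise ValueError("age, weight and serum creatinine must be > 0")
    if age >= 140:
        raise ValueError(f"age must be < 140 years, got {age}")
    ccr = (140.0 - age) * wt / (72.0 * scr / 88.4)
    if sex == "F":
        ccr *= 0.85
    elif sex != "M":
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return ccr


def apply_covariates(base: PKParameters, cov: CovariateSet,
                     model: CovariateModel) -> PKParameters:
    """Scale base-parameter values (CL0, V0) by each covariate factor.

    Q and Vp pass through unchanged.
    """
    cl, v = base.CL, base.Vc
    for e in model.effects:
        f = e.factor(cov)
        if e.target == "CL":
            cl *= f
        else:
            v *= f
    return PKParameters(cl, v, base.Q, base.Vp)


def apply_covariates_theta(theta: np.ndarray, cov: CovariateSet,
                           model: CovariateModel) -> np.ndarray:
    """Vectorized :func:`apply_covariates` on a (K, d) base-parameter array
    (columns CL, V[, Q, Vp])."""
    if not model.effects:
        return theta
    out = theta.copy()
    for e in model.effects:
        f = e.factor(cov)
        out[:, 0 if e.target == "CL" else 1] *= f
    return out


def screen_covariates(posteriors: pd.DataFrame, cohort: Cohort,
                      covariate_names: tuple[str, ...] = (
                          "age", "wt", "alb", "scr", "apache2", "ccr"),
                      ) -> pd.DataFrame:
    """OLS screen of posterior parameter estimates against each covariate.

    ``posteriors``: DataFrame indexed by subject id with columns CL, Vc
    (and optionally Q, Vp) of posterior-mean individual estimates.  Returns
    a long table (parameter, covariate, slope, r2, flag); a zero-variance
    covariate gets r2 = 0 and a flag.
    """
    if len(cohort) < 3:
        raise ValueError("screening needs at least 3 subjects")
    cov_rows = {}
    for s in cohort:
        c = s.covariates
        cov_rows[s.id] = {n: getattr(c, n) for n in covariate_names}
    covs = pd.DataFrame.from_dict(cov_rows, orient="index").loc[posteriors.index]

    rows = []
    for param in posteriors.columns:
        y = posteriors[param].to_numpy(dtype=float)
        for name in covariate_names:
            x = covs[name].to_numpy(dtype=float)
            flag = ""
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                slope, r2 = 0.0, 0.0
                flag = "zero-variance"
            else:
                slope, _ = np.polyfit(x, y, 1)
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            rows.append({"parameter": param, "covariate": name,
                         "slope": float(slope), "r2": r2, "flag": flag})
    return pd.DataFrame(rows)


def stepwise_select(cohort: Cohort, base_fit, base_model, space, config,
                    candidates: list[CovariateEffect]):
    """Stepwise covariate inclusion against a fitted base model.

    Each candidate effect is added to the base model and refitted; an
    effect is accepted when the -2LL drop exceeds :data:`CHI2_1DF_P01`
    (strictly) OR the population R^2 improves over the base.  When two or
    more effects are accepted the combined model is also fitted and
    returned as the final model.  Returns ``(final_model, table)`` where
    ``table`` has one row per fitted model (model comparison shape:
    label, n_effects, neg2ll, aicc, bic, r2_pop, r2_post, accepted,
    converged).
    """
    from .npag import fit_metrics, polish_support, run_npag

    def _factor_quantiles(eff):
        f = np.array([eff.factor(s.covariates) for s in cohort])
        return np.quantile(f, (0.2, 0.5, 0.8))

    def _rescaled(points, eff, factors):
        # seed the warm start at base-scale values divided (or multiplied)
        # by typical covariate factors, so points discovered under one
        # parameterization land near their image under the other
        col = 0 if eff.target == "CL" else 1
        out = [points]
        for f in factors:
            p = points.copy()
            p[:, col] *= f
            out.append(p)
        return np.vstack(out)

    existing = {(e.target, e.covariate) for e in base_model.covariates.effects}
    cand_fits = []
    for eff in candidates:
        if (eff.target, eff.covariate) in existing:
            cand_fits.append((eff, None, None))
            continue
        model = base_model.with_covariates(
            base_model.covariates.with_effect(eff))
        fq = _factor_quantiles(eff)
        init = _rescaled(base_fit.support.points, eff, 1.0 / fq)
        fit = run_npag(cohort, model, space, config, init_points=init)
        cand_fits.append((eff, model, fit))

    # before likelihoods are compared, strengthen the BASE side with
    # everything the candidate searches discovered: re-search the base
    # model seeded from the back-mapped candidate supports, then polish
    # its weights on the full pool.  Candidates keep their single search.
    # The asymmetry is deliberate and conservative: a candidate must beat
    # a base model that has seen the candidate's support, so a -2LL drop
    # reflects the covariate rather than search depth
    base_pool = [base_fit.support.points]
    for eff, _, f in cand_fits:
        if f is not None:
            base_pool.append(_rescaled(f.support.points, eff,
                                       _factor_quantiles(eff)))
    base_variants = [base_fit]
    if len(base_pool) > 1:
        pool = np.vstack(base_pool)
        research = run_npag(cohort, base_model, space, config,
                            init_points=pool)
        base_variants.append(research)
        base_eval = polish_support(
            cohort, base_model, np.vstack([pool, research.support.points]),
            space, config, gamma=research.gamma_final)
        base_eval.converged = base_fit.converged
        base_variants.append(base_eval)
    best = int(np.argmin([f.neg2ll for f in base_variants]))
    base_fit = base_variants[best]
    base_metrics = fit_metrics(base_fit, cohort, base_model)
    rows = [{"model": base_model.covariates.label(), "n_effects":
             len(base_model.covariates.effects),
             "neg2ll": base_metrics.neg2ll, "aicc": base_metrics.aicc,
             "bic": base_metrics.bic, "r2_pop": base_metrics.r2_pop,
             "r2_post": base_metrics.r2_post, "accepted": True,
             "converged": base_fit.converged}]

    accepted: list[CovariateEffect] = []
    for eff, model, fit in cand_fits:
        if model is None:
            rows.append({"model": f"duplicate {eff.target}~{eff.covariate}",
                         "n_effects": len(base_model.covariates.effects),
                         "neg2ll": np.nan, "aicc": np.nan, "bic": np.nan,
                         "r2_pop": np.nan, "r2_post": np.nan,
                         "accepted": False, "converged": False})
            continue
        m = fit_metrics(fit, cohort, model)
        ok = ((base_metrics.neg2ll - m.neg2ll > CHI2_1DF_P01)
              or (m.r2_pop > base_metrics.r2_pop))
        rows.append({"model": model.covariates.label(),
                     "n_effects": len(model.covariates.effects),
                     "neg2ll": m.neg2ll, "aicc": m.aicc, "bic": m.bic,
                     "r2_pop": m.r2_pop, "r2_post": m.r2_post,
                     "accepted": ok, "converged": fit.converged})
        if ok:
            accepted.append(eff)

    if len(accepted) >= 2:
        cm = base_model.covariates
        for eff in accepted:
            cm = cm.with_effect(eff)
        model = base_model.with_covariates(cm)
        fit = run_npag(cohort, model, space, config,
                       init_points=base_fit.support.points)
        m = fit_metrics(fit, cohort, model)
        rows.append({"model": cm.label(), "n_effects": len(cm.effects),
                     "neg2ll": m.neg2ll, "aicc": m.aicc, "bic": m.bic,
                     "r2_pop": m.r2_pop, "r2_post": m.r2_post,
                     "accepted": True, "converged": fit.converged})
        final = cm
    elif len(accepted) == 1:
        final = base_model.covariates.with_effect(accepted[0])
    else:
        final = base_model.covariates
    return final, pd.DataFrame(rows)
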