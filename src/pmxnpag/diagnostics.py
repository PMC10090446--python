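"""Model validation: goodness-of-fit tables, bootstrap, data splitting, VPC.

All outputs are plain DataFrames (CSV-friendly); plotting is left to the
caller.  Bootstrap and VPC draw every random number from one seeded
generator, so results are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .error import sd_of_observation
from .npag import (ModelSpec, NpagConfig, NPAGResult, ParameterSpace,
                   _LikCache, fit_metrics, posterior_subject, run_npag)

__all__ = ["gof_table", "bootstrap", "split_validate", "vpc"]


def gof_table(result: NPAGResult, cohort: Cohort):
    """Per-observation goodness-of-fit records and the two R^2 values.

    Returns ``(records, r2_pop, r2_post)``.  ``weighted_residual`` is
    (observed - population prediction) / (gamma * SD(observed)); the
    posterior-based residual is emitted alongside.
    """
    model = replace(result.model, error=result.error_final())
    cache = _LikCache(cohort, result.support.points, model, store_pred=True)
    w = result.support.weights
    err = result.error_final()
    rows = []
    for i, s in enumerate(cohort):
        obs = [o for o in s.observations if not o.blq]
        if not obs:
            continue
        pw, _ = posterior_subject(result, s)
        y = np.array([o.concentration for o in obs])
        pred = cache.preds[i]
        pop = w @ pred
        post = pw @ pred
        sigma = err.gamma * np.asarray(sd_of_observation(y, err))
        for k, o in enumerate(obs):
            rows.append({"id": s.id, "time": o.time, "observed": y[k],
                         "pop_pred": pop[k], "post_pred": post[k],
                         "weighted_residual": (y[k] - pop[k]) / sigma[k],
                         "post_weighted_residual": (y[k] - post[k]) / sigma[k]})
    records = pd.DataFrame(rows)
    m = fit_metrics(result, cohort)
    return records, m.r2_pop, m.r2_post


def bootstrap(cohort: Cohort, model: ModelSpec, space: ParameterSpace,
              B: int = 200, seed: int = 0,
              config: NpagConfig | None = None) -> pd.DataFrame:
    """Nonparametric bootstrap of the population means.

    Subjects are resampled with replacement to the cohort size; each
    replicate is refitted (typically with a reduced search budget) and the
    weighted population means are summarized as median and 2.5/97.5
    percentile CI.  Aborts if more than 20% of replicates fail to converge.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    config = config or NpagConfig(n_initial=256, max_cycles=40,
                                  delta_min=0.02, tol=0.05, seed=seed)
    rng = np.random.default_rng(seed)
    names = model.param_names
    means, n_fail = [], 0
    for b in range(B):
        idx = rng.integers(len(cohort), size=len(cohort))
        subs = []
        for k, i in enumerate(idx):
            s = cohort.subjects[i]
            subs.append(replace(s, id=f"{s.id}#r{k}"))
        rep = Cohort(subs)
        fit = run_npag(rep, model, space,
                       replace(config, seed=int(rng.integers(2**31))))
        if not fit.converged:
            n_fail += 1
            if n_fail > 0.2 * B:
                raise RuntimeError(
                    f"bootstrap aborted: {n_fail}/{b + 1} replicates "
                    "non-convergent")
        means.append(fit.support.mean())
    arr = np.array(means)
    return pd.DataFrame({
        "median": np.median(arr, axis=0),
        "ci_low": np.percentile(arr, 2.5, axis=0),
        "ci_high": np.percentile(arr, 97.5, axis=0),
        "B": len(means),
    }, index=list(names))


def split_validate(cohort: Cohort, model: ModelSpec, space: ParameterSpace,
                   seed: int = 0, fraction: float = 0.8,
                   config: NpagConfig | None = None) -> pd.DataFrame:
    """Random data-splitting stability check.

    Subjects are partitioned ``fraction`` / ``1-fraction`` and the model is
    fitted independently to the full cohort and each split; the table
    reports weighted population mean and SD per parameter and cohort.
    A split smaller than 3 subjects is still fitted, with a warning.
    """
    import warnings

    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_main = int(round(fraction * n))
    n_main = min(max(n_main, 1), n - 1)
    perm = rng.permutation(n)
    main = Cohort([cohort.subjects[i] for i in sorted(perm[:n_main])])
    held = Cohort([cohort.subjects[i] for i in sorted(perm[n_main:])])
    config = config or NpagConfig(seed=seed)
    rows = []
    for label, sub in (("full", cohort),
                       (f"{fraction:.0%}", main),
                       (f"{1 - fraction:.0%}", held)):
        if len(sub) < 3:
            warnings.warn(f"{label} split has only {len(sub)} subjects",
                          stacklevel=2)
        fit = run_npag(sub, model, space, config)
        mean, sd = fit.support.mean(), fit.support.sd()
        for j, nm in enumerate(model.param_names):
            rows.append({"parameter": nm, "cohort": label, "n_subjects":
                         len(sub), "mean": mean[j], "sd": sd[j]})
    return pd.DataFrame(rows)


def _time_after_last_dose(subject) -> np.ndarray:
    dose_times = np.array([d.time for d in subject.doses])
    out = []
    for o in subject.observations:
        prior = dose_times[dose_times <= o.time]
        out.append(o.time - prior.max() if prior.size else o.time)
    return np.array(out)


def vpc(result: NPAGResult, cohort: Cohort, n_sim: int = 1000,
        bins: int = 6, seed: int = 0) -> pd.DataFrame:
    """Visual-predictive-check table.

    ``n_sim`` cohort replicates are simulated at the observed design (same
    doses, times, covariates), sampling each subject's parameters from the
    fitted support by weight and the residual noise from the fitted error
    model.  Observations are binned by time after the last dose into
    quantile bins; the table reports the observed 5/50/95th percentiles and
    the 2.5/50/97.5 percentile band of each simulated percentile.
    """
    model = replace(result.model, error=result.error_final())
    cache = _LikCache(cohort, result.support.points, model, store_pred=True)
    err = result.error_final()
    rng = np.random.default_rng(seed)

    tald, y_obs, subj_slices = [], [], []
    for i, s in enumerate(cohort):
        obs = [o for o in s.observations if not o.blq]
        if not obs:
            subj_slices.append(None)
            continue
        mask = np.array([not o.blq for o in s.observations])
        t = _time_after_last_dose(s)[mask]
        tald.append(t)
        y_obs.append([o.concentration for o in obs])
        subj_slices.append(i)
    tald = np.concatenate(tald)
    y_obs = np.concatenate(y_obs)

    edges = np.quantile(tald, np.linspace(0, 1, bins + 1))
    edges = np.unique(edges)                      # merge degenerate bins
    edges[-1] += 1e-9
    bin_idx = np.clip(np.searchsorted(edges, tald, side="right") - 1,
                      0, len(edges) - 2)

    qs = (5.0, 50.0, 95.0)
    sim_perc = np.empty((n_sim, len(edges) - 1, len(qs)))
    for r in range(n_sim):
        sim_y = []
        for i, s in enumerate(cohort):
            if cache.preds[i].shape[1] == 0:
                continue
            j = rng.choice(result.support.K, p=result.support.weights)
            pred = cache.preds[i][j]
            sd = err.gamma * np.asarray(sd_of_observation(pred, err))
            sim_y.append(np.maximum(pred + sd * rng.standard_normal(pred.size),
                                    0.0))
        sim_y = np.concatenate(sim_y)
        for b in range(len(edges) - 1):
            sel = bin_idx == b
            sim_perc[r, b] = np.percentile(sim_y[sel], qs)

    rows = []
    for b in range(len(edges) - 1):
        sel = bin_idx == b
        row = {"bin": b, "t_lo": edges[b], "t_hi": edges[b + 1],
               "n_obs": int(sel.sum())}
        for k, q in enumerate(qs):
            row[f"obs_p{q:g}"] = float(np.percentile(y_obs[sel], q))
            band = sim_perc[:, b, k]
            row[f"sim_p{q:g}_lo"] = float(np.percentile(band, 2.5))
            row[f"sim_p{q:g}_mid"] = float(np.percentile(band, 50))
            row[f"sim_p{q:g}_hi"] = float(np.percentile(band, 97.5))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_sim"] = n_sim
    return out
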