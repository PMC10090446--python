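"""Nonparametric adaptive-grid (NPAG) population estimation.

The population distribution of the PK parameters is estimated
nonparametrically as a discrete distribution — K support points with
probabilities — maximizing the marginal likelihood

    L(F) = prod_i  sum_j  w_j p(y_i | theta_j),

which by Caratheodory/Lindsay theory needs no more support points than
subjects.  The adaptive-grid search alternates:

1. seed a scrambled low-discrepancy grid over the parameter box;
2. optimize the weights on the current grid by the multiplicative EM
   update (monotone, converges to the global optimum of this concave
   problem);
3. condense — drop points with negligible weight and merge near-duplicates;
4. expand — perturb each survivor by +/- a step Delta per dimension,
   halving Delta whenever a cycle stops improving, until Delta and the
   -2LL change both fall below tolerance.

The gamma error multiplier is re-optimized every cycle by a 1-D
golden-section search; because gamma enters the per-(subject, point)
log-likelihood only through cached residual statistics, this costs no
model re-evaluation.  If a cycle would worsen -2LL (possible only through
condensation round-off) the previous support is restored and the step is
halved, so the cycle log is non-increasing by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from scipy.stats import qmc

from .cohort import Cohort, Subject
from .covariates import CovariateModel, apply_covariates_theta
from .error import ErrorSpec, sd_of_observation
from .pk import PKParameters, predict_concentrations_many

__all__ = [
    "ModelSpec",
    "ParameterSpace",
    "SupportSet",
    "NpagConfig",
    "NPAGResult",
    "FitMetrics",
    "default_space",
    "likelihood_matrix",
    "optimize_weights",
    "run_npag",
    "posterior_subject",
    "posterior_table",
    "fit_metrics",
    "information_criteria",
]

_LOG_2PI = math.log(2.0 * math.pi)

_PARAM_NAMES = {1: ("CL", "Vc"), 2: ("CL", "Vc", "Q", "Vp")}

# default parameter box: covers the fitted means +/- >3 SD and the span of
# published polymyxin B models (CL 1.16-2.63 L/h, V 4-80 L)
_DEFAULT_BOUNDS = {"CL": (0.05, 8.0), "Vc": (1.0, 120.0),
                   "Q": (0.05, 30.0), "Vp": (1.0, 300.0)}


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate + error model choice for one fit."""

    compartments: int = 2
    covariates: CovariateModel = field(default_factory=CovariateModel)
    error: ErrorSpec = field(default_factory=ErrorSpec)

    def __post_init__(self) -> None:
        if self.compartments not in (1, 2):
            raise ValueError("compartments must be 1 or 2")

    @property
    def n_dim(self) -> int:
        return 2 * self.compartments

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.compartments]

    def with_covariates(self, cm: CovariateModel) -> "ModelSpec":
        return replace(self, covariates=cm)


@dataclass(frozen=True)
class ParameterSpace:
    """Search box: ordered names with elementwise lower < upper bounds."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if not (len(self.names) == lo.size == up.size):
            raise ValueError("names/lower/upper length mismatch")
        if not np.all(lo < up):
            raise ValueError("need lower < upper elementwise")

    @property
    def d(self) -> int:
        return len(self.names)

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower


def default_space(compartments: int = 2) -> ParameterSpace:
    names = _PARAM_NAMES[compartments]
    lo = np.array([_DEFAULT_BOUNDS[n][0] for n in names])
    up = np.array([_DEFAULT_BOUNDS[n][1] for n in names])
    return ParameterSpace(names, lo, up)


@dataclass
class SupportSet:
    """Discrete population distribution: (K, d) points with probabilities."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.shape[0] != self.weights.size:
            raise ValueError("points/weights length mismatch")
        if np.any(self.weights < -1e-12):
            raise ValueError("negative weight")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError(f"weights sum to {self.weights.sum()}, not 1")

    @property
    def K(self) -> int:
        return self.weights.size

    def mean(self) -> np.ndarray:
        return self.weights @ self.points

    def sd(self) -> np.ndarray:
        mu = self.mean()
        return np.sqrt(self.weights @ (self.points - mu) ** 2)

    def median(self) -> np.ndarray:
        """Per-parameter weighted median of the support."""
        out = np.empty(self.points.shape[1])
        for j in range(self.points.shape[1]):
            order = np.argsort(self.points[:, j])
            cw = np.cumsum(self.weights[order])
            out[j] = self.points[order, j][np.searchsorted(cw, 0.5)]
        return out


@dataclass(frozen=True)
class NpagConfig:
    """Adaptive-grid search budgets and tolerances.

    ``n_initial`` defaults to 512 per dimension (rounded to the Sobol
    power-of-two); tests and bootstrap replicates use smaller budgets.
    """

    n_initial: int | None = None
    max_cycles: int = 100
    tol: float = 0.01           # -2LL improvement regarded as "real"
    eps_w: float = 1e-8         # drop weight < eps_w * max weight
    eps_d: float = 1e-4         # merge points closer than eps_d * range
    delta_init: float = 0.2     # expansion step, fraction of range
    delta_min: float = 1e-4     # stop refining below this step
    n_explore: int = 32         # fresh quasi-random points injected per cycle
    n_diag: int = 50            # top-weight survivors given diagonal moves
    em_tol_search: float = 1e-7   # EM tolerance during search cycles
    em_max_iter_search: int = 500
    gamma_lo: float = 0.01
    gamma_hi: float = 50.0
    optimize_gamma: bool = True
    em_tol: float = 1e-10
    em_max_iter: int = 3000
    seed: int = 0


@dataclass
class NPAGResult:
    """Fit output: final support, fitted gamma, -2LL and the cycle trace."""

    support: SupportSet
    gamma_final: float
    neg2ll: float
    cycle_log: list[tuple[int, float, int, float]]   # (cycle, -2LL, K, delta)
    converged: bool
    model: ModelSpec
    space: ParameterSpace
    seed: int

    def error_final(self) -> ErrorSpec:
        return self.model.error.with_gamma(self.gamma_final)


@dataclass
class FitMetrics:
    """Model-comparison indices and per-parameter summary."""

    neg2ll: float
    aicc: float
    bic: float
    r2_pop: float
    r2_post: float
    params: "object"            # pandas DataFrame, one row per parameter
    k: int
    n_obs: int


# ---------------------------------------------------------------------------
# likelihood machinery


class _LikCache:
    """Per-(subject, support-point) residual statistics.

    The subject log-likelihood at error multiplier gamma is
    ``l_ij(gamma) = -R_ij / (2 gamma^2) - n_i log(gamma) + c_i`` where
    R_ij is the SD-standardized squared-residual sum, n_i the number of
    quantified observations, and c_i collects the gamma-free constants.
    Caching (R, n, c) makes the per-cycle gamma search free of model
    re-evaluation.
    """

    def __init__(self, cohort: Cohort, points: np.ndarray, model: ModelSpec,
                 store_pred: bool = False):
        N, K = len(cohort), points.shape[0]
        self.R = np.zeros((N, K))
        self.n = np.zeros(N)
        self.c = np.zeros(N)
        self.preds: list[np.ndarray] | None = [] if store_pred else None
        for i, s in enumerate(cohort):
            obs = [o for o in s.observations if not o.blq]
            if not obs:
                if store_pred:
                    self.preds.append(np.zeros((K, 0)))
                continue
            if model.covariates and s.covariates is None:
                raise ValueError(f"subject {s.id!r} lacks covariates required "
                                 f"by the covariate model")
            times = np.array([o.time for o in obs])
            y = np.array([o.concentration for o in obs])
            sd = np.asarray(sd_of_observation(y, model.error))
            theta = points[:, :model.n_dim]
            if model.covariates:
                theta = apply_covariates_theta(theta, s.covariates,
                                               model.covariates)
            pred = predict_concentrations_many(theta, s.doses, times)
            z = (y[None, :] - pred) / sd[None, :]
            self.R[i] = np.sum(z * z, axis=1)
            if not np.all(np.isfinite(self.R[i])):
                j = int(np.argmax(~np.isfinite(self.R[i])))
                raise FloatingPointError(
                    f"non-finite likelihood for subject {s.id!r} at support "
                    f"point {j}: {points[j]}")
            self.n[i] = len(obs)
            self.c[i] = float(np.sum(-np.log(sd))) - 0.5 * len(obs) * _LOG_2PI
            if store_pred:
                self.preds.append(pred)

    def loglik(self, gamma: float) -> np.ndarray:
        """(N, K) matrix of subject log-likelihoods at this gamma."""
        return (-0.5 * self.R / gamma**2
                - self.n[:, None] * math.log(gamma)
                + self.c[:, None])


def likelihood_matrix(cohort: Cohort, support, model: ModelSpec):
    """Row-scaled likelihood matrix P with exact log offsets.

    Returns ``(P, log_offsets)`` where ``P[i, j] = p(subject_i | theta_j)
    / exp(log_offsets[i])`` and each row's maximum is 1 (so -2LL can be
    recovered exactly while avoiding underflow).
    """
    points = support.points if isinstance(support, SupportSet) \
        else np.atleast_2d(np.asarray(support, dtype=float))
    cache = _LikCache(cohort, points, model)
    L = cache.loglik(model.error.gamma)
    off = L.max(axis=1)
    return np.exp(L - off[:, None]), off


def optimize_weights(P: np.ndarray, w0: np.ndarray | None = None,
                     tol: float = 1e-10, max_iter: int = 3000):
    """Maximize ``sum_i log(sum_j P_ij w_j)`` over the probability simplex.

    Multiplicative EM update ``w_j <- (w_j / N) * sum_i P_ij / (P w)_i``,
    which is monotone in the objective; iterated until the objective change
    falls below ``tol``.  Returns ``(weights, objective)``.
    """
    P = np.asarray(P, dtype=float)
    N, K = P.shape
    if np.any(P.max(axis=1) <= 0):
        bad = int(np.argmax(P.max(axis=1) <= 0))
        raise ValueError(f"row {bad} of the likelihood matrix is all zero "
                         "(subject unexplainable at any support point)")
    w = np.full(K, 1.0 / K) if w0 is None else np.asarray(w0, float) / np.sum(w0)
    obj_prev = -np.inf
    for _ in range(max_iter):
        Pw = P @ w
        obj = float(np.sum(np.log(Pw)))
        if obj - obj_prev < tol:
            break
        obj_prev = obj
        w = w * (P.T @ (1.0 / Pw)) / N
        w /= w.sum()
    return w, float(np.sum(np.log(P @ w)))


def _em_on_cache(cache: _LikCache, gamma: float, w0=None, tol=1e-10,
                 max_iter=3000):
    """EM weights on the cached log-likelihoods.

    Returns ``(w, total loglik, grad)`` with ``grad`` the per-point mixture
    directional derivative at the returned weights (used for support
    reduction)."""
    L = cache.loglik(gamma)
    off = L.max(axis=1)
    P = np.exp(L - off[:, None])
    w, obj = optimize_weights(P, w0=w0, tol=tol, max_iter=max_iter)
    grad = (P / (P @ w)[:, None]).mean(axis=0)
    return w, obj + float(off.sum()), grad


def _gamma_objective(cache: _LikCache, w: np.ndarray, gamma: float) -> float:
    L = cache.loglik(gamma)
    with np.errstate(divide="ignore"):
        lw = np.log(w)
    return float(np.sum(logsumexp(L + lw[None, :], axis=1)))


def _golden_gamma(cache: _LikCache, w: np.ndarray, lo: float, hi: float,
                  current: float, tol: float = 1e-4) -> float:
    """Golden-section maximization of the mixture log-likelihood in gamma
    (searched on the log scale; never returns a worse gamma than
    ``current``)."""
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = math.log(lo), math.log(hi)
    x1 = b - phi * (b - a)
    x2 = a + phi * (b - a)
    f1 = _gamma_objective(cache, w, math.exp(x1))
    f2 = _gamma_objective(cache, w, math.exp(x2))
    while b - a > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + phi * (b - a)
            f2 = _gamma_objective(cache, w, math.exp(x2))
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - phi * (b - a)
            f1 = _gamma_objective(cache, w, math.exp(x1))
    best = math.exp(0.5 * (a + b))
    if _gamma_objective(cache, w, best) < _gamma_objective(cache, w, current):
        return current
    return best


# ---------------------------------------------------------------------------
# adaptive-grid driver


def _condense(points, w, space, eps_w, eps_d, grad=None):
    """Support reduction: drop dominated and negligible points, then fold
    each point into a heavier point closer than ``eps_d`` of the range
    (locations unchanged).

    ``grad`` is the mixture directional derivative g_j = (1/N) sum_i
    P_ij/(Pw)_i; by the NPML optimality condition the optimal support has
    g_j = 1, so points with g_j clearly below 1 are dominated and removed
    even when the (slowly decaying) EM weight has not yet vanished.
    """
    keep = w >= eps_w * w.max()
    if grad is not None:
        keep &= (grad >= 1.0 - 1e-4) | (w >= 0.01 * w.max())
    if not keep.any():
        keep = w >= w.max()
    points, w = points[keep], w[keep]
    order = np.argsort(-w)
    points, w = points[order], w[order].copy()
    scale = space.range
    kept_idx: list[int] = []
    for j in range(len(w)):
        merged = False
        for ki in kept_idx:
            if np.max(np.abs(points[j] - points[ki]) / scale) < eps_d:
                w[ki] += w[j]
                merged = True
                break
        if not merged:
            kept_idx.append(j)
    points, w = points[kept_idx], w[kept_idx]
    return points, w / w.sum()


def _expand(points, w, space, delta, n_diag):
    """Survivors plus +/- delta*range moves: single-axis for every
    survivor, pairwise-diagonal for the ``n_diag`` heaviest (diagonal moves
    let the support track correlated-parameter ridges, e.g. CL-Vp).
    Out-of-box candidates are rejected, not clipped."""
    d = space.d
    cand = [points]

    def _push(base, cols, signs):
        p = base.copy()
        ok = np.ones(p.shape[0], dtype=bool)
        for j, s in zip(cols, signs):
            p[:, j] += s * delta * space.range[j]
            ok &= (p[:, j] > space.lower[j]) & (p[:, j] < space.upper[j])
        if ok.any():
            cand.append(p[ok])

    for j in range(d):
        for sgn in (1.0, -1.0):
            _push(points, (j,), (sgn,))
    top = points[np.argsort(-w)[:n_diag]]
    for j in range(d):
        for k in range(j + 1, d):
            for sj in (1.0, -1.0):
                for sk in (1.0, -1.0):
                    _push(top, (j, k), (sj, sk))
    return np.vstack(cand)


def run_npag(cohort: Cohort, model: ModelSpec, space: ParameterSpace | None = None,
             config: NpagConfig | None = None,
             init_points: np.ndarray | None = None) -> NPAGResult:
    """Fit the nonparametric population distribution by the adaptive grid.

    Returns the best support found with its weights, the per-cycle -2LL
    trace (non-increasing), and the re-optimized gamma.  ``converged`` is
    False when ``max_cycles`` ran out before the step and -2LL tolerances
    were both met.

    ``init_points`` (K0, d) seeds the grid with known-good locations in
    addition to the quasi-random sweep — used to warm-start refits of
    nested models (covariate steps, bootstrap replicates), which both
    speeds convergence and cancels search noise out of -2LL differences.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    space = space or default_space(model.compartments)
    config = config or NpagConfig()
    if space.d != model.n_dim:
        raise ValueError(f"space dimension {space.d} != model dimension "
                         f"{model.n_dim}")
    n0 = config.n_initial or 512 * space.d
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler = qmc.Sobol(d=space.d, scramble=True, seed=config.seed)
        points = qmc.scale(sampler.random(n0), space.lower, space.upper)
    if init_points is not None:
        init = np.atleast_2d(np.asarray(init_points, dtype=float))
        init = np.clip(init, space.lower + 1e-12 * space.range,
                       space.upper - 1e-12 * space.range)
        points = np.vstack([init, points])
    gamma = model.error.gamma
    delta = config.delta_init
    w = None
    prev = np.inf
    cycle_log: list[tuple[int, float, int, float]] = []
    best = None
    converged = False

    for cycle in range(1, config.max_cycles + 1):
        cache = _LikCache(cohort, points, model)
        w, obj, grad = _em_on_cache(cache, gamma, w0=w,
                                    tol=config.em_tol_search,
                                    max_iter=config.em_max_iter_search)
        if config.optimize_gamma:
            gamma = _golden_gamma(cache, w, config.gamma_lo, config.gamma_hi,
                                  gamma)
            w, obj, grad = _em_on_cache(cache, gamma, w0=w,
                                        tol=config.em_tol_search,
                                        max_iter=config.em_max_iter_search)
        neg2ll = -2.0 * obj
        if best is not None and neg2ll > prev + 1e-9:
            # revert to the previous support; tighten the step
            points, w, gamma = (best[0].copy(), best[1].copy(), best[2])
            grad = None
            neg2ll = prev
            improved = 0.0
            delta *= 0.5
        else:
            improved = prev - neg2ll
            prev = neg2ll
        cycle_log.append((cycle, neg2ll, points.shape[0], delta))
        points, w = _condense(points, w, space, config.eps_w, config.eps_d,
                              grad=grad)
        best = (points.copy(), w.copy(), gamma)
        if improved < config.tol:
            delta *= 0.5
        else:
            # still improving: re-open the search radius
            delta = min(2.0 * delta, config.delta_init)
        if delta < config.delta_min and improved < config.tol:
            converged = True
            break
        survivors = points
        points = _expand(survivors, w, space, delta, config.n_diag)
        if config.n_explore > 0:
            # continue the scrambled low-discrepancy sequence: global
            # exploration lets the support escape correlated-parameter ridges
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fresh = qmc.scale(sampler.random(config.n_explore),
                                  space.lower, space.upper)
            points = np.vstack([points, fresh])
        # warm start: keep most of the mass on the survivors
        k_new = points.shape[0] - survivors.shape[0]
        if k_new > 0:
            w = np.concatenate([0.8 * w, np.full(k_new, 0.2 / k_new)])

    # final polish: tight EM (and one more gamma pass) on the best support
    points, w, gamma = best
    cache = _LikCache(cohort, points, model)
    w, obj, _ = _em_on_cache(cache, gamma, w0=w, tol=config.em_tol,
                             max_iter=config.em_max_iter)
    if config.optimize_gamma:
        gamma = _golden_gamma(cache, w, config.gamma_lo, config.gamma_hi, gamma)
        w, obj, _ = _em_on_cache(cache, gamma, w0=w, tol=config.em_tol,
                                 max_iter=config.em_max_iter)
    prev = min(prev, -2.0 * obj)
    support = SupportSet(points, w)
    return NPAGResult(support=support, gamma_final=gamma, neg2ll=prev,
                      cycle_log=cycle_log, converged=converged, model=model,
                      space=space, seed=config.seed)


def polish_support(cohort: Cohort, model: ModelSpec, points: np.ndarray,
                   space: ParameterSpace, config: NpagConfig | None = None,
                   gamma: float | None = None) -> NPAGResult:
    """Optimize weights and gamma on a FIXED candidate point set.

    No grid search: one tight EM pass, a golden-section gamma pass, a
    second EM pass, then weight-based condensation.  Used to compare
    nested models on the union of the supports their searches discovered,
    which removes search-depth asymmetry from likelihood differences.
    """
    config = config or NpagConfig()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pts = np.clip(pts, space.lower + 1e-12 * space.range,
                  space.upper - 1e-12 * space.range)
    pts = np.unique(pts, axis=0)
    gamma = model.error.gamma if gamma is None else gamma
    cache = _LikCache(cohort, pts, model)
    w, obj, grad = _em_on_cache(cache, gamma, tol=config.em_tol,
                                max_iter=config.em_max_iter)
    if config.optimize_gamma:
        gamma = _golden_gamma(cache, w, config.gamma_lo, config.gamma_hi,
                              gamma)
        w, obj, grad = _em_on_cache(cache, gamma, w0=w, tol=config.em_tol,
                                    max_iter=config.em_max_iter)
    pts, w = _condense(pts, w, space, config.eps_w, config.eps_d, grad=grad)
    neg2ll = -2.0 * obj
    return NPAGResult(support=SupportSet(pts, w), gamma_final=gamma,
                      neg2ll=neg2ll,
                      cycle_log=[(1, neg2ll, pts.shape[0], 0.0)],
                      converged=True, model=model, space=space,
                      seed=config.seed)


# ---------------------------------------------------------------------------
# posteriors and fit indices


def posterior_subject(result: NPAGResult, subject: Subject):
    """Posterior distribution of one subject over the fitted support.

    Returns ``(posterior_weights, posterior_mean)`` with the mean as
    :class:`PKParameters` on the *base* parameter scale (covariate factors
    not folded in).  A subject with no quantified observations recovers the
    population weights.
    """
    model = replace(result.model, error=result.error_final())
    one = Cohort([subject])
    cache = _LikCache(one, result.support.points, model)
    L = cache.loglik(result.gamma_final)[0]
    logw = L + np.log(np.maximum(result.support.weights, 1e-300))
    logw -= logsumexp(logw)
    pw = np.exp(logw)
    pw /= pw.sum()
    theta = pw @ result.support.points
    params = (PKParameters(*theta) if theta.size == 4
              else PKParameters(theta[0], theta[1]))
    return pw, params


def posterior_table(result: NPAGResult, cohort: Cohort):
    """DataFrame of posterior-mean base parameters, indexed by subject id."""
    import pandas as pd

    rows = {}
    for s in cohort:
        _, pm = posterior_subject(result, s)
        rows[s.id] = dict(zip(result.model.param_names, pm.as_array()))
    return pd.DataFrame.from_dict(rows, orient="index")


def information_criteria(neg2ll: float, k: int, n: int) -> tuple[float, float]:
    """Small-sample AIC (AICc) and BIC from a -2LL value.

    ``k`` counts the fitted dimensions (structural parameters + 1 for
    gamma); ``n`` is the number of quantified observations.  AICc requires
    ``n > k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    aicc = neg2ll + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    bic = neg2ll + k * math.log(n)
    return aicc, bic


def _predictions(result: NPAGResult, cohort: Cohort):
    """Per-subject (K, n_i) prediction arrays plus observed vectors."""
    model = replace(result.model, error=result.error_final())
    cache = _LikCache(cohort, result.support.points, model, store_pred=True)
    return cache


def fit_metrics(result: NPAGResult, cohort: Cohort,
                model: ModelSpec | None = None) -> FitMetrics:
    """Fit indices (AICc/BIC with k = structural dims + 1 for gamma),
    population and posterior R^2, and the per-parameter summary table
    (weighted mean/median/SD, CV%, shrinkage%)."""
    import pandas as pd

    model = model or result.model
    k = model.n_dim + 1
    n = cohort.n_obs_quantified
    aicc, bic = information_criteria(result.neg2ll, k, n)

    cache = _predictions(result, cohort)
    w = result.support.weights
    obs_all, pop_all, post_all = [], [], []
    post_means = []
    for i, s in enumerate(cohort):
        obs = [o for o in s.observations if not o.blq]
        pw, pm = posterior_subject(result, s)
        post_means.append(pm.as_array())
        if not obs:
            continue
        y = np.array([o.concentration for o in obs])
        pred = cache.preds[i]
        obs_all.append(y)
        pop_all.append(w @ pred)
        post_all.append(pw @ pred)
    y = np.concatenate(obs_all)
    pop = np.concatenate(pop_all)
    post = np.concatenate(post_all)

    def _r2(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 1.0 if np.allclose(a, b) else 0.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    r2_pop = _r2(y, pop)
    r2_post = _r2(y, post)

    mean = result.support.mean()
    sd = result.support.sd()
    median = result.support.median()
    cv = 100.0 * sd / mean
    pm_sd = np.std(np.array(post_means), axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = 100.0 * (1.0 - pm_sd / np.where(sd > 0, sd, np.nan))
    params = pd.DataFrame(
        {"mean": mean, "median": median, "sd": sd, "cv_pct": cv,
         "shrinkage_pct": shrink}, index=list(model.param_names))
    return FitMetrics(neg2ll=result.neg2ll, aicc=aicc, bic=bic,
                      r2_pop=r2_pop, r2_post=r2_post, params=params,
                      k=k, n_obs=n)
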