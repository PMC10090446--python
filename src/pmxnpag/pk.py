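"""One- and two-compartment intravenous-infusion models.

The two-compartment disposition is

    dX1/dt = R(t) - (CL/Vc + Q/Vc) X1 + (Q/Vp) X2
    dX2/dt = (Q/Vc) X1 - (Q/Vp) X2

with X1/X2 the central/peripheral amounts (mg), R(t) the piecewise-constant
infusion rate (mg/h), and the predicted concentration C(t) = X1(t)/Vc.

Solutions are propagated analytically segment by segment: the timeline is
split at every infusion start/stop and query time, and within a segment the
affine ODE ``dX/dt = A X + b`` has the exact solution

    X(t0 + tau) = Xss + exp(A tau) (X0 - Xss),    Xss = -A^{-1} b,

with ``exp(A tau)`` evaluated from the (real, distinct) eigenvalues of the
2x2 disposition matrix.  No numerical ODE solver is involved; adaptive
integration is used only as an independent oracle in the test suite.

Units are fixed throughout the package: mg, L, h, mg/L, mg·h/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import DoseEvent

try:                                        # optional JIT speedup
    from numba import njit as _njit
except ImportError:                         # pragma: no cover
    _njit = None

__all__ = [
    "PKParameters",
    "Regimen",
    "predict_concentrations",
    "predict_one_compartment",
    "predict_concentrations_many",
    "predict_amounts",
    "steady_state_auc24",
    "regimen_doses",
]


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters: clearance CL (L/h), central volume Vc (L),
    inter-compartmental clearance Q (L/h) and peripheral volume Vp (L).
    Q and Vp are ``None`` for the one-compartment model."""

    CL: float
    Vc: float
    Q: float | None = None
    Vp: float | None = None

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.Vc > 0):
            raise ValueError(f"CL and Vc must be > 0, got CL={self.CL}, Vc={self.Vc}")
        if (self.Q is None) != (self.Vp is None):
            raise ValueError("Q and Vp must both be given or both omitted")
        if self.Q is not None and not (self.Q > 0 and self.Vp > 0):
            raise ValueError(f"Q and Vp must be > 0, got Q={self.Q}, Vp={self.Vp}")

    @property
    def n_compartments(self) -> int:
        return 1 if self.Q is None else 2

    def as_array(self) -> np.ndarray:
        if self.Q is None:
            return np.array([self.CL, self.Vc])
        return np.array([self.CL, self.Vc, self.Q, self.Vp])


@dataclass(frozen=True)
class Regimen:
    """An intermittent-infusion schedule: optional loading dose then
    ``maintenance_dose`` mg every ``interval`` h over ``infusion_duration`` h."""

    maintenance_dose: float
    loading_dose: float = 0.0
    interval: float = 12.0
    infusion_duration: float = 1.0

    def __post_init__(self) -> None:
        if not (self.interval > self.infusion_duration > 0):
            raise ValueError("need interval > infusion_duration > 0")
        if self.maintenance_dose < 0 or self.loading_dose < 0:
            raise ValueError("doses must be >= 0")


def regimen_doses(regimen: Regimen, n_doses: int) -> list[DoseEvent]:
    """Expand a regimen into explicit dose events (dose 0 is the loading
    dose when one is set, otherwise a maintenance dose)."""
    out = []
    for k in range(n_doses):
        amt = regimen.loading_dose if (k == 0 and regimen.loading_dose > 0) \
            else regimen.maintenance_dose
        out.append(DoseEvent(k * regimen.interval, amt, regimen.infusion_duration))
    return out


def _rate_schedule(doses: list[DoseEvent]):
    """Breakpoints and per-segment total infusion rates.

    Returns (bounds, rates): ``bounds`` of length m+1, ``rates`` of length m
    with the summed rate of all active infusions on each segment (overlapping
    infusions add).
    """
    pts = {0.0}
    for d in doses:
        pts.add(d.time)
        pts.add(d.end)
    bounds = np.array(sorted(pts))
    rates = np.zeros(len(bounds) - 1)
    for d in doses:
        if d.amount == 0:
            continue
        i0 = np.searchsorted(bounds, d.time)
        i1 = np.searchsorted(bounds, d.end)
        rates[i0:i1] += d.rate
    return bounds, rates


def _propagate_py(theta, merged, seg_rate, q_idx, out):
    """Per-segment analytic propagation, vectorized over the K parameter
    rows (numpy fallback; the numba version runs scalar per-point loops)."""
    K = theta.shape[0]
    CL, Vc = theta[:, 0], theta[:, 1]
    two_cpt = theta.shape[1] == 4
    n_times = out.shape[1]
    if two_cpt:
        Q, Vp = theta[:, 2], theta[:, 3]
        a11 = -(CL + Q) / Vc
        a12 = Q / Vp
        a21 = Q / Vc
        a22 = -Q / Vp
        tr = a11 + a22
        det = CL * Q / (Vc * Vp)
        disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
        lam1 = 0.5 * (tr + disc)
        lam2 = 0.5 * (tr - disc)
        dl = np.where(np.abs(lam1 - lam2) < 1e-12, 1e-12, lam1 - lam2)
        X1 = np.zeros(K)
        X2 = np.zeros(K)
    else:
        kel = CL / Vc
        X1 = np.zeros(K)

    q_ptr = 0
    while q_ptr < n_times and q_idx[q_ptr] == 0:
        out[:, q_ptr] = X1 / Vc
        q_ptr += 1
    for seg in range(len(merged) - 1):
        tau = merged[seg + 1] - merged[seg]
        R = seg_rate[seg]
        if tau > 0:
            if two_cpt:
                if R > 0:
                    xss1 = R * Vc / CL
                    xss2 = R * Vp / CL
                else:
                    xss1 = xss2 = 0.0
                y1 = X1 - xss1
                y2 = X2 - xss2
                e1 = np.exp(lam1 * tau)
                e2 = np.exp(lam2 * tau)
                c_a = (e1 - e2) / dl
                c_i = (lam1 * e2 - lam2 * e1) / dl
                z1 = (c_a * a11 + c_i) * y1 + c_a * a12 * y2
                z2 = c_a * a21 * y1 + (c_a * a22 + c_i) * y2
                X1 = xss1 + z1
                X2 = xss2 + z2
            else:
                xss = (R / kel) if R > 0 else 0.0
                X1 = xss + np.exp(-kel * tau) * (X1 - xss)
        while q_ptr < n_times and q_idx[q_ptr] == seg + 1:
            out[:, q_ptr] = X1 / Vc
            q_ptr += 1


if _njit is not None:
    @_njit(cache=True, fastmath=False)
    def _propagate_nb(theta, merged, seg_rate, q_idx, out):   # pragma: no cover
        K, dp = theta.shape
        n_seg = merged.shape[0] - 1
        n_times = out.shape[1]
        two_cpt = dp == 4
        for k in range(K):
            CL = theta[k, 0]
            Vc = theta[k, 1]
            if two_cpt:
                Q = theta[k, 2]
                Vp = theta[k, 3]
                a11 = -(CL + Q) / Vc
                a12 = Q / Vp
                a21 = Q / Vc
                a22 = -Q / Vp
                tr = a11 + a22
                det = CL * Q / (Vc * Vp)
                d2 = tr * tr - 4.0 * det
                disc = np.sqrt(d2) if d2 > 0.0 else 0.0
                lam1 = 0.5 * (tr + disc)
                lam2 = 0.5 * (tr - disc)
                dl = lam1 - lam2
                if abs(dl) < 1e-12:
                    dl = 1e-12
            else:
                kel = CL / Vc
            x1 = 0.0
            x2 = 0.0
            q_ptr = 0
            while q_ptr < n_times and q_idx[q_ptr] == 0:
                out[k, q_ptr] = x1 / Vc
                q_ptr += 1
            for seg in range(n_seg):
                tau = merged[seg + 1] - merged[seg]
                R = seg_rate[seg]
                if tau > 0.0:
                    if two_cpt:
                        if R > 0.0:
                            xss1 = R * Vc / CL
                            xss2 = R * Vp / CL
                        else:
                            xss1 = 0.0
                            xss2 = 0.0
                        y1 = x1 - xss1
                        y2 = x2 - xss2
                        e1 = np.exp(lam1 * tau)
                        e2 = np.exp(lam2 * tau)
                        c_a = (e1 - e2) / dl
                        c_i = (lam1 * e2 - lam2 * e1) / dl
                        x1 = xss1 + (c_a * a11 + c_i) * y1 + c_a * a12 * y2
                        x2 = xss2 + c_a * a21 * y1 + (c_a * a22 + c_i) * y2
                    else:
                        xss = R / kel if R > 0.0 else 0.0
                        x1 = xss + np.exp(-kel * tau) * (x1 - xss)
                while q_ptr < n_times and q_idx[q_ptr] == seg + 1:
                    out[k, q_ptr] = x1 / Vc
                    q_ptr += 1
else:                                       # pragma: no cover
    _propagate_nb = None


def predict_concentrations_many(theta: np.ndarray, doses: list[DoseEvent],
                                times: np.ndarray) -> np.ndarray:
    """Predict central concentrations for K parameter vectors at once.

    Parameters
    ----------
    theta
        (K, 4) array of (CL, Vc, Q, Vp) rows, or (K, 2) of (CL, V) for the
        one-compartment model.  All entries must be strictly positive.
    doses, times
        Shared dosing history and sorted query times (hours).

    Returns
    -------
    (K, len(times)) array of concentrations in mg/L.
    """
    theta = np.asarray(theta, dtype=float)
    times = np.asarray(times, dtype=float)
    if theta.ndim != 2 or theta.shape[1] not in (2, 4):
        raise ValueError("theta must be (K, 2) or (K, 4)")
    if np.any(theta <= 0):
        raise ValueError("all PK parameters must be strictly positive")
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise ValueError("times must be sorted and non-negative")
    K = theta.shape[0]
    out = np.zeros((K, times.size))
    if not doses or times.size == 0:
        return out

    bounds, rates = _rate_schedule(doses)
    # merge query times into the breakpoint sequence
    merged = np.union1d(bounds, times)
    merged = merged[merged >= 0]
    seg_rate = np.zeros(len(merged) - 1)
    idx = np.clip(np.searchsorted(bounds, merged[:-1], side="right") - 1,
                  0, len(rates) - 1)
    inside = (merged[:-1] >= bounds[0]) & (merged[:-1] < bounds[-1])
    seg_rate[inside] = rates[idx[inside]]
    q_idx = np.searchsorted(merged, times).astype(np.int64)

    if _propagate_nb is not None:
        _propagate_nb(np.ascontiguousarray(theta), merged, seg_rate, q_idx, out)
    else:
        _propagate_py(theta, merged, seg_rate, q_idx, out)
    # non-negativity guard against round-off at near-zero states
    np.maximum(out, 0.0, out=out)
    return out


def predict_concentrations(params: PKParameters, doses: list[DoseEvent],
                           times) -> np.ndarray:
    """Two-compartment concentration prediction at sorted query times."""
    if params.n_compartments != 2:
        raise ValueError("two-compartment parameters required; use "
                         "predict_one_compartment for the 1-compartment model")
    theta = params.as_array()[None, :]
    return predict_concentrations_many(theta, doses, np.asarray(times, float))[0]


def predict_one_compartment(params: PKParameters, doses: list[DoseEvent],
                            times) -> np.ndarray:
    """One-compartment concentration prediction (CL, V only)."""
    if params.n_compartments != 1:
        raise ValueError("one-compartment parameters required (Q, Vp absent)")
    theta = params.as_array()[None, :]
    return predict_concentrations_many(theta, doses, np.asarray(times, float))[0]


def predict_amounts(params: PKParameters, doses: list[DoseEvent],
                    times) -> tuple[np.ndarray, np.ndarray]:
    """Central and peripheral amounts X1, X2 (mg) at sorted query times.

    Same analytic propagation as the concentration path; used mainly for
    mass-balance verification.  X2 is all-zero for the one-compartment
    model.
    """
    times = np.asarray(times, dtype=float)
    x1 = np.zeros(times.size)
    x2 = np.zeros(times.size)
    if not doses or times.size == 0:
        return x1, x2
    bounds, rates = _rate_schedule(doses)
    merged = np.union1d(bounds, times)
    merged = merged[merged >= 0]
    seg_rate = np.zeros(len(merged) - 1)
    idx = np.clip(np.searchsorted(bounds, merged[:-1], side="right") - 1,
                  0, len(rates) - 1)
    inside = (merged[:-1] >= bounds[0]) & (merged[:-1] < bounds[-1])
    seg_rate[inside] = rates[idx[inside]]
    q_idx = np.searchsorted(merged, times)

    CL, Vc = params.CL, params.Vc
    two = params.n_compartments == 2
    if two:
        Q, Vp = params.Q, params.Vp
        a11, a12 = -(CL + Q) / Vc, Q / Vp
        a21, a22 = Q / Vc, -Q / Vp
        tr, det = a11 + a22, CL * Q / (Vc * Vp)
        disc = math.sqrt(max(tr * tr - 4 * det, 0.0))
        lam1, lam2 = 0.5 * (tr + disc), 0.5 * (tr - disc)
        dl = lam1 - lam2 if abs(lam1 - lam2) > 1e-12 else 1e-12
    X1 = X2 = 0.0
    q = 0
    while q < times.size and q_idx[q] == 0:
        q += 1
    for seg in range(len(merged) - 1):
        tau = merged[seg + 1] - merged[seg]
        R = seg_rate[seg]
        if tau > 0:
            if two:
                xss1 = R * Vc / CL if R > 0 else 0.0
                xss2 = R * Vp / CL if R > 0 else 0.0
                y1, y2 = X1 - xss1, X2 - xss2
                e1, e2 = math.exp(lam1 * tau), math.exp(lam2 * tau)
                c_a = (e1 - e2) / dl
                c_i = (lam1 * e2 - lam2 * e1) / dl
                X1 = xss1 + (c_a * a11 + c_i) * y1 + c_a * a12 * y2
                X2 = xss2 + c_a * a21 * y1 + (c_a * a22 + c_i) * y2
            else:
                kel = CL / Vc
                xss = R / kel if R > 0 else 0.0
                X1 = xss + math.exp(-kel * tau) * (X1 - xss)
        while q < times.size and q_idx[q] == seg + 1:
            x1[q], x2[q] = X1, X2
            q += 1
    return x1, x2


def steady_state_auc24(params: PKParameters, regimen: Regimen) -> float:
    """24-h steady-state AUC (mg·h/L) under an intermittent q-``interval``
    schedule.

    For linear PK this is the daily maintenance dose divided by clearance:
    ``(24/interval) * maintenance_dose / CL``.  The loading dose does not
    affect steady state.
    """
    return (24.0 / regimen.interval) * regimen.maintenance_dose / params.CL
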