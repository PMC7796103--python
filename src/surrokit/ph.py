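"""Proportional-hazards diagnostics between PFS and OS within an arm.

The two endpoints of the same arm are stacked into one sample with a
binary endpoint indicator (0 = OS, 1 = PFS) and compared by a Cox model
for that single covariate.  The partial likelihood uses Breslow's tie
handling -- reconstructed pseudo-IPD carries heavy ties at the digitized
step times -- and is maximized by Newton iteration.  Note the stacking
counts each patient in both endpoint groups with no within-patient
correlation adjustment; this mirrors the pragmatic PFS-vs-OS comparison
the analysis is built around and is documented as a limitation.

Proportionality is checked with the scaled-Schoenfeld-residual test of
Grambsch & Therneau, implemented as the score test for the coefficient of
an interaction between the covariate and a transform of time, evaluated
at the PH fit (for a single covariate the two formulations coincide).
The default time transform is the Kaplan-Meier-based g(t) = 1 - S(t-) of
the stacked sample.  When proportionality fails, time-dependent Cox
models with covariate effect b0 + b1 * g(t) are fit for a fixed candidate
set of transforms and the best model (including the PH model itself) is
chosen by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence

import numpy as np
from scipy import optimize, stats

from .types import PHDiagnostics, PseudoIPD, TimeFunction, ValidationError
from .endpoints import km_estimate

_TIME_FNS: Dict[TimeFunction, Callable[[np.ndarray], np.ndarray]] = {
    TimeFunction.LINEAR: lambda t: t,
    TimeFunction.LOG: lambda t: np.log(t),
    TimeFunction.STEP6MO: lambda t: (t >= 6.0).astype(float),
}


@dataclass(frozen=True)
class StackedSample:
    """PFS and OS records of one arm in a single sample."""

    arm_id: str
    times: np.ndarray
    events: np.ndarray
    group: np.ndarray  # 0 = OS, 1 = PFS

    def __len__(self) -> int:
        return len(self.times)


def stack_endpoints(os_ipd: PseudoIPD, pfs_ipd: PseudoIPD) -> StackedSample:
    if os_ipd.arm_id != pfs_ipd.arm_id:
        raise ValidationError(
            f"arm mismatch: {os_ipd.arm_id} vs {pfs_ipd.arm_id}"
        )
    times = np.concatenate((os_ipd.times, pfs_ipd.times))
    events = np.concatenate((os_ipd.events, pfs_ipd.events))
    group = np.concatenate(
        (np.zeros(len(os_ipd), dtype=float), np.ones(len(pfs_ipd), dtype=float))
    )
    return StackedSample(arm_id=os_ipd.arm_id, times=times, events=events,
                         group=group)


@dataclass(frozen=True)
class _RiskTable:
    """Per distinct event time: total/group-1 events and at-risk counts."""

    times: np.ndarray
    d: np.ndarray
    d1: np.ndarray
    n0: np.ndarray
    n1: np.ndarray


def _risk_table(s: StackedSample) -> _RiskTable:
    ev_times = np.unique(s.times[s.events])
    if len(ev_times) == 0:
        raise ValidationError("no events in the stacked sample")
    is1 = s.group == 1
    ev1_t = np.sort(s.times[s.events & is1])
    ev0_t = np.sort(s.times[s.events & ~is1])
    d1 = (np.searchsorted(ev1_t, ev_times, side="right")
          - np.searchsorted(ev1_t, ev_times, side="left")).astype(float)
    d0 = (np.searchsorted(ev0_t, ev_times, side="right")
          - np.searchsorted(ev0_t, ev_times, side="left")).astype(float)
    d = d0 + d1
    t1 = np.sort(s.times[is1])
    t0 = np.sort(s.times[~is1])
    n1 = (len(t1) - np.searchsorted(t1, ev_times, side="left")).astype(float)
    n0 = (len(t0) - np.searchsorted(t0, ev_times, side="left")).astype(float)
    if (d1.sum() == 0) or (d1.sum() == d.sum()):
        raise ValidationError("each endpoint group needs at least one event")
    return _RiskTable(times=ev_times, d=d, d1=d1, n0=n0, n1=n1)


def _loglik(rt: _RiskTable, eta: np.ndarray) -> float:
    """Breslow partial log-likelihood with group-1 linear predictor eta(t)."""
    return float(np.sum(rt.d1 * eta - rt.d * np.log(rt.n0 + rt.n1 * np.exp(eta))))


def _fit_ph(rt: _RiskTable, tol: float = 1e-8, max_iter: int = 50) -> float:
    beta = 0.0
    for _ in range(max_iter):
        e = np.exp(beta)
        denom = rt.n0 + rt.n1 * e
        xbar = rt.n1 * e / denom
        score = float(np.sum(rt.d1 - rt.d * xbar))
        info = float(np.sum(rt.d * xbar * (1.0 - xbar)))
        if info <= 0:
            raise ValidationError("monotone partial likelihood; no Cox fit")
        step = score / info
        beta += step
        if abs(step) < tol:
            return beta
    raise ValidationError("Cox Newton iteration did not converge")


def _km_transform(s: StackedSample, ev_times: np.ndarray) -> np.ndarray:
    """g(t) = 1 - S(t-) of the stacked sample, the cox.zph 'km' scaling."""
    from .types import Endpoint  # local import to avoid cycle noise

    km = km_estimate(PseudoIPD(arm_id=s.arm_id, endpoint=Endpoint.OS,
                               times=s.times, events=s.events))
    # left-continuous evaluation: S just before each event time
    idx = np.searchsorted(km.event_times, ev_times, side="left") - 1
    s_minus = np.where(idx >= 0, np.concatenate(([1.0], km.survival))[idx + 1], 1.0)
    return 1.0 - s_minus


def cox_ph_test(s: StackedSample, alpha: float = 0.05) -> PHDiagnostics:
    """Cox fit of the endpoint indicator plus the Schoenfeld-residual test."""
    rt = _risk_table(s)
    beta = _fit_ph(rt)
    e = np.exp(beta)
    denom = rt.n0 + rt.n1 * e
    xbar = rt.n1 * e / denom
    v = rt.d * xbar * (1.0 - xbar)          # per-time information
    resid = rt.d1 - rt.d * xbar             # summed Schoenfeld residual per time
    g = _km_transform(s, rt.times)
    u1 = float(np.sum(g * resid))
    i11 = float(np.sum(v))
    i12 = float(np.sum(g * v))
    i22 = float(np.sum(g * g * v))
    denom_info = i22 - i12**2 / i11
    if denom_info <= 0:
        p = 1.0
    else:
        chi2 = u1**2 / denom_info
        p = float(stats.chi2.sf(chi2, df=1))
    return PHDiagnostics(log_hr=beta, schoenfeld_p=p, ph_holds=p >= alpha)


def _fit_td(rt: _RiskTable, g: np.ndarray) -> tuple:
    """Maximize the 2-parameter likelihood with eta(t) = b0 + b1 g(t)."""

    def negll(b):
        return -_loglik(rt, b[0] + b[1] * g)

    def grad(b):
        eta = b[0] + b[1] * g
        e = np.exp(eta)
        xbar = rt.n1 * e / (rt.n0 + rt.n1 * e)
        r = rt.d1 - rt.d * xbar
        return -np.array([np.sum(r), np.sum(g * r)])

    res = optimize.minimize(negll, x0=np.zeros(2), jac=grad, method="BFGS",
                            options={"gtol": 1e-9, "maxiter": 200})
    if not res.success and np.linalg.norm(grad(res.x)) > 1e-4:
        raise ValidationError(f"time-dependent Cox fit did not converge: {res.message}")
    return res.x, -res.fun


def time_dependent_hr(
    s: StackedSample,
    candidates: Sequence[TimeFunction] = (
        TimeFunction.LINEAR, TimeFunction.LOG, TimeFunction.STEP6MO,
    ),
    alpha: float = 0.05,
    hr_grid_step: float = 1.0,
) -> PHDiagnostics:
    """Fit candidate time-dependent models and choose by AIC.

    The PH model participates as the 1-parameter candidate ``none``; its
    AIC equals that of any interaction model with b1 pinned at 0 plus the
    2-point penalty for the extra parameter, so the comparison is fair.
    HR(t) is emitted on a monthly grid only when the chosen model is
    time-dependent.
    """
    base = cox_ph_test(s, alpha=alpha)
    rt = _risk_table(s)
    ll_ph = _loglik(rt, np.full(len(rt.times), base.log_hr))
    aics: Dict[str, float] = {TimeFunction.NONE.value: 2.0 * 1 - 2.0 * ll_ph}
    fits: Dict[str, tuple] = {}
    for cand in candidates:
        g = _TIME_FNS[cand](rt.times)
        coef, ll = _fit_td(rt, g)
        aics[cand.value] = 2.0 * 2 - 2.0 * ll
        fits[cand.value] = coef
    chosen = min(aics, key=aics.get)
    chosen_fn = TimeFunction(chosen)
    hr_t = None
    if chosen_fn is not TimeFunction.NONE and not base.ph_holds:
        b0, b1 = fits[chosen]
        tmax = float(s.times.max())
        tt = np.arange(hr_grid_step, tmax + 1e-9, hr_grid_step)
        hr = np.exp(b0 + b1 * _TIME_FNS[chosen_fn](tt))
        hr_t = np.column_stack((tt, hr))
    return PHDiagnostics(
        log_hr=base.log_hr, schoenfeld_p=base.schoenfeld_p,
        ph_holds=base.ph_holds, chosen_time_fn=chosen_fn,
        aic_by_model=aics, hr_t=hr_t,
    )


def nonph_fraction(diagnostics: Sequence[PHDiagnostics]) -> float:
    """Percentage of arms violating proportionality, to one decimal."""
    if len(diagnostics) == 0:
        raise ValidationError("at least one arm is required")
    frac = sum(1 for d in diagnostics if not d.ph_holds) / len(diagnostics)
    return round(100.0 * frac, 1)
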