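"""Kaplan-Meier estimation and the endpoint statistics the surrogacy
analysis consumes: survival quantiles, restricted mean survival time at
fixed horizons, and the survival rate at a time point.

All confidence intervals are 95% two-sided.  Quantiles use the infimum
crossing convention (first event time with S-hat <= 1 - q) and invert the
complementary log-log pointwise band, the standard Brookmeyer-Crowley
construction for step functions.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .types import KMCurve, PseudoIPD, QuantileEstimate, RMSTEstimate, ValidationError

_Z = stats.norm.ppf(0.975)
QUANTILE_LEVELS = (0.25, 0.5, 0.75)


def km_estimate(ipd: PseudoIPD) -> KMCurve:
    """Product-limit estimator with Greenwood variance.

    Ties between events and censorings at the same time are resolved
    events-before-censorings: a record censored at t is still counted at
    risk for events occurring at t.
    """
    t = ipd.times
    e = ipd.events
    if np.all(t <= 0):
        raise ValidationError("all record times are <= 0")
    ev_times = np.unique(t[e])
    if len(ev_times) == 0:
        # no events: flat curve at 1 with zero variance
        return KMCurve(
            event_times=np.array([]), survival=np.array([]),
            greenwood_var=np.array([]), gw_sum=np.array([]),
            at_risk=np.array([], dtype=int), events=np.array([], dtype=int),
            n=len(t), max_followup=float(t.max()),
        )
    ev_sorted = np.sort(t[e])
    d = (np.searchsorted(ev_sorted, ev_times, side="right")
         - np.searchsorted(ev_sorted, ev_times, side="left"))
    t_sorted = np.sort(t)
    n_risk = len(t) - np.searchsorted(t_sorted, ev_times, side="left")
    frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    gw = np.cumsum(terms)
    var = np.where(surv > 0, surv**2 * np.where(np.isfinite(gw), gw, 0.0), 0.0)
    gw = np.where(np.isfinite(gw), gw, 0.0)
    return KMCurve(
        event_times=ev_times, survival=surv, greenwood_var=var, gw_sum=gw,
        at_risk=n_risk, events=d, n=len(t), max_followup=float(t.max()),
    )


def _cloglog_band(km: KMCurve) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise 95% band for S-hat on the complementary log-log scale."""
    s = km.survival
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    for i, (si, gwi) in enumerate(zip(s, km.gw_sum)):
        if si <= 0.0:
            lo[i] = hi[i] = 0.0
        elif si >= 1.0 or gwi == 0.0:
            lo[i] = hi[i] = si
        else:
            se = np.sqrt(gwi) / abs(np.log(si))
            lo[i] = si ** np.exp(_Z * se)
            hi[i] = si ** np.exp(-_Z * se)
    return lo, hi


def _first_crossing(times: np.ndarray, values: np.ndarray, thresh: float) -> Optional[float]:
    idx = np.nonzero(values <= thresh + 1e-12)[0]
    return float(times[idx[0]]) if len(idx) else None


def survival_quantile(km: KMCurve, q: float) -> QuantileEstimate:
    """Time by which a fraction q of patients has had the event."""
    if q not in QUANTILE_LEVELS:
        raise ValidationError(f"quantile level must be one of {QUANTILE_LEVELS}")
    thresh = 1.0 - q
    if len(km.event_times) == 0:
        return QuantileEstimate(level=q, time=None, ci_low=None, ci_high=None)
    time = _first_crossing(km.event_times, km.survival, thresh)
    lo_band, hi_band = _cloglog_band(km)
    # the lower survival band crosses the threshold earlier -> lower CI bound
    ci_low = _first_crossing(km.event_times, lo_band, thresh)
    ci_high = _first_crossing(km.event_times, hi_band, thresh)
    return QuantileEstimate(level=q, time=time, ci_low=ci_low, ci_high=ci_high)


def rmst(km: KMCurve, tau: float, allow_extend: bool = False) -> RMSTEstimate:
    """Restricted mean survival time: the area under S-hat on [0, tau].

    By default tau must lie within observed follow-up; ``allow_extend``
    carries the last S-hat value forward beyond it.
    """
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    if tau > km.max_followup + 1e-9 and not allow_extend:
        raise ValidationError(
            f"tau={tau} exceeds observed follow-up {km.max_followup:.4f}; "
            "pass allow_extend=True to carry the last estimate forward"
        )
    mask = km.event_times < tau
    et, s = km.event_times[mask], km.survival[mask]
    d, nk = km.events[mask], km.at_risk[mask]
    knots = np.concatenate(([0.0], et, [tau]))
    heights = np.concatenate(([1.0], s))
    area = float(np.sum(np.diff(knots) * heights))
    # variance: sum over event times t_k < tau of A_k^2 d/(n(n-d)), where
    # A_k is the area under S-hat from t_k to tau (suffix sums of segments)
    seg = np.diff(np.concatenate((et, [tau]))) if len(et) else np.array([])
    a_after = np.cumsum((s * seg)[::-1])[::-1] if len(et) else np.array([])
    ok = nk > d
    var = float(np.sum(a_after[ok] ** 2 * d[ok] / (nk[ok] * (nk[ok] - d[ok]))))
    se = float(np.sqrt(var))
    return RMSTEstimate(tau=tau, value=area, se=se,
                        ci_low=area - _Z * se, ci_high=area + _Z * se)


def survival_rate_at(km: KMCurve, t: float) -> Tuple[float, float, float]:
    """S-hat(t) with a complementary log-log 95% CI: (rate, lo, hi)."""
    if t > km.max_followup + 1e-9:
        raise ValidationError(f"t={t} is beyond observed follow-up {km.max_followup:.4f}")
    s = float(km.survival_at(t)[0])
    gw = float(km.gw_sum_at(t)[0])
    if s >= 1.0 or s <= 0.0 or gw == 0.0:
        return s, s, s
    se = np.sqrt(gw) / abs(np.log(s))
    return s, float(s ** np.exp(_Z * se)), float(s ** np.exp(-_Z * se))
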