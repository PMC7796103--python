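"""Reconstruction of pseudo individual-patient data from digitized
Kaplan-Meier coordinates constrained by the numbers-at-risk table.

Within each risk-table interval [t_j, t_{j+1}) the algorithm alternates
between (a) deriving integer event counts at every digitized step from the
KM recursion S(t_k) = S(t_{k-1}) (1 - d_k / n_k), rounding with carry of
the fractional residual so that conservation holds, and (b) adjusting the
number of censorings placed in the interval until the implied number at
risk at t_{j+1} matches the published value exactly.  Censorings are
placed deterministically at the interval positions t_j + (i - 1/2)/c * dt,
a fixed stand-in for "uniform over the interval" that keeps the
reconstruction free of random state.  Beyond the last risk-table entry
events continue to be derived from the curve steps (no censoring is
assumed there); when the published total event count is available the
residual is reconciled against it.  Patients still at risk at the end of
the digitized span are censored at its last time point.

The whole procedure is deterministic: identical input yields identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .types import DigitizedCurve, PseudoIPD, ValidationError
from .endpoints import km_estimate

_MAX_ADJUST = 1000


class ReconstructionError(ValidationError):
    """Published constraints cannot be satisfied (named interval)."""


@dataclass
class _State:
    n_at_risk: int
    s_rec: float        # reconstructed KM value so far
    carry: float        # fractional event residual carried to the next step
    events: List[Tuple[float, int]]
    censors: List[float]

    def clone(self) -> "_State":
        return _State(self.n_at_risk, self.s_rec, self.carry,
                      list(self.events), list(self.censors))


def _run_segment(state: _State, step_times, step_surv, censor_positions) -> _State:
    """Advance the KM recursion through one interval's steps and censorings."""
    items = [(t, 0, s) for t, s in zip(step_times, step_surv)]
    items += [(t, 1, None) for t in censor_positions]
    items.sort(key=lambda it: (it[0], it[1]))  # events before censorings at ties
    st = state.clone()
    for t, kind, s_target in items:
        if kind == 0:
            if st.n_at_risk <= 0 or st.s_rec <= 0:
                continue
            d_raw = st.n_at_risk * (1.0 - s_target / st.s_rec) + st.carry
            d = int(round(d_raw))
            d = max(0, min(d, st.n_at_risk))
            st.carry = d_raw - d
            if d > 0:
                st.s_rec *= 1.0 - d / st.n_at_risk
                st.n_at_risk -= d
                st.events.append((t, d))
        else:
            if st.n_at_risk > 0:
                st.n_at_risk -= 1
                st.censors.append(t)
            else:
                st.n_at_risk -= 1  # over-censored: flagged by the caller
    return st


def _trim_events(st: _State, target: int, interval_start: float) -> Optional[_State]:
    """Reduce the latest event counts in the current interval until the
    number at risk matches the published target; None when impossible."""
    need = target - st.n_at_risk
    if need <= 0:
        return None
    out = st.clone()
    events = []
    for time, d in reversed(out.events):
        if need > 0 and time >= interval_start:
            cut = min(d, need)
            need -= cut
            d -= cut
            out.n_at_risk += cut
        if d > 0:
            events.append((time, d))
    if need > 0:
        return None
    out.events = list(reversed(events))
    return out


def reconstruct(curve: DigitizedCurve) -> PseudoIPD:
    """Rebuild per-patient (time, event) records from a digitized curve."""
    t, s = curve.times, curve.survival
    rt, nr = curve.risk_times, curve.n_risk
    state = _State(n_at_risk=int(nr[0]), s_rec=1.0, carry=0.0,
                   events=[], censors=[])

    for j in range(len(rt) - 1):
        lo, hi = rt[j], rt[j + 1]
        target = int(nr[j + 1])
        mask = (t >= lo) & (t < hi) & (t > 0)
        step_t, step_s = t[mask], s[mask]
        s_published = s[np.searchsorted(t, lo, side="right") - 1]
        if s_published <= 0 and target > 0:
            raise ReconstructionError(
                f"interval [{lo}, {hi}): curve reached 0 but {target} "
                "patients are published at risk"
            )
        accepted = None
        base = _run_segment(state, step_t, step_s, [])
        if base.n_at_risk < target:
            # rounding noise can make the implied events overshoot the
            # published count even with no censoring; the integer rounding
            # of d_k is free to go the other way, so trim trailing events
            accepted = _trim_events(base, target, lo)
            if accepted is None:
                raise ReconstructionError(
                    f"interval [{lo}, {hi}): published number at risk {target} "
                    "exceeds what the curve steps allow"
                )
            # trimming invalidates the running KM value; re-anchor it to the
            # digitized curve at the end of the interval
            if len(step_s) and step_s[-1] > 0:
                accepted.s_rec = float(step_s[-1])
        elif base.n_at_risk == target:
            accepted = base
        else:
            # scan censoring counts; event roundings interact with the
            # censoring positions, so the implied count is not strictly
            # monotone in c and may skip the target by one
            best = (base.n_at_risk - target, 0, base)
            c_limit = min(base.n_at_risk - target + 20, _MAX_ADJUST)
            for c in range(1, c_limit + 1):
                pos = lo + (np.arange(1, c + 1) - 0.5) / c * (hi - lo)
                cand = _run_segment(state, step_t, step_s, pos)
                gap = cand.n_at_risk - target
                if gap == 0:
                    best = (0, c, cand)
                    break
                if 0 < gap < best[0]:
                    best = (gap, c, cand)
                if gap < 0 and best[0] <= 2:
                    break
            gap, c, cand = best
            if gap > 0:
                # settle the residual with censorings at the interval end,
                # after every step, so event counts stay untouched
                last = max([lo] + list(step_t) + ([] if c == 0 else
                                                  [lo + (c - 0.5) / c * (hi - lo)]))
                end_pos = np.full(gap, (last + hi) / 2.0)
                pos = lo + (np.arange(1, c + 1) - 0.5) / c * (hi - lo) if c else []
                cand = _run_segment(state, step_t, step_s,
                                    np.concatenate((np.asarray(pos), end_pos)))
                if cand.n_at_risk != target:
                    raise ReconstructionError(
                        f"interval [{lo}, {hi}): censoring adjustment did "
                        "not converge"
                    )
            accepted = cand
        state = accepted

    # beyond the last published at-risk time: no censoring assumed, events
    # from the remaining curve steps
    mask = (t >= rt[-1]) & (t > 0)
    state = _run_segment(state, t[mask], s[mask], [])
    if curve.total_events is not None:
        total = sum(d for _, d in state.events)
        residual = curve.total_events - total
        if residual > 0 and state.n_at_risk > 0:
            extra = min(residual, state.n_at_risk)
            state.events.append((float(t[-1]), extra))
            state.n_at_risk -= extra
        elif residual < 0:
            deficit = -residual
            trimmed = []
            for time, d in reversed(state.events):
                if deficit > 0 and time >= rt[-1]:
                    cut = min(d, deficit)
                    deficit -= cut
                    d -= cut
                    # excess events become censorings at the same time
                    state.censors.extend([time] * cut)
                if d > 0:
                    trimmed.append((time, d))
            state.events = list(reversed(trimmed))
    # survivors censored at the end of the digitized span
    end = float(max(t[-1], rt[-1]))
    state.censors.extend([end] * max(state.n_at_risk, 0))

    times = np.concatenate(
        [np.repeat([tt for tt, _ in state.events], [d for _, d in state.events]),
         np.array(state.censors, dtype=float)]
    ) if state.events or state.censors else np.array([])
    events = np.concatenate(
        [np.ones(sum(d for _, d in state.events), dtype=bool),
         np.zeros(len(state.censors), dtype=bool)]
    )
    if len(times) != curve.n:
        raise ReconstructionError(
            f"reconstructed {len(times)} records but the arm has n={curve.n}"
        )
    order = np.argsort(times, kind="stable")
    return PseudoIPD(arm_id=curve.arm_id, endpoint=curve.endpoint,
                     times=np.maximum(times[order], 1e-9),
                     events=events[order])


@dataclass(frozen=True)
class FidelityReport:
    sup_norm: float
    risk_match: np.ndarray      # boolean per risk-table entry
    events_delta: Optional[int]

    @property
    def all_risk_match(self) -> bool:
        return bool(np.all(self.risk_match))


def validate_reconstruction(ipd: PseudoIPD, curve: DigitizedCurve) -> FidelityReport:
    """Compare a reconstruction against its source curve.

    The sup-norm is taken over the digitized point times; the risk-table
    comparison is exact-integer; the event-count delta is reported when the
    curve carries a published total.
    """
    if ipd.arm_id != curve.arm_id or ipd.endpoint != curve.endpoint:
        raise ValidationError(
            f"identifier mismatch: IPD is {ipd.arm_id}/{ipd.endpoint.value}, "
            f"curve is {curve.arm_id}/{curve.endpoint.value}"
        )
    km = km_estimate(ipd)
    sup = float(np.max(np.abs(km.survival_at(curve.times) - curve.survival)))
    risk_match = np.array(
        [(ipd.times >= rt - 1e-9).sum() == n for rt, n in
         zip(curve.risk_times, curve.n_risk)]
    )
    delta = None
    if curve.total_events is not None:
        delta = int(ipd.events.sum()) - curve.total_events
    return FidelityReport(sup_norm=sup, risk_match=risk_match, events_delta=delta)
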