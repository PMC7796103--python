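"""Random-effects summary survival curves across trial arms.

Per grid interval, each arm contributes its conditional survival (the ratio
of KM estimates at the interval ends).  Conditional survivals are carried
to the complementary log-log scale, pooled by DerSimonian-Laird random
effects with a method-of-moments between-study variance per interval
(truncated at zero), and the pooled curve is the cumulative product of the
back-transformed pooled conditionals.  Pointwise confidence limits come
from accumulating the pooled interval variances on the log-survival scale
(delta method).  Heterogeneity is summarized by the I2 statistic,
max(0, (Q - df)/Q) * 100, computed per interval; the single I2 attached to
a pooled median is by convention the value at the interval containing that
median.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .types import PooledCurve, PseudoIPD, QuantileEstimate, ValidationError
from .endpoints import km_estimate

_Z = stats.norm.ppf(0.975)
_CLIP = 1e-6


def _dl_pool(theta: np.ndarray, var: np.ndarray) -> Tuple[float, float, float, float]:
    """DerSimonian-Laird: (pooled theta, its variance, tau2, I2%)."""
    w = 1.0 / var
    theta_fe = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = len(theta) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (var + tau2)
    pooled = float(np.sum(w_re * theta) / np.sum(w_re))
    pooled_var = float(1.0 / np.sum(w_re))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return pooled, pooled_var, tau2, i2


def pool_curves(arms: Sequence[PseudoIPD], grid_step: float = 1.0) -> PooledCurve:
    """Pool arm-level KM curves on a common monthly grid.

    The grid runs from 0 to the shortest arm's maximum follow-up: beyond
    that horizon the pooled conditional survival would silently drop arms.
    """
    if len(arms) < 2:
        raise ValidationError("pooling requires at least 2 arms")
    kms = [km_estimate(a) for a in arms]
    horizon = min(km.max_followup for km in kms)
    grid = np.arange(0.0, horizon + 1e-9, grid_step)
    if grid[-1] < horizon - 1e-9:
        grid = np.append(grid, horizon)
    m = len(grid) - 1
    pooled_logp = np.zeros(m)
    pooled_logp_var = np.zeros(m)
    tau2 = np.zeros(m)
    i2 = np.zeros(m)
    for j in range(m):
        g0, g1 = grid[j], grid[j + 1]
        thetas, varis = [], []
        all_flat = True
        for km, arm in zip(kms, arms):
            s0 = float(km.survival_at(g0)[0])
            s1 = float(km.survival_at(g1)[0])
            p = s1 / s0 if s0 > 0 else 0.0
            var_logp = float(km.gw_sum_at(g1)[0] - km.gw_sum_at(g0)[0])
            if var_logp <= 0:
                # no events in the interval: half-event continuity floor so
                # the arm keeps a finite weight instead of an infinite one
                n_risk = int((arm.times >= g0).sum())
                n_risk = max(n_risk, 1)
                var_logp = 0.5 / (n_risk * max(n_risk - 0.5, 0.5))
            if p < 1.0:
                all_flat = False
            p = float(np.clip(p, _CLIP, 1.0 - _CLIP))
            theta = np.log(-np.log(p))
            # delta method: var(cloglog p) = var(log p) / (log p)^2
            varis.append(var_logp / (np.log(p) ** 2))
            thetas.append(theta)
        if all_flat:
            pooled_logp[j] = 0.0
            pooled_logp_var[j] = 0.0
            continue
        th, va = np.array(thetas), np.array(varis)
        pooled_theta, pooled_theta_var, t2, i2j = _dl_pool(th, va)
        logp = -np.exp(pooled_theta)
        pooled_logp[j] = logp
        pooled_logp_var[j] = pooled_theta_var * np.exp(2.0 * pooled_theta)
        tau2[j] = t2
        i2[j] = i2j
    log_s = np.concatenate(([0.0], np.cumsum(pooled_logp)))
    var_log_s = np.concatenate(([0.0], np.cumsum(pooled_logp_var)))
    surv = np.exp(log_s)
    se = np.sqrt(var_log_s)
    lo = np.clip(np.exp(log_s - _Z * se), 0.0, 1.0)
    hi = np.clip(np.exp(log_s + _Z * se), 0.0, 1.0)
    return PooledCurve(
        grid=grid, pooled_survival=surv, ci_low=lo, ci_high=hi,
        tau2=tau2, i2_per_interval=i2, i2_pct=_summary_i2(surv, i2),
        n_studies=len(arms),
    )


def _summary_i2(surv: np.ndarray, i2: np.ndarray) -> float:
    """I2 at the grid interval containing the pooled median (the last
    interval when the pooled curve never crosses 0.5)."""
    if len(i2) == 0:
        return 0.0
    below = np.nonzero(surv <= 0.5)[0]
    j = below[0] - 1 if len(below) else len(i2) - 1
    j = int(np.clip(j, 0, len(i2) - 1))
    return float(i2[j])


def _crossing(grid: np.ndarray, surv: np.ndarray, thresh: float) -> Optional[float]:
    """Linear-interpolated first crossing time of a grid curve."""
    below = np.nonzero(surv <= thresh + 1e-12)[0]
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        return float(grid[0])
    s0, s1 = surv[i - 1], surv[i]
    if s0 == s1:
        return float(grid[i])
    frac = (s0 - thresh) / (s0 - s1)
    return float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))


def pooled_quantile(pc: PooledCurve, q: float) -> QuantileEstimate:
    """Crossing time of the pooled curve; CI from the pointwise band."""
    thresh = 1.0 - q
    time = _crossing(pc.grid, pc.pooled_survival, thresh)
    ci_low = _crossing(pc.grid, pc.ci_low, thresh)
    ci_high = _crossing(pc.grid, pc.ci_high, thresh)
    return QuantileEstimate(level=q, time=time, ci_low=ci_low, ci_high=ci_high)
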