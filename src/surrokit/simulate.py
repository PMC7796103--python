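"""Synthetic multi-arm trial generator with coupled PFS/OS.

The generative model is a three-state illness-death process per patient:

    on treatment --(progression, hazard h_prog)--> progressed
    on treatment --(death,       hazard h_death_pre)--> dead
    progressed   --(death,       hazard h_death_post)--> dead

PFS is the time of the first transition out of the initial state (a
composite of progression and death); OS is the time of death, with the
post-progression clock restarting at progression (semi-Markov).  With
exponential transitions all endpoint statistics have closed or one-
dimensional-numeric forms, which serve as oracles downstream; per-
transition Weibull shapes are available solely to create non-proportional
hazards.

Trial-level heterogeneity enters as a bivariate-normal pair of log-hazard
shifts per trial: the PFS shift multiplies h_prog and h_death_pre, the OS
shift multiplies h_death_post, and their correlation rho is the dial that
induces trial-level surrogacy.  Censoring is uniform accrual over
``accrual_mo`` plus an administrative cutoff at calendar time
``admin_censor_mo``; there is no dropout, so the independent-censoring
assumption of the Kaplan-Meier estimator holds exactly.

Default rates emulate second-line trials in advanced hepatocellular
carcinoma: median PFS around 2-3 months, median OS around 12 months,
with post-progression survival dominating OS so that the OS-scale trial
effect, not the shared progression clock, carries most of the between-
trial OS variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
from scipy import integrate, optimize

from .types import (
    ArmRecord,
    DigitizedCurve,
    DrugClass,
    Endpoint,
    Phase,
    PseudoIPD,
    TreatmentLine,
    ValidationError,
)
from . import endpoints as ep


@dataclass(frozen=True)
class SimConfig:
    n_trials: int = 24
    arms_per_trial: int = 1
    n_per_arm: int = 235
    h_prog: float = 0.30            # per month
    h_death_pre: float = 0.01
    h_death_post: float = 0.08
    trial_effect_sd_pfs: float = 0.25
    trial_effect_sd_os: float = 0.40
    trial_effect_corr: float = 0.7
    accrual_mo: float = 12.0
    admin_censor_mo: float = 30.0
    seed: int = 0
    # Weibull shapes per transition; 1.0 = exponential
    shape_prog: float = 1.0
    shape_death_pre: float = 1.0
    shape_death_post: float = 1.0

    def __post_init__(self) -> None:
        for name in ("h_prog", "h_death_pre", "h_death_post"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if abs(self.trial_effect_corr) > 1:
            raise ValidationError("|trial_effect_corr| must be <= 1")
        if self.trial_effect_sd_pfs < 0 or self.trial_effect_sd_os < 0:
            raise ValidationError("trial effect SDs must be >= 0")
        if self.admin_censor_mo <= 0:
            raise ValidationError("admin_censor_mo must be > 0")
        if self.accrual_mo < 0:
            raise ValidationError("accrual_mo must be >= 0")


@dataclass(frozen=True)
class SimulatedArm:
    """One simulated arm together with its generating truth."""

    record: ArmRecord
    ipd_os: PseudoIPD
    ipd_pfs: PseudoIPD
    b_pfs: float  # trial-level log-hazard shift, PFS scale
    b_os: float   # trial-level log-hazard shift, OS scale


def _weibull_times(rng, rate: float, shape: float, size: int) -> np.ndarray:
    """Times with cumulative hazard H(t) = (rate * t)^shape."""
    e = rng.exponential(1.0, size)
    return e ** (1.0 / shape) / rate


def simulate_trial_set(config: SimConfig) -> List[SimulatedArm]:
    """Generate the full trial set; byte-identical under a fixed seed.

    Per-trial random substreams are derived from the global seed so the
    output is reproducible regardless of evaluation order.
    """
    master = np.random.default_rng(config.seed)
    rho = config.trial_effect_corr
    cov = np.array(
        [
            [config.trial_effect_sd_pfs**2,
             rho * config.trial_effect_sd_pfs * config.trial_effect_sd_os],
            [rho * config.trial_effect_sd_pfs * config.trial_effect_sd_os,
             config.trial_effect_sd_os**2],
        ]
    )
    if config.trial_effect_sd_pfs > 0 or config.trial_effect_sd_os > 0:
        effects = master.multivariate_normal([0.0, 0.0], cov, size=config.n_trials,
                                             method="cholesky")
    else:
        effects = np.zeros((config.n_trials, 2))
    arms: List[SimulatedArm] = []
    for i in range(config.n_trials):
        b_pfs, b_os = float(effects[i, 0]), float(effects[i, 1])
        for a in range(config.arms_per_trial):
            rng = np.random.default_rng([config.seed, 7919, i, a])
            arms.append(
                _simulate_arm(config, rng, f"trial{i:03d}", f"trial{i:03d}_arm{a}",
                              b_pfs, b_os)
            )
    return arms


def _simulate_arm(config: SimConfig, rng, trial_id: str, arm_id: str,
                  b_pfs: float, b_os: float) -> SimulatedArm:
    n = config.n_per_arm
    a = config.h_prog * np.exp(b_pfs)
    b = config.h_death_pre * np.exp(b_pfs)
    c = config.h_death_post * np.exp(b_os)
    t_prog = _weibull_times(rng, a, config.shape_prog, n)
    t_dpre = _weibull_times(rng, b, config.shape_death_pre, n)
    t_post = _weibull_times(rng, c, config.shape_death_post, n)
    pfs = np.minimum(t_prog, t_dpre)
    os_ = np.where(t_dpre < t_prog, t_dpre, t_prog + t_post)
    entry = rng.uniform(0.0, config.accrual_mo, n) if config.accrual_mo > 0 else np.zeros(n)
    cens = config.admin_censor_mo - entry
    cens = np.maximum(cens, 1e-6)
    pfs_obs = np.minimum(pfs, cens)
    os_obs = np.minimum(os_, cens)
    ipd_pfs = PseudoIPD(arm_id=arm_id, endpoint=Endpoint.PFS,
                        times=pfs_obs, events=pfs <= cens)
    ipd_os = PseudoIPD(arm_id=arm_id, endpoint=Endpoint.OS,
                       times=os_obs, events=os_ <= cens)
    record = _summarize_arm(trial_id, arm_id, n, ipd_os, ipd_pfs,
                            float(np.max(cens)))
    return SimulatedArm(record=record, ipd_os=ipd_os, ipd_pfs=ipd_pfs,
                        b_pfs=b_pfs, b_os=b_os)


def _summarize_arm(trial_id, arm_id, n, ipd_os, ipd_pfs, followup) -> ArmRecord:
    km_os = ep.km_estimate(ipd_os)
    km_pfs = ep.km_estimate(ipd_pfs)
    q = {}
    for label, km in (("os", km_os), ("pfs", km_pfs)):
        q[f"q1_{label}"] = ep.survival_quantile(km, 0.25).time
        q[f"median_{label}"] = ep.survival_quantile(km, 0.5).time
        q[f"q3_{label}"] = ep.survival_quantile(km, 0.75).time
    rate_t = min(followup, km_os.max_followup)
    rate, _, _ = ep.survival_rate_at(km_os, rate_t)
    return ArmRecord(
        trial_id=trial_id, arm_id=arm_id, drug_class=DrugClass.ICI,
        line=TreatmentLine.FIRST, n=n, phase=Phase.I_II, controlled=False,
        os_rate_end_fu_pct=100.0 * rate, followup_mo=followup, **q,
    )


def digitize(ipd: PseudoIPD, grid_step: float, risk_times,
             rounding: int = 3) -> DigitizedCurve:
    """Emulate plot digitization of an arm's KM curve.

    The survival function is sampled at the union of a regular grid and the
    event times, then rounded to ``rounding`` decimals (grid sampling plus
    rounding is what reading coordinates off a published figure amounts
    to).  The risk table holds the true numbers at risk at ``risk_times``
    and ``total_events`` the true event count.
    """
    if grid_step <= 0:
        raise ValidationError("grid_step must be > 0")
    km = ep.km_estimate(ipd)
    risk_times = np.asarray(risk_times, dtype=float)
    if len(risk_times) == 0 or risk_times[0] != 0:
        raise ValidationError("risk_times must start at 0")
    if risk_times.max() > km.max_followup + 1e-9:
        raise ValidationError(
            f"risk time {risk_times.max()} lies beyond follow-up {km.max_followup:.4f}"
        )
    grid = np.arange(0.0, km.max_followup + grid_step / 2, grid_step)
    t = np.unique(np.concatenate((grid, km.event_times)))
    t = t[t <= km.max_followup + 1e-9]
    s_true = km.survival_at(t)
    s = np.round(s_true, rounding)
    # a curve still above the axis never digitizes to exactly zero: floor
    # at one resolution unit so downstream risk-table checks stay feasible
    s = np.where((s_true > 0) & (s <= 0), 10.0 ** -rounding, s)
    # rounding preserves monotonicity; enforce exactly against float fuzz
    s = np.minimum.accumulate(s)
    n_risk = np.array([(ipd.times >= rt).sum() for rt in risk_times])
    return DigitizedCurve(
        arm_id=ipd.arm_id, endpoint=ipd.endpoint, times=t, survival=s,
        risk_times=risk_times, n_risk=n_risk,
        total_events=int(ipd.events.sum()),
    )


# ---------------------------------------------------------------------------
# analytic truth


def pfs_survival(config: SimConfig, b_pfs: float = 0.0):
    """S_PFS(t) under the trial-adjusted hazards (exact for any shapes)."""
    a = config.h_prog * np.exp(b_pfs)
    b = config.h_death_pre * np.exp(b_pfs)
    ka, kb = config.shape_prog, config.shape_death_pre

    def S(t):
        t = np.asarray(t, dtype=float)
        return np.exp(-((a * t) ** ka) - ((b * t) ** kb))

    return S


def os_survival(config: SimConfig, b_pfs: float = 0.0, b_os: float = 0.0):
    """S_OS(t): survivors still progression-free plus progressors alive.

    S_OS(t) = S_PFS(t) + int_0^t h_prog(u) S_PFS(u) S_post(t - u) du,
    evaluated by adaptive quadrature (closed form exists only for
    exponential transitions; the numeric form covers Weibull shapes too).
    """
    a = config.h_prog * np.exp(b_pfs)
    c = config.h_death_post * np.exp(b_os)
    ka, kc = config.shape_prog, config.shape_death_post
    S_pfs = pfs_survival(config, b_pfs)

    def h_prog(u):
        return ka * a * (a * u) ** (ka - 1.0) if u > 0 else (a if ka == 1.0 else 0.0)

    def S_post(v):
        return np.exp(-((c * v) ** kc))

    def S(t: float) -> float:
        if t <= 0:
            return 1.0
        val, _ = integrate.quad(lambda u: h_prog(u) * S_pfs(u) * S_post(t - u),
                                0.0, t, limit=200)
        return float(S_pfs(t)) + val

    return S


def true_endpoint_values(config: SimConfig, b_pfs: float = 0.0,
                         b_os: float = 0.0,
                         taus=(6.0, 12.0)) -> Dict[str, float]:
    """True median/Q1 and RMST(tau) for PFS and OS under the trial effects.

    Closed forms are used for the exponential PFS quantities; OS and any
    Weibull-shaped quantity fall back to high-precision numerics.
    """
    out: Dict[str, float] = {}
    S_pfs = pfs_survival(config, b_pfs)
    S_os = os_survival(config, b_pfs, b_os)
    for label, S in (("pfs", S_pfs), ("os", S_os)):
        for qlabel, level in (("q1", 0.75), ("median", 0.5)):
            f = lambda t: float(S(t)) - level
            hi = 1.0
            while f(hi) > 0 and hi < 1e4:
                hi *= 2.0
            out[f"{label}_{qlabel}"] = float(optimize.brentq(f, 1e-9, hi))
        for tau in taus:
            val, _ = integrate.quad(lambda u: float(S(u)), 0.0, tau, limit=200)
            out[f"{label}_rmst{int(tau)}"] = float(val)
    return out
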