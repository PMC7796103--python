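"""Trial-level surrogacy quantification.

The strength of the association between an arm-level surrogate statistic
(a PFS quantile, a PFS RMST, or the ORR) and the corresponding true-
endpoint statistic (OS) is summarized by the coefficient of determination
of a sample-size-weighted linear regression:

    R^2 = (sum w dx dy)^2 / (sum w dx^2 * sum w dy^2),

with deviations about the weighted means -- the squared weighted Pearson
correlation, which is exactly the R^2 of the weighted least-squares fit.
Weights are the arm sample sizes, not inverse variances.  The default
confidence interval is the Olkin-Finn large-sample Wald interval, left
untruncated so a weak association can produce a lower bound below zero;
a percentile bootstrap over arms is available as a sensitivity method.
Arms missing either statistic (unreported, or a quantile never reached)
are excluded pairwise and never imputed.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import ArmRecord, SubgroupInteraction, SurrogacyFit, ValidationError

log = logging.getLogger(__name__)

_Z = stats.norm.ppf(0.975)

#: surrogate/true column pairs, in the package's statistics-table dialect
ENDPOINT_PAIRS: Dict[str, Tuple[str, str]] = {
    "median": ("median_pfs", "median_os"),
    "q1": ("q1_pfs", "q1_os"),
    "q3": ("q3_pfs", "q3_os"),
    "rmst6": ("rmst6_pfs", "rmst6_os"),
    "rmst12": ("rmst12_pfs", "rmst12_os"),
}


def weighted_linear_fit(x, y, w, x_label: str = "x", y_label: str = "y") -> SurrogacyFit:
    """Weighted least squares of y on x; R^2 from the weighted correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (len(x) == len(y) == len(w)):
        raise ValidationError("x, y, w must have equal length")
    if len(x) < 3:
        raise ValidationError(f"a fit needs at least 3 arms, got {len(x)}")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    dx, dy = x - xm, y - ym
    sxx = float(np.sum(w * dx * dx))
    syy = float(np.sum(w * dy * dy))
    if sxx <= 0 or syy <= 0:
        raise ValidationError("zero weighted variance in x or y; R^2 undefined")
    sxy = float(np.sum(w * dx * dy))
    r2 = sxy**2 / (sxx * syy)
    wls = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = wls.params
    ci_low, ci_high = _olkin_finn_ci(r2, len(x))
    return SurrogacyFit(
        x_label=x_label, y_label=y_label, slope=float(slope),
        intercept=float(intercept), r2=float(r2),
        r2_ci_low=ci_low, r2_ci_high=ci_high,
        n_arms=len(x), weights=w, x=x, y=y,
    )


def _olkin_finn_ci(r2: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Large-sample Wald interval for R^2 (one predictor), untruncated."""
    z = stats.norm.ppf(0.5 + level / 2)
    var = 4.0 * r2 * (1.0 - r2) ** 2 * (n - 2) ** 2 / ((n**2 - 1) * (n + 3))
    se = float(np.sqrt(max(var, 0.0)))
    return r2 - z * se, r2 + z * se


def r2_confidence(fit: SurrogacyFit, method: str = "wald", level: float = 0.95,
                  n_boot: int = 2000, seed: int = 0) -> Tuple[float, float]:
    """Confidence interval for the fit's R^2.

    ``wald`` recomputes the Olkin-Finn interval at the requested level;
    ``bootstrap`` resamples arms with their weights and takes percentile
    limits over ``n_boot`` replicates.
    """
    if method == "wald":
        return _olkin_finn_ci(fit.r2, fit.n_arms, level)
    if method != "bootstrap":
        raise ValidationError(f"unknown CI method '{method}'")
    if fit.n_arms < 4:
        raise ValidationError("bootstrap CI needs at least 4 arms")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, fit.n_arms, fit.n_arms)
        x, y, w = fit.x[idx], fit.y[idx], fit.weights[idx]
        xm = np.average(x, weights=w)
        ym = np.average(y, weights=w)
        dx, dy = x - xm, y - ym
        sxx, syy = np.sum(w * dx * dx), np.sum(w * dy * dy)
        if sxx <= 0 or syy <= 0:
            continue
        reps.append(np.sum(w * dx * dy) ** 2 / (sxx * syy))
    a = (1.0 - level) / 2
    return (float(np.quantile(reps, a)), float(np.quantile(reps, 1 - a)))


def interaction_test(x, y, w, group) -> SubgroupInteraction:
    """Meta-regression interaction test between two subgroups.

    Fits weighted least squares of y on {x, group, x*group}; the reported
    p-value is the two-sided t-test on the interaction coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    group = np.asarray(group)
    labels = [str(g) for g in pd.unique(group)]
    if len(labels) != 2:
        raise ValidationError(f"exactly 2 groups required, got {labels}")
    gbin = (group == pd.unique(group)[1]).astype(float)
    if (gbin == 0).sum() < 2 or (gbin == 1).sum() < 2:
        raise ValidationError("each group must contribute at least 2 arms")
    design = np.column_stack((np.ones_like(x), x, gbin, x * gbin))
    res = sm.WLS(y, design, weights=w).fit()
    return SubgroupInteraction(
        subgroup_var="group",
        interaction_coef=float(res.params[3]),
        interaction_p=float(np.clip(res.pvalues[3], 0.0, 1.0)),
        groups=labels,
    )


def arm_statistics_table(arms: Sequence[ArmRecord],
                         rmst: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Flatten arm summaries (and an optional per-arm RMST table keyed on
    trial_id/arm_id) into one statistics DataFrame for the suite."""
    rows = []
    for a in arms:
        rows.append(
            {
                "trial_id": a.trial_id, "arm_id": a.arm_id,
                "drug_class": a.drug_class.value, "line": a.line.value,
                "phase": a.phase.value, "controlled": a.controlled, "n": a.n,
                "median_pfs": a.median_pfs, "median_os": a.median_os,
                "q1_pfs": a.q1_pfs, "q1_os": a.q1_os,
                "q3_pfs": a.q3_pfs, "q3_os": a.q3_os,
                "orr_pct": a.orr_pct,
                "os_rate_end_fu_pct": a.os_rate_end_fu_pct,
                "followup_mo": a.followup_mo,
            }
        )
    df = pd.DataFrame(rows)
    if rmst is not None:
        df = df.merge(rmst, on=["trial_id", "arm_id"], how="left",
                      suffixes=("", "_rmst"))
    return df


def surrogacy_suite(
    arms: Sequence[ArmRecord],
    pairs: Sequence[str] = ("median", "q1", "q3", "rmst6", "rmst12"),
    rmst: Optional[pd.DataFrame] = None,
    strata: Sequence[Optional[str]] = (None, "ICI", "MKI"),
) -> Dict[Tuple[str, str], SurrogacyFit]:
    """One weighted fit per endpoint pair and drug-class stratum.

    Arms lacking either statistic of a pair are dropped for that pair only;
    strata with fewer than 3 usable arms are skipped with a logged reason.
    Returns a mapping (pair, stratum) -> fit where stratum is ``overall``,
    ``ICI`` or ``MKI``.
    """
    df = arm_statistics_table(arms, rmst=rmst)
    fits: Dict[Tuple[str, str], SurrogacyFit] = {}
    for pair in pairs:
        if pair not in ENDPOINT_PAIRS:
            raise ValidationError(f"unknown endpoint pair '{pair}'")
        xcol, ycol = ENDPOINT_PAIRS[pair]
        for stratum in strata:
            name = stratum or "overall"
            sub = df if stratum is None else df[df["drug_class"] == stratum]
            if xcol not in sub.columns or ycol not in sub.columns:
                log.info("pair %s stratum %s skipped: statistics unavailable",
                         pair, name)
                continue
            usable = sub.dropna(subset=[xcol, ycol])
            if len(usable) < 3:
                log.info("pair %s stratum %s skipped: %d usable arms (<3)",
                         pair, name, len(usable))
                continue
            log.info("pair %s stratum %s arms: %s", pair, name,
                     list(usable["arm_id"]))
            fits[(pair, name)] = weighted_linear_fit(
                usable[xcol], usable[ycol], usable["n"],
                x_label=xcol, y_label=ycol,
            )
    return fits


def subgroup_interactions(
    arms: Sequence[ArmRecord],
    pairs: Sequence[str] = ("median", "q1", "rmst6", "rmst12"),
    subgroups: Sequence[str] = ("controlled", "phase", "line"),
    rmst: Optional[pd.DataFrame] = None,
    followup_cutoff_mo: float = 24.0,
) -> Dict[Tuple[str, str], SubgroupInteraction]:
    """Interaction p-values for each endpoint pair by arm-level subgroup.

    Subgroups: ``controlled`` (control arm present), ``phase`` (I/II vs
    III), ``line`` (first vs second; arms treating mixed lines are
    excluded from the split), and ``followup`` (duration above or below
    ``followup_cutoff_mo``).  A combination is skipped (and logged) when
    either group contributes fewer than 2 usable arms.
    """
    df = arm_statistics_table(arms, rmst=rmst)
    out: Dict[Tuple[str, str], SubgroupInteraction] = {}
    for pair in pairs:
        xcol, ycol = ENDPOINT_PAIRS[pair]
        if xcol not in df.columns or ycol not in df.columns:
            continue
        usable = df.dropna(subset=[xcol, ycol])
        for var in subgroups:
            sub = usable
            if var == "line":
                sub = usable[usable["line"].isin(["first", "second"])]
                labels = sub["line"]
            elif var == "followup":
                sub = usable.dropna(subset=["followup_mo"])
                labels = np.where(sub["followup_mo"] >= followup_cutoff_mo,
                                  "long_fu", "short_fu")
            else:
                labels = sub[var].astype(str)
            counts = pd.Series(labels).value_counts()
            if len(counts) != 2 or counts.min() < 2:
                log.info("pair %s subgroup %s skipped: group sizes %s",
                         pair, var, counts.to_dict())
                continue
            res = interaction_test(sub[xcol], sub[ycol], sub["n"], labels)
            out[(pair, var)] = SubgroupInteraction(
                subgroup_var=var, interaction_coef=res.interaction_coef,
                interaction_p=res.interaction_p, groups=res.groups,
            )
    return out


def orr_surrogacy(arms: Sequence[ArmRecord]) -> SurrogacyFit:
    """Weighted fit of the OS rate at end of follow-up on the ORR."""
    rows = [
        (a.orr_pct, a.os_rate_end_fu_pct, a.n)
        for a in arms
        if a.orr_pct is not None and a.os_rate_end_fu_pct is not None
    ]
    if len(rows) < 3:
        raise ValidationError(
            f"ORR surrogacy needs >= 3 arms with both ORR and OS rate, got {len(rows)}"
        )
    x, y, w = map(np.array, zip(*rows))
    return weighted_linear_fit(x, y, w, x_label="orr_pct",
                               y_label="os_rate_end_fu_pct")
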