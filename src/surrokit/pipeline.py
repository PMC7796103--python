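"""End-to-end orchestration: simulate -> digitize -> reconstruct ->
endpoints -> pool -> PH diagnostics -> surrogacy, from a single config.

The bundle returned by :func:`run_pipeline` holds every stage output, and
:func:`render_tables` formats them without recomputation (months to 2
decimals, R^2 to 2 decimals, percentages to 1 decimal).
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import endpoints as ep
from . import io, ph, pooling, surrogacy
from .reconstruct import reconstruct, validate_reconstruction
from .simulate import SimConfig, digitize, simulate_trial_set
from .types import Endpoint, ValidationError

log = logging.getLogger(__name__)

DEFAULT_CONFIG: Dict = {
    "source": "simulate",
    "simulate": {},
    "digitize": {"grid_step": 0.5, "rounding": 3, "risk_interval": 3.0},
    "endpoints": {"taus": [6.0, 12.0]},
    "pool": {"grid_step": 1.0},
    "surrogacy": {"pairs": ["median", "q1", "q3", "rmst6", "rmst12"]},
}


def _merged(config: Optional[Dict]) -> Dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config: Optional[Dict] = None, seed: Optional[int] = None) -> Dict:
    """Run the full pipeline; deterministic given config and seed.

    With ``source: simulate`` the digitization step is emulated on the
    simulated curves and endpoints are recomputed from the reconstruction,
    mirroring how published curves would be processed.  With
    ``source: fixtures`` the packaged arm-level tables feed the surrogacy
    stage directly.
    """
    cfg = _merged(config)
    bundle: Dict = {"config": cfg}
    if cfg["source"] == "fixtures":
        arms = io.load_ici_arm_table()
        rmst = io.load_rmst_table()
        bundle["arms"] = arms
        bundle["surrogacy"] = surrogacy.surrogacy_suite(
            arms, pairs=cfg["surrogacy"]["pairs"], rmst=rmst,
        )
        return bundle
    if cfg["source"] != "simulate":
        raise ValidationError(f"unknown source '{cfg['source']}'")

    sim_kwargs = dict(cfg["simulate"])
    if seed is not None:
        sim_kwargs["seed"] = seed
    sim_cfg = SimConfig(**sim_kwargs)
    sim = simulate_trial_set(sim_cfg)
    bundle["sim_config"] = asdict(sim_cfg)

    dz = cfg["digitize"]
    taus = cfg["endpoints"]["taus"]
    rows = []
    recon_os, recon_pfs, diagnostics = [], [], []
    for arm in sim:
        row = {"trial_id": arm.record.trial_id, "arm_id": arm.record.arm_id,
               "n": arm.record.n, "drug_class": arm.record.drug_class.value}
        ipds = {}
        for endpoint, ipd in ((Endpoint.OS, arm.ipd_os), (Endpoint.PFS, arm.ipd_pfs)):
            try:
                risk_times = np.arange(
                    0.0, ipd.times.max() + 1e-9, dz["risk_interval"])
                curve = digitize(ipd, grid_step=dz["grid_step"],
                                 risk_times=risk_times, rounding=dz["rounding"])
                rec = reconstruct(curve)
                rep = validate_reconstruction(rec, curve)
            except ValidationError as exc:
                raise ValidationError(
                    f"stage reconstruct, arm {ipd.arm_id}/{endpoint.value}: {exc}"
                ) from exc
            ipds[endpoint] = rec
            label = endpoint.value.lower()
            row[f"recon_supnorm_{label}"] = rep.sup_norm
            km = ep.km_estimate(rec)
            for q, qn in ((0.25, "q1"), (0.5, "median"), (0.75, "q3")):
                est = ep.survival_quantile(km, q)
                row[f"{qn}_{label}"] = est.time
            for tau in taus:
                est = ep.rmst(km, tau, allow_extend=False) \
                    if tau <= km.max_followup else None
                row[f"rmst{int(tau)}_{label}"] = est.value if est else None
        recon_os.append(ipds[Endpoint.OS])
        recon_pfs.append(ipds[Endpoint.PFS])
        try:
            stacked = ph.stack_endpoints(ipds[Endpoint.OS], ipds[Endpoint.PFS])
            diag = ph.time_dependent_hr(stacked)
        except ValidationError as exc:
            raise ValidationError(
                f"stage ph, arm {arm.record.arm_id}: {exc}") from exc
        diagnostics.append(diag)
        row["log_hr_pfs_vs_os"] = diag.log_hr
        row["schoenfeld_p"] = diag.schoenfeld_p
        row["ph_holds"] = diag.ph_holds
        row["chosen_time_fn"] = diag.chosen_time_fn.value
        rows.append(row)
    endpoints_df = pd.DataFrame(rows)
    bundle["endpoints"] = endpoints_df
    bundle["ph"] = {
        "diagnostics": diagnostics,
        "nonph_pct": ph.nonph_fraction(diagnostics),
    }

    pool_summary = {}
    pooled_curves = {}
    for label, arms_ipd in (("os", recon_os), ("pfs", recon_pfs)):
        try:
            pc = pooling.pool_curves(arms_ipd, grid_step=cfg["pool"]["grid_step"])
        except ValidationError as exc:
            raise ValidationError(f"stage pool ({label}): {exc}") from exc
        med = pooling.pooled_quantile(pc, 0.5)
        pooled_curves[label] = pc
        pool_summary[label] = {
            "median": med.time, "median_ci_low": med.ci_low,
            "median_ci_high": med.ci_high, "i2_pct": pc.i2_pct,
            "n_studies": pc.n_studies,
        }
    bundle["pooled"] = pool_summary
    bundle["pooled_curves"] = pooled_curves

    stats_df = endpoints_df.copy()
    fits = {}
    for pair in cfg["surrogacy"]["pairs"]:
        xcol, ycol = surrogacy.ENDPOINT_PAIRS[pair]
        usable = stats_df.dropna(subset=[xcol, ycol])
        if len(usable) < 3:
            log.info("surrogacy pair %s skipped: %d usable arms", pair, len(usable))
            continue
        fits[(pair, "overall")] = surrogacy.weighted_linear_fit(
            usable[xcol], usable[ycol], usable["n"], x_label=xcol, y_label=ycol)
    bundle["surrogacy"] = fits
    return bundle


def surrogacy_table(fits: Dict) -> pd.DataFrame:
    rows = []
    for (pair, stratum), fit in fits.items():
        rows.append({
            "pair": pair, "stratum": stratum, "n_arms": fit.n_arms,
            "slope": fit.slope, "intercept": fit.intercept, "r2": fit.r2,
            "r2_ci_low": fit.r2_ci_low, "r2_ci_high": fit.r2_ci_high,
        })
    return pd.DataFrame(rows)


def fmt_months(x) -> str:
    return "NR" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.2f}"


def fmt_r2(x) -> str:
    return f"{x:.2f}"


def fmt_pct(x) -> str:
    return f"{x:.1f}"


def render_tables(bundle: Dict, outdir, fmt: str = "csv") -> Dict[str, Path]:
    """Write the bundle's tables; every number traces to a stage output."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame):
        if fmt == "markdown":
            p = outdir / f"{name}.md"
            p.write_text(df.to_markdown(index=False))
        else:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
        written[name] = p

    if "endpoints" in bundle:
        df = bundle["endpoints"].copy()
        for c in df.columns:
            if df[c].dtype.kind == "f" and c != "schoenfeld_p":
                df[c] = df[c].map(lambda v: f"{v:.2f}" if pd.notna(v) else "NR")
        _write("endpoints", df)
    if "pooled" in bundle:
        rows = []
        for label, s in bundle["pooled"].items():
            rows.append({
                "endpoint": label.upper(),
                "pooled_median": fmt_months(s["median"]),
                "ci_low": fmt_months(s["median_ci_low"]),
                "ci_high": fmt_months(s["median_ci_high"]),
                "i2_pct": fmt_pct(s["i2_pct"]),
                "n_studies": s["n_studies"],
            })
        _write("pooled", pd.DataFrame(rows))
    if "ph" in bundle:
        _write("ph_summary", pd.DataFrame(
            [{"nonph_pct": fmt_pct(bundle["ph"]["nonph_pct"]),
              "n_arms": len(bundle["ph"]["diagnostics"])}]))
    if "surrogacy" in bundle:
        df = surrogacy_table(bundle["surrogacy"])
        for c in ("r2", "r2_ci_low", "r2_ci_high"):
            df[c] = df[c].map(fmt_r2)
        for c in ("slope", "intercept"):
            df[c] = df[c].map(lambda v: f"{v:.3f}")
        _write("surrogacy", df)
    return written
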