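"""Readers and writers for the package's CSV dialects.

All files are UTF-8, comma-separated, decimal point ``.``.  Empty cells and
the strings ``NA``/``NR`` all map to an absent value: a quantile printed as
"not reached" and one simply not reported are equally unusable downstream,
so no sentinel numerics are introduced.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Optional

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

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

ARM_COLUMNS = [
    "trial_id", "arm_id", "drug_class", "line", "n", "phase", "controlled",
    "median_os", "q1_os", "q3_os", "median_pfs", "q1_pfs", "q3_pfs",
    "hr_os", "hr_pfs", "orr_pct", "os_rate_end_fu_pct", "followup_mo",
]

_MISSING = {"", "na", "nr", "nan", "none", "-"}


def _opt_float(cell, row: int, col: str) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    s = str(cell).strip()
    if s.lower() in _MISSING:
        return None
    try:
        return float(s)
    except ValueError:
        raise ValidationError(f"row {row}, column '{col}': cannot parse '{cell}'")


def read_arm_table(path) -> List[ArmRecord]:
    """Read an arm-level summary table (the ``arms.csv`` dialect)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ARM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"arm table {path} lacks columns: {missing}")
    records = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            rec = ArmRecord(
                trial_id=row["trial_id"].strip(),
                arm_id=row["arm_id"].strip(),
                drug_class=DrugClass(row["drug_class"].strip()),
                line=TreatmentLine(row["line"].strip()),
                n=int(row["n"]),
                phase=Phase(row["phase"].strip()),
                controlled=row["controlled"].strip().lower() in {"true", "1", "yes"},
                **{
                    col: _opt_float(row[col], rownum, col)
                    for col in ARM_COLUMNS[7:]
                },
            )
        except (ValueError, KeyError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise ValidationError(f"row {rownum} of {path}: {exc}") from exc
        records.append(rec)
    return records


def write_arm_table(records: List[ArmRecord], path) -> None:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in ARM_COLUMNS}
        d["drug_class"] = r.drug_class.value
        d["line"] = r.line.value
        d["phase"] = r.phase.value
        rows.append(d)
    pd.DataFrame(rows, columns=ARM_COLUMNS).to_csv(path, index=False)


def isotonic_decreasing(values: np.ndarray) -> np.ndarray:
    """Least-squares projection onto non-increasing sequences (PAVA)."""
    v = np.asarray(values, dtype=float)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    return iso.fit_transform(np.arange(len(v), dtype=float), v)


def read_digitized_curve(
    points_path,
    risk_path,
    arm_id: str = "arm",
    endpoint: Endpoint = Endpoint.OS,
    total_events: Optional[int] = None,
) -> DigitizedCurve:
    """Read digitized KM coordinates plus the numbers-at-risk table.

    Survival values carry pixel noise from the digitization step; they are
    clipped to [0, 1] and repaired to a non-increasing sequence by decreasing
    isotonic projection rather than rejected.
    """
    pts = pd.read_csv(points_path)
    risk = pd.read_csv(risk_path)
    for col in ("time_mo", "surv"):
        if col not in pts.columns:
            raise ValidationError(f"points file {points_path} lacks column '{col}'")
    for col in ("time_mo", "n_risk"):
        if col not in risk.columns:
            raise ValidationError(f"risk file {risk_path} lacks column '{col}'")
    t = pts["time_mo"].to_numpy(dtype=float)
    s = np.clip(pts["surv"].to_numpy(dtype=float), 0.0, 1.0)
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    if len(t) < 2:
        raise ValidationError("digitized curve needs at least 2 points")
    s = isotonic_decreasing(s)
    rt = risk["time_mo"].to_numpy(dtype=float)
    nr = risk["n_risk"].to_numpy(dtype=int)
    if len(rt) == 0 or rt[0] != 0:
        raise ValidationError("risk table must contain a time-0 entry")
    return DigitizedCurve(
        arm_id=arm_id, endpoint=endpoint, times=t, survival=s,
        risk_times=rt, n_risk=nr, total_events=total_events,
    )


def write_ipd(ipd: PseudoIPD, path) -> None:
    """Serialize pseudo-IPD; times kept to 6 decimals."""
    pd.DataFrame(
        {
            "arm_id": ipd.arm_id,
            "endpoint": ipd.endpoint.value,
            "time_mo": np.round(ipd.times, 6),
            "event": ipd.events.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_ipd(path) -> PseudoIPD:
    df = pd.read_csv(path)
    for col in ("arm_id", "endpoint", "time_mo", "event"):
        if col not in df.columns:
            raise ValidationError(f"IPD file {path} lacks column '{col}'")
    if len(df) == 0:
        raise ValidationError(f"IPD file {path} contains no records")
    ev = df["event"].to_numpy()
    if not np.isin(ev, (0, 1)).all():
        raise ValidationError(f"IPD file {path}: event flags must be 0 or 1")
    return PseudoIPD(
        arm_id=str(df["arm_id"].iloc[0]),
        endpoint=Endpoint(df["endpoint"].iloc[0]),
        times=np.round(df["time_mo"].to_numpy(dtype=float), 6),
        events=ev.astype(bool),
    )


def _fixture(name: str):
    return resources.files("surrokit.data").joinpath(name)


def load_ici_arm_table() -> List[ArmRecord]:
    """Packaged arm-level summary table of the ICI trials (plus their
    sorafenib comparator arms), transcribed from the published report."""
    with resources.as_file(_fixture("table1_ici_arms.csv")) as p:
        return read_arm_table(p)


def load_rmst_table() -> pd.DataFrame:
    """Packaged per-arm 6- and 12-month RMST point estimates (both drug
    classes), transcribed from the published report."""
    with resources.as_file(_fixture("table2_rmst.csv")) as p:
        return pd.read_csv(p)
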