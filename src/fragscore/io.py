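"""CSV/JSON readers and writers for manifests, plates and results.

qPCR instruments export CSV, so CSV with a header row is the exchange
format for every table; JSON carries configuration and the calibration
object.  Timestamps are ISO-8601.  Readers never silently drop rows: rows
failing type checks come back as structured error records alongside the
parsed objects, and structural faults (missing columns, duplicate patient
ids) are hard errors.
"""

from __future__ import annotations

import dataclasses
import json
import math
from datetime import datetime
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import pandas as pd

from .datatypes import (
    CohortRecord,
    CutpointCalibration,
    Dye,
    DYE_FOR_TARGET,
    FragmentProfile,
    ProgressionLabel,
    QcVerdict,
    QpcrWell,
    SampleDraw,
    Target,
)

MANIFEST_REQUIRED = (
    "patient_id", "cancer_type",
    "collected_at_1", "received_at_1", "collected_at_2", "received_at_2",
    "treatment_date", "baseline_scan_date", "assessment_scan_date",
)
MANIFEST_OPTIONAL_BOOLS = (
    "secondary_malignancy", "autoimmune_treatment", "recent_dvt_pe_sepsis",
)
PLATE_REQUIRED = ("well", "sample_id", "multiplex", "target", "dye", "replicate", "ct")

#: Ct strings the instrument emits for no amplification.
MISSING_CT = {"", "undetermined", "nan", "na", "none"}


def _parse_ts(value: str, field: str) -> datetime:
    try:
        return datetime.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(f"{field}: not an ISO-8601 timestamp ({value!r})") from exc


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n", "", "nan"):
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_manifest(path: Union[str, Path]) -> Tuple[List[CohortRecord], List[dict]]:
    """Read a cohort manifest CSV.

    Returns ``(records, row_errors)``: one record per valid patient row,
    and a structured error entry (patient_id, row, error) for each row
    failing a type or invariant check.  Missing required columns and
    duplicated patient ids are hard errors.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {', '.join(missing)}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate patient_id: {', '.join(map(str, dupes))}")

    records: List[CohortRecord] = []
    errors: List[dict] = []
    for i, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        try:
            volume = float(row["plasma_volume_uL"]) if str(row.get("plasma_volume_uL", "")).strip() else 500.0
            draws = (
                SampleDraw(pid, 1, _parse_ts(row["collected_at_1"], "collected_at_1"),
                           _parse_ts(row["received_at_1"], "received_at_1"), volume),
                SampleDraw(pid, 2, _parse_ts(row["collected_at_2"], "collected_at_2"),
                           _parse_ts(row["received_at_2"], "received_at_2"), volume),
            )
            change = str(row.get("sum_diameter_change_pct", "")).strip()
            outcome = ProgressionLabel.from_change_pct(float(change)) if change else None
            scan = str(row["assessment_scan_date"]).strip()
            records.append(
                CohortRecord(
                    patient_id=pid,
                    cancer_type=str(row["cancer_type"]).strip(),
                    draws=draws,
                    treatment_date=_parse_ts(row["treatment_date"], "treatment_date"),
                    baseline_scan_date=_parse_ts(row["baseline_scan_date"], "baseline_scan_date"),
                    assessment_scan_date=_parse_ts(scan, "assessment_scan_date") if scan else None,
                    outcome=outcome,
                    **{
                        k: _parse_bool(row[k]) if k in df.columns else False
                        for k in MANIFEST_OPTIONAL_BOOLS
                    },
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append({"patient_id": pid, "row": int(i) + 2, "error": str(exc)})
    return records, errors


def read_plate(path: Union[str, Path]) -> Tuple[List[QpcrWell], List[QcVerdict]]:
    """Read a qPCR plate export CSV.

    "Undetermined" or empty Ct parses as the missing sentinel (None), never
    zero.  Rows whose dye does not match the assay's dye-target pairing
    (FAM on the short ALU targets, Cy5 on SVA, HEX on the IPC) come back as
    QC error verdicts, not wells.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in PLATE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"plate missing required column(s): {', '.join(missing)}")

    wells: List[QpcrWell] = []
    qc_errors: List[QcVerdict] = []
    for i, row in df.iterrows():
        where = f"{row['sample_id']}/{row['well'] or f'row {int(i) + 2}'}"
        try:
            target = Target(str(row["target"]).strip())
            dye = Dye(str(row["dye"]).strip())
        except ValueError as exc:
            qc_errors.append(QcVerdict(where, "plate_parse", False, str(exc)))
            continue
        if DYE_FOR_TARGET[target] is not dye:
            qc_errors.append(
                QcVerdict(
                    where, "dye_target_mismatch", False,
                    f"{target.value} must carry {DYE_FOR_TARGET[target].value}, got {dye.value}",
                )
            )
            continue
        raw_ct = str(row["ct"]).strip()
        ct = None if raw_ct.lower() in MISSING_CT else float(raw_ct)
        try:
            wells.append(
                QpcrWell(
                    sample_id=str(row["sample_id"]).strip(),
                    multiplex=int(row["multiplex"]),
                    target=target,
                    dye=dye,
                    replicate=int(row["replicate"]),
                    ct=ct,
                    well=str(row["well"]).strip(),
                )
            )
        except ValueError as exc:
            qc_errors.append(QcVerdict(where, "plate_parse", False, str(exc)))
    return wells, qc_errors


def read_standards(path: Union[str, Path]) -> Dict[Target, List[Tuple[float, float]]]:
    """Standard-curve points CSV (target, quantity, ct) grouped by target."""
    df = pd.read_csv(path)
    for col in ("target", "quantity", "ct"):
        if col not in df.columns:
            raise ValueError(f"standards file missing column: {col}")
    out: Dict[Target, List[Tuple[float, float]]] = {}
    for _, row in df.iterrows():
        out.setdefault(Target(str(row["target"]).strip()), []).append(
            (float(row["quantity"]), float(row["ct"]))
        )
    return out


# ---------------------------------------------------------------------------
# writers


def write_profiles(profiles: Sequence[FragmentProfile], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id, "SM1": p.SM1, "MM1": p.MM1,
                "SM2": p.SM2, "MM2": p.MM2, "flags": ";".join(p.flags),
            }
            for p in profiles
        ]
    ).to_csv(path, index=False)


def read_profiles(path: Union[str, Path]) -> List[FragmentProfile]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("patient_id", "SM1", "MM1", "SM2", "MM2"):
        if col not in df.columns:
            raise ValueError(f"profiles file missing column: {col}")
    out = []
    for _, row in df.iterrows():
        flags = row.get("flags", "")
        flags = tuple(str(flags).split(";")) if isinstance(flags, str) and flags else ()
        out.append(
            FragmentProfile(
                patient_id=str(row["patient_id"]),
                SM1=float(row["SM1"]), MM1=float(row["MM1"]),
                SM2=float(row["SM2"]), MM2=float(row["MM2"]),
                flags=flags,
            )
        )
    return out


def write_manifest(records: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    rows = []
    for r in records:
        d1, d2 = r.draws
        rows.append(
            {
                "patient_id": r.patient_id,
                "cancer_type": r.cancer_type,
                "collected_at_1": d1.collected_at.isoformat(),
                "received_at_1": d1.received_at.isoformat(),
                "collected_at_2": d2.collected_at.isoformat(),
                "received_at_2": d2.received_at.isoformat(),
                "plasma_volume_uL": d1.plasma_volume_uL,
                "treatment_date": r.treatment_date.isoformat(),
                "baseline_scan_date": r.baseline_scan_date.isoformat(),
                "assessment_scan_date": (
                    r.assessment_scan_date.isoformat() if r.assessment_scan_date else ""
                ),
                "sum_diameter_change_pct": (
                    r.outcome.sum_diameter_change_pct if r.outcome else ""
                ),
                "secondary_malignancy": r.secondary_malignancy,
                "autoimmune_treatment": r.autoimmune_treatment,
                "recent_dvt_pe_sepsis": r.recent_dvt_pe_sepsis,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_plate(wells: Sequence[QpcrWell], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "well": w.well, "sample_id": w.sample_id, "multiplex": w.multiplex,
                "target": w.target.value, "dye": w.dye.value,
                "replicate": w.replicate,
                "ct": "Undetermined" if w.ct is None else w.ct,
            }
            for w in wells
        ]
    ).to_csv(path, index=False)


def calibration_to_json(calib: CutpointCalibration, path: Union[str, Path]) -> None:
    data = dataclasses.asdict(calib)
    data["expected_ppv"] = [
        None if (isinstance(v, float) and math.isnan(v)) else v
        for v in data["expected_ppv"]
    ]
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def calibration_from_json(path: Union[str, Path]) -> CutpointCalibration:
    data = json.loads(Path(path).read_text())
    data["candidate_thresholds"] = tuple(data["candidate_thresholds"])
    data["expected_ppv"] = tuple(
        float("nan") if v is None else v for v in data["expected_ppv"]
    )
    data["n_defined"] = tuple(data["n_defined"])
    return CutpointCalibration(**data)
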