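"""End-to-end orchestration: inputs -> QC -> quantification -> features ->
model selection -> cut-point calibration -> scoring -> performance.

Stages are decoupled: a run can start from a synthetic scenario, from
manifest + plate CSVs, or from a pre-quantified concentration table.  Given
identical inputs and seed the run is deterministic and its output files are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    CohortRecord,
    FragmentProfile,
    QcVerdict,
    QpcrWell,
    StandardCurve,
    Target,
)
from .calibration import performance, score_patients
from .features import features_frame
from .io import (
    read_manifest,
    read_plate,
    read_profiles,
    read_standards,
    calibration_to_json,
    write_manifest,
    write_plate,
)
from .model import ProgressionScoreModel
from .qc import (
    apply_exclusions,
    check_ipc_shift,
    check_sva_concordance,
    gate_record,
)
from .qpcr import build_profiles, fit_standard_curve, sva_quantities
from .simulate import (
    ScenarioConfig,
    default_curves,
    generate_cohort,
    simulate_plate,
)


@dataclass
class PipelineConfig:
    """Everything a run needs; every QC/model tunable is a key here."""

    # input source: synthetic scenario, or file paths
    scenario: Optional[ScenarioConfig] = None
    manifest_path: Optional[str] = None
    plate_paths: Tuple[str, ...] = ()
    standards_path: Optional[str] = None
    profiles_path: Optional[str] = None  # pre-quantified concentrations

    out_dir: Optional[str] = None
    seed: int = 0

    # QC tunables
    max_transit_hours: float = 120.0
    ipc_max_shift_ct: float = 1.0
    sva_max_rel_diff: float = 0.30
    min_curve_r2: float = 0.98

    # modeling / calibration tunables
    selection: str = "parsimony-on-flag"
    n_bootstrap: int = 1000
    min_ppv: float = 0.99
    refit_bootstrap: bool = True
    compute_loocv: bool = True

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "scenario" in data and data["scenario"] is not None:
            data["scenario"] = ScenarioConfig(**data["scenario"])
        if "plate_paths" in data:
            data["plate_paths"] = tuple(data["plate_paths"])
        return cls(**data)


@dataclass
class PipelineResult:
    """Bundle of every stage's output tables."""

    features: pd.DataFrame
    model_table: pd.DataFrame
    results: object  # ProgressionScoreResults
    calibration: object  # CutpointCalibration
    calls: pd.DataFrame
    performance_table: pd.DataFrame
    exclusions: pd.DataFrame
    truth: Optional[pd.DataFrame] = None


def _stage(name: str):
    """Decorator attaching the stage name to any hard error."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


@_stage("inputs")
def _load_inputs(config: PipelineConfig):
    """Resolve the input source into (records, profiles, wells, curves, truth)."""
    truth = None
    wells: List[QpcrWell] = []
    curves: Optional[Dict[Target, StandardCurve]] = None
    profiles: Optional[List[FragmentProfile]] = None

    if config.scenario is not None:
        scenario = dataclasses.replace(config.scenario, seed=config.seed)
        records, true_profiles, truth = generate_cohort(scenario)
        curves = default_curves(scenario)
        rng = np.random.default_rng(scenario.seed + 7)
        for prof, (_, t) in zip(true_profiles, truth.iterrows()):
            inhibited = tuple(
                d for d in (1, 2) if t[f"inhibited_draw{d}"]
            )
            wells.extend(
                simulate_plate(prof, curves, scenario, rng, inhibited_draws=inhibited)
            )
        profiles = None  # quantified from the simulated wells
    elif config.manifest_path:
        records, row_errors = read_manifest(config.manifest_path)
        if row_errors:
            bad = ", ".join(e["patient_id"] or f"row {e['row']}" for e in row_errors)
            raise ValueError(f"manifest rows failed validation: {bad}")
        for p in config.plate_paths:
            w, qc_err = read_plate(p)
            if qc_err:
                detail = "; ".join(f"{v.subject}: {v.detail}" for v in qc_err)
                raise ValueError(f"plate {p} has invalid rows: {detail}")
            wells.extend(w)
        if config.standards_path:
            pts = read_standards(config.standards_path)
            curves = {
                t: fit_standard_curve(p, target=t, min_r2=config.min_curve_r2)
                for t, p in pts.items()
            }
        if config.profiles_path:
            profiles = read_profiles(config.profiles_path)
    else:
        raise ValueError("config must name a synthetic scenario or input paths")
    return records, profiles, wells, curves, truth


@_stage("qc")
def _run_qc(
    config: PipelineConfig,
    records: Sequence[CohortRecord],
    wells: Sequence[QpcrWell],
    curves,
) -> Tuple[List[CohortRecord], pd.DataFrame, List[QcVerdict]]:
    verdicts: List[QcVerdict] = []
    for rec in records:
        verdicts.extend(gate_record(rec, config.max_transit_hours))
    if wells:
        sample_verdicts = check_ipc_shift(wells, "run1", config.ipc_max_shift_ct)
        # sample ids are <patient>-D<draw>; lift failures to the patient
        for v in sample_verdicts:
            pid = v.subject.split("-D")[0]
            verdicts.append(QcVerdict(pid, v.rule, v.passed, f"{v.subject}: {v.detail}"))
        if curves is not None:
            by_sample: Dict[str, List[QpcrWell]] = {}
            for w in wells:
                by_sample.setdefault(w.sample_id, []).append(w)
            for sid, ws in sorted(by_sample.items()):
                q1, q2 = sva_quantities(ws, curves)
                v = check_sva_concordance(q1, q2, config.sva_max_rel_diff)
                if not v.indeterminate:
                    pid = sid.split("-D")[0]
                    verdicts.append(
                        QcVerdict(pid, v.rule, v.passed, f"{sid}: {v.detail}")
                    )
    analyzable, exclusion_rows = apply_exclusions(records, verdicts)
    if not analyzable:
        raise ValueError("no analyzable patients")
    return analyzable, pd.DataFrame(exclusion_rows, columns=["patient_id", "rule", "detail"]), verdicts


@_stage("quantify")
def _quantify(
    config: PipelineConfig,
    analyzable: Sequence[CohortRecord],
    profiles: Optional[List[FragmentProfile]],
    wells: Sequence[QpcrWell],
    curves,
) -> List[FragmentProfile]:
    keep = {r.patient_id for r in analyzable}
    if profiles is None:
        if not wells or curves is None:
            raise ValueError("no plates/curves and no concentration table supplied")
        dmap = {
            sid: (pid, d)
            for sid, (pid, d) in draw_map_from_wells(wells).items()
            if pid in keep
        }
        profiles, unquantifiable = build_profiles(wells, curves, dmap)
        keep -= set(unquantifiable)
    out = [p for p in profiles if p.patient_id in keep]
    if not out:
        raise ValueError("no quantifiable patients")
    return out


def draw_map_from_wells(wells: Sequence[QpcrWell]) -> Dict[str, Tuple[str, int]]:
    """Recover sample_id -> (patient, draw) from '<patient>-D<draw>' ids."""
    out: Dict[str, Tuple[str, int]] = {}
    for w in wells:
        sid = w.sample_id
        if "-D" in sid:
            pid, _, d = sid.rpartition("-D")
            try:
                out[sid] = (pid, int(d[0]))
            except (ValueError, IndexError):
                continue
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and (optionally) write the result bundle.

    With ``config.out_dir`` set, writes features.csv, model_table.csv,
    calibration.json, calls.csv, performance.csv, exclusions.csv and
    run_log.json (plus the synthetic inputs when a scenario was used).
    """
    records, profiles, wells, curves, truth = _load_inputs(config)
    analyzable, exclusions, _ = _run_qc(config, records, wells, curves)
    profiles = _quantify(config, analyzable, profiles, wells, curves)
    feats = features_frame(profiles)

    outcome_by_pid = {
        r.patient_id: (r.outcome.progressed if r.outcome else None) for r in records
    }
    labels = feats["patient_id"].map(outcome_by_pid)
    if labels.isna().any():
        missing = feats.loc[labels.isna(), "patient_id"].tolist()
        raise RuntimeError(
            "pipeline stage 'fit' failed: outcome required for model fitting, "
            f"missing for: {', '.join(missing)}"
        )
    y = labels.astype(bool).to_numpy()

    model = ProgressionScoreModel(feats, y.astype(float))
    results = model.fit(
        selection=config.selection, compute_loocv=config.compute_loocv
    )
    calib = results.calibrate_cutpoint(
        n_bootstrap=config.n_bootstrap,
        min_ppv=config.min_ppv,
        seed=config.seed,
        refit=config.refit_bootstrap,
    )

    ps_results = score_patients(
        feats["patient_id"].tolist(), results.predict(), calib.selected_cutpoint
    )
    calls = pd.DataFrame(
        [{"patient_id": r.patient_id, "ps": r.ps, "call": r.call} for r in ps_results]
    )
    perf = performance([r.call for r in ps_results], [bool(v) for v in y])
    perf_df = pd.DataFrame(
        [
            {
                "n_called": perf.n_called, "n_not_called": perf.n_not_called,
                "true_positives": perf.true_positives,
                "false_positives": perf.false_positives,
                "true_negatives": perf.true_negatives,
                "false_negatives": perf.false_negatives,
                "ppv": perf.ppv, "npv": perf.npv,
            }
        ]
    )

    result = PipelineResult(
        features=feats,
        model_table=results.model_table(),
        results=results,
        calibration=calib,
        calls=calls,
        performance_table=perf_df,
        exclusions=exclusions,
        truth=truth,
    )
    if config.out_dir:
        _write_bundle(config, result, records, wells)
    return result


@_stage("write")
def _write_bundle(config: PipelineConfig, result: PipelineResult, records, wells) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.model_table.to_csv(out / "model_table.csv", index=False)
    result.calls.to_csv(out / "calls.csv", index=False)
    result.performance_table.to_csv(out / "performance.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    calibration_to_json(result.calibration, out / "calibration.json")
    if result.truth is not None:
        result.truth.to_csv(out / "ground_truth.csv", index=False)
        write_manifest(records, out / "manifest.csv")
        write_plate(wells, out / "plate.csv")
    log = {
        "fragscore_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "selected_model": result.results.selected.spec.name,
        "selected_cutpoint": result.calibration.selected_cutpoint,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
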