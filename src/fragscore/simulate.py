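"""Synthetic cohort, plate and interference-panel generation.

No patient-level data from the monitoring study is deposited, so this
module generates cohorts with the statistical structure the analysis
assumes: two draws per patient, log-normal cfDNA concentration marginals,
a short-fragment excess that grows in progressors, white-blood-cell lysis
spikes that inflate both size classes of a draw by a common amount,
PCR-inhibition events that shift every target's Ct including the internal
positive control, and non-cancer cfDNA elevations that multiply both size
classes proportionally.  A ground-truth table accompanies every cohort so
recovery can be checked.

Concentration scales and variances are not reported for the real cohort;
the defaults here are plausible for plasma cfDNA (total cfDNA a few
thousand copies/mL with a right-skewed spread, short-fragment excess an
order of magnitude smaller) and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import (
    CohortRecord,
    DYE_FOR_TARGET,
    FragmentProfile,
    MULTIPLEX_TARGETS,
    ProgressionLabel,
    QpcrWell,
    SampleDraw,
    StandardCurve,
    Target,
)
from .qpcr import ELUATE_UL, PLASMA_UL, REACTION_TEMPLATE_UL

#: Interference panel composition: condition -> (n subjects, multiplier
#: applied to both cfDNA size classes of the post-event draw).
DEFAULT_PANEL = {
    "acute stroke": (3, 3.0),
    "asthma hospitalization": (2, 1.4),
    "COPD exacerbation": (3, 2.2),
    "diabetic ketoacidosis": (3, 1.5),
    "inflammatory bowel disease": (4, 1.4),
    "myocardial infarction": (2, 2.5),
    "rheumatoid arthritis": (5, 2.0),
    "severe seizure": (3, 1.5),
    "viral infection": (5, 1.6),
}


@dataclass
class ScenarioConfig:
    """Generator parameters; defaults define the reference study conditions.

    Concentrations are copies per mL plasma.  ``progression_effect_*``
    parametrise the log-normal additive shift applied to the second-draw
    short-fragment excess of progressors; the long tail towards small
    effects produces the low-shedding progressors that cap real-world
    sensitivity.
    """

    n_patients: int = 128
    prevalence: float = 20.0 / 128.0

    mm_log_mean: float = math.log(2000.0)
    mm_log_sd: float = 0.8
    frag_log_mean: float = math.log(300.0)
    frag_log_sd: float = 0.8
    frag_noise_sd: float = 0.35  # draw-2 multiplicative noise on the excess
    mm_drift_sd: float = 0.25

    progression_effect_log_mean: float = math.log(1500.0)
    progression_effect_log_sd: float = 1.0

    lysis_rate: float = 0.05  # per draw
    lysis_fold_range: Tuple[float, float] = (2.0, 10.0)  # raw-SM fold increase
    inhibitor_rate: float = 0.03  # per sample (draw)
    inhibitor_ct_shift: float = 2.5
    noncancer_event_rate: float = 0.08  # draw-2 proportional elevation
    noncancer_fold_range: Tuple[float, float] = (1.3, 3.0)

    ct_noise_sd: float = 0.15
    max_cycles: float = 40.0
    #: standard-curve (slope, intercept) per target; slope -3.3219 is a
    #: perfectly doubling reaction
    curve_params: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "SHORT80": (-3.3219, 38.0),
            "SHORT105": (-3.3219, 38.5),
            "SVA265": (-3.45, 39.0),
            "IPC172": (-3.3219, 37.0),
        }
    )
    ipc_quantity: float = 100.0  # copies per reaction, spiked constant
    sva_factor: float = 0.5  # SVA quantity as a fraction of MM concentration

    # fractions of patients generated to violate each eligibility gate
    transit_violation_rate: float = 0.0
    draw_window_violation_rate: float = 0.0
    scan_window_violation_rate: float = 0.0

    seed: int = 0

    def validate(self) -> None:
        rates = (
            self.prevalence, self.lysis_rate, self.inhibitor_rate,
            self.noncancer_event_rate, self.transit_violation_rate,
            self.draw_window_violation_rate, self.scan_window_violation_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        sds = (
            self.mm_log_sd, self.frag_log_sd, self.frag_noise_sd,
            self.mm_drift_sd, self.progression_effect_log_sd, self.ct_noise_sd,
        )
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for lo, hi in (self.lysis_fold_range, self.noncancer_fold_range):
            if not 1.0 <= lo <= hi:
                raise ValueError("fold ranges must satisfy 1 <= low <= high")


def default_curves(config: Optional[ScenarioConfig] = None) -> Dict[Target, StandardCurve]:
    """Exact standard curves at the configured (slope, intercept)."""
    cfg = config or ScenarioConfig()
    out = {}
    for name, (slope, intercept) in cfg.curve_params.items():
        target = Target(name)
        out[target] = StandardCurve(
            target=target, slope=slope, intercept=intercept, r2=1.0,
            efficiency=10.0 ** (-1.0 / slope) - 1.0,
        )
    return out


def standard_points(
    curve: StandardCurve,
    quantities: Sequence[float] = (1e1, 1e2, 1e3, 1e4, 1e5),
    replicates: int = 3,
    ct_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[float, float]]:
    """Simulated standard-curve points (quantity, Ct) on a curve."""
    rng = rng or np.random.default_rng(0)
    pts = []
    for q in quantities:
        for _ in range(replicates):
            ct = curve.ct_of(q)
            if ct_noise_sd > 0:
                ct += rng.normal(0.0, ct_noise_sd)
            pts.append((float(q), float(ct)))
    return pts


def _plasma_to_reaction(conc: float) -> float:
    """copies/mL plasma -> copies per reaction (inverse of the unit
    conversion in :mod:`fragscore.qpcr`)."""
    return conc * (PLASMA_UL / 1000.0) / (ELUATE_UL / REACTION_TEMPLATE_UL)


def generate_cohort(
    config: Optional[ScenarioConfig] = None,
) -> Tuple[List[CohortRecord], List[FragmentProfile], pd.DataFrame]:
    """Generate a cohort with records, measured profiles and ground truth.

    Returns
    -------
    (records, profiles, truth)
        ``profiles`` carry the artifact-laden (lysis / non-cancer event)
        concentrations the lab would measure; ``truth`` holds the
        pre-artifact concentrations, the true labels and per-patient
        artifact flags, aligned 1:1 with the cohort.
    """
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t0 = datetime(2024, 1, 8, 9, 0, 0)

    records: List[CohortRecord] = []
    profiles: List[FragmentProfile] = []
    truth_rows: List[dict] = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"
        progressed = bool(rng.random() < cfg.prevalence)

        mm1 = float(rng.lognormal(cfg.mm_log_mean, cfg.mm_log_sd))
        frag1 = float(rng.lognormal(cfg.frag_log_mean, cfg.frag_log_sd))
        sm1 = mm1 + frag1
        frag2 = frag1 * float(np.exp(rng.normal(0.0, cfg.frag_noise_sd)))
        if progressed:
            frag2 += float(
                rng.lognormal(cfg.progression_effect_log_mean, cfg.progression_effect_log_sd)
            )
        mm2 = mm1 * float(np.exp(rng.normal(0.0, cfg.mm_drift_sd)))
        sm2 = mm2 + frag2

        true_conc = {"SM1": sm1, "MM1": mm1, "SM2": sm2, "MM2": mm2}
        meas = dict(true_conc)

        noncancer = bool(rng.random() < cfg.noncancer_event_rate)
        if noncancer:
            fold = float(np.exp(rng.uniform(*np.log(cfg.noncancer_fold_range))))
            meas["SM2"] *= fold
            meas["MM2"] *= fold

        lysis = [bool(rng.random() < cfg.lysis_rate) for _ in (1, 2)]
        for d, hit in zip((1, 2), lysis):
            if hit:
                fold = float(rng.uniform(*cfg.lysis_fold_range))
                g = meas[f"SM{d}"] * (fold - 1.0)  # common genomic-DNA spike
                meas[f"SM{d}"] += g
                meas[f"MM{d}"] += g

        inhibited = [bool(rng.random() < cfg.inhibitor_rate) for _ in (1, 2)]

        # timestamps satisfying every gate unless a violation is requested
        treatment = t0 + timedelta(days=int(rng.integers(0, 365)))
        c1 = treatment - timedelta(days=1)
        transit1 = float(rng.uniform(18.0, 72.0))
        d2_days = int(rng.integers(12, 22))
        if rng.random() < cfg.draw_window_violation_rate:
            d2_days = int(rng.integers(22, 40))
        c2 = treatment + timedelta(days=d2_days)
        transit2 = float(rng.uniform(18.0, 72.0))
        if rng.random() < cfg.transit_violation_rate:
            transit2 = float(rng.uniform(121.0, 200.0))
        scan_weeks = float(rng.uniform(9.0, 12.0))
        if rng.random() < cfg.scan_window_violation_rate:
            scan_weeks = float(rng.uniform(12.5, 16.0))

        if progressed:
            change_pct = float(rng.uniform(20.0, 80.0))
        else:
            change_pct = float(rng.uniform(-30.0, 19.0))

        draws = (
            SampleDraw(pid, 1, c1, c1 + timedelta(hours=transit1)),
            SampleDraw(pid, 2, c2, c2 + timedelta(hours=transit2)),
        )
        records.append(
            CohortRecord(
                patient_id=pid,
                cancer_type=str(rng.choice(["breast", "colorectal", "lung"])),
                draws=draws,
                treatment_date=treatment,
                baseline_scan_date=treatment - timedelta(days=7),
                assessment_scan_date=c1 + timedelta(days=scan_weeks * 7.0),
                outcome=ProgressionLabel.from_change_pct(change_pct),
            )
        )
        profiles.append(FragmentProfile(patient_id=pid, **meas))
        truth_rows.append(
            {
                "patient_id": pid,
                "progressed": progressed,
                "true_SM1": sm1, "true_MM1": mm1,
                "true_SM2": sm2, "true_MM2": mm2,
                "lysis_draw1": lysis[0], "lysis_draw2": lysis[1],
                "inhibited_draw1": inhibited[0], "inhibited_draw2": inhibited[1],
                "noncancer_event": noncancer,
            }
        )
    return records, profiles, pd.DataFrame(truth_rows)


def simulate_plate(
    profile: FragmentProfile,
    curves: Mapping[Target, StandardCurve],
    config: Optional[ScenarioConfig] = None,
    rng: Optional[np.random.Generator] = None,
    inhibited_draws: Sequence[int] = (),
) -> List[QpcrWell]:
    """Simulate triplicate wells for both draws of one patient.

    Sample ids are ``<patient>-D<draw>``.  Ct values are drawn from the
    target's standard curve plus replicate noise; inhibited samples shift
    every target including the IPC; Ct beyond the cycle count is emitted
    as missing.
    """
    cfg = config or ScenarioConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    wells: List[QpcrWell] = []
    for draw in (1, 2):
        sid = f"{profile.patient_id}-D{draw}"
        shift = cfg.inhibitor_ct_shift if draw in inhibited_draws else 0.0
        sm = getattr(profile, f"SM{draw}")
        mm = getattr(profile, f"MM{draw}")
        conc_for = {
            Target.SHORT80: sm,
            Target.SHORT105: mm,
            Target.SVA265: mm * cfg.sva_factor,
        }
        for mpx, targets in MULTIPLEX_TARGETS.items():
            for target in targets:
                if target is Target.IPC172:
                    q = cfg.ipc_quantity
                else:
                    q = _plasma_to_reaction(conc_for[target])
                for rep in (1, 2, 3):
                    if q <= 0:
                        ct = None
                    else:
                        val = curves[target].ct_of(q) + shift
                        if cfg.ct_noise_sd > 0:
                            val += float(rng.normal(0.0, cfg.ct_noise_sd))
                        ct = None if val > cfg.max_cycles else float(val)
                    wells.append(
                        QpcrWell(
                            sample_id=sid,
                            multiplex=mpx,
                            target=target,
                            dye=DYE_FOR_TARGET[target],
                            replicate=rep,
                            ct=ct,
                            well=f"{sid}-M{mpx}-{target.value}-R{rep}",
                        )
                    )
    return wells


def draw_map(profiles: Sequence[FragmentProfile]) -> Dict[str, Tuple[str, int]]:
    """sample_id -> (patient_id, draw_index) for plates from simulate_plate."""
    out = {}
    for p in profiles:
        for d in (1, 2):
            out[f"{p.patient_id}-D{d}"] = (p.patient_id, d)
    return out


def generate_noncancer_panel(
    config: Optional[ScenarioConfig] = None,
    panel: Mapping[str, Tuple[int, float]] = DEFAULT_PANEL,
    n_healthy: int = 9,
    short_only: bool = False,
) -> pd.DataFrame:
    """Interference panel: condition-labeled subjects plus healthy controls.

    Healthy subjects follow the baseline concentration distributions in
    both draws.  Condition subjects experience the event before draw 2,
    elevating both size classes by the condition multiplier (the
    proportional elevation the fragmentomic difference largely cancels);
    ``short_only=True`` instead elevates only the short class, the pattern
    that *does* mimic progression.

    Returns a profile table (SM1..MM2) with ``group`` and ``condition``
    columns.
    """
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []

    def one_subject(sid: str, group: str, condition: str, mult: float) -> dict:
        mm1 = float(rng.lognormal(cfg.mm_log_mean, cfg.mm_log_sd))
        frag1 = float(rng.lognormal(cfg.frag_log_mean, cfg.frag_log_sd))
        sm1 = mm1 + frag1
        frag2 = frag1 * float(np.exp(rng.normal(0.0, cfg.frag_noise_sd)))
        mm2 = mm1 * float(np.exp(rng.normal(0.0, cfg.mm_drift_sd)))
        sm2 = mm2 + frag2
        if mult > 1.0:
            if short_only:
                sm2 += (mult - 1.0) * sm2
            else:
                sm2 *= mult
                mm2 *= mult
        return {
            "patient_id": sid, "group": group, "condition": condition,
            "SM1": sm1, "MM1": mm1, "SM2": sm2, "MM2": mm2,
        }

    for h in range(n_healthy):
        rows.append(one_subject(f"H{h + 1:03d}", "healthy", "healthy", 1.0))
    i = 0
    for condition, (n, mult) in panel.items():
        for _ in range(n):
            i += 1
            rows.append(one_subject(f"N{i:03d}", "condition", condition, mult))
    return pd.DataFrame(rows)
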