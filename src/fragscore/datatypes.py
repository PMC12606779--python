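"""Domain types for the Progression Score assay pipeline.

The assay measures, per blood draw, the plasma concentration of cell-free
DNA longer than 80 bp (short marker, SM) and longer than 105 bp
(mid marker, MM) by multiplex qPCR against high-copy retrotransposon
targets.  Their difference estimates the short-fragment excess enriched in
tumor-derived cfDNA.  Types here carry the data between pipeline stages;
they hold no behaviour beyond validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Optional, Sequence

# RECIST-style progression boundary: >=20% increase in sum of target-lesion
# diameters calls progression (boundary inclusive).
PROGRESSION_DIAMETER_PCT = 20.0


class Target(str, Enum):
    """qPCR amplicon targets.

    SHORT80 / SHORT105 are ALU amplicons of 80 and 105 bp: an amplicon of
    length L amplifies only templates >= L bp, so each measures the ">L bp"
    cfDNA concentration.  SVA265 is a 265 bp cross-multiplex concordance
    control, IPC172 a 172 bp spiked synthetic inhibition control.
    """

    SHORT80 = "SHORT80"
    SHORT105 = "SHORT105"
    SVA265 = "SVA265"
    IPC172 = "IPC172"


class Dye(str, Enum):
    FAM = "FAM"
    CY5 = "Cy5"
    HEX = "HEX"


#: Dye-target pairing fixed by the assay design: short ALU probes carry FAM,
#: the long SVA probe Cy5, the IPC HEX.
DYE_FOR_TARGET = {
    Target.SHORT80: Dye.FAM,
    Target.SHORT105: Dye.FAM,
    Target.SVA265: Dye.CY5,
    Target.IPC172: Dye.HEX,
}

#: Multiplex layout: multiplex 1 carries the 80 bp ALU target, multiplex 2
#: the 105 bp ALU target; both carry SVA265 and IPC172.
MULTIPLEX_TARGETS = {
    1: (Target.SHORT80, Target.SVA265, Target.IPC172),
    2: (Target.SHORT105, Target.SVA265, Target.IPC172),
}


@dataclass(frozen=True)
class SampleDraw:
    """One blood draw with transit timestamps and plasma volume."""

    patient_id: str
    draw_index: int
    collected_at: datetime
    received_at: datetime
    plasma_volume_uL: float = 500.0

    def __post_init__(self) -> None:
        if self.draw_index not in (1, 2):
            raise ValueError(f"draw_index must be 1 or 2, got {self.draw_index}")
        if self.received_at < self.collected_at:
            raise ValueError(
                f"{self.patient_id} draw {self.draw_index}: received_at precedes collected_at"
            )
        if not self.plasma_volume_uL > 0:
            raise ValueError("plasma_volume_uL must be positive")

    @property
    def transit_hours(self) -> float:
        return (self.received_at - self.collected_at).total_seconds() / 3600.0


@dataclass(frozen=True)
class ProgressionLabel:
    """Imaging outcome: progression iff lesion-diameter sum grew >= 20%."""

    progressed: bool
    sum_diameter_change_pct: float

    def __post_init__(self) -> None:
        expected = self.sum_diameter_change_pct >= PROGRESSION_DIAMETER_PCT
        if self.progressed != expected:
            raise ValueError(
                "progressed inconsistent with sum_diameter_change_pct "
                f"({self.sum_diameter_change_pct}%)"
            )

    @classmethod
    def from_change_pct(cls, pct: float) -> "ProgressionLabel":
        return cls(progressed=pct >= PROGRESSION_DIAMETER_PCT, sum_diameter_change_pct=pct)


@dataclass
class CohortRecord:
    """One enrolled patient: two draws, treatment/scan dates, outcome.

    ``outcome`` may be missing at scoring time (prospective use); model
    fitting and calibration require it.  Clinical exclusion flags mirror
    enrollment criteria the assay itself cannot diagnose.
    """

    patient_id: str
    cancer_type: str
    draws: tuple  # (SampleDraw, SampleDraw)
    treatment_date: datetime
    baseline_scan_date: datetime
    assessment_scan_date: Optional[datetime]
    outcome: Optional[ProgressionLabel] = None
    secondary_malignancy: bool = False
    autoimmune_treatment: bool = False
    recent_dvt_pe_sepsis: bool = False

    def __post_init__(self) -> None:
        if len(self.draws) != 2:
            raise ValueError(f"{self.patient_id}: exactly two draws required")
        d1, d2 = self.draws
        if not (d1.draw_index == 1 and d2.draw_index == 2):
            raise ValueError(f"{self.patient_id}: draws must be ordered (1, 2)")
        if d2.collected_at < d1.collected_at:
            raise ValueError(f"{self.patient_id}: draw 1 must precede draw 2")


@dataclass(frozen=True)
class QpcrWell:
    """One well's quantification cycle for one target in one multiplex.

    ``ct`` is None when the instrument reports no amplification within the
    run's cycle count ("Undetermined").
    """

    sample_id: str
    multiplex: int
    target: Target
    dye: Dye
    replicate: int
    ct: Optional[float]
    well: str = ""

    def __post_init__(self) -> None:
        if self.multiplex not in (1, 2):
            raise ValueError(f"multiplex must be 1 or 2, got {self.multiplex}")
        if self.target not in MULTIPLEX_TARGETS[self.multiplex]:
            raise ValueError(
                f"target {self.target.value} not carried by multiplex {self.multiplex}"
            )
        if not 1 <= self.replicate <= 3:
            raise ValueError(f"replicate must be in 1..3, got {self.replicate}")
        if self.ct is not None and not self.ct >= 0:
            raise ValueError(f"ct must be >= 0 or missing, got {self.ct}")


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear qPCR standard curve Ct = slope * log10(q) + intercept.

    ``efficiency`` is the per-cycle amplification gain minus one:
    10**(-1/slope) - 1, so a perfect doubling curve (slope -3.3219) has
    efficiency 1.0.
    """

    target: Target
    slope: float
    intercept: float
    r2: float
    efficiency: float

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError("standard curve slope must be negative")
        if not math.isclose(
            self.efficiency, 10.0 ** (-1.0 / self.slope) - 1.0, rel_tol=1e-9
        ):
            raise ValueError("efficiency inconsistent with slope")

    def ct_of(self, quantity: float) -> float:
        """Expected Ct for a template quantity (> 0) in the reaction."""
        if not quantity > 0:
            raise ValueError("quantity must be positive")
        return self.slope * math.log10(quantity) + self.intercept


@dataclass
class FragmentProfile:
    """Per-patient plasma concentrations (copies/mL) of both size classes.

    SM = ">80 bp" concentration, MM = ">105 bp"; suffix 1/2 = first/second
    blood draw.
    """

    patient_id: str
    SM1: float
    MM1: float
    SM2: float
    MM2: float
    flags: tuple = ()

    def __post_init__(self) -> None:
        for name in ("SM1", "MM1", "SM2", "MM2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.patient_id}: {name} negative")


@dataclass(frozen=True)
class DerivedFeatures:
    """The four derived fragmentomic predictors.

    Frag1/Frag2 are the floored short-fragment excesses per draw;
    FragDiff and MMDiff are signed between-draw changes (not floored).
    """

    patient_id: str
    Frag1: float
    Frag2: float
    FragDiff: float
    MMDiff: float

    def __post_init__(self) -> None:
        if self.Frag1 < 0 or self.Frag2 < 0:
            raise ValueError("Frag1/Frag2 are floored at zero and cannot be negative")


@dataclass(frozen=True)
class QcVerdict:
    """Outcome of one QC rule for one subject (patient, sample or run)."""

    subject: str
    rule: str
    passed: bool
    detail: str = ""
    indeterminate: bool = False


@dataclass(frozen=True)
class ModelSpec:
    """One of the six pre-defined logistic models (ordered predictors)."""

    name: str
    predictors: tuple

    def __post_init__(self) -> None:
        allowed = {"FragDiff", "Frag1", "SM1", "MMDiff"}
        bad = set(self.predictors) - allowed
        if bad:
            raise ValueError(f"unknown predictors: {sorted(bad)}")


#: The six pre-defined models, in their canonical order.  Each pairs a
#: biological hypothesis with a predictor subset: FragDiff tracks change in
#: tumor burden; Frag1/SM1 add initial burden; MMDiff is expected to clean
#: up non-tumor cfDNA noise (negative coefficient).
PREDEFINED_MODELS = (
    ModelSpec("FragDiff", ("FragDiff",)),
    ModelSpec("Frag1 + FragDiff", ("Frag1", "FragDiff")),
    ModelSpec("SM1 + FragDiff", ("SM1", "FragDiff")),
    ModelSpec("MMDiff + FragDiff", ("MMDiff", "FragDiff")),
    ModelSpec("Frag1 + MMDiff + FragDiff", ("Frag1", "MMDiff", "FragDiff")),
    ModelSpec("SM1 + MMDiff + FragDiff", ("SM1", "MMDiff", "FragDiff")),
)


@dataclass
class FitResult:
    """A fitted logistic model with its diagnostics."""

    spec: ModelSpec
    coefficients: dict  # name -> estimate; includes "Intercept"
    std_errors: dict
    p_values: dict  # Wald, per coefficient
    training_auc: float
    model_p_value: float  # LRT vs intercept-only
    bonferroni_adjusted_p: float
    log_likelihood: float
    converged: bool
    separation_flag: bool
    n_iterations: int
    loocv_auc: Optional[float] = None
    error: Optional[str] = None
    notes: str = ""

    @property
    def nonsignificant_added(self) -> Sequence[str]:
        """Predictors with Wald p > 0.05 (mirrors Table-style footnotes)."""
        return [
            p for p in self.spec.predictors if self.p_values.get(p, 0.0) > 0.05
        ]


@dataclass(frozen=True)
class PSResult:
    """A patient's Progression Score and call."""

    patient_id: str
    ps: float
    call: str  # "progression" | "likely-non-progression"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ps <= 100.0:
            raise ValueError("PS must lie in [0, 100]")
        if self.call not in ("progression", "likely-non-progression"):
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class CutpointCalibration:
    """Bootstrap expected-PPV curve over candidate PS thresholds.

    ``expected_ppv`` is aligned with ``candidate_thresholds``; entries are
    NaN where no bootstrap iteration produced any call at that threshold.
    """

    candidate_thresholds: tuple
    expected_ppv: tuple
    n_defined: tuple  # bootstrap iterations contributing per threshold
    n_bootstrap: int
    min_ppv: float
    selected_cutpoint: Optional[float]
    seed: int
    best_achievable: Optional[float] = None

    def __post_init__(self) -> None:
        th = self.candidate_thresholds
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("candidate thresholds must be strictly ascending")
        if self.selected_cutpoint is not None and self.selected_cutpoint not in th:
            raise ValueError("selected cut-point must be a candidate threshold")

    def expected_ppv_at(self, threshold: float) -> float:
        return self.expected_ppv[self.candidate_thresholds.index(threshold)]


@dataclass
class PerformanceTable:
    """2x2 call-vs-imaging contingency counts with PPV/NPV."""

    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int
    n_missing_outcome: int = 0

    @property
    def n_called(self) -> int:
        return self.true_positives + self.false_positives

    @property
    def n_not_called(self) -> int:
        return self.true_negatives + self.false_negatives

    @property
    def ppv(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")

    @property
    def npv(self) -> float:
        denom = self.true_negatives + self.false_negatives
        return self.true_negatives / denom if denom else float("nan")
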