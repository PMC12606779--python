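"""Shared fixtures: a seed-fixed default synthetic cohort and toy data."""

from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fragscore import ScenarioConfig, features_frame, generate_cohort
from fragscore.datatypes import CohortRecord, ProgressionLabel, SampleDraw

COHORT_SEED = 1


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: n=128, prevalence 20/128, fixed seed."""
    records, profiles, truth = generate_cohort(ScenarioConfig(seed=COHORT_SEED))
    feats = features_frame(profiles)
    labels = truth["progressed"].astype(float).to_numpy()
    return records, profiles, truth, feats, labels


@pytest.fixture
def make_record():
    """Factory for a minimal valid CohortRecord with adjustable timing."""

    def _make(
        pid="P1",
        transit2_hours=24.0,
        draw2_days=14.0,
        scan_weeks=10.0,
        change_pct=None,
    ):
        treatment = datetime(2024, 3, 1, 9, 0)
        c1 = treatment - timedelta(days=1)
        c2 = treatment + timedelta(days=draw2_days)
        return CohortRecord(
            patient_id=pid,
            cancer_type="lung",
            draws=(
                SampleDraw(pid, 1, c1, c1 + timedelta(hours=24.0)),
                SampleDraw(pid, 2, c2, c2 + timedelta(hours=transit2_hours)),
            ),
            treatment_date=treatment,
            baseline_scan_date=treatment - timedelta(days=7),
            assessment_scan_date=c1 + timedelta(weeks=scan_weeks),
            outcome=(
                ProgressionLabel.from_change_pct(change_pct)
                if change_pct is not None
                else None
            ),
        )

    return _make
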