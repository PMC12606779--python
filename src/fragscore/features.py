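"""Derived fragmentomic variables.

Frag = SM - MM floored at zero is the short-fragment excess of one draw:
the concentration of cfDNA between 80 and 105 bp, the size band enriched
for tumor-derived fragments.  Because white-blood-cell lysis adds genomic
DNA to both size classes roughly equally, the subtraction cancels it —
the mechanism that keeps transport artifacts from mimicking progression.
FragDiff and MMDiff are signed between-draw changes; only the per-draw
excesses are floored.
"""

from __future__ import annotations

from typing import Iterable, List

import pandas as pd

from .datatypes import DerivedFeatures, FragmentProfile


def compute_frag(sm: float, mm: float) -> float:
    """Short-fragment excess max(SM - MM, 0) for one draw."""
    if sm < 0 or mm < 0:
        raise ValueError("concentrations must be non-negative")
    return max(sm - mm, 0.0)


def derive_features(profile: FragmentProfile) -> DerivedFeatures:
    """Frag1, Frag2, FragDiff = Frag2 - Frag1, MMDiff = MM2 - MM1."""
    frag1 = compute_frag(profile.SM1, profile.MM1)
    frag2 = compute_frag(profile.SM2, profile.MM2)
    return DerivedFeatures(
        patient_id=profile.patient_id,
        Frag1=frag1,
        Frag2=frag2,
        FragDiff=frag2 - frag1,
        MMDiff=profile.MM2 - profile.MM1,
    )


def features_frame(profiles: Iterable[FragmentProfile]) -> pd.DataFrame:
    """Features table: one row per patient, raw concentrations passed through."""
    rows: List[dict] = []
    for p in profiles:
        f = derive_features(p)
        rows.append(
            {
                "patient_id": p.patient_id,
                "SM1": p.SM1,
                "MM1": p.MM1,
                "SM2": p.SM2,
                "MM2": p.MM2,
                "Frag1": f.Frag1,
                "Frag2": f.Frag2,
                "FragDiff": f.FragDiff,
                "MMDiff": f.MMDiff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "SM1", "MM1", "SM2", "MM2",
            "Frag1", "Frag2", "FragDiff", "MMDiff",
        ],
    )


def compute_ps_change(ps: float, healthy_mean_ps: float) -> float:
    """PS relative to the healthy-cohort mean.

    Used for non-cancer interference panels: a positive value means the
    subject scores above healthy controls, i.e. the condition could mimic
    a progression-like signal.
    """
    for v in (ps, healthy_mean_ps):
        if not 0.0 <= v <= 100.0:
            raise ValueError("PS values must lie in [0, 100]")
    return ps - healthy_mean_ps
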