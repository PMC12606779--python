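"""Standard-curve quantification of cfDNA from triplicate Ct values.

qPCR quantification is log-linear: Ct = slope * log10(quantity) + intercept,
with slope near -3.32 for a perfectly doubling reaction.  Quantities are in
copies per reaction against calibrated standards, then converted to copies
per mL plasma through the extraction volumes (500 uL plasma -> 60 uL eluate,
2 uL template per reaction).
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from scipy import stats

from .datatypes import FragmentProfile, QpcrWell, StandardCurve, Target

#: Triplicate Ct spread above which the aggregate is flagged high-scatter.
DEFAULT_SCATTER_CT = 0.5
#: Minimum acceptable r-squared for a standard curve.
DEFAULT_MIN_R2 = 0.98

# Volume constants of the extraction protocol.
REACTION_TEMPLATE_UL = 2.0
ELUATE_UL = 60.0
PLASMA_UL = 500.0


def fit_standard_curve(
    points: Sequence[Tuple[float, float]],
    target: Target = Target.SHORT80,
    min_r2: float = DEFAULT_MIN_R2,
) -> StandardCurve:
    """Least-squares fit of the log-linear standard curve.

    Parameters
    ----------
    points
        ``(known_quantity, ct)`` pairs; at least three distinct positive
        quantity levels are required.
    target
        Amplicon the curve belongs to.
    min_r2
        Curves below this r-squared are rejected as unusable.

    Returns
    -------
    StandardCurve
        With slope (Ct per log10 quantity), intercept, r-squared and the
        amplification efficiency ``10**(-1/slope) - 1``.
    """
    if any(q <= 0 for q, _ in points):
        raise ValueError("standard quantities must be positive")
    if any(ct is None for _, ct in points):
        raise ValueError("standard-curve Ct values must all be present")
    levels = {q for q, _ in points}
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct quantity levels, got {len(levels)}"
        )
    logq = [math.log10(q) for q, _ in points]
    cts = [ct for _, ct in points]
    fit = stats.linregress(logq, cts)
    if fit.slope >= 0:
        raise ValueError("inverted curve: Ct must decrease with quantity")
    r2 = fit.rvalue**2
    if r2 < min_r2:
        raise ValueError(f"standard curve r2 {r2:.4f} below minimum {min_r2}")
    return StandardCurve(
        target=target,
        slope=fit.slope,
        intercept=fit.intercept,
        r2=r2,
        efficiency=10.0 ** (-1.0 / fit.slope) - 1.0,
    )


def aggregate_replicates(
    cts: Sequence[Optional[float]], max_scatter_ct: float = DEFAULT_SCATTER_CT
) -> Tuple[Optional[float], Tuple[str, ...]]:
    """Mean Ct over a triplicate, with dropout / scatter flags.

    Missing replicates are excluded from the mean and flagged ``dropout``;
    a spread above ``max_scatter_ct`` among present replicates flags
    ``high-scatter``; all-missing yields a missing mean with
    ``no-amplification``.
    """
    if not 1 <= len(cts) <= 3:
        raise ValueError("expected 1-3 replicate Ct values")
    present = [c for c in cts if c is not None]
    flags: List[str] = []
    if not present:
        return None, ("no-amplification",)
    if len(present) < len(cts):
        flags.append("dropout")
    if max(present) - min(present) > max_scatter_ct:
        flags.append("high-scatter")
    return sum(present) / len(present), tuple(flags)


def quantify(mean_ct: Optional[float], curve: StandardCurve) -> Tuple[float, Tuple[str, ...]]:
    """Invert the standard curve: quantity = 10**((ct - intercept) / slope).

    A missing Ct quantifies as zero with a ``no-amplification`` flag
    (template below the assay's detection floor).
    """
    if mean_ct is None:
        return 0.0, ("no-amplification",)
    return 10.0 ** ((mean_ct - curve.intercept) / curve.slope), ()


def to_plasma_concentration(
    q_reaction: float,
    reaction_template_uL: float = REACTION_TEMPLATE_UL,
    eluate_uL: float = ELUATE_UL,
    plasma_uL: float = PLASMA_UL,
) -> float:
    """Copies per reaction -> copies per mL plasma.

    The reaction sees ``reaction_template_uL`` of an ``eluate_uL`` eluate
    extracted from ``plasma_uL`` of plasma, so
    ``c = q * (eluate/template) / (plasma/1000)``.
    """
    if min(reaction_template_uL, eluate_uL, plasma_uL) <= 0:
        raise ValueError("all volumes must be positive")
    return q_reaction * (eluate_uL / reaction_template_uL) / (plasma_uL / 1000.0)


def sva_quantities(
    wells: Sequence[QpcrWell], curves: Mapping[Target, StandardCurve]
) -> Tuple[Optional[float], Optional[float]]:
    """Per-multiplex SVA quantity for one sample (concordance QC input)."""
    out: Dict[int, Optional[float]] = {1: None, 2: None}
    by_mpx: Dict[int, List[Optional[float]]] = defaultdict(list)
    for w in wells:
        if w.target is Target.SVA265:
            by_mpx[w.multiplex].append(w.ct)
    for mpx, cts in by_mpx.items():
        mean_ct, _ = aggregate_replicates(cts)
        if mean_ct is not None:
            q, _ = quantify(mean_ct, curves[Target.SVA265])
            out[mpx] = q
    return out[1], out[2]


def build_profiles(
    wells: Sequence[QpcrWell],
    curves: Mapping[Target, StandardCurve],
    draws: Mapping[str, Tuple[str, int]],
    plasma_uL: float = PLASMA_UL,
) -> Tuple[List[FragmentProfile], List[str]]:
    """Assemble per-patient fragment profiles from QC-passing wells.

    Parameters
    ----------
    wells
        Wells surviving QC.  SM comes from the 80 bp target in multiplex 1,
        MM from the 105 bp target in multiplex 2.
    curves
        Standard curve per target, from the same run as the wells.
    draws
        ``sample_id -> (patient_id, draw_index)``.  Several sample_ids may
        map to the same draw (duplicate extractions); their concentrations
        are averaged at the concentration level, not the Ct level.

    Returns
    -------
    (profiles, unquantifiable)
        Profiles for patients with all four concentrations, and the ids of
        patients lacking either target in either draw (excluded from
        modeling upstream).
    """
    # (patient, draw, target) -> {sample_id: [cts]}
    grouped: Dict[Tuple[str, int, Target], Dict[str, List[Optional[float]]]] = (
        defaultdict(lambda: defaultdict(list))
    )
    for w in wells:
        if w.sample_id not in draws:
            continue
        pid, didx = draws[w.sample_id]
        if (w.target, w.multiplex) == (Target.SHORT80, 1) or (
            w.target,
            w.multiplex,
        ) == (Target.SHORT105, 2):
            grouped[(pid, didx, w.target)][w.sample_id].append(w.ct)

    conc: Dict[Tuple[str, int, Target], float] = {}
    flags: Dict[str, List[str]] = defaultdict(list)
    for key, extractions in grouped.items():
        pid, didx, target = key
        per_extraction = []
        for sid, cts in extractions.items():
            mean_ct, agg_flags = aggregate_replicates(cts)
            for f in agg_flags:
                flags[pid].append(f"{target.value}/draw{didx}:{f}")
            if mean_ct is None:
                continue
            q, _ = quantify(mean_ct, curves[target])
            per_extraction.append(to_plasma_concentration(q, plasma_uL=plasma_uL))
        if per_extraction:
            if len(per_extraction) < len(extractions):
                flags[pid].append(f"{target.value}/draw{didx}:extraction-dropout")
            conc[key] = sum(per_extraction) / len(per_extraction)

    patients = sorted({pid for pid, _, _ in conc})
    profiles, unquantifiable = [], []
    for pid in patients:
        needed = {
            "SM1": (pid, 1, Target.SHORT80),
            "MM1": (pid, 1, Target.SHORT105),
            "SM2": (pid, 2, Target.SHORT80),
            "MM2": (pid, 2, Target.SHORT105),
        }
        if any(k not in conc for k in needed.values()):
            unquantifiable.append(pid)
            continue
        profiles.append(
            FragmentProfile(
                patient_id=pid,
                SM1=conc[needed["SM1"]],
                MM1=conc[needed["MM1"]],
                SM2=conc[needed["SM2"]],
                MM2=conc[needed["MM2"]],
                flags=tuple(flags.get(pid, ())),
            )
        )
    return profiles, unquantifiable
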