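"""Progression Score scaling, bootstrap cut-point calibration, calls.

The Progression Score is the selected model's predicted progression
probability scaled to 0-100 and rounded to one decimal.  The call
threshold is chosen so that the *expected* positive predictive value —
estimated by refitting the model on bootstrap resamples of the training
cohort and averaging the PPV of each candidate threshold over resamples —
meets a target (99% by default), prioritising specificity: a progression
call should very rarely be wrong.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import CutpointCalibration, ModelSpec, PerformanceTable, PSResult
from .model import fit_logistic, predict_proba


def ps_from_prob(p: float) -> float:
    """Map a predicted probability to the 0-100 Progression Score
    (one-decimal rounding)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return round(100.0 * p, 1)


def classify(ps: float, cutpoint: float) -> str:
    """Call progression iff PS >= cut-point (boundary calls progression)."""
    for v in (ps, cutpoint):
        if not 0.0 <= v <= 100.0:
            raise ValueError("PS and cut-point must lie in [0, 100]")
    return "progression" if ps >= cutpoint else "likely-non-progression"


def _ppv_curve(ps: np.ndarray, y: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Empirical PPV at each threshold; NaN where no calls are made."""
    out = np.full(len(thresholds), np.nan)
    for i, t in enumerate(thresholds):
        called = ps >= t
        n_called = int(called.sum())
        if n_called:
            out[i] = float(y[called].sum()) / n_called
    return out


def bootstrap_expected_ppv(
    features: pd.DataFrame,
    labels: Union[pd.Series, np.ndarray, Sequence[int]],
    spec: ModelSpec,
    n_bootstrap: int = 1000,
    thresholds: Optional[Sequence[float]] = None,
    seed: int = 0,
    refit: bool = True,
    min_ppv: float = 0.99,
) -> CutpointCalibration:
    """Bootstrap expected-PPV curve over candidate PS thresholds.

    Each iteration resamples the n patients with replacement, refits the
    model on the resample (propagating model uncertainty; set
    ``refit=False`` to rescore with the full-cohort fit instead), scores
    the resample's patients, and records PPV at every threshold where at
    least one call is made.  The expected PPV per threshold is the mean
    over the iterations where it was defined; thresholds never producing a
    call stay missing rather than being imputed, which would bias the
    curve towards the target.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    y = np.asarray(labels, dtype=float)
    n = len(y)
    th = np.asarray(
        list(thresholds) if thresholds is not None else np.arange(0, 101),
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    full_fit = fit_logistic(features, y, spec) if not refit else None

    ppv_sum = np.zeros(len(th))
    ppv_n = np.zeros(len(th), dtype=int)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        fb = features.iloc[idx]
        yb = y[idx]
        if yb.sum() == 0 or yb.sum() == n:
            continue  # degenerate resample carries no PPV information
        fit = fit_logistic(fb, yb, spec) if refit else full_fit
        probs = predict_proba(fit, fb)
        ps = np.round(100.0 * probs, 1)
        curve = _ppv_curve(ps, yb, th)
        defined = ~np.isnan(curve)
        ppv_sum[defined] += curve[defined]
        ppv_n[defined] += 1

    expected = np.where(ppv_n > 0, ppv_sum / np.maximum(ppv_n, 1), np.nan)
    return CutpointCalibration(
        candidate_thresholds=tuple(th.tolist()),
        expected_ppv=tuple(expected.tolist()),
        n_defined=tuple(ppv_n.tolist()),
        n_bootstrap=n_bootstrap,
        min_ppv=min_ppv,
        selected_cutpoint=None,
        seed=seed,
    )


def select_cutpoint(
    calib: CutpointCalibration, min_ppv: float = 0.99
) -> CutpointCalibration:
    """Choose the smallest stable threshold meeting the expected-PPV target.

    A threshold qualifies when its expected PPV is at least ``min_ppv``
    *and* every larger threshold with a defined expected PPV also meets the
    target — a one-time dip back below the target above the candidate
    would make calls at the candidate unsafe.

    Raises
    ------
    ValueError
        When no threshold qualifies; the message reports the best
        achievable expected PPV.
    """
    th = calib.candidate_thresholds
    ppv = calib.expected_ppv
    qualifies_above = True
    selected = None
    # scan from the top so the stability suffix condition is incremental
    for t, v in zip(reversed(th), reversed(ppv)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if v >= min_ppv and qualifies_above:
            selected = t
        else:
            qualifies_above = qualifies_above and v >= min_ppv
    defined = [v for v in ppv if not (isinstance(v, float) and math.isnan(v))]
    best = max(defined) if defined else None
    if selected is None:
        raise ValueError(
            "cannot meet PPV target "
            f"{min_ppv:g}; best achievable expected PPV is "
            f"{best if best is not None else float('nan'):.4f}"
        )
    return CutpointCalibration(
        candidate_thresholds=th,
        expected_ppv=ppv,
        n_defined=calib.n_defined,
        n_bootstrap=calib.n_bootstrap,
        min_ppv=min_ppv,
        selected_cutpoint=selected,
        seed=calib.seed,
        best_achievable=best,
    )


def score_patients(
    patient_ids: Sequence[str], probs: Sequence[float], cutpoint: float
) -> List[PSResult]:
    """Turn predicted probabilities into PS values and calls."""
    return [
        PSResult(pid, ps_from_prob(p), classify(ps_from_prob(p), cutpoint))
        for pid, p in zip(patient_ids, probs)
    ]


def performance(
    calls: Sequence[str], outcomes: Sequence[Optional[bool]]
) -> PerformanceTable:
    """2x2 contingency of calls against imaging outcomes with PPV and NPV.

    Patients with missing outcome are excluded from the counts and tallied
    in ``n_missing_outcome``.
    """
    if len(calls) != len(outcomes):
        raise ValueError("calls and outcomes must align")
    tp = fp = tn = fn = missing = 0
    for call, out in zip(calls, outcomes):
        if out is None:
            missing += 1
            continue
        called = call == "progression"
        if called and out:
            tp += 1
        elif called and not out:
            fp += 1
        elif not called and not out:
            tn += 1
        else:
            fn += 1
    return PerformanceTable(
        true_positives=tp,
        false_positives=fp,
        true_negatives=tn,
        false_negatives=fn,
        n_missing_outcome=missing,
    )
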