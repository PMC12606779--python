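"""Logistic model selection for progression prediction.

Six pre-defined predictor subsets of {FragDiff, Frag1, SM1, MMDiff} are fit
by maximum likelihood, ranked by training AUC with a Bonferroni-adjusted
likelihood-ratio p-value per model, and the preferred model is validated by
leave-one-out cross-validation.  The shape follows statsmodels:
``ProgressionScoreModel(features, labels).fit()`` returns a
``ProgressionScoreResults`` carrying the model table, the selected fit and
``summary()``.

The logistic MLE is an in-package iteratively reweighted least squares
(Newton) solver: predictors are standardized internally for conditioning,
convergence is declared when the score norm drops below 1e-8 (max 100
iterations), and quasi-complete separation is detected and flagged rather
than raised so that resampling loops never abort.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import PREDEFINED_MODELS, FitResult, ModelSpec

SCORE_TOL = 1e-8
MAX_ITER = 100
#: |standardized coefficient| beyond which a non-converged fit is treated as
#: diverging towards +-inf (quasi-complete separation).
SEPARATION_BETA = 12.0
WALD_ALPHA = 0.05


# ---------------------------------------------------------------------------
# core logistic MLE


def _irls(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float, bool, bool, int]:
    """Newton/IRLS logistic fit on a design matrix with intercept column.

    Returns (beta, covariance, loglik, converged, separation_flag, n_iter).
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = special.expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), score)
        # step-halving keeps Newton monotone on near-separated data
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            eta_c = X @ cand
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-13:
                beta, eta, ll = cand, eta_c, ll_c
                break
            factor *= 0.5
        else:
            break  # no improving step remains
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    separation = (not converged) and bool(np.max(np.abs(beta)) > SEPARATION_BETA)
    # fitted probabilities numerically pure 0/1 on the correct side is the
    # textbook signature of complete separation even if iteration stopped
    if not separation:
        separation = bool(ll > -1e-6 and np.all((mu > 0.5) == (y == 1)))
    return beta, cov, ll, converged, separation, it


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _null_loglik(y: np.ndarray) -> float:
    n = y.size
    k = float(y.sum())
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return k * math.log(p) + (n - k) * math.log(1.0 - p)


def fit_logistic(
    features: pd.DataFrame,
    labels: Union[pd.Series, np.ndarray, Sequence[int]],
    spec: ModelSpec,
) -> FitResult:
    """Maximum-likelihood logistic fit of one pre-defined model.

    Parameters
    ----------
    features
        Per-patient predictor table; must contain every column in
        ``spec.predictors`` with no missing values.
    labels
        Progression booleans (both classes required).
    spec
        Which predictor subset to fit.

    Returns
    -------
    FitResult
        Coefficients on the raw predictor scale, Wald standard errors and
        p-values, training AUC of the fitted probabilities, the
        likelihood-ratio p-value of the model against intercept-only, and
        convergence / separation diagnostics.
    """
    y = np.asarray(labels, dtype=float)
    if y.ndim != 1 or len(y) != len(features):
        raise ValueError("labels must align with the feature rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("degenerate outcome: need at least one case and one control")
    cols = list(spec.predictors)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"features table lacks columns {missing}")
    Xraw = features[cols].to_numpy(dtype=float)
    if np.isnan(Xraw).any():
        raise ValueError("missing predictor values are not allowed")

    # standardize for conditioning; coefficients mapped back afterwards
    mean = Xraw.mean(axis=0)
    sd = Xraw.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xraw - mean) / sd
    X = np.column_stack([np.ones(len(y)), Xs])

    beta_s, cov_s, ll, converged, separation, n_iter = _irls(X, y)

    # back-transform: beta_j = beta_s_j / sd_j ; b0 = b0_s - sum beta_s_j m_j / sd_j
    k = len(cols)
    A = np.zeros((k + 1, k + 1))
    A[0, 0] = 1.0
    A[0, 1:] = -mean / sd
    for j in range(k):
        A[j + 1, j + 1] = 1.0 / sd[j]
    beta = A @ beta_s
    cov = A @ cov_s @ A.T
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    names = ["Intercept"] + cols
    probs = special.expit(X @ beta_s)
    training_auc = auc(probs, y)

    ll0 = _null_loglik(y)
    lrt = max(2.0 * (ll - ll0), 0.0)
    model_p = float(stats.chi2.sf(lrt, df=k))

    notes = []
    nonsig = [c for c, p in zip(cols, pvals[1:]) if p > WALD_ALPHA]
    for c in nonsig:
        notes.append(f"{c} is not statistically significant.")
    if separation:
        notes.append("Quasi-complete separation detected; estimates diverge.")

    return FitResult(
        spec=spec,
        coefficients=dict(zip(names, beta.tolist())),
        std_errors=dict(zip(names, se.tolist())),
        p_values=dict(zip(names, pvals.tolist())),
        training_auc=training_auc,
        model_p_value=model_p,
        bonferroni_adjusted_p=min(1.0, model_p * len(PREDEFINED_MODELS)),
        log_likelihood=ll,
        converged=converged,
        separation_flag=separation,
        n_iterations=n_iter,
        notes=" ".join(notes),
    )


def predict_proba(
    fit: FitResult, features: pd.DataFrame
) -> np.ndarray:
    """Predicted progression probabilities of a fitted model on new rows."""
    cols = list(fit.spec.predictors)
    X = features[cols].to_numpy(dtype=float)
    beta = np.array([fit.coefficients[c] for c in cols])
    b0 = fit.coefficients["Intercept"]
    return special.expit(b0 + X @ beta)


# ---------------------------------------------------------------------------
# AUC and cross-validation


def auc(scores: Sequence[float], labels: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute one half.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def loocv_predictions(
    features: pd.DataFrame,
    labels: Union[pd.Series, np.ndarray, Sequence[int]],
    spec: ModelSpec,
) -> Tuple[np.ndarray, List[int]]:
    """Held-out probability per patient from n leave-one-out refits.

    Folds whose training set collapses to a single class predict the
    training prevalence instead and are returned as flagged indices.
    """
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs n >= 3")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("degenerate outcome: need both classes")
    preds = np.empty(n)
    flagged: List[int] = []
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        ytr = y[mask]
        if ytr.sum() == 0 or ytr.sum() == ytr.size:
            preds[i] = float(ytr.mean())
            flagged.append(i)
            continue
        fit = fit_logistic(features.iloc[mask], ytr, spec)
        preds[i] = predict_proba(fit, features.iloc[[i]])[0]
    return preds, flagged


def loocv_auc(
    features: pd.DataFrame,
    labels: Union[pd.Series, np.ndarray, Sequence[int]],
    spec: ModelSpec,
) -> float:
    """Pooled held-out AUC over all leave-one-out folds."""
    preds, _ = loocv_predictions(features, labels, spec)
    return auc(preds, np.asarray(labels, dtype=float))


# ---------------------------------------------------------------------------
# model table and selection


def evaluate_models(
    features: pd.DataFrame,
    labels: Union[pd.Series, np.ndarray, Sequence[int]],
    specs: Sequence[ModelSpec] = PREDEFINED_MODELS,
) -> List[FitResult]:
    """Fit every pre-defined model; a failing row records its error
    without aborting the others.  Bonferroni multiplier equals the number
    of pre-defined models (6)."""
    out: List[FitResult] = []
    for spec in specs:
        try:
            out.append(fit_logistic(features, labels, spec))
        except ValueError as exc:
            out.append(
                FitResult(
                    spec=spec, coefficients={}, std_errors={}, p_values={},
                    training_auc=float("nan"), model_p_value=float("nan"),
                    bonferroni_adjusted_p=float("nan"),
                    log_likelihood=float("nan"), converged=False,
                    separation_flag=False, n_iterations=0, error=str(exc),
                )
            )
    return out


def select_best(
    table: Sequence[FitResult],
    selection: str = "parsimony-on-flag",
    auc_tol: float = 0.0,
) -> FitResult:
    """Pick the preferred model from the six-model table.

    ``selection="highest-auc"`` is the literal rule: argmax training AUC,
    ties broken by fewer predictors then canonical order, with flagged
    (non-significant-predictor) models disfavored only on exact ties.

    ``selection="parsimony-on-flag"`` (default) restricts the argmax to
    models whose every predictor is significant (Wald p <= 0.05) whenever
    at least one such model exists — matching the practice of preferring
    a smaller model when the extra predictor adds no significant
    information even if its training AUC is marginally higher.
    """
    fitted = [f for f in table if f.error is None and not math.isnan(f.training_auc)]
    if not fitted:
        raise ValueError("no successfully fitted model to select from")
    order = {id(f): i for i, f in enumerate(table)}

    def rank_key(f: FitResult):
        # higher AUC first; then fewer predictors; then clean models; then order
        return (
            -f.training_auc,
            len(f.spec.predictors),
            1 if f.nonsignificant_added else 0,
            order[id(f)],
        )

    if selection == "parsimony-on-flag":
        clean = [f for f in fitted if not f.nonsignificant_added]
        pool = clean if clean else fitted
        return min(pool, key=rank_key)
    if selection == "highest-auc":
        return min(fitted, key=rank_key)
    raise ValueError(f"unknown selection rule {selection!r}")


# ---------------------------------------------------------------------------
# statsmodels-style front end


class ProgressionScoreModel:
    """Progression-prediction model over derived fragmentomic features.

    Parameters
    ----------
    features
        Per-patient table containing at least the columns used by the
        pre-defined models (FragDiff, Frag1, SM1, MMDiff); a
        ``patient_id`` column is carried through if present.
    labels
        Imaging-confirmed progression indicator per row.

    Examples
    --------
    >>> model = ProgressionScoreModel(features, labels)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> calib = res.calibrate_cutpoint(seed=1)
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Union[pd.Series, np.ndarray, Sequence[int]],
        specs: Sequence[ModelSpec] = PREDEFINED_MODELS,
    ) -> None:
        self.features = features.reset_index(drop=True)
        self.labels = np.asarray(labels, dtype=float)
        if len(self.labels) != len(self.features):
            raise ValueError("labels must align with the feature rows")
        self.specs = tuple(specs)
        self.patient_ids = (
            self.features["patient_id"].astype(str).tolist()
            if "patient_id" in self.features.columns
            else [str(i) for i in range(len(self.features))]
        )

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, label_col: str = "progressed"
    ) -> "ProgressionScoreModel":
        """Build from one table holding features and the outcome column."""
        if label_col not in data.columns:
            raise ValueError(f"missing outcome column {label_col!r}")
        labels = data[label_col].astype(float).to_numpy()
        return cls(data.drop(columns=[label_col]), labels)

    def fit(
        self,
        selection: str = "parsimony-on-flag",
        compute_loocv: bool = True,
    ) -> "ProgressionScoreResults":
        """Fit all pre-defined models, select the preferred one and
        cross-validate it."""
        table = evaluate_models(self.features, self.labels, self.specs)
        selected = select_best(table, selection=selection)
        if compute_loocv:
            cv = loocv_auc(self.features, self.labels, selected.spec)
            selected = replace(selected, loocv_auc=cv)
            table = [selected if f.spec == selected.spec else f for f in table]
        return ProgressionScoreResults(self, table, selected)


class ProgressionScoreResults:
    """Fitted six-model table with the selected model and its diagnostics."""

    def __init__(
        self,
        model: ProgressionScoreModel,
        table: List[FitResult],
        selected: FitResult,
    ) -> None:
        self.model = model
        self.table = table
        self.selected = selected

    @property
    def training_auc(self) -> float:
        return self.selected.training_auc

    @property
    def loocv_auc(self) -> Optional[float]:
        return self.selected.loocv_auc

    def model_table(self) -> pd.DataFrame:
        """The six-model comparison table (AUC, adjusted p, notes)."""
        rows = []
        for f in self.table:
            rows.append(
                {
                    "model": f.spec.name,
                    "auc": f.training_auc,
                    "model_p": f.model_p_value,
                    "bonferroni_p": f.bonferroni_adjusted_p,
                    "note": f.error or f.notes
                    or ("Best model" if f.spec == self.selected.spec else ""),
                }
            )
        return pd.DataFrame(rows)

    def predict(self, features: Optional[pd.DataFrame] = None) -> np.ndarray:
        """Predicted progression probabilities of the selected model."""
        df = self.model.features if features is None else features
        return predict_proba(self.selected, df)

    def progression_scores(
        self, features: Optional[pd.DataFrame] = None
    ) -> np.ndarray:
        """Progression Scores (0-100) of the selected model."""
        from .calibration import ps_from_prob

        return np.array([ps_from_prob(p) for p in self.predict(features)])

    def calibrate_cutpoint(
        self,
        n_bootstrap: int = 1000,
        min_ppv: float = 0.99,
        thresholds: Optional[Sequence[float]] = None,
        seed: int = 0,
        refit: bool = True,
    ):
        """Bootstrap expected-PPV cut-point calibration of the selected
        model (see :mod:`fragscore.calibration`)."""
        from .calibration import bootstrap_expected_ppv, select_cutpoint

        calib = bootstrap_expected_ppv(
            self.model.features,
            self.model.labels,
            self.selected.spec,
            n_bootstrap=n_bootstrap,
            thresholds=thresholds,
            seed=seed,
            refit=refit,
            min_ppv=min_ppv,
        )
        return select_cutpoint(calib, min_ppv=min_ppv)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        lines = [
            "Progression Score model selection",
            "=" * 64,
            f"n = {len(self.model.labels)}, cases = {int(self.model.labels.sum())}",
            "",
            f"{'Model':<28}{'AUC':>8}{'adj. p':>12}  Note",
            "-" * 64,
        ]
        for f in self.table:
            note = f.error or f.notes
            if f.spec == self.selected.spec and not note:
                note = "Best model"
            lines.append(
                f"{f.spec.name:<28}{f.training_auc:>8.3f}{f.bonferroni_adjusted_p:>12.3g}  {note}"
            )
        lines += [
            "-" * 64,
            f"Selected: {self.selected.spec.name}",
        ]
        if self.selected.loocv_auc is not None:
            lines.append(f"LOOCV AUC: {self.selected.loocv_auc:.3f}")
        lines += ["", f"{'Coefficient':<14}{'estimate':>12}{'std err':>12}{'P>|z|':>10}"]
        for name, b in self.selected.coefficients.items():
            lines.append(
                f"{name:<14}{b:>12.4g}{self.selected.std_errors[name]:>12.4g}"
                f"{self.selected.p_values[name]:>10.3g}"
            )
        return "\n".join(lines)
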