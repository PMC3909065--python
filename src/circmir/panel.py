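"""Logistic-regression / ROC evaluation of miRNA biomarker panels.

Panels are fitted by binary logistic regression on log10 normalised
relative quantities, scored by the ROC curve of the fitted probabilities
(trapezoidal AUC; ties between a case and a control score count 1/2), and
summarised at the operating point maximising Youden's J = sensitivity +
specificity − 1. All non-empty candidate subsets up to a size cap can be
searched exhaustively and ranked by AUC.

The headline panel metric is in-sample AUC — the fit and the ROC use the
same samples, matching typical discovery-stage workflows; an optional
stratified cross-validation mode gives an honest out-of-sample estimate.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticModel",
    "RocCurve",
    "PanelResult",
    "fit_logistic",
    "roc_curve",
    "evaluate_panel",
    "search_combinations",
]

MAX_ITER = 100
TOL = 1e-8
SEPARATION_MARGIN = 0.999


@dataclass
class LogisticModel:
    """Maximum-likelihood binary logistic fit (IRLS).

    ``coefficients`` holds the intercept first, then one slope per retained
    predictor (log-odds per unit). Complete separation leaves the
    coefficients at the iteration cap with ``separation_detected`` set.
    """

    mirna_ids: list[str]
    coefficients: np.ndarray  # [intercept, slopes...]
    converged: bool
    separation_detected: bool
    log_likelihood: float
    n_iter: int
    dropped: list[str] = field(default_factory=list)
    kept_indices: list[int] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.coefficients) - 1 and self.kept_indices:
            X = X[:, self.kept_indices]  # columns dropped during fitting
        z = self.coefficients[0] + X @ self.coefficients[1:]
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-15
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(predictors: np.ndarray, labels: Sequence[int],
                 predictor_names: Sequence[str] | None = None) -> LogisticModel:
    """Fit by iteratively reweighted least squares with an intercept.

    Constant predictors are dropped with a warning, as are collinear columns
    (detected by rank of the design matrix). Convergence requires the
    maximum coefficient change to fall below 1e-8 within 100 iterations;
    complete separation (every fitted probability within 0.001 of its
    label) is flagged and the coefficients of the final iteration returned.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and len(labels) > 1:
        X = X.T
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes (0 and 1)")
    names = list(predictor_names) if predictor_names is not None else [
        f"x{j}" for j in range(X.shape[1])]

    dropped: list[str] = []
    keep = []
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            dropped.append(names[j])
            warnings.warn(f"dropping constant predictor {names[j]!r}")
        else:
            keep.append(j)
    X = X[:, keep]
    names = [names[j] for j in keep]
    orig_cols = list(keep)

    # drop collinear columns greedily
    while X.shape[1] > 0:
        design = np.column_stack([np.ones(len(y)), X])
        if np.linalg.matrix_rank(design) == design.shape[1]:
            break
        for k in range(X.shape[1] - 1, -1, -1):
            trial = np.delete(X, k, axis=1)
            d2 = np.column_stack([np.ones(len(y)), trial])
            if np.linalg.matrix_rank(d2) == d2.shape[1]:
                warnings.warn(f"dropping collinear predictor {names[k]!r}")
                dropped.append(names.pop(k))
                orig_cols.pop(k)
                X = trial
                break
        else:
            break

    design = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(design.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        z = design @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        W = p * (1 - p)
        W = np.maximum(W, 1e-10)
        # Newton step via weighted least squares
        XtW = design.T * W
        try:
            step = np.linalg.solve(XtW @ design, design.T @ (y - p))
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtW @ design, design.T @ (y - p), rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < TOL:
            converged = True
            break

    p = 1.0 / (1.0 + np.exp(-np.clip(design @ beta, -500, 500)))
    separated = bool(np.all(np.abs(p - y) < 1 - SEPARATION_MARGIN))
    if separated:
        converged = False
        warnings.warn("complete separation detected; coefficients reported "
                      "at the iteration cap")
    return LogisticModel(names, beta, converged, separated,
                         _log_likelihood(y, p), n_iter, dropped, orig_cols)


@dataclass
class RocCurve:
    """Operating characteristics over descending score thresholds."""

    thresholds: np.ndarray  # descending; +inf first
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_point: tuple[float, float, float]  # (threshold, sens, spec)
    degenerate: bool = False


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC from raw scores; higher score means more case-like.

    Thresholds sit at the unique score values (classify positive when
    score ≥ threshold), bracketed by +inf (sens 0, spec 1) and −inf
    (sens 1, spec 0). AUC is the trapezoidal area, which equals the
    case-control concordance probability with ties counted 1/2. The
    operating point maximises Youden's J; ties prefer higher sensitivity.
    Constant scores give the chance diagonal (AUC 0.5, flagged degenerate).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for a ROC curve")

    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate([[np.inf], uniq, [-np.inf]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = s >= t
        sens[i] = (pred & (y == 1)).sum() / n_pos
        spec[i] = (~pred & (y == 0)).sum() / n_neg
    auc = float(np.trapezoid(sens, 1.0 - spec))
    degenerate = len(uniq) == 1

    j = sens + spec - 1.0
    best = max(range(len(thresholds)), key=lambda i: (round(j[i], 12), sens[i]))
    op = (float(thresholds[best]), float(sens[best]), float(spec[best]))
    return RocCurve(thresholds, sens, spec, auc, op, degenerate)


@dataclass(frozen=True)
class PanelResult:
    """AUC and Youden-optimal sens/spec of one fitted miRNA panel."""

    mirna_ids: tuple[str, ...]
    auc: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    model: LogisticModel | None = None
    roc: RocCurve | None = None

    def sort_key(self):
        return (-round(self.auc, 12), len(self.mirna_ids), self.mirna_ids)


def _panel_design(expression, mirna_ids: Sequence[str], labels: pd.Series):
    """log10-NRQ design matrix over samples complete for every member."""
    from .qpcr import ExpressionTable

    nrq = expression.nrq if isinstance(expression, ExpressionTable) else expression
    missing = [m for m in mirna_ids if m not in nrq.columns]
    if missing:
        raise ValueError(f"miRNAs absent from expression table: {missing}")
    sub = nrq[list(mirna_ids)]
    labels = labels.reindex(sub.index)
    complete = sub.notna().all(axis=1) & labels.notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropping %d sample(s) with missing panel members", n_dropped)
    sub = sub[complete]
    y = labels[complete].astype(int).to_numpy()
    return np.log10(sub.to_numpy(dtype=float)), y


def evaluate_panel(expression, mirna_ids: Sequence[str], labels: pd.Series,
                   cv_folds: int | None = None, seed: int = 0) -> PanelResult:
    """Fit a logistic panel on log10 NRQ and score its ROC.

    By default the ROC uses in-sample fitted probabilities (the
    discovery-stage convention). With ``cv_folds`` set, probabilities come
    from stratified k-fold cross-validation (each sample scored by a model
    that never saw it), giving an honest AUC whose null distribution is
    centred at 0.5.
    """
    X, y = _panel_design(expression, mirna_ids, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required after dropping incomplete samples")
    model = fit_logistic(X, y, predictor_names=list(mirna_ids))
    if cv_folds is None:
        scores = model.predict_proba(X)
    else:
        scores = _cv_scores(X, y, cv_folds, seed)
    roc = roc_curve(scores, y)
    return PanelResult(tuple(mirna_ids), roc.auc, roc.operating_point[1],
                       roc.operating_point[2], int(y.sum()),
                       int((1 - y).sum()), model, roc)


def _cv_scores(X: np.ndarray, y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Out-of-fold fitted probabilities from stratified k-fold CV."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.where(y == cls)[0])
        folds[idx] = np.arange(len(idx)) % k
    scores = np.empty(len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in range(k):
            held = folds == f
            m = fit_logistic(X[~held], y[~held])
            scores[held] = m.predict_proba(X[held])
    return scores


def search_combinations(expression, candidate_ids: Sequence[str],
                        labels: pd.Series, max_size: int) -> list[PanelResult]:
    """Exhaustively evaluate all non-empty candidate subsets up to max_size.

    Results are ranked by AUC descending; ties prefer the smaller panel,
    then lexicographic member order. The exhaustive bound is 15 candidates.
    """
    candidates = list(dict.fromkeys(candidate_ids))
    if not candidates:
        raise ValueError("no candidates given")
    if len(candidates) > 15:
        raise ValueError("exhaustive search is limited to 15 candidates")
    if max_size > len(candidates):
        raise ValueError("max_size exceeds the number of candidates")
    results = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(sorted(candidates), size):
            results.append(evaluate_panel(expression, combo, labels))
    return sorted(results, key=PanelResult.sort_key)


def panel_table(results: Sequence[PanelResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "rank": i + 1,
        "mirna_ids": "+".join(r.mirna_ids),
        "panel_size": len(r.mirna_ids),
        "auc": r.auc,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "n_cases": r.n_cases,
        "n_controls": r.n_controls,
    } for i, r in enumerate(results)])
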