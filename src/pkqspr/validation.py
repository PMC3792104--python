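"""Model validation statistics.

Regression models are judged by the external prediction coefficient Q_e²
(the R² of the regression line of predicted on observed, i.e. the squared
Pearson correlation), by the mean fold error MFE and by fold-error band
percentages (share of compounds predicted within 2-, 3- and 5-fold of the
observation).  Classification models are judged by the confusion matrix,
one-vs-rest sensitivity/specificity per class, and the Hand & Till (2001)
multiclass AUC, the average of all pairwise one-vs-one ranking probabilities.
Y-randomization guards against chance correlation: models refit on permuted
responses must collapse, with the R²Y- and Q²-intercepts of the regression of
performance on |correlation with the true response| below 0.3 and 0.05.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport",
    "external_q2",
    "fold_errors",
    "confusion_matrix",
    "class_sensitivity",
    "class_specificity",
    "hand_till_auc",
    "y_randomization",
]


def external_q2(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """R² of the regression line of predicted vs observed (squared Pearson r).

    Note this is the regression-line definition, not 1 − PRESS/SS: it is
    invariant to affine transforms of the predictions.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("constant input")
    r, _ = stats.pearsonr(obs, pred)
    return float(r**2)


def fold_errors(
    observed: Sequence[float],
    predicted: Sequence[float],
    bands: Sequence[float] = (2, 3, 5),
    method: str = "geometric",
) -> dict:
    """Per-compound fold errors, MFE, and percent-within-k-fold bands.

    FE_i = max(pred_i/obs_i, obs_i/pred_i) >= 1.  MFE defaults to the
    geometric form 10^mean(|log10(pred/obs)|), the standard central tendency
    for multiplicative pharmacokinetic errors; ``method='arithmetic'`` gives
    the plain mean of FE.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if np.any(obs <= 0) or np.any(pred <= 0):
        raise ValueError("fold errors require strictly positive values")
    log_ratio = np.log10(pred / obs)
    fe = np.power(10.0, np.abs(log_ratio))
    if method == "geometric":
        mfe = float(np.power(10.0, np.mean(np.abs(log_ratio))))
    elif method == "arithmetic":
        mfe = float(fe.mean())
    else:
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    pct = {float(k): float(100.0 * np.mean(fe <= k)) for k in bands}
    return {"fold_errors": fe, "mfe": mfe, "pct_within": pct}


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence, classes: Sequence) -> pd.DataFrame:
    """K x K confusion counts; rows are true classes, columns predicted."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    classes = list(classes)
    known = set(classes)
    bad = set(true_labels) | set(predicted_labels)
    if not bad <= known:
        raise ValueError(f"unknown label(s): {sorted(bad - known)}")
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        mat.loc[t, p] += 1
    return mat


def class_sensitivity(confusion: pd.DataFrame, cls) -> float:
    """True-positive rate for one class: correct-in-class / total-in-class."""
    row = confusion.loc[cls]
    total = row.sum()
    if total == 0:
        raise ValueError(f"class {cls!r} has no members")
    return float(confusion.loc[cls, cls] / total)


def class_specificity(confusion: pd.DataFrame, cls) -> float:
    """One-vs-rest specificity: correctly-rejected / total-not-in-class."""
    total_neg = confusion.values.sum() - confusion.loc[cls].sum()
    if total_neg == 0:
        raise ValueError(f"complement of class {cls!r} is empty")
    false_pos = confusion[cls].sum() - confusion.loc[cls, cls]
    return float((total_neg - false_pos) / total_neg)


def _pair_ranking_prob(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """P(random positive scores above random negative), ties counted 0.5."""
    ranks = stats.rankdata(np.concatenate([scores_pos, scores_neg]))
    n_pos, n_neg = scores_pos.size, scores_neg.size
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def hand_till_auc(true_labels: Sequence, scores: np.ndarray, classes: Sequence) -> float:
    """Hand & Till multiclass AUC: M = 2/(K(K−1)) Σ_{i<j} Â(i, j).

    ``scores`` is (n, K) with a column of class-membership scores per class in
    the order of ``classes``.  Â(i, j) averages the two one-vs-one ranking
    probabilities — class-i scores separating i from j, and class-j scores
    separating j from i — over compounds of those two classes only.  For K=2
    this reduces to the ordinary binary AUC.
    """
    true_labels = np.asarray(true_labels)
    scores = np.asarray(scores, dtype=float)
    classes = list(classes)
    K = len(classes)
    if K < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if not np.any(true_labels == cls):
            raise ValueError(f"class {cls!r} absent from true labels")
    total = 0.0
    for i in range(K):
        for j in range(i + 1, K):
            mask_i = true_labels == classes[i]
            mask_j = true_labels == classes[j]
            a_ij = _pair_ranking_prob(scores[mask_i, i], scores[mask_j, i])
            a_ji = _pair_ranking_prob(scores[mask_j, j], scores[mask_i, j])
            total += 0.5 * (a_ij + a_ji)
    return float(2.0 * total / (K * (K - 1)))


def y_randomization(
    X: np.ndarray,
    Y: np.ndarray,
    model_builder: Callable[[np.ndarray, np.ndarray], tuple[float, float]],
    n_permutations: int = 50,
    seed: int = 0,
) -> dict:
    """Response-permutation (Y-randomization) test.

    ``model_builder(X, Y) -> (r2y, q2)`` fits the model and returns its fit
    and cross-validated statistics.  For each permutation the rows of Y are
    shuffled, the model refit, and (|corr with true Y|, R²Y, Q²) recorded.
    R²Y and Q² are then regressed on the correlation — including the original
    model at correlation 1 — and the intercepts reported.  The test passes
    when the R²Y-intercept is below 0.3 and the Q²-intercept below 0.05.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Y2 = Y.reshape(-1, 1) if Y.ndim == 1 else Y
    rng = np.random.default_rng(seed)

    def mean_abs_corr(Yp: np.ndarray) -> float:
        cs = []
        for k in range(Y2.shape[1]):
            if np.ptp(Y2[:, k]) == 0:
                cs.append(1.0)
            else:
                cs.append(abs(stats.pearsonr(Yp[:, k], Y2[:, k])[0]))
        return float(np.mean(cs))

    r2_orig, q2_orig = model_builder(X, Y)
    corrs, r2s, q2s = [1.0], [r2_orig], [q2_orig]
    n_failed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(Y2.shape[0])
        Yp = Y2[perm]
        try:
            r2, q2 = model_builder(X, Yp if Y.ndim > 1 else Yp.ravel())
        except Exception as exc:  # builder failure: log and skip
            n_failed += 1
            logger.warning("permutation skipped: %s", exc)
            continue
        corrs.append(mean_abs_corr(Yp))
        r2s.append(r2)
        q2s.append(q2)
    corrs_a, r2s_a, q2s_a = map(np.asarray, (corrs, r2s, q2s))
    r2_slope, r2_intercept = np.polyfit(corrs_a, r2s_a, 1)
    q2_slope, q2_intercept = np.polyfit(corrs_a, q2s_a, 1)
    return {
        "r2_intercept": float(r2_intercept),
        "q2_intercept": float(q2_intercept),
        "r2_pass": bool(r2_intercept < 0.3),
        "q2_pass": bool(q2_intercept < 0.05),
        "original": {"r2y": r2_orig, "q2": q2_orig},
        "permuted_r2": r2s_a[1:],
        "permuted_q2": q2s_a[1:],
        "correlations": corrs_a[1:],
        "n_failed": n_failed,
    }


@dataclass
class ValidationReport:
    """Bundle of regression and classification validation statistics."""

    qe2: dict = field(default_factory=dict)  # per response
    mfe: dict = field(default_factory=dict)
    pct_within: dict = field(default_factory=dict)  # per response -> {fold: pct}
    confusion: pd.DataFrame | None = None
    sensitivity: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)
    auc: float | None = None
    outliers_excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "qe2": self.qe2,
            "mfe": self.mfe,
            "pct_within": {k: {str(f): v for f, v in d.items()} for k, d in self.pct_within.items()},
            "confusion": None if self.confusion is None else self.confusion.to_dict(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "outliers_excluded": list(self.outliers_excluded),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))

    def summary(self) -> str:
        lines = []
        for resp, v in self.qe2.items():
            line = f"{resp}: Qe2={v:.3f}"
            if resp in self.mfe:
                line += f"  MFE={self.mfe[resp]:.2f}"
            if resp in self.pct_within:
                bands = "  ".join(f"<{int(k)}-fold {v:.0f}%" for k, v in self.pct_within[resp].items())
                line += "  " + bands
            lines.append(line)
        if self.auc is not None:
            lines.append(f"multiclass AUC (Hand-Till): {self.auc:.3f}")
        for cls in self.sensitivity:
            lines.append(
                f"class {cls}: sensitivity {self.sensitivity[cls]:.2f}, specificity {self.specificity.get(cls, float('nan')):.2f}"
            )
        if self.outliers_excluded:
            lines.append(f"outliers excluded: {', '.join(map(str, self.outliers_excluded))}")
        return "\n".join(lines)
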