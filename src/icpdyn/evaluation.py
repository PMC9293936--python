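"""Time-dependent discrimination and error-rate evaluation.

A dynamic mortality model emits a death-risk probability for each patient at
every scheduled prediction time (every 8 h from 24 h).  Because patients drop
out (end of monitoring, missing windows), each time-point is evaluated on the
patients who actually have a prediction there, and that evaluated-n is always
reported alongside the metrics.

Error rates follow the clinical reading "out of 100 patients predicted to
die / survive": ``fp_rate`` is the false-discovery proportion fp/(fp+tp)
(share of predicted deaths who survived, 1 - precision) and ``fn_rate`` the
false-omission proportion fn/(fn+tn) (share of predicted survivors who
died).  The textbook fp/(fp+tn), fn/(fn+tp) convention is available via
``convention="classic"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import SCHEDULE_H

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.25, 0.50, 0.75)


def classify(probability: float, threshold: float = 0.50) -> int:
    """Predicted class: death (1) iff probability strictly exceeds threshold.

    The tie at exactly the threshold is classified as survival, keeping the
    strict "higher than" reading deterministic.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return int(probability > threshold)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    t_h: float | None = None
    threshold: float = 0.50

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _aligned(predictions: pd.Series, outcomes: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and labels for patients with a prediction (NaN dropped)."""
    p = predictions.dropna()
    y = outcomes.reindex(p.index)
    if y.isna().any():
        raise ValueError("every predicted patient needs an outcome label")
    return p.to_numpy(dtype=float), y.to_numpy(dtype=int)


def confusion_at(predictions: pd.Series, outcomes: pd.Series,
                 threshold: float = 0.50, t_h: float | None = None) -> ConfusionCounts:
    """Confusion counts over the patients with a prediction.

    ``predictions`` is a probability per patient_id (NaN = no prediction at
    this time-point, excluded); ``outcomes`` the 30-day mortality labels
    (1 = death, the positive class).
    """
    p, y = _aligned(predictions, outcomes)
    pred = p > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        t_h=t_h,
        threshold=threshold,
    )


def fp_fn_rates(counts: ConfusionCounts,
                convention: str = "predicted") -> tuple[float, float]:
    """(fp_rate, fn_rate) under the chosen denominator convention.

    ``"predicted"`` (default): denominators are the predicted-death and
    predicted-survival counts -- fp/(fp+tp) and fn/(fn+tn).  ``"classic"``:
    denominators are the true classes -- fp/(fp+tn) and fn/(fn+tp).
    Degenerate denominators yield NaN.
    """
    if convention == "predicted":
        pairs = ((counts.fp, counts.fp + counts.tp), (counts.fn, counts.fn + counts.tn))
    elif convention == "classic":
        pairs = ((counts.fp, counts.fp + counts.tn), (counts.fn, counts.fn + counts.tp))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    out = []
    for num, den in pairs:
        if den == 0:
            logger.info("degenerate denominator at t=%s, threshold=%s",
                        counts.t_h, counts.threshold)
            out.append(math.nan)
        else:
            out.append(num / den)
    return tuple(out)  # type: ignore[return-value]


def precision_recall_accuracy(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, accuracy); degenerate denominators give NaN."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else math.nan
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    accuracy = (counts.tp + counts.tn) / counts.n if counts.n else math.nan
    return precision, recall, accuracy


def auc_at(predictions: pd.Series, outcomes: pd.Series) -> float:
    """Probability-of-concordance AUC with ties counted 1/2.

    Equals the chance that a random patient who died was ranked above a
    random survivor.  NaN (with a warning) when only one class is present
    among the evaluated patients.
    """
    p, y = _aligned(predictions, outcomes)
    if len(np.unique(y)) < 2:
        logger.warning("AUC undefined: a single outcome class among %d patients", y.size)
        return math.nan
    return float(roc_auc_score(y, p))


def auprc_at(predictions: pd.Series, outcomes: pd.Series) -> float:
    """Area under the precision-recall curve (step-wise interpolation).

    An uninformative scorer lands near the positive prevalence; NaN when no
    positives are present.
    """
    p, y = _aligned(predictions, outcomes)
    if not np.any(y == 1):
        logger.warning("AUPRC undefined: no deaths among evaluated patients")
        return math.nan
    return float(average_precision_score(y, p))


def metric_curves(tracks: pd.DataFrame, outcomes: pd.Series,
                  thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                  schedule: tuple[int, ...] = SCHEDULE_H,
                  convention: str = "predicted") -> pd.DataFrame:
    """Per-(time, threshold) evaluation table for a cohort's prediction tracks.

    ``tracks`` is long-format ``patient_id, t_h, probability``.  Returns one
    row per (t_h, threshold) with columns ``n_evaluated, auc, auprc,
    accuracy, precision, recall, fp_rate, fn_rate, tp, fp, fn, tn``.  AUC and
    AUPRC do not depend on the threshold but are repeated per row so the
    table is self-contained.
    """
    required = {"patient_id", "t_h", "probability"}
    if not required.issubset(tracks.columns):
        raise ValueError(f"tracks must have columns {sorted(required)}")
    rows = []
    for t in schedule:
        at_t = tracks[tracks["t_h"] == t]
        preds = at_t.set_index("patient_id")["probability"]
        if preds.index.has_duplicates:
            raise ValueError(f"duplicate predictions for a patient at t={t}")
        preds = preds.dropna()
        if preds.empty:
            continue
        auc = auc_at(preds, outcomes)
        auprc = auprc_at(preds, outcomes)
        for theta in thresholds:
            counts = confusion_at(preds, outcomes, threshold=theta, t_h=t)
            fp_rate, fn_rate = fp_fn_rates(counts, convention=convention)
            precision, recall, accuracy = precision_recall_accuracy(counts)
            rows.append({
                "t_h": t, "threshold": theta, "n_evaluated": counts.n,
                "auc": auc, "auprc": auprc, "accuracy": accuracy,
                "precision": precision, "recall": recall,
                "fp_rate": fp_rate, "fn_rate": fn_rate,
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn,
            })
    return pd.DataFrame(rows)


def average_fold_curves(fold_curves: list[pd.DataFrame]) -> pd.DataFrame:
    """Average metric curves across CV folds (metrics averaged per (t, theta)).

    Counts are summed, rate/score columns averaged over the folds where they
    are defined.  This mirrors reporting "average rates in all
    cross-validation repetitions"; pooling predictions before computing
    metrics is the alternative, available by concatenating tracks upstream.
    """
    if not fold_curves:
        return pd.DataFrame()
    stacked = pd.concat(fold_curves, ignore_index=True)
    mean_cols = ["auc", "auprc", "accuracy", "precision", "recall",
                 "fp_rate", "fn_rate"]
    sum_cols = ["n_evaluated", "tp", "fp", "fn", "tn"]
    grouped = stacked.groupby(["t_h", "threshold"], as_index=False)
    out = grouped[mean_cols].mean()
    sums = grouped[sum_cols].sum()
    return out.merge(sums, on=["t_h", "threshold"])
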