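"""Time-windowed dynamic logistic regression for 30-day mortality.

The model is a single pooled logistic regression: one row per (patient,
prediction time) with the patient's 30-day mortality label repeated, features
recomputed from rolling windows at each time-point, and *constant*
coefficients across prediction times.  The dynamics live entirely in the
features -- at every scheduled time (each 8 h from 24 h to 120 h) the same
coefficients are applied to freshly windowed feature values, producing an
updated death-risk between 0 and 1.

Feature selection is recursive feature elimination (RFE): the candidate set
is standardized, the weakest feature (smallest absolute standardized
coefficient) is repeatedly removed, and each candidate feature-count is
scored by mean out-of-fold AUC under stratified *group* k-fold
cross-validation -- folds always split by patient, never by row, so a
patient's own time-points can never leak across the train/test boundary.

Usage follows the Model/Results convention::

    model = DynamicMortalityModel.from_cohort(cohort)
    res = model.fit()                  # RFE + pooled logistic fit
    print(res.summary())
    tracks = res.predict_tracks(feature_table)
    report = model.cross_validate()    # 5-fold internal validation
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold

from . import evaluation
from .features import SCHEDULE_H, FeatureGrammar, featurize_cohort
from .vitals import Cohort

logger = logging.getLogger(__name__)

ARTIFACT_SCHEMA_VERSION = 1
ID_COLUMNS = ("patient_id", "t_h", "outcome")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    """Training-time knobs.

    ``regularization_strength`` is the L2 penalty weight lambda; the default
    is a numerically negligible ridge kept only so that perfectly separated
    fits stay finite.  ``rfe_grid`` lists the candidate feature-counts scored
    during selection (None: every count from 1 up to the full set).
    ``pooling`` chooses the training-row assembly: ``"all"`` pools every
    (patient, time) row; ``"last"`` keeps one row per patient at their final
    prediction time (sensitivity analysis only).
    """

    n_folds: int = 5
    rfe_grid: tuple[int, ...] | None = None
    seed: int = 0
    regularization_strength: float = 1e-2
    pooling: str = "all"
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ModelError("n_folds must be at least 2")
        if self.regularization_strength <= 0:
            raise ModelError("regularization_strength must be positive")
        if self.pooling not in ("all", "last"):
            raise ModelError("pooling must be 'all' or 'last'")

    @property
    def C(self) -> float:
        """scikit-learn's inverse regularization strength."""
        return 1.0 / self.regularization_strength


def assemble_training_rows(
    feature_table: pd.DataFrame,
    feature_names: list[str],
    pooling: str = "all",
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Design matrix, labels and patient groups from a feature table.

    Rows with any missing value among ``feature_names`` are dropped (and
    logged) -- the patient is simply excluded from that time-point.  The
    returned groups (patient ids) let cross-validation split by patient.
    A cohort with a single outcome class is unfittable and raises.
    """
    missing_cols = [c for c in feature_names if c not in feature_table.columns]
    if missing_cols:
        raise ModelError(f"feature table lacks columns {missing_cols}")
    table = feature_table
    if pooling == "last":
        table = table.sort_values("t_h").groupby("patient_id", as_index=False).last()
    complete = table[feature_names].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing features (of %d)", n_dropped, len(table))
    kept = table[complete]
    y = kept["outcome"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelError("training rows contain a single outcome class; unfittable")
    # a patient's rows must all carry one label
    per_patient = kept.groupby("patient_id")["outcome"].nunique()
    if (per_patient > 1).any():
        raise ModelError("inconsistent outcome labels within a patient")
    return kept[feature_names], y, kept["patient_id"].to_numpy()


@dataclass
class _CoreFit:
    """A logistic fit in standardized feature space."""

    features: list[str]
    intercept: float
    coef: np.ndarray          # aligned with features
    means: np.ndarray
    sds: np.ndarray
    cov: np.ndarray | None = None   # (intercept + coef) covariance


def _fit_core(X: pd.DataFrame, y: np.ndarray, config: TrainingConfig,
              with_cov: bool = False, drop_constant: bool = True) -> _CoreFit:
    """Standardize, fit a weakly ridged logistic regression, return the fit.

    Zero-variance columns carry no information and are dropped with a
    warning (their weight would be indeterminate under standardization).
    """
    means = X.mean(axis=0).to_numpy()
    sds = X.std(axis=0, ddof=0).to_numpy()
    keep = sds > 0
    if not keep.all():
        dropped = [c for c, k in zip(X.columns, keep) if not k]
        if drop_constant:
            logger.warning("dropping zero-variance features: %s", dropped)
        else:
            raise ModelError(f"zero-variance features: {dropped}")
    cols = [c for c, k in zip(X.columns, keep) if k]
    Z = (X[cols].to_numpy() - means[keep]) / sds[keep]
    # newton-cholesky: exact Hessian steps cope with the strongly collinear
    # trend features where first-order solvers crawl
    clf = LogisticRegression(C=config.C, solver="newton-cholesky",
                             max_iter=config.max_iter, tol=1e-8)
    clf.fit(Z, y)
    coef = clf.coef_[0].copy()
    intercept = float(clf.intercept_[0])
    cov = None
    if with_cov:
        # observed-information covariance at the ridge optimum
        eta = intercept + Z @ coef
        p = expit(eta)
        w = p * (1.0 - p)
        A = np.hstack([np.ones((Z.shape[0], 1)), Z])
        H = (A * w[:, None]).T @ A
        H[1:, 1:] += np.eye(len(coef)) * config.regularization_strength
        cov = np.linalg.inv(H)
    return _CoreFit(features=cols, intercept=intercept, coef=coef,
                    means=means[keep], sds=sds[keep], cov=cov)


def _oof_auc(X: pd.DataFrame, y: np.ndarray, groups: np.ndarray,
             features: list[str], config: TrainingConfig,
             rng_seed: int) -> list[float]:
    """Per-fold held-out AUC for one feature subset (grouped, stratified)."""
    splitter = StratifiedGroupKFold(n_splits=config.n_folds, shuffle=True,
                                    random_state=rng_seed)
    aucs = []
    Xs = X[features]
    for train_idx, test_idx in splitter.split(Xs, y, groups):
        fit = _fit_core(Xs.iloc[train_idx], y[train_idx], config)
        Zt = (Xs.iloc[test_idx][fit.features].to_numpy() - fit.means) / fit.sds
        score = fit.intercept + Zt @ fit.coef
        y_test = y[test_idx]
        if len(np.unique(y_test)) < 2:
            continue
        aucs.append(float(roc_auc_score(y_test, score)))
    if not aucs:
        raise ModelError("no fold had both outcome classes; increase cohort size")
    return aucs


def rfe_select(X: pd.DataFrame, y: np.ndarray, groups: np.ndarray,
               config: TrainingConfig) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination with CV-scored subset-size selection.

    The elimination path drops, at each step, the feature with the smallest
    absolute standardized coefficient of a full-data fit.  Every candidate
    feature-count in ``config.rfe_grid`` is then scored by mean out-of-fold
    AUC under stratified group k-fold CV; the best count wins, ties going to
    the smaller subset.  Returns the selected names and a per-count report.
    """
    n_unique_groups = len(np.unique(groups))
    if n_unique_groups < config.n_folds:
        raise ModelError(
            f"{n_unique_groups} patients cannot be split into {config.n_folds} folds")
    current = list(X.columns)
    subsets: dict[int, list[str]] = {}
    while current:
        subsets[len(current)] = list(current)
        if len(current) == 1:
            break
        fit = _fit_core(X[current], y, config)
        if len(fit.features) < len(current):
            # constant columns eliminated out of band
            current = fit.features
            subsets[len(current)] = list(current)
            if len(current) <= 1:
                break
            fit = _fit_core(X[current], y, config)
        weakest = fit.features[int(np.argmin(np.abs(fit.coef)))]
        current = [c for c in current if c != weakest]

    grid = config.rfe_grid or tuple(sorted(subsets))
    rows = []
    for count in grid:
        if count not in subsets:
            logger.warning("rfe_grid count %d unavailable (path max %d); skipped",
                           count, max(subsets))
            continue
        fold_aucs = _oof_auc(X, y, groups, subsets[count], config,
                             rng_seed=config.seed)
        rows.append({"n_features": count, "mean_cv_auc": float(np.mean(fold_aucs)),
                     **{f"fold{j}_auc": a for j, a in enumerate(fold_aucs)}})
    report = pd.DataFrame(rows).sort_values("n_features").reset_index(drop=True)
    if report.empty:
        raise ModelError("rfe_grid matched no feature count on the elimination path")
    best = report.loc[report["mean_cv_auc"].idxmax()]
    # ties: prefer fewer features
    tied = report[np.isclose(report["mean_cv_auc"], best["mean_cv_auc"])]
    n_best = int(tied["n_features"].min())
    logger.info("RFE selected %d features (mean CV AUC %.3f)", n_best,
                float(best["mean_cv_auc"]))
    return subsets[n_best], report


class DynamicMortalityModel:
    """Pooled dynamic logistic mortality model built from a feature table.

    Parameters
    ----------
    feature_table : DataFrame
        Wide table from :func:`icpdyn.features.featurize_cohort`: columns
        ``patient_id, t_h, outcome`` plus candidate feature columns.
    config : TrainingConfig, optional
    grammar : FeatureGrammar, optional
        Recorded (hashed) in the fitted artifact so that predictions refuse
        feature tables produced under a different grammar.
    """

    def __init__(self, feature_table: pd.DataFrame,
                 config: TrainingConfig | None = None,
                 grammar: FeatureGrammar | None = None):
        for col in ID_COLUMNS:
            if col not in feature_table.columns:
                raise ModelError(f"feature table lacks column {col!r}")
        self.feature_table = feature_table.reset_index(drop=True)
        self.config = config or TrainingConfig()
        self.grammar = grammar or FeatureGrammar()
        self.candidate_features = [c for c in feature_table.columns
                                   if c not in ID_COLUMNS]

    @classmethod
    def from_cohort(cls, cohort: Cohort, config: TrainingConfig | None = None,
                    grammar: FeatureGrammar | None = None,
                    schedule: tuple[int, ...] = SCHEDULE_H) -> "DynamicMortalityModel":
        grammar = grammar or FeatureGrammar()
        table = featurize_cohort(cohort, grammar, schedule)
        return cls(table, config=config, grammar=grammar)

    # -- fitting ----------------------------------------------------------

    def fit(self, select: bool = True) -> "DynamicMortalityResults":
        """Fit the pooled model; with ``select=True`` run RFE first."""
        X, y, groups = assemble_training_rows(
            self.feature_table, self.candidate_features, self.config.pooling)
        if select:
            selected, rfe_report = rfe_select(X, y, groups, self.config)
        else:
            selected, rfe_report = list(X.columns), None
        fit = _fit_core(X[selected], y, self.config, with_cov=True)
        return DynamicMortalityResults(model=self, core=fit, rfe_report=rfe_report,
                                       nobs=len(y), n_patients=len(np.unique(groups)),
                                       prevalence=float(np.mean(y)))

    # -- internal validation ---------------------------------------------

    def cross_validate(
        self,
        thresholds: tuple[float, ...] = evaluation.DEFAULT_THRESHOLDS,
        select: bool = True,
        convention: str = "predicted",
    ) -> "CVReport":
        """Stratified k-fold internal validation, split by patient.

        Per fold: RFE + fit on the training patients, predictions for every
        held-out patient at every scheduled time they have data for, and a
        metric curve over those out-of-fold predictions.  Fold curves are
        averaged per (time, threshold).
        """
        table = self.feature_table
        patients = table.groupby("patient_id")["outcome"].first()
        if patients.nunique() < 2 or len(patients) < self.config.n_folds:
            raise ModelError("cohort too small or single-class for cross-validation")
        splitter = StratifiedGroupKFold(n_splits=self.config.n_folds, shuffle=True,
                                        random_state=self.config.seed)
        ids = patients.index.to_numpy()
        fold_curves: list[pd.DataFrame] = []
        fold_results: list[DynamicMortalityResults] = []
        oof_tracks: list[pd.DataFrame] = []
        for k, (tr, te) in enumerate(splitter.split(ids, patients.to_numpy(), ids)):
            train_ids, test_ids = set(ids[tr]), set(ids[te])
            train_table = table[table["patient_id"].isin(train_ids)]
            test_table = table[table["patient_id"].isin(test_ids)]
            submodel = DynamicMortalityModel(train_table, config=self.config,
                                             grammar=self.grammar)
            res = submodel.fit(select=select)
            tracks = res.predict_tracks(test_table)
            outcomes = test_table.groupby("patient_id")["outcome"].first()
            curve = evaluation.metric_curves(tracks, outcomes, thresholds=thresholds,
                                             convention=convention)
            curve.insert(0, "fold", k)
            fold_curves.append(curve)
            fold_results.append(res)
            tracks = tracks.copy()
            tracks["fold"] = k
            oof_tracks.append(tracks)
        mean_curve = evaluation.average_fold_curves(
            [c.drop(columns="fold") for c in fold_curves])
        return CVReport(mean_curve=mean_curve, fold_curves=fold_curves,
                        fold_results=fold_results,
                        oof_tracks=pd.concat(oof_tracks, ignore_index=True),
                        seed=self.config.seed)


@dataclass
class CVReport:
    """Fold-wise and averaged internal-validation metrics."""

    mean_curve: pd.DataFrame
    fold_curves: list[pd.DataFrame]
    fold_results: list["DynamicMortalityResults"]
    oof_tracks: pd.DataFrame
    seed: int

    def auc(self, t_h: float) -> float:
        sub = self.mean_curve[self.mean_curve["t_h"] == t_h]
        if sub.empty:
            return math.nan
        return float(sub["auc"].iloc[0])


class DynamicMortalityResults:
    """Fitted coefficients, their uncertainty and prediction machinery.

    Coefficients live in standardized feature space; the training means and
    standard deviations are stored so prediction is deterministic and the
    artifact is self-contained.
    """

    def __init__(self, model: DynamicMortalityModel, core: _CoreFit,
                 rfe_report: pd.DataFrame | None, nobs: int, n_patients: int,
                 prevalence: float):
        self.model = model
        self._core = core
        self.rfe_report = rfe_report
        self.nobs = nobs
        self.n_patients = n_patients
        self.prevalence = prevalence
        self.selected_features = list(core.features)
        self.params = pd.Series(
            np.concatenate([[core.intercept], core.coef]),
            index=["intercept"] + self.selected_features, name="coef")
        if core.cov is not None:
            self.bse = pd.Series(np.sqrt(np.diag(core.cov)), index=self.params.index,
                                 name="std err")
        else:  # pragma: no cover
            self.bse = pd.Series(np.nan, index=self.params.index)
        self.grammar_digest = model.grammar.digest()
        self.config = model.config

    # -- prediction -------------------------------------------------------

    def predict(self, feature_table: pd.DataFrame) -> pd.Series:
        """Death-risk probability per row; NaN where a selected feature is missing."""
        missing_cols = [c for c in self.selected_features
                        if c not in feature_table.columns]
        if missing_cols:
            raise ModelError(f"feature table lacks model features {missing_cols}")
        X = feature_table[self.selected_features].to_numpy(dtype=float)
        complete = ~np.isnan(X).any(axis=1)
        probs = np.full(len(feature_table), np.nan)
        if complete.any():
            Z = (X[complete] - self._core.means) / self._core.sds
            eta = self._core.intercept + Z @ self._core.coef
            probs[complete] = expit(eta)
        return pd.Series(probs, index=feature_table.index, name="probability")

    def predict_tracks(self, feature_table: pd.DataFrame,
                       threshold: float = 0.50) -> pd.DataFrame:
        """Long-format prediction tracks with the 50% classification attached."""
        probs = self.predict(feature_table)
        out = feature_table[["patient_id", "t_h"]].copy()
        out["probability"] = probs
        out["classification_50"] = [
            "" if np.isnan(p) else ("death" if evaluation.classify(p, threshold)
                                    else "survival")
            for p in probs
        ]
        return out

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        z = self.params / self.bse
        from scipy.stats import norm
        pvals = 2 * norm.sf(np.abs(z))
        lines = [
            "Dynamic mortality logistic regression (pooled time-windows)",
            "=" * 66,
            f"rows: {self.nobs}    patients: {self.n_patients}    "
            f"30-day mortality: {self.prevalence:.1%}",
            f"selected features: {len(self.selected_features)} "
            f"of {len(self.model.candidate_features)} candidates "
            f"(grammar {self.grammar_digest})",
            "-" * 66,
            f"{'feature':<18}{'coef':>10}{'std err':>10}{'z':>8}{'P>|z|':>9}",
        ]
        for name, p in zip(self.params.index, pvals):
            lines.append(f"{name:<18}{self.params[name]:>10.4f}"
                         f"{self.bse[name]:>10.4f}{z[name]:>8.2f}{p:>9.3f}")
        lines.append("=" * 66)
        lines.append("coefficients are per standard deviation of the training feature")
        return "\n".join(lines)

    def feature_importance(self) -> pd.Series:
        """Features ranked by absolute standardized coefficient."""
        w = self.params.drop("intercept")
        return w.reindex(w.abs().sort_values(ascending=False).index)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": ARTIFACT_SCHEMA_VERSION,
            "grammar_digest": self.grammar_digest,
            "selected_features": self.selected_features,
            "intercept": float(self._core.intercept),
            "coef": {f: float(c) for f, c in zip(self.selected_features, self._core.coef)},
            "standardization": {
                f: {"mean": float(m), "sd": float(s)}
                for f, m, s in zip(self.selected_features, self._core.means,
                                   self._core.sds)
            },
            "config": asdict(self.config),
            "nobs": self.nobs,
            "n_patients": self.n_patients,
            "prevalence": self.prevalence,
            "rfe_report": (self.rfe_report.to_dict(orient="list")
                           if self.rfe_report is not None else None),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FrozenModel":
        with open(path) as fh:
            payload = json.load(fh)
        return FrozenModel(payload)


class FrozenModel:
    """A saved model artifact rehydrated for prediction only."""

    def __init__(self, payload: dict):
        if payload.get("schema_version") != ARTIFACT_SCHEMA_VERSION:
            raise ModelError("model artifact schema version mismatch")
        self.payload = payload
        self.selected_features = payload["selected_features"]
        self.grammar_digest = payload["grammar_digest"]
        self._intercept = payload["intercept"]
        self._coef = np.array([payload["coef"][f] for f in self.selected_features])
        self._means = np.array([payload["standardization"][f]["mean"]
                                for f in self.selected_features])
        self._sds = np.array([payload["standardization"][f]["sd"]
                              for f in self.selected_features])

    def check_grammar(self, grammar: FeatureGrammar) -> None:
        if grammar.digest() != self.grammar_digest:
            raise ModelError(
                "feature grammar mismatch: the model was trained under a "
                f"different grammar ({self.grammar_digest})")

    def predict(self, feature_table: pd.DataFrame) -> pd.Series:
        missing_cols = [c for c in self.selected_features
                        if c not in feature_table.columns]
        if missing_cols:
            raise ModelError(f"feature table lacks model features {missing_cols}")
        X = feature_table[self.selected_features].to_numpy(dtype=float)
        complete = ~np.isnan(X).any(axis=1)
        probs = np.full(len(feature_table), np.nan)
        if complete.any():
            Z = (X[complete] - self._means) / self._sds
            probs[complete] = expit(self._intercept + Z @ self._coef)
        return pd.Series(probs, index=feature_table.index, name="probability")

    def predict_tracks(self, feature_table: pd.DataFrame,
                       threshold: float = 0.50) -> pd.DataFrame:
        probs = self.predict(feature_table)
        out = feature_table[["patient_id", "t_h"]].copy()
        out["probability"] = probs
        out["classification_50"] = [
            "" if np.isnan(p) else ("death" if evaluation.classify(p, threshold)
                                    else "survival")
            for p in probs
        ]
        return out
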