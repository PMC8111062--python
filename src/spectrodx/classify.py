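"""Per-spectrum probabilistic cancer classifier with patient-grouped,
class-stratified cross-validation and consensus-level threshold tuning.

The original diagnostic algorithm is proprietary; this module provides two
standard families behind one contract — a regularised linear model
(logistic regression, L2) and a tree ensemble (random forest) — trained on
preprocessed spectral features.  All fold assignment is at patient level so
the nine replicate spectra of a patient never straddle a train/validation
split, and every reported performance number comes from out-of-fold
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .consensus import ConsensusConfig, patient_scores as consensus_patient_scores
from .errors import (
    ConsistencyError,
    DegenerateInputError,
    IncompatibleGridError,
    InvalidConfigError,
)
from .simulate import CANCER, PatientRecord

__all__ = [
    "TrainingConfig",
    "TrainedClassifier",
    "assign_grouped_folds",
    "train",
    "predict_proba",
    "tune_threshold",
]


@dataclass(frozen=True)
class TrainingConfig:
    model_family: str = "tree-ensemble"  # tree-ensemble | regularised-linear
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    n_folds: int = 5
    tuning_objective: str = "balanced"  # balanced | max_sensitivity_at_min_specificity
    min_specificity: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in ("tree-ensemble", "regularised-linear"):
            raise InvalidConfigError(f"unknown model_family {self.model_family!r}")
        if self.n_folds < 2:
            raise InvalidConfigError("n_folds must be >= 2")
        if self.tuning_objective not in ("balanced", "max_sensitivity_at_min_specificity"):
            raise InvalidConfigError(f"unknown tuning_objective {self.tuning_objective!r}")
        if not 0.0 <= self.min_specificity <= 1.0:
            raise InvalidConfigError("min_specificity must be in [0,1]")


def _make_estimator(config: TrainingConfig):
    hp = dict(config.hyperparameters)
    if config.model_family == "tree-ensemble":
        hp.setdefault("n_estimators", 200)
        hp.setdefault("min_samples_leaf", 2)
        return RandomForestClassifier(random_state=config.seed, n_jobs=1, **hp)
    hp.setdefault("C", 1.0)
    hp.setdefault("max_iter", 2000)
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(random_state=config.seed, **hp)),
        ]
    )


def assign_grouped_folds(
    records: Sequence[PatientRecord], n_folds: int, seed: int
) -> dict[str, int]:
    """Assign each patient to one cross-validation fold, class-stratified.

    Patients (not spectra) are the unit of assignment, so all replicate
    spectra of a patient inherit its fold.  Within each class patients are
    shuffled with the given seed and dealt round-robin, keeping fold class
    counts balanced to within one patient.
    """
    by_class: dict[str, list[str]] = {}
    for r in records:
        by_class.setdefault(r.true_class, []).append(r.patient_id)
    for cls, pids in by_class.items():
        if len(pids) < n_folds:
            raise InvalidConfigError(
                f"class {cls!r} has {len(pids)} patients; need >= {n_folds} for {n_folds} folds"
            )
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    for cls in sorted(by_class):
        pids = sorted(by_class[cls])
        rng.shuffle(pids)
        for i, pid in enumerate(pids):
            folds[pid] = i % n_folds
    return folds


@dataclass
class TrainedClassifier:
    """Fitted per-spectrum model plus the bookkeeping needed to audit it."""

    estimator: object
    feature_grid: np.ndarray
    config: TrainingConfig
    folds: dict[str, int]
    oof: pd.DataFrame  # patient_id, well, scan, p_cancer (out-of-fold)

    def predict_proba(self, features: np.ndarray, index: pd.DataFrame) -> pd.DataFrame:
        return predict_proba(self, features, index)


def train(
    features: np.ndarray,
    labels: Sequence[str],
    index: pd.DataFrame,
    records: Sequence[PatientRecord],
    config: TrainingConfig,
    feature_grid: np.ndarray | None = None,
) -> TrainedClassifier:
    """Fit the per-spectrum classifier with patient-grouped cross-validation.

    ``labels`` gives the true class of each feature row (spectrum);
    ``index`` carries patient_id/well/scan per row.  Returns the model
    refitted on all data together with out-of-fold cancer probabilities for
    every training spectrum, which downstream threshold tuning uses so that
    no tuned number is contaminated by training-set fit.
    """
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise DegenerateInputError("training data contains a single class")
    if features.shape[0] != len(labels) or features.shape[0] != len(index):
        raise ConsistencyError("features, labels and index must align row-wise")

    folds = assign_grouped_folds(records, config.n_folds, config.seed)
    missing = set(index["patient_id"]) - set(folds)
    if missing:
        raise ConsistencyError(f"spectra from patients without fold assignment: {sorted(missing)[:5]}")
    row_fold = index["patient_id"].map(folds).to_numpy()

    y = (labels == CANCER).astype(int)
    oof = np.full(features.shape[0], np.nan)
    for k in range(config.n_folds):
        test_mask = row_fold == k
        est = _make_estimator(config)
        est.fit(features[~test_mask], y[~test_mask])
        oof[test_mask] = est.predict_proba(features[test_mask])[:, 1]

    final = _make_estimator(config)
    final.fit(features, y)

    oof_df = index.copy()
    oof_df["p_cancer"] = oof
    if feature_grid is None:
        feature_grid = np.arange(features.shape[1], dtype=float)
    return TrainedClassifier(
        estimator=final,
        feature_grid=np.asarray(feature_grid, dtype=float),
        config=config,
        folds=folds,
        oof=oof_df,
    )


def predict_proba(
    model: TrainedClassifier, features: np.ndarray, index: pd.DataFrame
) -> pd.DataFrame:
    """Per-spectrum cancer probabilities for new features.

    Returns a frame with columns patient_id, well, scan, p_cancer.
    """
    if features.ndim != 2 or features.shape[1] != model.feature_grid.size:
        raise IncompatibleGridError(
            f"expected {model.feature_grid.size} features, got {features.shape}"
        )
    p = model.estimator.predict_proba(features)[:, 1]
    out = index.copy()
    out["p_cancer"] = np.clip(p, 0.0, 1.0)
    return out


def tune_threshold(
    probs: pd.DataFrame,
    truth: Mapping[str, str],
    config: TrainingConfig,
    consensus: ConsensusConfig | None = None,
) -> float:
    """Choose the probability threshold on patient-level consensus predictions.

    ``probs`` must be out-of-fold per-spectrum probabilities (columns
    patient_id, p_cancer).  The ``balanced`` objective maximises
    min(sensitivity, specificity); ties prefer smaller |sens - spec|, then
    the lower threshold.  ``max_sensitivity_at_min_specificity`` maximises
    sensitivity subject to specificity >= ``config.min_specificity``.
    Candidate thresholds are the unique probabilities plus 0 (all-positive)
    — votes use p >= threshold, so every achievable vote pattern is visited.
    """
    consensus = consensus or ConsensusConfig()
    classes = {truth[pid] for pid in probs["patient_id"].unique()}
    if len(classes) < 2:
        raise DegenerateInputError("threshold tuning needs both classes in the truth")

    candidates = np.unique(probs["p_cancer"].to_numpy())
    candidates = np.concatenate([[0.0], candidates])
    scores = consensus_patient_scores(probs, consensus)
    is_cancer = np.array([truth[pid] == CANCER for pid in scores.index])
    pos = np.sort(scores.to_numpy()[is_cancer])
    neg = np.sort(scores.to_numpy()[~is_cancer])
    sens_all = 1.0 - np.searchsorted(pos, candidates, side="left") / pos.size
    spec_all = np.searchsorted(neg, candidates, side="left") / neg.size
    best = None
    for t, sens, spec in zip(candidates, sens_all, spec_all):
        if config.tuning_objective == "balanced":
            key = (min(sens, spec), -abs(sens - spec), -t)
        else:
            if spec < config.min_specificity:
                continue
            key = (sens, -t)
        if best is None or key > best[0]:
            best = (key, float(t))
    if best is None:
        # No threshold met the specificity floor; fall back to the most
        # specific candidate (threshold above every probability).
        return float(np.nextafter(candidates[-1], 2.0))
    return best[1]
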