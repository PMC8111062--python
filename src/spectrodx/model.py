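"""End-to-end spectral diagnostic model.

:class:`SpectralDiagnosticModel` ties the stages together in the
statsmodels idiom: build the model from a cohort (truth records plus raw
spectra), call :meth:`fit`, and read everything — per-spectrum out-of-fold
probabilities, tuned threshold, patient-level consensus predictions, ROC
table and diagnostic-accuracy metrics — off the returned
:class:`SpectralDiagnosticResults`.

The fit is fully cross-validated at patient level: each patient's nine
spectra are scored by a model that never saw that patient, the vote
threshold is tuned on those out-of-fold scores, and the reported metrics
are therefore honest estimates of generalisation performance on cohorts of
this kind.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, consensus as consensus_mod
from .classify import TrainedClassifier, TrainingConfig
from .consensus import ConsensusConfig, PatientPrediction, predictions_to_frame
from .errors import ConsistencyError
from .metrics import DiagnosticAccuracy, DiagnosticAccuracyResults
from .preprocess import PreprocessConfig, preprocess_pipeline
from .simulate import PatientRecord, Spectrum

__all__ = ["SpectralDiagnosticModel", "SpectralDiagnosticResults"]


class SpectralDiagnosticModel:
    """Cross-validated spectral classifier + consensus diagnosis for one cohort."""

    def __init__(
        self,
        records: Sequence[PatientRecord],
        spectra: Sequence[Spectrum],
        preprocess_config: PreprocessConfig | None = None,
        training_config: TrainingConfig | None = None,
        consensus_config: ConsensusConfig | None = None,
    ):
        known = {r.patient_id for r in records}
        orphans = sorted({s.patient_id for s in spectra} - known)
        if orphans:
            raise ConsistencyError(f"spectra reference unknown patients: {orphans[:5]}")
        self.records = list(records)
        self.spectra = list(spectra)
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.training_config = training_config or TrainingConfig()
        self.consensus_config = consensus_config or ConsensusConfig()

    def fit(self, seed: int | None = None) -> "SpectralDiagnosticResults":
        """Preprocess, train with grouped CV, tune the threshold, and report.

        ``seed`` overrides the training configuration's seed (fold shuffling
        and any stochastic estimator internals).
        """
        tc = self.training_config
        if seed is not None:
            tc = replace(tc, seed=seed)

        X, grid, index = preprocess_pipeline(self.spectra, self.preprocess_config)
        truth = {r.patient_id: r.true_class for r in self.records}
        labels = index["patient_id"].map(truth).to_numpy()

        clf = classify.train(X, labels, index, self.records, tc, feature_grid=grid)

        threshold = classify.tune_threshold(
            clf.oof, truth, tc, consensus=self.consensus_config
        )
        preds = consensus_mod.consensus_predict_cohort(
            clf.oof, threshold, self.consensus_config
        )
        roc_table, auc = consensus_mod.roc_curve(clf.oof, truth, self.consensus_config)
        accuracy = DiagnosticAccuracy.from_predictions(preds, self.records).fit()
        return SpectralDiagnosticResults(
            model=self,
            classifier=clf,
            threshold=threshold,
            spectrum_probabilities=clf.oof,
            patient_predictions=preds,
            roc_table=roc_table,
            auc=auc,
            accuracy=accuracy,
        )


@dataclass
class SpectralDiagnosticResults:
    """Everything the cross-validated fit produced."""

    model: SpectralDiagnosticModel
    classifier: TrainedClassifier
    threshold: float
    spectrum_probabilities: pd.DataFrame
    patient_predictions: list[PatientPrediction]
    roc_table: pd.DataFrame
    auc: float
    accuracy: DiagnosticAccuracyResults

    def predictions_frame(self) -> pd.DataFrame:
        return predictions_to_frame(self.patient_predictions)

    def summary(self) -> str:
        lines = [
            "Spectral liquid-biopsy diagnostic evaluation",
            "=" * 44,
            f"Patients: {len(self.model.records)}   "
            f"Spectra: {len(self.model.spectra)}   "
            f"Classifier: {self.classifier.config.model_family}",
            f"Tuned vote threshold: {self.threshold:.4f}   "
            f"Consensus rule: >= {self.model.consensus_config.votes_required} of "
            f"{self.model.consensus_config.expected_spectra} votes",
            f"Patient-level ROC AUC (out-of-fold): {self.auc:.3f}",
            "",
            self.accuracy.summary(),
        ]
        return "\n".join(lines)
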