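"""Patient-level consensus voting and ROC construction.

Each patient contributes several per-spectrum cancer probabilities (nine in
the standard 3-wells x 3-scans design).  A probability threshold turns each
spectrum into a binary vote, and the patient is called "cancer" when at
least ``votes_required`` (default 5) of the expected 9 votes agree.  ROC
curves are built at patient level by sweeping the threshold over every
distinct probability and recomputing the consensus predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidConfigError, InvalidInputError
from .simulate import CANCER, NON_CANCER

__all__ = [
    "ConsensusConfig",
    "PatientPrediction",
    "votes_from_probabilities",
    "consensus_predict",
    "consensus_predict_cohort",
    "roc_curve",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Voting rule: cancer iff >= votes_required of expected_spectra agree.

    ``incomplete_policy`` governs patients with fewer spectra than expected:
    ``strict_majority_of_available`` calls cancer when cancer votes reach at
    least half of the available votes (an exact tie resolves to cancer, so
    ambiguity never produces false reassurance in a rule-out test);
    ``error`` refuses incomplete patients outright.
    """

    votes_required: int = 5
    expected_spectra: int = 9
    incomplete_policy: str = "strict_majority_of_available"

    def __post_init__(self) -> None:
        if not 1 <= self.votes_required <= self.expected_spectra:
            raise InvalidConfigError(
                f"votes_required must be in [1, {self.expected_spectra}], "
                f"got {self.votes_required}"
            )
        if self.incomplete_policy not in ("strict_majority_of_available", "error"):
            raise InvalidConfigError(f"unknown incomplete_policy {self.incomplete_policy!r}")


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    n_spectra: int
    n_cancer_votes: int
    predicted_class: str
    threshold: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_cancer_votes <= self.n_spectra:
            raise InvalidConfigError("n_cancer_votes must be within [0, n_spectra]")


def votes_from_probabilities(p_cancer: Sequence[float] | np.ndarray,
                             threshold: float) -> np.ndarray:
    """Binary votes: cancer iff p_cancer >= threshold (inclusive)."""
    if not 0.0 <= threshold <= 1.0 + 1e-9:
        raise InvalidInputError(f"threshold must be in [0,1], got {threshold}")
    return np.asarray(p_cancer, dtype=float) >= threshold


def consensus_predict(patient_id: str, votes: Sequence[bool] | np.ndarray,
                      config: ConsensusConfig, threshold: float = float("nan")
                      ) -> PatientPrediction:
    """Aggregate one patient's votes into a single diagnosis.

    With the expected number of votes the rule is: cancer iff at least
    ``votes_required`` cancer votes.  With fewer votes, behaviour follows
    ``incomplete_policy`` (see :class:`ConsensusConfig`).
    """
    votes = np.asarray(votes, dtype=bool)
    n = votes.size
    if n == 0:
        raise InvalidInputError(f"patient {patient_id}: no votes to aggregate")
    n_cancer = int(votes.sum())
    if n == config.expected_spectra:
        is_cancer = n_cancer >= config.votes_required
    elif config.incomplete_policy == "error":
        raise InvalidInputError(
            f"patient {patient_id}: expected {config.expected_spectra} votes, got {n}"
        )
    else:
        # Strict majority of available, ties resolved towards cancer.
        is_cancer = 2 * n_cancer >= n
    return PatientPrediction(
        patient_id=patient_id,
        n_spectra=n,
        n_cancer_votes=n_cancer,
        predicted_class=CANCER if is_cancer else NON_CANCER,
        threshold=threshold,
    )


def consensus_predict_cohort(probs: pd.DataFrame, threshold: float,
                             config: ConsensusConfig) -> list[PatientPrediction]:
    """Consensus predictions for every patient in a per-spectrum probability frame.

    ``probs`` needs columns ``patient_id`` and ``p_cancer``.
    """
    preds = []
    for pid, grp in probs.groupby("patient_id", sort=True):
        votes = votes_from_probabilities(grp["p_cancer"].to_numpy(), threshold)
        preds.append(consensus_predict(str(pid), votes, config, threshold))
    return preds


def patient_scores(probs: pd.DataFrame, config: ConsensusConfig) -> pd.Series:
    """Per-patient consensus score: the m-th largest spectrum probability.

    A patient is called cancer at threshold t exactly when at least m of its
    spectra have p >= t, i.e. when its m-th largest probability is >= t —
    so the consensus prediction is a simple threshold on this order
    statistic (m = votes_required for complete patients, the tie-to-cancer
    majority count otherwise).  Sorting once per patient makes threshold
    sweeps linear instead of quadratic.
    """
    out = {}
    for pid, grp in probs.groupby("patient_id", sort=True):
        p = np.sort(grp["p_cancer"].to_numpy())[::-1]
        k = p.size
        if k == config.expected_spectra:
            m = config.votes_required
        elif config.incomplete_policy == "error":
            raise InvalidInputError(
                f"patient {pid}: expected {config.expected_spectra} votes, got {k}"
            )
        else:
            m = (k + 1) // 2
        out[str(pid)] = p[m - 1]
    return pd.Series(out, name="score")


def predictions_to_frame(preds: Sequence[PatientPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in preds],
            "n_spectra": [p.n_spectra for p in preds],
            "n_cancer_votes": [p.n_cancer_votes for p in preds],
            "predicted_class": [p.predicted_class for p in preds],
            "threshold": [p.threshold for p in preds],
        }
    )


def roc_curve(probs: pd.DataFrame, truth: Mapping[str, str],
              config: ConsensusConfig | None = None
              ) -> tuple[pd.DataFrame, float]:
    """Patient-level ROC by sweeping the vote threshold.

    Thresholds are the sorted unique probabilities plus 0 (everything votes
    cancer) and a value just above the maximum (nothing votes cancer).  At
    each threshold the consensus predictions are recomputed and patient-level
    sensitivity and specificity noted; because each patient's cancer-vote
    count is non-increasing in the threshold, sensitivity is non-increasing
    and specificity non-decreasing along the sweep.  The AUC is the
    trapezoidal area over (1 - specificity, sensitivity).

    Returns (table with columns threshold/sensitivity/specificity, auc).
    """
    config = config or ConsensusConfig()
    pids = probs["patient_id"].unique()
    classes = {truth[str(pid)] for pid in pids}
    if len(classes) < 2:
        raise DegenerateInputError("ROC needs both classes present in the truth")

    uniq = np.unique(probs["p_cancer"].to_numpy())
    thresholds = np.concatenate([[0.0], uniq, [np.nextafter(max(uniq[-1], 1.0), 2.0)]])
    scores = patient_scores(probs, config)
    is_cancer = np.array([truth[pid] == CANCER for pid in scores.index])
    pos_scores = np.sort(scores.to_numpy()[is_cancer])
    neg_scores = np.sort(scores.to_numpy()[~is_cancer])
    # patient called cancer at t iff score >= t
    sens = 1.0 - np.searchsorted(pos_scores, thresholds, side="left") / pos_scores.size
    spec = np.searchsorted(neg_scores, thresholds, side="left") / neg_scores.size
    table = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )

    fpr = 1.0 - table["specificity"].to_numpy()
    tpr = table["sensitivity"].to_numpy()
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return table, auc
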