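"""Diagnostic test accuracy: confusion matrix, the six standard metrics with
binomial confidence intervals, precision (CI half-width) and sample-size
planning, prevalence-transported predictive values, and subgroup sensitivity.

The central objects follow the statsmodels convention: build a
:class:`DiagnosticAccuracy` model from patient-level predictions and truth
(or directly from confusion counts), call :meth:`~DiagnosticAccuracy.fit`,
and read estimates, confidence intervals and a formatted summary off the
returned :class:`DiagnosticAccuracyResults`.

Confidence intervals default to the Wald normal approximation
``p +/- z * sqrt(p (1 - p) / n)`` clipped to [0, 1]; the Wilson score
interval is available via ``ci_method="wilson"``.  ``z`` for the 95% level
is the exact normal quantile 1.959964 (display rounding absorbs the
difference from 1.96).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .consensus import PatientPrediction
from .errors import (
    ConsistencyError,
    DegenerateInputError,
    InvalidConfigError,
    UndefinedMetricError,
)
from .simulate import CANCER, PatientRecord

__all__ = [
    "ConfusionMatrix",
    "PrevalenceScenario",
    "DiagnosticAccuracy",
    "DiagnosticAccuracyResults",
    "confusion",
    "wald_ci",
    "wilson_ci",
    "half_width",
    "required_n",
    "adjust_predictive_values",
    "subgroup_sensitivity",
]

METRIC_NAMES = ("sensitivity", "specificity", "prevalence", "ppv", "npv", "accuracy")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient-level confusion counts; positive = cancer."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvalidConfigError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise InvalidConfigError("confusion matrix must contain at least one patient")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive_truth(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative_truth(self) -> int:
        return self.tn + self.fp

    @property
    def n_positive_test(self) -> int:
        return self.tp + self.fp

    @property
    def n_negative_test(self) -> int:
        return self.tn + self.fn

    def as_table(self) -> pd.DataFrame:
        """Confusion matrix with margins, laid out test-rows x truth-columns."""
        return pd.DataFrame(
            {
                "Positive": [self.tp, self.fn, self.tp + self.fn],
                "Negative": [self.fp, self.tn, self.fp + self.tn],
                "Total": [self.n_positive_test, self.n_negative_test, self.total],
            },
            index=["Test positive", "Test negative", "Total"],
        )


def confusion(predictions: Sequence[PatientPrediction],
              truth: Sequence[PatientRecord]) -> ConfusionMatrix:
    """Tally patient-level predictions against the truth table.

    Requires exactly one prediction per truth patient; mismatched or
    duplicated ids raise :class:`ConsistencyError` naming the offender.
    """
    truth_map = {}
    for r in truth:
        if r.patient_id in truth_map:
            raise ConsistencyError(f"duplicate patient in truth table: {r.patient_id}")
        truth_map[r.patient_id] = r.true_class
    seen = set()
    tp = fp = fn = tn = 0
    for p in predictions:
        if p.patient_id in seen:
            raise ConsistencyError(f"duplicate prediction for patient {p.patient_id}")
        seen.add(p.patient_id)
        if p.patient_id not in truth_map:
            raise ConsistencyError(f"prediction for unknown patient {p.patient_id}")
        actual = truth_map[p.patient_id]
        predicted = p.predicted_class
        if actual == CANCER:
            tp += predicted == CANCER
            fn += predicted != CANCER
        else:
            fp += predicted == CANCER
            tn += predicted != CANCER
    missing = set(truth_map) - seen
    if missing:
        raise ConsistencyError(f"no prediction for patients: {sorted(missing)[:5]}")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Binomial proportion intervals and precision.

def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise InvalidConfigError(f"confidence level must be in (0,1), got {level}")
    return float(norm.ppf(0.5 + level / 2.0))


def wald_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald (normal-approximation) binomial interval, clipped to [0, 1]."""
    if n < 1:
        raise UndefinedMetricError("Wald interval undefined for n = 0")
    if not 0.0 <= p <= 1.0:
        raise InvalidConfigError(f"proportion must be in [0,1], got {p}")
    h = _z(level) * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - h), min(1.0, p + h)


def wilson_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (better small-sample coverage than Wald)."""
    if n < 1:
        raise UndefinedMetricError("Wilson interval undefined for n = 0")
    z = _z(level)
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    h = z * math.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - h), min(1.0, centre + h)


_CI_METHODS = {"wald": wald_ci, "wilson": wilson_ci}


def half_width(p: float, n: float, level: float = 0.95) -> float:
    """CI half-width ('precision') in percentage points: 100 z sqrt(p(1-p)/n).

    ``n`` may be fractional, as in planning calculations where the expected
    number of positives is prevalence x cohort size.
    """
    if n <= 0:
        raise UndefinedMetricError("half-width undefined for n <= 0")
    if not 0.0 <= p <= 1.0:
        raise InvalidConfigError(f"proportion must be in [0,1], got {p}")
    return 100.0 * _z(level) * math.sqrt(p * (1.0 - p) / n)


def required_n(p: float, target_half_width: float, prevalence: float,
               level: float = 0.95) -> int:
    """Smallest total cohort size whose expected positives give the target precision.

    Solves for the smallest integer N with
    ``half_width(p, N * prevalence) <= target_half_width`` (target in
    percentage points).  This is the sample-size calculation for estimating
    a test's sensitivity to a stated CI half-width when only a fraction
    ``prevalence`` of recruits carry the disease.
    """
    if target_half_width <= 0:
        raise InvalidConfigError("target half-width must be > 0")
    if not 0.0 < prevalence <= 1.0:
        raise InvalidConfigError("prevalence must be in (0,1]")
    z = _z(level)
    n_pos = z * z * p * (1.0 - p) / (target_half_width / 100.0) ** 2
    n_total = max(1, math.ceil(n_pos / prevalence))
    # Guard against float edge cases at the boundary.
    while n_total > 1 and half_width(p, (n_total - 1) * prevalence, level) <= target_half_width:
        n_total -= 1
    while half_width(p, n_total * prevalence, level) > target_half_width:
        n_total += 1
    return n_total


@dataclass(frozen=True)
class PrevalenceScenario:
    """A target population prevalence and the transport method to apply."""

    target_prevalence: float
    method: str = "bayes"  # bayes | linear

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise DegenerateInputError(
                f"target prevalence must be in (0,1), got {self.target_prevalence}"
            )
        if self.method not in ("bayes", "linear"):
            raise InvalidConfigError(f"unknown transport method {self.method!r}")


def adjust_predictive_values(
    sensitivity: float,
    specificity: float,
    scenario: PrevalenceScenario,
    cohort_ppv: float | None = None,
    cohort_prevalence: float | None = None,
) -> tuple[float, float | None]:
    """Predictive values transported to a population with different prevalence.

    ``bayes`` applies the exact identities
    ``PPV = sens pi / (sens pi + (1 - spec)(1 - pi))`` and
    ``NPV = spec (1 - pi) / (spec (1 - pi) + (1 - sens) pi)``.
    ``linear`` rescales the cohort PPV by the prevalence ratio
    ``PPV = cohort_ppv * pi / cohort_prevalence`` — a first-order
    approximation sometimes used in screening discussions; it has no NPV
    analogue, so NPV is returned as None.
    """
    pi = scenario.target_prevalence
    if scenario.method == "bayes":
        ppv_num = sensitivity * pi
        ppv_den = ppv_num + (1.0 - specificity) * (1.0 - pi)
        npv_num = specificity * (1.0 - pi)
        npv_den = npv_num + (1.0 - sensitivity) * pi
        if ppv_den == 0.0 or npv_den == 0.0:
            raise DegenerateInputError("predictive value undefined (zero denominator)")
        return ppv_num / ppv_den, npv_num / npv_den
    if cohort_ppv is None or cohort_prevalence is None or cohort_prevalence == 0.0:
        raise InvalidConfigError("linear transport needs cohort_ppv and cohort_prevalence")
    return cohort_ppv * pi / cohort_prevalence, None


def subgroup_sensitivity(
    predictions: Sequence[PatientPrediction],
    truth: Sequence[PatientRecord],
    subtype: str,
    level: float = 0.95,
    ci_method: str = "wald",
) -> tuple[float, tuple[float, float]]:
    """Sensitivity restricted to cancer patients of one tumour subtype."""
    pred_map = {p.patient_id: p.predicted_class for p in predictions}
    members = [r for r in truth if r.true_class == CANCER and r.subtype == subtype]
    if not members:
        raise UndefinedMetricError(f"no cancer patients of subtype {subtype!r}")
    tp = sum(pred_map.get(r.patient_id) == CANCER for r in members)
    n = len(members)
    p = tp / n
    return p, _CI_METHODS[ci_method](p, n, level)


# ---------------------------------------------------------------------------
# Model / Results pair.

class DiagnosticAccuracy:
    """Diagnostic-accuracy model for a binary test against a reference standard.

    Construct from a confusion matrix (``DiagnosticAccuracy(cm)``), raw
    counts (:meth:`from_counts`), or patient-level predictions and truth
    records (:meth:`from_predictions`); then :meth:`fit` computes the six
    standard metrics with confidence intervals.
    """

    def __init__(self, confusion_matrix: ConfusionMatrix,
                 truth: Sequence[PatientRecord] | None = None,
                 predictions: Sequence[PatientPrediction] | None = None):
        self.confusion_matrix = confusion_matrix
        self.truth = list(truth) if truth is not None else None
        self.predictions = list(predictions) if predictions is not None else None

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "DiagnosticAccuracy":
        return cls(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))

    @classmethod
    def from_predictions(cls, predictions: Sequence[PatientPrediction],
                         truth: Sequence[PatientRecord]) -> "DiagnosticAccuracy":
        return cls(confusion(predictions, truth), truth=truth, predictions=predictions)

    def fit(self, level: float = 0.95, ci_method: str = "wald"
            ) -> "DiagnosticAccuracyResults":
        if ci_method not in _CI_METHODS:
            raise InvalidConfigError(f"unknown ci_method {ci_method!r}")
        cm = self.confusion_matrix
        denominators = {
            "sensitivity": cm.n_positive_truth,
            "specificity": cm.n_negative_truth,
            "prevalence": cm.total,
            "ppv": cm.n_positive_test,
            "npv": cm.n_negative_test,
            "accuracy": cm.total,
        }
        numerators = {
            "sensitivity": cm.tp,
            "specificity": cm.tn,
            "prevalence": cm.n_positive_truth,
            "ppv": cm.tp,
            "npv": cm.tn,
            "accuracy": cm.tp + cm.tn,
        }
        estimates: dict[str, float] = {}
        cis: dict[str, tuple[float, float]] = {}
        undefined: list[str] = []
        ci_fn = _CI_METHODS[ci_method]
        for name in METRIC_NAMES:
            n = denominators[name]
            if n == 0:
                undefined.append(name)
                estimates[name] = float("nan")
                cis[name] = (float("nan"), float("nan"))
                continue
            p = numerators[name] / n
            estimates[name] = p
            cis[name] = ci_fn(p, n, level)
        return DiagnosticAccuracyResults(
            model=self, estimates=estimates, conf_ints=cis,
            undefined=tuple(undefined), level=level, ci_method=ci_method,
        )


@dataclass
class DiagnosticAccuracyResults:
    """Fitted diagnostic-accuracy metrics with confidence intervals."""

    model: DiagnosticAccuracy
    estimates: Mapping[str, float]
    conf_ints: Mapping[str, tuple[float, float]]
    undefined: tuple[str, ...]
    level: float
    ci_method: str

    def __getattr__(self, name: str) -> float:
        if name in METRIC_NAMES:
            return self.estimates[name]
        raise AttributeError(name)

    def conf_int(self, metric: str) -> tuple[float, float]:
        if metric in self.undefined:
            raise UndefinedMetricError(f"{metric} is undefined (zero denominator)")
        return self.conf_ints[metric]

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        """Metrics table; ``percent=True`` applies nearest-whole-percent rounding."""
        rows = []
        for name in METRIC_NAMES:
            p = self.estimates[name]
            lo, hi = self.conf_ints[name]
            if percent and name not in self.undefined:
                rows.append((name, round(100 * p), round(100 * lo), round(100 * hi)))
            else:
                rows.append((name, p, lo, hi))
        return pd.DataFrame(rows, columns=["metric", "estimate", "ci_lower", "ci_upper"]
                            ).set_index("metric")

    def adjust_predictive_values(self, scenario: PrevalenceScenario
                                 ) -> tuple[float, float | None]:
        """Transport PPV/NPV to the scenario prevalence (see module function)."""
        return adjust_predictive_values(
            self.estimates["sensitivity"], self.estimates["specificity"], scenario,
            cohort_ppv=self.estimates["ppv"],
            cohort_prevalence=self.estimates["prevalence"],
        )

    def precision(self) -> float:
        """Half-width of the sensitivity CI, percentage points."""
        cm = self.model.confusion_matrix
        return half_width(self.estimates["sensitivity"], cm.n_positive_truth, self.level)

    def summary(self) -> str:
        """Human-readable report: confusion matrix with margins, then metrics."""
        cm = self.model.confusion_matrix
        lines = ["Diagnostic accuracy report", "=" * 26, ""]
        lines.append("Confusion matrix (test rows x reference columns):")
        lines.append(cm.as_table().to_string())
        lines.append("")
        pct = f"{100 * self.level:g}%"
        lines.append(f"{'Metric':<12} {'Estimate':>9} {pct + ' CI lower':>12} {pct + ' CI upper':>12}")
        for name in METRIC_NAMES:
            if name in self.undefined:
                lines.append(f"{name:<12} {'undefined':>9}")
                continue
            p = self.estimates[name]
            lo, hi = self.conf_ints[name]
            lines.append(f"{name:<12} {round(100 * p):>8}% {round(100 * lo):>11}% {round(100 * hi):>11}%")
        lines.append("")
        lines.append(f"CI method: {self.ci_method}; "
                     f"sensitivity precision (CI half-width): "
                     f"+/-{self.precision():.1f} percentage points")
        return "\n".join(lines)
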