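"""ROC calibration of the aberration score and closed-form filter performance.

A small random sample of tracks is judged by eye as "pass" or "fail"; the
ROC curve of τ against those annotations yields an operating threshold.  The
default criterion maximizes the Youden index J = sensitivity + specificity − 1
(equivalently, balanced accuracy).  The positive class is "fail": TrAM
detects tracking failures, so sensitivity is the fraction of failed tracks
rejected and specificity the fraction of good tracks kept.

Given the failed-track prevalence P and the operating point's error rates
α = 1 − specificity (good tracks rejected) and β = 1 − sensitivity (failures
admitted), filter performance follows in closed form:

    precision (unfiltered)  = 1 − P
    precision (filtered)    = (1 − P)(1 − α) / [ (1 − P)(1 − α) + P β ]
    recall                  = 1 − α  (= specificity: good cells kept)
    residual prevalence     = 1 − precision (filtered)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CalibrationError

__all__ = [
    "AnnotationSet",
    "RocCurve",
    "OperatingPoint",
    "FilterPerformance",
    "roc_curve",
    "youden_operating_point",
    "operating_point",
    "predicted_performance",
    "percent",
]

PASS, FAIL = "pass", "fail"


def percent(x: float) -> int:
    """Express a proportion as an integer percentage, rounding half-up."""
    return int(math.floor(100.0 * x + 0.5))


@dataclass(frozen=True)
class AnnotationSet:
    """Per-cell pass/fail labels from manual inspection of tracks."""

    labels: Mapping[str, str]
    annotator: str | None = None

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {PASS, FAIL}
        if bad:
            raise CalibrationError(f"labels must be 'pass'/'fail', got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_fail(self) -> int:
        return sum(1 for v in self.labels.values() if v == FAIL)

    @property
    def prevalence(self) -> float:
        """Failed-track prevalence estimated from this annotated sample."""
        return self.n_fail / len(self.labels)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "AnnotationSet":
        df = pd.read_csv(path)
        return cls(
            labels=dict(
                zip(df["cell_id"].astype(str), df["label"].str.strip().str.lower())
            ),
            **kw,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"cell_id": list(self.labels), "label": list(self.labels.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class RocCurve:
    """Sensitivity/specificity over candidate thresholds, plus AUC.

    Thresholds are the midpoints between adjacent distinct scores with ±inf
    sentinels; a cell is predicted "fail" when its score exceeds the
    threshold.  AUC is the tie-corrected Mann–Whitney statistic.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pass: int
    n_fail: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax=None):
        """Plot the ROC curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(1 - self.specificity, self.sensitivity, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls=":", c="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {self.auc:.3f}")
        return ax


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "threshold": self.threshold,
                    "sensitivity": self.sensitivity,
                    "specificity": self.specificity,
                    "youden_j": self.youden_j,
                    "balanced_accuracy": self.balanced_accuracy,
                },
                indent=2,
            )
        )


def _align(scores, labels: AnnotationSet | Mapping[str, str]):
    if isinstance(labels, AnnotationSet):
        labels = labels.labels
    if isinstance(scores, Mapping):
        s = np.array([float(scores[cid]) for cid in labels], dtype=float)
        y = np.array([labels[cid] == FAIL for cid in labels], dtype=bool)
    elif isinstance(scores, pd.DataFrame):
        lut = dict(zip(scores["cell_id"].astype(str), scores["tau"]))
        s = np.array([float(lut[cid]) for cid in labels], dtype=float)
        y = np.array([labels[cid] == FAIL for cid in labels], dtype=bool)
    else:
        s = np.asarray(scores, dtype=float)
        lab = list(labels.values()) if isinstance(labels, Mapping) else list(labels)
        y = np.array([v == FAIL for v in lab], dtype=bool)
        if len(s) != len(y):
            raise CalibrationError("scores and labels have different lengths")
    return s, y


def roc_curve(
    scores: Mapping[str, float] | Sequence[float] | pd.DataFrame,
    labels: AnnotationSet | Mapping[str, str] | Sequence[str],
) -> RocCurve:
    """ROC of a score against pass/fail annotations (positive class: fail).

    ``scores`` may be a mapping cell_id -> τ, a table with ``cell_id`` and
    ``tau`` columns, or a plain sequence aligned with the labels.
    """
    s, y = _align(scores, labels)
    if not np.all(np.isfinite(s)):
        raise CalibrationError("scores must be finite")
    n_fail = int(y.sum())
    n_pass = int((~y).sum())
    if n_fail == 0 or n_pass == 0:
        raise CalibrationError("both pass and fail annotations are required")

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # predicted fail when score > threshold
    pred = s[None, :] > thresholds[:, None]
    sens = (pred & y[None, :]).sum(axis=1) / n_fail
    spec = (~pred & ~y[None, :]).sum(axis=1) / n_pass

    ranks = rankdata(s)  # average ranks: ties score 1/2 in the pairwise count
    auc = (ranks[y].sum() - n_fail * (n_fail + 1) / 2.0) / (n_fail * n_pass)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        n_pass=n_pass,
        n_fail=n_fail,
    )


def youden_operating_point(roc: RocCurve) -> OperatingPoint:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Ties are broken toward the larger threshold (higher specificity), which
    preserves throughput.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)[-1]  # thresholds sorted ascending
    return OperatingPoint(
        threshold=float(roc.thresholds[best]),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
    )


def operating_point(
    roc: RocCurve,
    criterion: str = "youden",
    *,
    target: float | None = None,
    prevalence: float | None = None,
) -> OperatingPoint:
    """Choose an operating threshold under one of several criteria.

    - ``"youden"``: maximize sensitivity + specificity (the default).
    - ``"min_sensitivity"``: highest specificity subject to
      sensitivity >= ``target``.
    - ``"min_specificity"``: highest sensitivity subject to
      specificity >= ``target``.
    - ``"max_accuracy"``: maximize P·sens + (1−P)·spec at the given
      ``prevalence`` P.
    """
    if criterion == "youden":
        return youden_operating_point(roc)
    if criterion in ("min_sensitivity", "min_specificity"):
        if target is None:
            raise CalibrationError(f"criterion {criterion!r} needs target=")
        if criterion == "min_sensitivity":
            ok = roc.sensitivity >= target
            obj = roc.specificity
        else:
            ok = roc.specificity >= target
            obj = roc.sensitivity
        if not ok.any():
            raise CalibrationError(f"no threshold satisfies {criterion} >= {target}")
        cand = np.flatnonzero(ok)
        best = cand[np.flatnonzero(obj[cand] >= obj[cand].max() - 1e-12)[-1]]
    elif criterion == "max_accuracy":
        if prevalence is None:
            raise CalibrationError("criterion 'max_accuracy' needs prevalence=")
        acc = prevalence * roc.sensitivity + (1 - prevalence) * roc.specificity
        best = np.flatnonzero(acc >= acc.max() - 1e-12)[-1]
    else:
        raise CalibrationError(f"unknown criterion {criterion!r}")
    return OperatingPoint(
        threshold=float(roc.thresholds[best]),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
    )


@dataclass(frozen=True)
class FilterPerformance:
    """Prevalence-aware precision/recall of a pass/fail filter."""

    prevalence: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def alpha(self) -> float:
        """Good tracks rejected: 1 − specificity."""
        return 1.0 - self.specificity

    @property
    def beta(self) -> float:
        """Failed tracks admitted: 1 − sensitivity."""
        return 1.0 - self.sensitivity

    @property
    def precision_unfiltered(self) -> float:
        return 1.0 - self.prevalence

    @property
    def precision_filtered(self) -> float:
        P = self.prevalence
        good = (1.0 - P) * (1.0 - self.alpha)
        bad = P * self.beta
        if good + bad == 0.0:
            return 1.0  # nothing accepted; no failures admitted either
        return good / (good + bad)

    @property
    def recall(self) -> float:
        """Fraction of accurate cells accepted: 1 − α = specificity."""
        return 1.0 - self.alpha

    @property
    def residual_prevalence(self) -> float:
        return 1.0 - self.precision_filtered

    def as_percent(self) -> dict[str, int]:
        """Integer-percent report (rounded half-up)."""
        return {
            "precision_unfiltered": percent(self.precision_unfiltered),
            "precision_filtered": percent(self.precision_filtered),
            "recall": percent(self.recall),
            "residual_prevalence": percent(self.residual_prevalence),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "prevalence": self.prevalence,
                    "sensitivity": self.sensitivity,
                    "specificity": self.specificity,
                    "alpha": self.alpha,
                    "beta": self.beta,
                    "precision_unfiltered": self.precision_unfiltered,
                    "precision_filtered": self.precision_filtered,
                    "recall": self.recall,
                    "residual_prevalence": self.residual_prevalence,
                    "percent": self.as_percent(),
                },
                indent=2,
            )
        )


def predicted_performance(
    prevalence: float, sensitivity: float, specificity: float
) -> FilterPerformance:
    """Closed-form filter performance from prevalence and error rates.

    With P = 0 the filtered precision is 1 regardless of the error rates:
    there are no failures to admit.
    """
    return FilterPerformance(
        prevalence=prevalence, sensitivity=sensitivity, specificity=specificity
    )
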