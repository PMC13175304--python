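"""Threshold classification of detected responses and performance metrics.

Detected voxels are classified on two independent axes:

* timing — ``early`` iff the estimated peak time is below the critical
  peak time t_p* (default 45 min), else ``late``;
* amplitude — ``low`` iff the normalized response magnitude
  M_hat = gamma_hat / k2a_hat is below the critical magnitude M*
  (default 0.8), else ``high``.

Equality sits on the ``late`` / ``high`` side: the printed rules use strict
inequalities on both sides, and under continuous estimates the boundary has
zero measure, so the tie rule is a determinism convention only.

Scalar metrics:

* detection sensitivity DS_DA = 100 * #{dBIC < 0} / k
* characterization sensitivity CS = P(called c | truly c)
  - P(called c | truly not-c) + 1, bounded in [0, 2]: 2 for a perfect
  separator, 1 for any classifier that ignores the truth
* characterization accuracy CA = 100 * (TP + TN) / (TP + TN + FP + FN)
* PPV / NPV and their complements FDR = 100 - PPV, FOR = 100 - NPV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassifierThresholds",
    "ConfusionCounts",
    "MetricsReport",
    "classify_timing",
    "classify_amplitude",
    "detection_sensitivity",
    "detection_specificity",
    "characterization_sensitivity_tp",
    "characterization_sensitivity_m",
    "characterization_accuracy",
    "predictive_values",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Critical peak-time (min) and normalized-magnitude thresholds."""

    tp_star: float = 45.0
    m_star: float = 0.8
    scan_minutes: float = 90.0

    def __post_init__(self):
        if not 0 < self.tp_star < self.scan_minutes:
            raise ValueError("tp_star must lie within the scan duration")
        if self.m_star <= 0:
            raise ValueError("m_star must be positive")


def classify_timing(tp_hat, thr: ClassifierThresholds):
    """'early' iff tp_hat < tp_star (ties late). Vectorized over arrays."""
    tp_hat = np.asarray(tp_hat, dtype=float)
    if not np.all(np.isfinite(tp_hat)):
        raise ValueError("tp_hat must be finite")
    out = np.where(tp_hat < thr.tp_star, "early", "late")
    return out.item() if out.ndim == 0 else out


def classify_amplitude(gamma_hat, k2a_hat, thr: ClassifierThresholds):
    """'low' iff gamma_hat/k2a_hat < m_star (ties high).

    Voxels with k2a_hat == 0 have an undefined magnitude and raise.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    k2a_hat = np.asarray(k2a_hat, dtype=float)
    if np.any(k2a_hat == 0):
        raise ValueError("k2a_hat is zero: magnitude undefined (invalid voxel)")
    out = np.where(gamma_hat / k2a_hat < thr.m_star, "low", "high")
    return out.item() if out.ndim == 0 else out


def detection_sensitivity(delta_bics) -> float:
    """DS_DA: percentage of responses with dBIC < 0."""
    d = np.asarray(delta_bics, dtype=float)
    if d.size == 0:
        raise ValueError("empty dBIC collection")
    return 100.0 * float(np.mean(d < 0))


def detection_specificity(detected_null) -> float:
    """TN/(TN+FP) over ground-truth-null voxels, as a percentage."""
    d = np.asarray(detected_null, dtype=bool)
    if d.size == 0:
        raise ValueError("empty null collection")
    return 100.0 * float(np.mean(~d))


def _cs(values_true_pos, values_true_neg, threshold) -> float:
    pos = np.asarray(values_true_pos, dtype=float)
    neg = np.asarray(values_true_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both truth groups must be non-empty")
    return float(np.mean(pos < threshold) - np.mean(neg < threshold) + 1.0)


def characterization_sensitivity_tp(tp_hats_true_early, tp_hats_true_late,
                                    tp_star: float) -> float:
    """CS_tp*: fraction of true-early called early minus fraction of
    true-late called early, plus one."""
    return _cs(tp_hats_true_early, tp_hats_true_late, tp_star)


def characterization_sensitivity_m(m_hats_true_low, m_hats_true_high,
                                   m_star: float) -> float:
    """CS_M*: same construction on the low/high axis.

    Oriented so that 2 means a perfect separator: fraction of true-low
    called low minus fraction of true-high called low, plus one.
    """
    return _cs(m_hats_true_low, m_hats_true_high, m_star)


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class confusion counts for one classification c."""

    tp: int
    tn: int
    fp: int
    fn: int
    class_label: str = ""

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def characterization_accuracy(c: ConfusionCounts) -> float:
    """CA_c = 100 * (TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    return 100.0 * (c.tp + c.tn) / c.total


def predictive_values(c: ConfusionCounts) -> dict:
    """PPV, NPV, FDR, FOR (percent); NaN where a denominator is zero."""
    ppv = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    npv = 100.0 * c.tn / (c.tn + c.fn) if (c.tn + c.fn) else float("nan")
    return dict(ppv=ppv, npv=npv, fdr=100.0 - ppv, for_=100.0 - npv)


@dataclass(frozen=True)
class MetricsReport:
    """Scalar performance summary of one phantom experiment.

    Percentages are in [0, 100]; CS values in [0, 2].  Per-class entries
    are keyed by class label ('early', 'late', 'low', 'high').
    """

    ds_da: float
    detection_specificity: float
    cs_tp: float | None = None
    cs_m: float | None = None
    ca_by_class: dict = field(default_factory=dict)
    predictive_by_class: dict = field(default_factory=dict)
    confusion_by_class: dict = field(default_factory=dict)

    def to_rows(self):
        """Tidy (class, metric, value) rows for CSV export."""
        rows = [("all", "ds_da", self.ds_da),
                ("all", "detection_specificity", self.detection_specificity)]
        if self.cs_tp is not None:
            rows.append(("all", "cs_tp", self.cs_tp))
        if self.cs_m is not None:
            rows.append(("all", "cs_m", self.cs_m))
        for cls, ca in self.ca_by_class.items():
            rows.append((cls, "ca", ca))
        for cls, pv in self.predictive_by_class.items():
            for k, v in pv.items():
                rows.append((cls, k.rstrip("_"), v))
        return rows


def confusion_from_labels(predicted, truth, cls: str,
                          valid=None) -> ConfusionCounts:
    """Confusion counts for class ``cls`` from label arrays.

    ``predicted`` and ``truth`` are string label arrays over the same
    voxels; entries of ``predicted`` that are not a class on this axis
    (e.g. 'undetected') count as negative calls, so a detection miss is a
    false negative for the voxel's own class and a true negative for the
    complementary class.  ``valid`` optionally masks voxels to include.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if valid is None:
        valid = np.ones(predicted.shape, dtype=bool)
    pred_c = (predicted == cls) & valid
    true_c = (truth == cls) & valid
    tp = int(np.sum(pred_c & true_c))
    fp = int(np.sum(pred_c & ~true_c & valid))
    fn = int(np.sum(~pred_c & true_c & valid))
    tn = int(np.sum(~pred_c & ~true_c & valid))
    return ConfusionCounts(tp, tn, fp, fn, cls)
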