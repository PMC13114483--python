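"""Two-step bruise discrimination on reduced-scattering maps.

Step 1 separates non-bruised from bruised samples by the coefficient of
variation (CV) of the global mu_s' map: bruising makes the map heterogeneous
and inflates the CV.  Step 2 grades samples called bruised as mild or severe
by the mean ratio M = mean(mu_s' bruised region) / mean(mu_s' adjacent sound
region); severe bruising collapses mu_s' and drives M down.  Both thresholds
are selected by maximizing the Youden index (sensitivity + specificity - 1)
along an ROC sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleScore",
    "ROCAnalysis",
    "DiscriminationReport",
    "coefficient_of_variation",
    "mean_ratio",
    "roc_curve",
    "youden_index",
    "youden_optimal_threshold",
    "strict_threshold",
    "classify_bruised",
    "classify_severity",
    "severity_confusion_table",
    "two_step_pipeline",
]


@dataclass
class SampleScore:
    """Per-sample discrimination scores and ground truth."""

    sample_id: str
    cv: float = np.nan
    mean_ratio: float = np.nan
    true_bruised: bool | None = None
    true_severity: str | None = None  # "mild" | "severe" | None
    fruit_kind: str = "apple"
    called_bruised: bool | None = None
    called_severity: str | None = None


@dataclass
class ROCAnalysis:
    """ROC sweep with AUC and the Youden-optimal operating point.

    ``orientation`` records the decision rule: ``"higher"`` means scores at
    or above a threshold are called positive, ``"lower"`` means scores at or
    below it are.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    orientation: str
    optimal_threshold: float = np.nan
    youden: float = np.nan


def coefficient_of_variation(mu_s_prime_map, valid_mask=None) -> float:
    """Population-sd-over-mean of the global mu_s' distribution."""
    m = np.asarray(mu_s_prime_map, dtype=float)
    if valid_mask is not None:
        m = m[np.asarray(valid_mask, dtype=bool)]
    if m.size == 0:
        raise ValueError("empty valid mask")
    mean = m.mean()
    if mean <= 0:
        raise ValueError("mean mu_s' must be > 0")
    return float(m.std(ddof=0) / mean)


def mean_ratio(mu_s_prime_map, bruise_mask, sound_mask) -> float:
    """Mean mu_s' over the bruised region divided by the adjacent sound region."""
    m = np.asarray(mu_s_prime_map, dtype=float)
    bruise_mask = np.asarray(bruise_mask, dtype=bool)
    sound_mask = np.asarray(sound_mask, dtype=bool)
    if not bruise_mask.any() or not sound_mask.any():
        raise ValueError("both region masks must be non-empty")
    if (bruise_mask & sound_mask).any():
        raise ValueError("bruise and sound masks must be disjoint")
    sound_mean = m[sound_mask].mean()
    if sound_mean <= 0:
        raise ValueError("sound-region mean must be > 0")
    return float(m[bruise_mask].mean() / sound_mean)


def roc_curve(scores, labels, orientation: str = "lower") -> ROCAnalysis:
    """ROC sweep over the unique score values.

    ``labels`` are booleans marking positives (e.g. severe).  With
    ``orientation="lower"`` a lower score argues for the positive class
    (severe bruises have lower mean ratios); ``"higher"`` reverses this.
    AUC is the trapezoid over the sweep, which equals concordance-pair
    counting with ties credited 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if orientation not in ("lower", "higher"):
        raise ValueError(f"unknown orientation {orientation!r}")

    s = -scores if orientation == "lower" else scores
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = labels[order]
    # sweep: positive called when transformed score >= threshold
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    idx = np.where(distinct)[0]
    # last index of each tie-group
    last = np.r_[idx[1:] - 1, y_sorted.size - 1]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    thr_internal = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = -thr_internal if orientation == "lower" else thr_internal
    return ROCAnalysis(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                       orientation=orientation)


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def youden_optimal_threshold(roc: ROCAnalysis) -> tuple[float, float]:
    """Operating point maximizing the Youden index along the sweep.

    Ties go to the point with higher sensitivity, then to the lower
    threshold value.  The analysis object is updated in place and the
    ``(threshold, youden)`` pair returned.
    """
    j = roc.tpr + (1.0 - roc.fpr) - 1.0
    best = np.flatnonzero(j == j.max())
    best = best[roc.tpr[best] == roc.tpr[best].max()]
    vals = roc.thresholds[best]
    finite = best[np.isfinite(vals)]
    k = finite[np.argmin(roc.thresholds[finite])] if finite.size else best[0]
    roc.optimal_threshold = float(roc.thresholds[k])
    roc.youden = float(j[k])
    return roc.optimal_threshold, roc.youden


def strict_threshold(roc: ROCAnalysis) -> float:
    """Convert the Youden operating score into a strict-inequality cut.

    The ROC operating rule is inclusive (score at the threshold is called
    positive) while the printed classification rules are strict, so the cut
    is moved to the midpoint between the operating score and the nearest
    score on the negative side.
    """
    thr, _ = youden_optimal_threshold(roc)
    scores = roc.thresholds[np.isfinite(roc.thresholds)]
    if roc.orientation == "higher":
        below = scores[scores < thr]
        return float((thr + below.max()) / 2.0) if below.size else thr - abs(thr) - 1.0
    above = scores[scores > thr]
    return float((thr + above.min()) / 2.0) if above.size else thr + abs(thr) + 1.0


def classify_bruised(cv: float, threshold: float) -> bool:
    """CV strictly above the threshold is called bruised."""
    return cv > threshold


def classify_severity(M: float, threshold: float) -> str:
    """Mean ratio strictly below the threshold is called severe, else mild."""
    return "severe" if M < threshold else "mild"


def severity_confusion_table(fault_counts: dict, actual_counts: dict) -> pd.DataFrame:
    """Mild/severe fault table with per-grade and overall rates.

    ``fault_counts`` and ``actual_counts`` map grade -> count; the overall
    row aggregates both grades (rate = total faults / total samples).
    """
    rows = []
    total_f, total_a = 0, 0
    for grade in ("mild", "severe"):
        f = int(fault_counts.get(grade, 0))
        a = int(actual_counts.get(grade, 0))
        rows.append({"grade": grade, "actual": a, "faults": f,
                     "rate": f / a if a else np.nan})
        total_f += f
        total_a += a
    rows.append({"grade": "total", "actual": total_a, "faults": total_f,
                 "rate": total_f / total_a if total_a else np.nan})
    return pd.DataFrame(rows)


@dataclass
class DiscriminationReport:
    """Outcome of the two-step discrimination on one cohort."""

    samples: list
    cv_threshold: float
    cv_roc: ROCAnalysis
    step1_accuracy: float
    m_threshold: float = np.nan
    m_roc: ROCAnalysis | None = None
    severity_table: pd.DataFrame | None = None
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "fruit_kind": s.fruit_kind,
                    "cv": s.cv,
                    "mean_ratio": s.mean_ratio,
                    "true_bruised": s.true_bruised,
                    "true_severity": s.true_severity,
                    "called_bruised": s.called_bruised,
                    "called_severity": s.called_severity,
                }
                for s in self.samples
            ]
        )


def two_step_pipeline(samples) -> DiscriminationReport:
    """Run CV classification then mean-ratio grading over a scored cohort.

    ``samples`` is a sequence of :class:`SampleScore` with ``cv`` filled for
    all samples, ``mean_ratio`` filled for truly bruised ones, and ground
    truth set.  Thresholds are Youden-selected on the cohort itself
    (calibration-set convention).
    """
    samples = list(samples)
    cvs = np.array([s.cv for s in samples])
    bruised_truth = np.array([bool(s.true_bruised) for s in samples])
    cv_roc = roc_curve(cvs, bruised_truth, orientation="higher")
    cv_thr = strict_threshold(cv_roc)
    for s in samples:
        s.called_bruised = classify_bruised(s.cv, cv_thr)
    step1_acc = float(
        np.mean([s.called_bruised == s.true_bruised for s in samples])
    )

    report = DiscriminationReport(
        samples=samples, cv_threshold=cv_thr, cv_roc=cv_roc,
        step1_accuracy=step1_acc,
    )

    called = [s for s in samples if s.called_bruised and s.true_severity]
    if not called:
        report.notes.append("no bruised calls; severity grading skipped")
        return report
    severities = np.array([s.true_severity == "severe" for s in called])
    if severities.all() or not severities.any():
        report.notes.append("one severity class among bruised calls; grading skipped")
        return report
    ms = np.array([s.mean_ratio for s in called])
    m_roc = roc_curve(ms, severities, orientation="lower")
    m_thr = strict_threshold(m_roc)
    for s in called:
        s.called_severity = classify_severity(s.mean_ratio, m_thr)

    faults = {"mild": 0, "severe": 0}
    actual = {"mild": 0, "severe": 0}
    for s in called:
        actual[s.true_severity] += 1
        if s.called_severity != s.true_severity:
            faults[s.true_severity] += 1
    report.m_threshold = m_thr
    report.m_roc = m_roc
    report.severity_table = severity_confusion_table(faults, actual)
    return report
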