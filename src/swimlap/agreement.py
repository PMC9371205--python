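"""Classification reports and paired lap-time agreement statistics.

Classification is scored with the standard per-class precision, recall and
F1 (harmonic mean 2PR/(P+R), zero when P+R = 0), macro and support-weighted
averages, overall accuracy, and the 8x8 confusion matrix.

Lap-time agreement between a device and a reference uses the sports-science
conventions:

* bias — mean of (device - reference) with a 95% t-based confidence
  interval (n-1 degrees of freedom);
* typical error of measurement (TEM) — sd of the paired differences
  divided by sqrt(2), with a 95% CI from the chi-squared distribution of
  (n-1)s^2/sigma^2;
* Bland-Altman limits of agreement — bias +/- 1.96 * sd(differences);
* MAPE — mean absolute percentage error with its SD, also expressed in
  seconds through the reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

from .activities import ActivityClass, LabelSequence, N_CLASSES

__all__ = [
    "ClassificationReport",
    "AgreementReport",
    "classification_report",
    "bias_ci",
    "tem_ci",
    "bland_altman",
    "mape",
]


@dataclass
class ClassificationReport:
    precision: np.ndarray  # per class, length 8
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    confusion: np.ndarray  # (8, 8), rows = truth
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def per_class(self) -> dict[str, dict[str, float]]:
        return {
            ActivityClass(c).name: {
                "precision": float(self.precision[c]),
                "recall": float(self.recall[c]),
                "f1": float(self.f1[c]),
                "support": int(self.support[c]),
            }
            for c in range(N_CLASSES)
        }

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro": {"precision": self.macro_precision, "recall": self.macro_recall,
                      "f1": self.macro_f1},
            "weighted": {"precision": self.weighted_precision,
                         "recall": self.weighted_recall, "f1": self.weighted_f1},
            "classes": self.per_class(),
            "confusion": self.confusion.tolist(),
        }


def classification_report(pred: LabelSequence, truth: LabelSequence) -> ClassificationReport:
    """Frame-wise classification metrics of a prediction against ground truth."""
    if pred.n_frames != truth.n_frames:
        raise ValueError(
            f"length mismatch: prediction has {pred.n_frames} frames, "
            f"truth has {truth.n_frames}"
        )
    y_true, y_pred = truth.labels, pred.labels
    labels = np.arange(N_CLASSES)
    p, r, f1, support = _skm.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    mp, mr, mf1, _ = _skm.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    wp, wr, wf1, _ = _skm.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="weighted", zero_division=0
    )
    return ClassificationReport(
        precision=p, recall=r, f1=f1, support=support,
        accuracy=float(_skm.accuracy_score(y_true, y_pred)),
        confusion=_skm.confusion_matrix(y_true, y_pred, labels=labels),
        macro_precision=float(mp), macro_recall=float(mr), macro_f1=float(mf1),
        weighted_precision=float(wp), weighted_recall=float(wr), weighted_f1=float(wf1),
    )


def _paired(pred_s, ref_s, min_n: int = 2):
    pred_s = np.asarray(pred_s, dtype=float).ravel()
    ref_s = np.asarray(ref_s, dtype=float).ravel()
    if pred_s.shape != ref_s.shape:
        raise ValueError("paired vectors must have equal length")
    if pred_s.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {pred_s.size}")
    return pred_s, ref_s


def bias_ci(pred_s, ref_s, confidence: float = 0.95):
    """Mean difference (device - reference) and its t-based CI."""
    pred_s, ref_s = _paired(pred_s, ref_s)
    d = pred_s - ref_s
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / np.sqrt(n)
    return bias, (bias - half, bias + half)


def tem_ci(pred_s, ref_s, confidence: float = 0.95):
    """Typical error of measurement sd(diff)/sqrt(2) and its chi-squared CI."""
    pred_s, ref_s = _paired(pred_s, ref_s)
    d = pred_s - ref_s
    n = d.size
    sd = float(d.std(ddof=1))
    tem = sd / np.sqrt(2.0)
    alpha = 1.0 - confidence
    lo = sd * np.sqrt((n - 1) / stats.chi2.ppf(1 - alpha / 2, n - 1)) / np.sqrt(2.0)
    hi = sd * np.sqrt((n - 1) / stats.chi2.ppf(alpha / 2, n - 1)) / np.sqrt(2.0)
    return float(tem), (float(lo), float(hi))


def bland_altman(pred_s, ref_s, multiplier: float = 1.96):
    """Bias, limits of agreement, and the per-pair means and differences."""
    pred_s, ref_s = _paired(pred_s, ref_s)
    d = pred_s - ref_s
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_lower": bias - multiplier * sd,
        "loa_upper": bias + multiplier * sd,
        "means": (pred_s + ref_s) / 2.0,
        "diffs": d,
    }


def mape(pred_s, ref_s):
    """(MAPE %, SD of the per-pair absolute percentage errors %, MAPE in
    seconds via the reference mean). Requires strictly positive references."""
    pred_s, ref_s = _paired(pred_s, ref_s, min_n=1)
    if np.any(ref_s <= 0):
        raise ValueError("reference values must be strictly positive")
    ape = np.abs(pred_s - ref_s) / ref_s * 100.0
    m = float(ape.mean())
    sd = float(ape.std(ddof=1)) if ape.size > 1 else 0.0
    return m, sd, (m / 100.0) * float(ref_s.mean())


@dataclass
class AgreementReport:
    """All paired lap-time agreement statistics for one comparison."""

    n: int
    pred_mean: float
    pred_sd: float
    ref_mean: float
    ref_sd: float
    bias: float
    bias_ci95: tuple[float, float]
    tem: float
    tem_ci95: tuple[float, float]
    loa_lower: float
    loa_upper: float
    mape_pct: float
    mape_sd_pct: float
    mape_s: float

    @classmethod
    def compute(cls, pred_s, ref_s) -> "AgreementReport":
        pred_s, ref_s = _paired(pred_s, ref_s)
        b, b_ci = bias_ci(pred_s, ref_s)
        t, t_ci = tem_ci(pred_s, ref_s)
        ba = bland_altman(pred_s, ref_s)
        m, m_sd, m_s = mape(pred_s, ref_s)
        return cls(
            n=pred_s.size,
            pred_mean=float(pred_s.mean()), pred_sd=float(pred_s.std(ddof=1)),
            ref_mean=float(ref_s.mean()), ref_sd=float(ref_s.std(ddof=1)),
            bias=b, bias_ci95=b_ci, tem=t, tem_ci95=t_ci,
            loa_lower=ba["loa_lower"], loa_upper=ba["loa_upper"],
            mape_pct=m, mape_sd_pct=m_sd, mape_s=m_s,
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pred_mean_s": self.pred_mean, "pred_sd_s": self.pred_sd,
            "ref_mean_s": self.ref_mean, "ref_sd_s": self.ref_sd,
            "bias_s": self.bias, "bias_ci95_s": list(self.bias_ci95),
            "tem_s": self.tem, "tem_ci95_s": list(self.tem_ci95),
            "loa_lower_s": self.loa_lower, "loa_upper_s": self.loa_upper,
            "mape_pct": self.mape_pct, "mape_sd_pct": self.mape_sd_pct,
            "mape_s": self.mape_s,
        }
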