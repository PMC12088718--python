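"""Patient-level evaluation: AUC with repeat-level CI, Brier, calibration,
and the low-threshold operating-point sweep.

Discrimination is summarized by AUC-ROC; with five repeated train/val/test
splits the aggregate is the mean AUC with a t-based 95% confidence interval
across repeats.  Calibration uses equal-width probability bins (empty bins
dropped, so low-prevalence arteries naturally yield fewer bins).  The
threshold sweep reports sensitivity/specificity/precision/F-score for
decision thresholds 0.01–0.50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import brier_score_loss, roc_auc_score


def roc_auc(labels, scores) -> float:
    """AUC-ROC; equal to the normalized Mann–Whitney U statistic (ties ½)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, s))


def brier(labels, probs) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return float(brier_score_loss(np.asarray(labels, dtype=int), p))


def threshold_sweep(labels, probs, start: float = 0.01, stop: float = 0.50, step: float = 0.01) -> pd.DataFrame:
    """Confusion-matrix metrics at each threshold; positive iff prob ≥ t.

    Precision (and hence F-score) is NaN when nothing is predicted positive.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    n_steps = int(round((stop - start) / step)) + 1
    thresholds = start + step * np.arange(n_steps)
    rows = []
    for t in thresholds:
        pred = p >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        prec = tp / (tp + fp) if tp + fp else np.nan
        if np.isnan(prec) or np.isnan(sens) or prec + sens == 0:
            f1 = np.nan
        else:
            f1 = 2 * prec * sens / (prec + sens)
        rows.append(
            {"threshold": round(float(t), 10), "sensitivity": sens, "specificity": spec, "precision": prec, "f_score": f1}
        )
    return pd.DataFrame(rows)


def calibration_table(labels, probs, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration bins on [0, 1]; empty bins are dropped.

    Each row: bin interval, mean predicted probability, observed event
    fraction and patient count; counts sum to the number of patients.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    idx = np.minimum((p * n_bins).astype(int), n_bins - 1)  # last bin right-closed
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        count = int(in_bin.sum())
        if count == 0:
            continue
        rows.append(
            {
                "bin_low": b / n_bins,
                "bin_high": (b + 1) / n_bins,
                "mean_predicted": float(p[in_bin].mean()),
                "observed_fraction": float(y[in_bin].mean()),
                "count": count,
            }
        )
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "mean_predicted", "observed_fraction", "count"])


def aggregate_repeats(values, confidence: float = 0.95, method: str = "t") -> tuple[float, float, float]:
    """Mean and CI of a metric across repeated test sets.

    ``t``: mean ± t_{1-α/2, k-1}·sd/√k (default); ``normal`` uses the z
    quantile instead.
    """
    v = np.asarray(values, dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError("aggregation requires at least two repeats")
    mean = float(v.mean())
    se = float(v.std(ddof=1)) / np.sqrt(k)
    if method == "t":
        q = stats.t.ppf(0.5 + confidence / 2, df=k - 1)
    elif method == "normal":
        q = stats.norm.ppf(0.5 + confidence / 2)
    else:
        raise ValueError("method must be 't' or 'normal'")
    return mean, mean - q * se, mean + q * se


@dataclass
class FoldSummary:
    """Per-repeat patient-level predictions and aggregate metrics."""

    repeats: list[pd.DataFrame] = field(default_factory=list)  # patient_id, label, prob per repeat
    aucs: list[float] = field(default_factory=list)
    briers: list[float] = field(default_factory=list)
    attention_hits: list[tuple[int, int]] = field(default_factory=list)  # (hits, positives) per repeat

    def add_repeat(self, frame: pd.DataFrame) -> None:
        self.repeats.append(frame)
        self.aucs.append(roc_auc(frame["label"], frame["prob"]))
        self.briers.append(brier(frame["label"], frame["prob"]))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_ci(self) -> tuple[float, float]:
        _, lo, hi = aggregate_repeats(self.aucs)
        return lo, hi

    @property
    def mean_brier(self) -> float:
        return float(np.mean(self.briers))

    @property
    def attention_hit_rate(self) -> float:
        hits = sum(h for h, _ in self.attention_hits)
        total = sum(t for _, t in self.attention_hits)
        return hits / total if total else np.nan

    def pooled(self) -> pd.DataFrame:
        frames = []
        for i, f in enumerate(self.repeats):
            f = f.copy()
            f["repeat"] = i
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        lo, hi = self.auc_ci
        return {
            "n_repeats": len(self.aucs),
            "aucs": [float(a) for a in self.aucs],
            "mean_auc": self.mean_auc,
            "auc_ci95": [lo, hi],
            "briers": [float(b) for b in self.briers],
            "mean_brier": self.mean_brier,
            "attention_hit_rate": self.attention_hit_rate,
        }
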