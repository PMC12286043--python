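"""Validity, reliability and efficiency metrics for fixation annotation.

Classification scores wrap scikit-learn; the chance-corrected multi-rater
agreement wraps statsmodels' Fleiss kappa.  Threshold sweeps (background
ROC over ``t`` and accuracy/annotation-ratio over ``t_aoi``) evaluate the
selective decision rule on precomputed probability vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .io import AOISchema
from .engine import ABSTAIN, ThresholdConfig, decide

__all__ = [
    "MetricsReport", "SweepResult",
    "confusion_matrix", "classwise_metrics", "fleiss_kappa",
    "roc_sweep_bg", "sweep_aoi_threshold", "collapse_classes",
    "annotation_rate", "mean_completion_time",
    "chunked_completion_times", "class_annotation_times",
    "plot_roc", "plot_aoi_sweep",
]


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Accuracy, per-class P/R/F1 with macro and support-weighted averages,
    and the confusion matrix in counts and row-normalized form."""

    labels: tuple
    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    support: dict
    macro: dict                   # {"precision", "recall", "f1"}
    weighted: dict
    confusion: np.ndarray         # counts
    confusion_normalized: np.ndarray
    undefined_precision: tuple = ()   # classes never predicted

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "accuracy": self.accuracy,
            "per_class": {
                lab: {"precision": self.precision[lab], "recall": self.recall[lab],
                      "f1": self.f1[lab], "support": self.support[lab]}
                for lab in self.labels
            },
            "macro": self.macro,
            "weighted": self.weighted,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "undefined_precision": list(self.undefined_precision),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [{"class": lab, "precision": self.precision[lab],
                 "recall": self.recall[lab], "f1": self.f1[lab],
                 "support": self.support[lab]} for lab in self.labels]
        rows.append({"class": "macro avg", **self.macro, "support": sum(self.support.values())})
        rows.append({"class": "weighted avg", **self.weighted,
                     "support": sum(self.support.values())})
        return pd.DataFrame(rows)


def _label_list(schema_or_labels) -> list:
    if isinstance(schema_or_labels, AOISchema):
        return list(schema_or_labels.labels)
    return list(schema_or_labels)


def confusion_matrix(truth: Sequence[str], pred: Sequence[str], schema,
                     normalize: str = "none") -> np.ndarray:
    """Confusion counts with rows = true class; ``normalize="rows"``
    divides by row sums, leaving empty rows as zeros."""
    labels = _label_list(schema)
    m = _sk_confusion(list(truth), list(pred), labels=labels).astype(float)
    if normalize == "rows":
        sums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(sums > 0, m / np.where(sums == 0, 1, sums), 0.0)
    elif normalize != "none":
        raise ValueError("normalize must be 'none' or 'rows'")
    return m


def classwise_metrics(truth: Sequence[str], pred: Sequence[str], schema) -> MetricsReport:
    """Per-class precision/recall/F1 (undefined precision reported as 0 and
    flagged), macro and support-weighted averages, and overall accuracy."""
    labels = _label_list(schema)
    truth = list(truth)
    pred = list(pred)
    p, r, f, s = precision_recall_fscore_support(
        truth, pred, labels=labels, zero_division=0)
    acc = float(np.mean(np.asarray(truth) == np.asarray(pred)))
    mp, mr, mf, _ = precision_recall_fscore_support(
        truth, pred, labels=labels, average="macro", zero_division=0)
    wp, wr, wf, _ = precision_recall_fscore_support(
        truth, pred, labels=labels, average="weighted", zero_division=0)
    pred_counts = pd.Series(pred).value_counts()
    undefined = tuple(lab for lab in labels if pred_counts.get(lab, 0) == 0)
    counts = confusion_matrix(truth, pred, labels)
    return MetricsReport(
        labels=tuple(labels),
        accuracy=acc,
        precision=dict(zip(labels, p.tolist())),
        recall=dict(zip(labels, r.tolist())),
        f1=dict(zip(labels, f.tolist())),
        support=dict(zip(labels, s.tolist())),
        macro={"precision": float(mp), "recall": float(mr), "f1": float(mf)},
        weighted={"precision": float(wp), "recall": float(wr), "f1": float(wf)},
        confusion=counts,
        confusion_normalized=confusion_matrix(truth, pred, labels, normalize="rows"),
        undefined_precision=undefined,
    )


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa for an items × categories count matrix.

    Every row must sum to the same number of raters n >= 2.  Complete
    agreement with degenerate chance agreement (all ratings in a single
    category) is reported as 1.0.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("ratings must be an items × categories matrix")
    row_sums = m.sum(axis=1)
    n = row_sums[0]
    if n < 2 or not np.all(row_sums == n):
        raise ValueError("all items must be rated by the same n >= 2 raters")
    p_j = m.sum(axis=0) / m.sum()
    p_e = float(np.sum(p_j ** 2))
    p_i = (np.sum(m ** 2, axis=1) - n) / (n * (n - 1))
    p_bar = float(np.mean(p_i))
    if p_e >= 1.0:
        return 1.0 if p_bar == 1.0 else 0.0
    return float(_sm_fleiss(m))


@dataclass
class SweepResult:
    """Per-threshold operating points of the selective decision rule."""

    grid: np.ndarray
    annotation_ratio: np.ndarray | None = None
    accuracy: np.ndarray | None = None
    tpr: np.ndarray | None = None
    fpr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"threshold": self.grid}
        for name in ("annotation_ratio", "accuracy", "tpr", "fpr"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


def roc_sweep_bg(p_max: np.ndarray, truth: Sequence[str], schema: AOISchema,
                 grid: np.ndarray) -> SweepResult:
    """ROC for the background-vs-rest decision as ``t = t_bg = t_aoi`` varies.

    At each t the predicted-background set is ``{p_max < t}``; TPR is the
    background recall and FPR the fraction of non-background truth swept
    into it.  Both are non-decreasing in t.
    """
    p_max = np.asarray(p_max, dtype=float)
    is_bg = np.asarray([lab == schema.bg_name for lab in truth])
    grid = np.asarray(grid, dtype=float)
    tpr = np.empty_like(grid)
    fpr = np.empty_like(grid)
    n_bg = max(int(is_bg.sum()), 1)
    n_fg = max(int((~is_bg).sum()), 1)
    for i, t in enumerate(grid):
        pred_bg = p_max < t
        tpr[i] = np.sum(pred_bg & is_bg) / n_bg
        fpr[i] = np.sum(pred_bg & ~is_bg) / n_fg
    return SweepResult(grid=grid, tpr=tpr, fpr=fpr)


def sweep_aoi_threshold(probabilities: np.ndarray, truth: Sequence[str],
                        schema: AOISchema, t_bg: float,
                        grid: np.ndarray) -> SweepResult:
    """Accuracy over suggested samples and annotation ratio as ``t_aoi``
    rises at fixed ``t_bg``.

    The annotation ratio is the non-abstain fraction; accuracy is computed
    over suggested samples only, so at ``t_aoi = 1`` (with ``t_bg > 0``)
    it equals the background precision.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    truth = np.asarray(list(truth))
    grid = np.asarray(grid, dtype=float)
    ratio = np.empty_like(grid)
    acc = np.empty_like(grid)
    for i, t_aoi in enumerate(grid):
        cfg = ThresholdConfig(t_bg=t_bg, t_aoi=max(t_aoi, t_bg), trust=0.5)
        pred = np.array([decide(p, cfg, schema) for p in probabilities])
        suggested = pred != ABSTAIN
        ratio[i] = suggested.mean() if len(pred) else 0.0
        if suggested.any():
            acc[i] = float(np.mean(pred[suggested] == truth[suggested]))
        else:
            acc[i] = np.nan
    return SweepResult(grid=grid, annotation_ratio=ratio, accuracy=acc)


def collapse_classes(truth: Sequence[str], pred: Sequence[str],
                     mapping: Mapping[str, str]) -> tuple:
    """Map twinned labels onto summary classes (identity for absent keys);
    the background label never changes under the intended mappings."""
    t = [mapping.get(lab, lab) for lab in truth]
    p = [mapping.get(lab, lab) for lab in pred]
    return t, p


def annotation_rate(total_time_s: float, n_fixations: int) -> float:
    """Seconds per fixation, rounded half-up to 2 decimals for reporting."""
    if n_fixations <= 0:
        raise ValueError("n_fixations must be positive")
    return _round_half_up(total_time_s / n_fixations, 2)


def mean_completion_time(times_s: Sequence[float], ndigits: int = 0) -> float:
    """Mean task completion time across annotators, rounded half-up."""
    return _round_half_up(float(np.mean(np.asarray(times_s, dtype=float))), ndigits)


def chunked_completion_times(deltas_s: Sequence[float], window: int = 100,
                             step: int = 1) -> np.ndarray:
    """Moving-window total annotation time: position i covers annotations
    i..i+window-1; the series has length n - window + 1."""
    d = np.asarray(deltas_s, dtype=float)
    if np.any(d < 0):
        raise ValueError("time deltas must be non-negative")
    n = len(d)
    if n < window:
        raise ValueError("need at least `window` annotations")
    csum = np.concatenate([[0.0], np.cumsum(d)])
    out = csum[window:] - csum[:-window]
    return out[::step]


def class_annotation_times(labels: Sequence[str], deltas_s: Sequence[float]) -> pd.DataFrame:
    """Mean seconds per annotation and annotation count, per final label."""
    df = pd.DataFrame({"label": list(labels), "delta": list(deltas_s)})
    if (df["delta"] < 0).any():
        raise ValueError("time deltas must be non-negative")
    g = df.groupby("label")["delta"]
    return pd.DataFrame({"mean_time_s": g.mean(), "count": g.count()}).reset_index()


def plot_roc(sweep: SweepResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(sweep.fpr, sweep.tpr, marker="o", ms=3)
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false-positive rate (background)")
    ax.set_ylabel("true-positive rate (background recall)")
    ax.set_title("Background decision ROC over t")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_aoi_sweep(sweep: SweepResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(sweep.grid, sweep.accuracy, marker="o", ms=3, label="accuracy (suggested)")
    ax.plot(sweep.grid, sweep.annotation_ratio, marker="s", ms=3, label="annotation ratio")
    ax.set_xlabel("t_aoi")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
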