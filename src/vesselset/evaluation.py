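"""Segmentation metrics inside a field-of-view mask.

Accuracy is the fraction of correctly classified pixels among FOV pixels;
sensitivity is the vessel-pixel true-positive rate TP/(TP+FN); specificity
is the background true-negative rate TN/(TN+FP).  Pixels outside the FOV
never enter any count.  When a rate's denominator is zero (e.g. no vessel
pixels in truth ∩ FOV) it is reported as missing (None), not as zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_fov(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_fov

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None


def score(pred: np.ndarray, truth: np.ndarray, fov: np.ndarray) -> MetricsReport:
    """Confusion counts of a binary vessel map against ground truth in FOV."""
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    fov = np.asarray(fov, bool)
    if not (pred.shape == truth.shape == fov.shape):
        raise ValueError(
            f"shape mismatch: pred {pred.shape}, truth {truth.shape}, fov {fov.shape}"
        )
    if not fov.any():
        raise ValueError("FOV mask is empty")
    p, t = pred[fov], truth[fov]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn)


def aggregate(reports: dict[str, MetricsReport]) -> dict[str, float | None]:
    """Unweighted per-image means of accuracy / sensitivity / specificity.

    Images where a rate is undefined are excluded from that rate's mean.
    """
    if not reports:
        raise ValueError("no reports to aggregate")

    def mean_of(attr: str) -> float | None:
        vals = [getattr(r, attr) for r in reports.values()]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return {
        "accuracy": mean_of("accuracy"),
        "sensitivity": mean_of("sensitivity"),
        "specificity": mean_of("specificity"),
    }


def _fmt(v: float | None) -> str:
    return f"{v:.4f}" if v is not None else "n/a"


def metrics_table(reports: dict[str, MetricsReport], label: str = "Sample") -> str:
    """Pretty text table: one row per sample plus the average row."""
    header = f"{label:<24}{'Average accuracy':>18}{'Sensitivity':>14}{'Specificity':>14}"
    lines = [header, "-" * len(header)]
    for sid, r in reports.items():
        lines.append(
            f"{sid:<24}{_fmt(r.accuracy):>18}{_fmt(r.sensitivity):>14}{_fmt(r.specificity):>14}"
        )
    agg = aggregate(reports)
    lines.append("-" * len(header))
    lines.append(
        f"{'Average':<24}{_fmt(agg['accuracy']):>18}"
        f"{_fmt(agg['sensitivity']):>14}{_fmt(agg['specificity']):>14}"
    )
    return "\n".join(lines)


def write_metrics_csv(path: str | Path, reports: dict[str, MetricsReport]) -> None:
    """Per-sample metrics plus an aggregate row, as CSV."""
    agg = aggregate(reports)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["sample_id", "accuracy", "sensitivity", "specificity",
             "tp", "fp", "tn", "fn", "n_fov"]
        )
        for sid, r in reports.items():
            w.writerow(
                [sid, f"{r.accuracy:.6f}",
                 "" if r.sensitivity is None else f"{r.sensitivity:.6f}",
                 "" if r.specificity is None else f"{r.specificity:.6f}",
                 r.tp, r.fp, r.tn, r.fn, r.n_fov]
            )
        w.writerow(
            ["mean", f"{agg['accuracy']:.6f}",
             "" if agg["sensitivity"] is None else f"{agg['sensitivity']:.6f}",
             "" if agg["specificity"] is None else f"{agg['specificity']:.6f}",
             "", "", "", "", ""]
        )
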