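"""Per-run confusion matrices, cross-run summaries, and training curves.

Positive class = low dose (10 Gy): a true positive is a low-dose volume
correctly predicted as low dose.  Five independent train/test runs are
summarised by their accuracy table (mean and sample standard deviation) and
by the element-wise average of their confusion matrices, whose fractional
entries still sum to the per-run test-set size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """2x2 counts with positive = low dose; entries may be fractional
    (e.g. after averaging across runs)."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)


@dataclass
class RunReport:
    """Outcome of one train/test run."""

    run_id: int
    train_accuracy: float
    test_accuracy: float
    confusion: ConfusionMatrix
    optimal_epoch: int
    history: object = None

    def __post_init__(self) -> None:
        if abs(self.test_accuracy - self.confusion.accuracy) > 1e-12:
            raise ValueError(
                "test accuracy inconsistent with the confusion matrix: "
                f"{self.test_accuracy} vs {self.confusion.accuracy}"
            )


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    """Confusion counts of binary predictions (positive label = 1 = low dose)."""
    y = np.asarray(labels).ravel().astype(int)
    p = np.asarray(predictions).ravel().astype(int)
    if len(y) == 0:
        raise ValueError("empty label vector")
    if len(y) != len(p):
        raise ValueError("labels and predictions differ in length")
    if not (set(np.unique(y)) <= {0, 1} and set(np.unique(p)) <= {0, 1}):
        raise ValueError("labels and predictions must be binary")
    return ConfusionMatrix(
        tp=float(np.sum((y == 1) & (p == 1))),
        fp=float(np.sum((y == 0) & (p == 1))),
        fn=float(np.sum((y == 1) & (p == 0))),
        tn=float(np.sum((y == 0) & (p == 0))),
    )


def average_matrices(matrices: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise mean of same-n confusion matrices (entries fractional)."""
    if len(matrices) == 0:
        raise ValueError("no matrices to average")
    ns = {m.n for m in matrices}
    if len(ns) > 1:
        raise ValueError(f"matrices have mixed test-set sizes: {sorted(ns)}")
    k = len(matrices)
    return ConfusionMatrix(
        tp=sum(m.tp for m in matrices) / k,
        fp=sum(m.fp for m in matrices) / k,
        fn=sum(m.fn for m in matrices) / k,
        tn=sum(m.tn for m in matrices) / k,
    )


def summarize_runs(reports: Sequence[RunReport]) -> pd.DataFrame:
    """Accuracy table across runs with mean and sample (n-1) std rows.

    A single run has no sample standard deviation; it is reported as 0 with
    the ``degenerate_std`` attribute set on the frame.
    """
    if len(reports) == 0:
        raise ValueError("no run reports")
    rows = [
        {
            "run": r.run_id,
            "train_accuracy": r.train_accuracy,
            "test_accuracy": r.test_accuracy,
            "optimal_epoch": r.optimal_epoch,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    accs = df["test_accuracy"].to_numpy()
    mean = float(accs.mean())
    std = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    df.attrs["mean_test_accuracy"] = mean
    df.attrs["std_test_accuracy"] = std
    df.attrs["degenerate_std"] = len(accs) < 2
    return df


def format_summary(df: pd.DataFrame) -> str:
    lines = ["run  train_acc  test_acc  optimal_epoch"]
    for _, row in df.iterrows():
        lines.append(
            f"{int(row['run']):>3d}  {row['train_accuracy']:9.3f}  "
            f"{row['test_accuracy']:8.3f}  {int(row['optimal_epoch']):>13d}"
        )
    lines.append(
        f"avg test accuracy: {df.attrs['mean_test_accuracy']:.3f}  "
        f"std: {df.attrs['std_test_accuracy']:.3f}"
    )
    return "\n".join(lines)


def plot_history(history, out_path) -> list[Path]:
    """Accuracy and loss curves vs epoch, optimal epoch marked.

    Writes ``<out>.png`` with two panels (train/test series as raw points
    with connecting guides) and ``<out>.csv`` holding the exact per-epoch
    values; returns the written paths.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df = history.to_frame()
    epochs = df["epoch"].to_numpy()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, kind in zip(axes, ("accuracy", "loss")):
        for split, color in (("train", "tab:blue"), ("test", "tab:orange")):
            ax.plot(epochs, df[f"{split}_{kind}"], "o-", color=color,
                    label=split, markersize=4)
        if history.optimal_epoch is not None:
            ax.axvline(history.optimal_epoch, color="gray", ls="--", lw=1,
                       label=f"optimal epoch {history.optimal_epoch}")
        ax.set_xlabel("epoch")
        ax.set_ylabel(kind)
        ax.legend(fontsize=8)
    fig.tight_layout()
    png = out_path.with_suffix(".png")
    csv = out_path.with_suffix(".csv")
    fig.savefig(png, dpi=120)
    plt.close(fig)
    df.to_csv(csv, index=False)
    return [png, csv]
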