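#!/usr/bin/env python
"""Summarise the five runs: accuracy table, averaged confusion matrix,
training curves.

Reads the run reports produced by 04_train_models.py and writes the
accuracy summary (CSV + formatted table), the element-wise averaged
confusion matrix (fractional entries, quadrants summing to 32), and the
run-1 accuracy/loss curves with the optimal epoch marked.
"""

import json

import pandas as pd

from _common import RESULTS


def main():
    from svdose import evaluation
    from svdose.cnn import TrainingHistory
    from svdose.evaluation import ConfusionMatrix, RunReport

    runs_dir = RESULTS / "runs"
    payload = json.loads((runs_dir / "reports.json").read_text())
    reports = [
        RunReport(
            run_id=r["run"],
            train_accuracy=r["train_accuracy"],
            test_accuracy=r["test_accuracy"],
            confusion=ConfusionMatrix(**r["confusion"]),
            optimal_epoch=r["optimal_epoch"],
        )
        for r in payload
    ]
    summary = evaluation.summarize_runs(reports)
    summary.to_csv(RESULTS / "accuracy_summary.csv", index=False)
    text = evaluation.format_summary(summary)
    (RESULTS / "accuracy_summary.txt").write_text(text + "\n")
    print(text)

    avg = evaluation.average_matrices([r.confusion for r in reports])
    pd.DataFrame(
        avg.as_array(),
        index=["true low (10 Gy)", "true high (30 Gy)"],
        columns=["pred low", "pred high"],
    ).to_csv(RESULTS / "average_confusion_matrix.csv")
    print(f"\naveraged confusion matrix (n = {avg.n:.0f}):")
    print(f"  TP {avg.tp:5.2f}   FN {avg.fn:5.2f}")
    print(f"  FP {avg.fp:5.2f}   TN {avg.tn:5.2f}")

    hist_csv = runs_dir / "run1_history.csv"
    df = pd.read_csv(hist_csv)
    hist = TrainingHistory(
        train_accuracy=df["train_accuracy"].tolist(),
        test_accuracy=df["test_accuracy"].tolist(),
        train_loss=df["train_loss"].tolist(),
        test_loss=df["test_loss"].tolist(),
    )
    hist.optimal_epoch = payload[0]["optimal_epoch"]
    paths = evaluation.plot_history(hist, RESULTS / "run1_curves")
    print(f"\nwrote accuracy_summary.csv/.txt, average_confusion_matrix.csv, "
          f"{', '.join(p.name for p in paths)}")


if __name__ == "__main__":
    main()
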