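#!/usr/bin/env python
"""Train the 3D CNN on each of the five train/test combinations.

Each run builds the four-block network (16/32/64/64 filters, dense 256/64,
sigmoid head), trains 10 epochs of Adam (step size 1e-4) on the augmented
200-volume training set, and records per-epoch accuracy/loss on both sets.
Histories and per-run reports go to results/runs/.
"""

import json
import time

from _common import RESULTS, SEED, experiment_config, load_or_process_volumes


def main():
    from svdose import cnn, dataset, pipeline

    spec, volumes, manifest = load_or_process_volumes()
    config = experiment_config()
    plans = dataset.make_splits(manifest, n_runs=config.n_runs, seed=SEED)
    out = RESULTS / "runs"
    out.mkdir(parents=True, exist_ok=True)

    model_for_summary = cnn.build_model(
        cnn.CNNConfig(seed=SEED), config.cnn_shape
    )
    (out / "architecture.txt").write_text(cnn.summarize(model_for_summary) + "\n")

    reports = []
    for plan in plans:
        t0 = time.time()
        report = pipeline.run_split(volumes, plan, config, seed=SEED)
        reports.append(report)
        report.history.to_frame().to_csv(out / f"run{plan.run_id}_history.csv",
                                         index=False)
        print(
            f"run {plan.run_id}: test acc {report.test_accuracy:.3f} "
            f"(train {report.train_accuracy:.3f}) at optimal epoch "
            f"{report.optimal_epoch}  [{(time.time()-t0)/60:.1f} min]"
        )
    (out / "reports.json").write_text(json.dumps(
        [
            {
                "run": r.run_id,
                "train_accuracy": r.train_accuracy,
                "test_accuracy": r.test_accuracy,
                "optimal_epoch": r.optimal_epoch,
                "divergence": r.history.divergence,
                "confusion": {"tp": r.confusion.tp, "fp": r.confusion.fp,
                              "fn": r.confusion.fn, "tn": r.confusion.tn},
            }
            for r in reports
        ],
        indent=2,
    ) + "\n")
    print(f"wrote {out}/runN_history.csv, reports.json, architecture.txt")


if __name__ == "__main__":
    main()
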