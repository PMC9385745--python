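#!/usr/bin/env python
"""Plan the five mouse-disjoint train/test splits and the augmentation.

Each run trains on 8 mice (4 per class) and tests on 2 held-out mice
(1 per class); across the five runs every mouse is a test mouse exactly
once, and no time point of an animal ever crosses the train/test boundary.
Augmentation (3D flips and en-face rotations in [-40, 90] degrees) scales
each run to 200 training and 32 testing volumes.  Split plans and the run-1
augmentation inventory go to results/.
"""

import json

import pandas as pd

from _common import RESULTS, SEED, experiment_config, load_or_process_volumes


def main():
    from svdose import dataset

    spec, volumes, manifest = load_or_process_volumes()
    config = experiment_config()
    plans = dataset.make_splits(manifest, n_runs=config.n_runs, seed=SEED)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "splits.json").write_text(json.dumps(
        [
            {"run": p.run_id, "train_mice": sorted(p.train_mice),
             "test_mice": sorted(p.test_mice)}
            for p in plans
        ],
        indent=2,
    ) + "\n")
    for p in plans:
        print(f"run {p.run_id}: test mice {sorted(p.test_mice)}, "
              f"{len(p.train_mice)} train mice")

    train, test = dataset.split_volumes(volumes, plans[0])
    train_aug = dataset.augment_to_count(train, config.train_per_class,
                                         seed=(SEED, 1, 0))
    test_aug = dataset.augment_to_count(test, config.test_per_class,
                                        seed=(SEED, 1, 1))
    inv = pd.DataFrame(
        [
            {"set": name, "mouse_id": v.mouse_id, "day": v.day,
             "dose_class": v.dose_class, "augmentation": v.augmentation}
            for name, vols in (("train", train_aug), ("test", test_aug))
            for v in vols
        ]
    )
    inv.to_csv(RESULTS / "run1_augmentation_inventory.csv", index=False)
    print(f"run 1 augmented sets: {len(train_aug)} train / {len(test_aug)} test "
          f"({len(train_aug) + len(test_aug)} total)")
    print(f"wrote {RESULTS}/splits.json, run1_augmentation_inventory.csv")


if __name__ == "__main__":
    main()
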