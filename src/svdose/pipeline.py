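"""End-to-end orchestration: simulate -> process -> VOI -> datasets -> CNN.

This is the glue the analysis scripts, the acceptance checks and the tests
drive.  Each step delegates to the corresponding module; nothing here adds
behaviour beyond wiring and seed bookkeeping (one experiment seed expands
deterministically into per-volume and per-run streams).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import cnn, dataset, evaluation, svoct, voi
from . import synthetic_data as synth


def process_acquisition(
    raw, avg_factor: int = 2, denoise_params: Optional[svoct.DenoiseParams] = None,
) -> svoct.AngioVolume:
    """Raw repeated B-scans -> denoised speckle-variance angiogram."""
    vol = svoct.speckle_variance(raw)
    vol = svoct.lateral_average(vol, avg_factor)
    return svoct.denoise(vol, denoise_params or svoct.DenoiseParams())


def surface_contours_from_gt(gt: synth.GroundTruth) -> list[tuple[int, np.ndarray]]:
    """Subsample the ground-truth surface every 20 B-scans.

    Stands in for the manual tumour-surface contouring of the real workflow.
    """
    y_ext = gt.surface_depth_map.shape[1]
    return [
        (int(y), gt.surface_depth_map[:, y].astype(float))
        for y in range(0, y_ext, synth.CONTOUR_SPACING)
    ]


def build_voi_from_gt(
    gt: synth.GroundTruth, spec: synth.CohortSpec, fluor_seed,
) -> voi.TumourVOIMask:
    """Run the full VOI chain on synthetic ground truth.

    Fluorescence rendering -> binarization (threshold 77) -> similarity
    registration from fiducials -> lateral ROI warp; contour subsampling ->
    slow-axis interpolation -> conjunction, projected to the full depth.
    The surface is taken conservatively (deeper of each averaged line pair)
    when moving to the laterally averaged frame.
    """
    fluor = synth.generate_fluorescence_image(gt, fluor_seed)
    tf = voi.estimate_similarity(gt.fiducials)
    roi = voi.warp_mask(
        voi.binarize_fluorescence(fluor), tf, spec.processed_lateral_shape
    )
    contours = surface_contours_from_gt(gt)
    y_ext = gt.surface_depth_map.shape[1]
    dense = voi.interpolate_surface(contours, y_ext)  # (X, Y_raw)
    f = spec.lateral_average_factor
    x_ext = dense.shape[0]
    surf_proc = dense.reshape(x_ext, y_ext // f, f).max(axis=2)
    z_ext = spec.raw_shape[3]
    return voi.build_voi(roi, surf_proc, z_ext, contours=contours)


def process_cohort(
    spec: synth.CohortSpec,
    target_shape: tuple[int, int, int] = (64, 64, 64),
    denoise_params: Optional[svoct.DenoiseParams] = None,
    keep_ground_truth: bool = False,
):
    """Generate and process a cohort into CNN-ready labelled volumes.

    Acquisitions are generated, variance-processed, VOI-masked and resized
    one at a time (a full-scale 4D volume is large; nothing but the final
    CNN-ready volumes is retained).  Returns ``(volumes, manifest)`` — plus
    the per-volume ground truths when ``keep_ground_truth`` is set.
    """
    volumes: list[dataset.LabeledVolume] = []
    gts = []
    for raw, gt in synth.iter_cohort(spec):
        angio = process_acquisition(
            raw, spec.lateral_average_factor, denoise_params
        )
        fluor_seed = synth._volume_seed_seq(
            spec, raw.dose_class, raw.mouse_id, raw.day
        ).spawn(3)[2]
        mask = build_voi_from_gt(gt, spec, fluor_seed)
        volumes.append(voi.mask_and_resize(angio, mask, target_shape))
        if keep_ground_truth:
            gts.append(gt)
    manifest = synth.cohort_manifest(spec)
    if keep_ground_truth:
        return volumes, manifest, gts
    return volumes, manifest


@dataclass
class ExperimentConfig:
    """Scaled study configuration for a train/test experiment."""

    cnn_shape: tuple[int, int, int] = (64, 64, 64)
    n_runs: int = 5
    epochs: int = 10
    batch_size: int = 2
    learning_rate: float = 1e-4
    train_per_class: int = 100
    test_per_class: int = 16
    augment_test: bool = True


def run_split(
    volumes: Sequence[dataset.LabeledVolume],
    plan: dataset.SplitPlan,
    config: ExperimentConfig,
    seed: int,
    checkpoint_dir=None,
    verbose: bool = False,
) -> evaluation.RunReport:
    """Train and evaluate the CNN on one mouse-level split.

    The report's accuracies and confusion matrix are taken at the optimal
    epoch (test-loss minimum), matching the post-hoc model selection rule.
    """
    train_orig, test_orig = dataset.split_volumes(volumes, plan)
    train_aug = dataset.augment_to_count(
        train_orig, config.train_per_class, seed=(seed, plan.run_id, 0)
    )
    if config.augment_test:
        test_aug = dataset.augment_to_count(
            test_orig, config.test_per_class, seed=(seed, plan.run_id, 1)
        )
    else:
        test_aug = list(test_orig)
    train_t = dataset.assemble_tensor(train_aug)
    test_t = dataset.assemble_tensor(test_aug)
    cfg = cnn.CNNConfig(
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=int(np.random.SeedSequence((seed, plan.run_id, 2)).generate_state(1)[0]
                 % (2**31)),
    )
    model = cnn.build_model(cfg, config.cnn_shape)
    history = cnn.train(
        model,
        train_t.samples, train_t.labels,
        test_t.samples, test_t.labels,
        cfg,
        checkpoint_dir=checkpoint_dir,
        verbose=verbose,
    )
    opt = history.optimal_epoch
    probs, labels = history.test_predictions[opt - 1]
    preds = (probs > 0.5).astype(int)
    cm = evaluation.confusion(labels.astype(int), preds)
    return evaluation.RunReport(
        run_id=plan.run_id,
        train_accuracy=history.train_accuracy[opt - 1],
        test_accuracy=cm.accuracy,
        confusion=cm,
        optimal_epoch=opt,
        history=history,
    )


def run_experiment(
    spec: synth.CohortSpec,
    config: Optional[ExperimentConfig] = None,
    seed: int = 0,
    volumes=None,
    manifest=None,
    verbose: bool = False,
):
    """The full dose-classification experiment on a (synthetic) cohort.

    Returns ``(reports, summary frame, averaged confusion matrix)``.
    Pre-processed volumes may be passed in to reuse a cohort across
    experiments.
    """
    config = config or ExperimentConfig()
    if volumes is None:
        volumes, manifest = process_cohort(spec, target_shape=config.cnn_shape)
    plans = dataset.make_splits(manifest, n_runs=config.n_runs, seed=seed)
    reports = [
        run_split(volumes, plan, config, seed, verbose=verbose) for plan in plans
    ]
    summary = evaluation.summarize_runs(reports)
    avg_cm = evaluation.average_matrices([r.confusion for r in reports])
    return reports, summary, avg_cm
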