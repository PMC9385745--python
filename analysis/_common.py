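"""Shared plumbing for the numbered analysis scripts."""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
sys.path.insert(0, str(ROOT / "src"))

SEED = 1
CNN_SHAPE = (32, 32, 32)
VOLUME_CACHE = SCRATCH / "processed_volumes.h5"


def default_spec():
    from svdose.synthetic_data import CohortSpec

    return CohortSpec(seed=SEED)


def experiment_config():
    from svdose import pipeline

    return pipeline.ExperimentConfig(cnn_shape=CNN_SHAPE, n_runs=5, epochs=10)


def load_or_process_volumes():
    """CNN-ready original volumes, cached in scratch/ between scripts."""
    from svdose import io as svio
    from svdose import pipeline
    from svdose.dataset import LabeledVolume
    from svdose.synthetic_data import cohort_manifest

    spec = default_spec()
    manifest = cohort_manifest(spec)
    if VOLUME_CACHE.exists():
        tensor = svio.read_dataset_h5(VOLUME_CACHE)
        volumes = [
            LabeledVolume(
                volume=tensor.samples[i, ..., 0],
                dose_class=p["dose_class"],
                mouse_id=p["mouse_id"],
                day=p["day"],
                augmentation=p["augmentation"],
            )
            for i, p in enumerate(tensor.provenance)
        ]
        if len(volumes) == len(manifest):
            return spec, volumes, manifest
    volumes, manifest = pipeline.process_cohort(spec, target_shape=CNN_SHAPE)
    return spec, volumes, manifest


def cache_volumes(volumes):
    from svdose import io as svio
    from svdose.dataset import assemble_tensor

    SCRATCH.mkdir(exist_ok=True)
    svio.write_dataset_h5(assemble_tensor(volumes), VOLUME_CACHE)
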