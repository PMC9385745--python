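#!/usr/bin/env python
"""Define the synthetic cohort and record its study conditions.

Writes the cohort specification (YAML), the volume manifest (CSV) and the
expected vascular-density trajectories per dose class (CSV).  The cohort
follows the published two-cohort layout: 5 mice per dose class imaged at
2-3 time points between days 14 and 32 post-irradiation, giving 13 low-dose
(10 Gy) and 14 high-dose (30 Gy) volumes.
"""

import pandas as pd

from _common import RESULTS, default_spec


def main():
    from svdose import io as svio
    from svdose.synthetic_data import cohort_manifest

    out = RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    spec = default_spec()
    svio.spec_to_yaml(spec, out / "cohort_spec.yaml")
    manifest = cohort_manifest(spec)
    manifest.to_csv(out / "manifest.csv", index=False)

    rows = [
        {"day": day, "dose_class": cls,
         "expected_density": spec.expected_density(cls, day)}
        for day in range(14, 33)
        for cls in ("low", "high")
    ]
    dens = pd.DataFrame(rows)
    dens.to_csv(out / "expected_densities.csv", index=False)

    counts = manifest.groupby("dose_class").size()
    print(f"cohort: {counts['low']} low-dose + {counts['high']} high-dose "
          f"volumes from {manifest['mouse_id'].nunique()} mice")
    ratio21 = (spec.expected_density("high", 21)
               / spec.expected_density("low", 21))
    print(f"high/low density ratio at day 21: {ratio21:.2f}")
    print(f"wrote {out}/cohort_spec.yaml, manifest.csv, expected_densities.csv")


if __name__ == "__main__":
    main()
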