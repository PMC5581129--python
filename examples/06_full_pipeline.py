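"""The whole pipeline on a synthetic three-patient study.

Materializes a study directory (per patient/time point: pre+post IR series,
masks, seed file, acquisition sidecar), then runs
fit -> NAWM-scale -> ΔqT1 -> segment -> pooled ROC -> overlap ->
transformation, exactly as `qt1map run-all` would from the shell.
"""

import json
import tempfile
from pathlib import Path

from qt1map import RunConfig, make_phantom_study, run_all

with tempfile.TemporaryDirectory() as td:
    manifest = make_phantom_study(Path(td) / "study", n_patients=3, base_seed=1)
    print(f"study written under {manifest.parent.name}/ (3 patients x 1 time point)")

    bundle = run_all(manifest, Path(td) / "out", config=RunConfig(rng_seed=1))

    roc = bundle["roc"]
    print(f"\npooled ROC over {roc['n_tumor']} tumor / {roc['n_surround']} surround voxels:")
    print(f"  optimal cutoff {roc['optimal_cutoff_ms']:.0f} ms, "
          f"sens {100 * roc['sensitivity']:.1f}%, spec {100 * roc['specificity']:.1f}%, "
          f"AUC {100 * roc['auc']:.1f}%")

    print("\nper-case overlap of the supra-cutoff area with the enhancing tumor:")
    for rep in bundle["overlap"]:
        print(f"  {rep['patient_id']}/{rep['timepoint_id']}: "
              f"{rep['overlap_percent']:.1f}% ({rep['overlap_class']})")

    print("\ncohort summary:")
    print(json.dumps(bundle["cohort_summary"], indent=2))
    print("\nA cutoff in (2000, 2100) ms with excellent overlap everywhere means the")
    print("pre-contrast surrogate found the same tumor the contrast gold standard did.")
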