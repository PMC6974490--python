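"""Run the entire pipeline on a graded-demyelination phantom.

One 6-mm lesion binds ~11% below white matter with a perilesional rim in
which binding recovers linearly over 8 mm; the pipeline should show DVR
falling monotonically from NAWM through the rings into the lesion.
"""

import json

import pandas as pd

from myelinpet import run_pipeline

cfg = {
    "seed": 1,
    "out_dir": "scratch/pipeline_demo",
    "phantom": {
        "grid_shape": [32, 32, 32],
        "noise_scale": 0.0,
        "lesions": [{
            "center_vox": [16.0, 16.0, 16.0], "radius_mm": 6.0,
            "bp_nd": 0.28, "core_bp_nd": 0.16, "rim_width_mm": 8.0,
            "t1_visible": True,
        }],
    },
    "n_control_scans": 1,
}
out = run_pipeline(cfg)
df = pd.read_csv(out / "roi_table.csv")
print(df[df.quantity == "DVR"][["roi", "mean", "n_voxels"]].to_string(index=False))
summary = json.loads((out / "roc_summary.json").read_text())
print(f"\nAUC DVR {summary['auc_dvr']:.3f}, AUC SUV {summary['auc_suv']:.3f}, "
      f"DeLong p {summary['delong_p']:.2g}")
print(f"all intermediates + provenance sidecars written to {out}/")
print("The DVR column should decrease monotonically: NAWM > outer ring > "
      "inner ring > outer lesion layer > inner lesion layer — the spatial "
      "demyelination gradient the method is designed to chart.")
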