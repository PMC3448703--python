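#!/usr/bin/env python
"""Count foci per nucleus in the simulated micrographs.

Runs the full pipeline (preset enhancement, nucleus segmentation + QC,
LoG spot detection, in-nucleus enumeration) on the images written by
01_simulate_images.py and summarizes counted foci/cell per stress level —
the cytocentrifugation dose-response in pipeline units.
"""

from pathlib import Path

import pandas as pd

from fociquant.focus_quant import per_cell_table, quantify_image, segment_nuclei
from fociquant.image_model import read_image

IN = Path("scratch/analysis/images")
RESULTS = Path("results")

if not IN.exists():
    raise SystemExit("run analysis/01_simulate_images.py first")

all_records = []
nuclei_by_image = {}
level_of = {}
for tif in sorted(IN.rglob("*.tif")):
    img = read_image(tif)
    image_id = f"{tif.parent.name}/{tif.stem}"
    recs = quantify_image(img, image_id=image_id)
    nuclei_by_image[image_id] = segment_nuclei(img.dapi)
    level_of[image_id] = float(tif.parent.name.split("_")[1])
    all_records.extend(recs)

table = per_cell_table(all_records, nuclei_by_image)
table["stress"] = table["image_id"].map(level_of)
RESULTS.mkdir(exist_ok=True)
table.to_csv(RESULTS / "per_cell_counts.csv", index=False)

summary = table.groupby("stress")["foci_count"].agg(["mean", "sem", "count"])
summary.to_csv(RESULTS / "stress_response.csv")
print("counted foci/cell (QC-passing nuclei) by stress level:")
print(summary.round(3).to_string())
print("\ncounted damage increases monotonically with the spin-stress knob:",
      bool(summary["mean"].is_monotonic_increasing))
print(f"wrote {RESULTS / 'per_cell_counts.csv'} and "
      f"{RESULTS / 'stress_response.csv'}")
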