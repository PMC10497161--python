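"""Generate a synthetic two-channel micrograph, run the full pipeline,
and print the resulting per-cell table.

The scene plants 8 rod-shaped cells with bright-field halos and nuclear
fluorescence; the pipeline should recover every interior cell, so the CSV
has one row per planted cell with its length/width/area (pixels, since no
calibration is embedded) and nuclear/whole-cell mean intensities.
"""

import tempfile
from pathlib import Path

import pandas as pd

import halocell as hc

spec = hc.SceneSpec(n_cells=8, image_size=(700, 700), seed=11)
image, truth = hc.generate_scene(spec)

with tempfile.TemporaryDirectory() as tmp:
    tif = Path(tmp) / "scene.tif"
    hc.write_tiff(image, tif)
    summary = hc.run_pipeline(hc.RunOptions(input_path=tif, output_dir=tmp))
    df = pd.read_csv(summary.csv_path)

print(f"planted {len(truth.interior_cells)} cells, "
      f"recovered {summary.n_cells} rows, {df.shape[1]} columns")
print(df[["1: Cell Index", "1: Cell Length", "1: Cell Area",
          "2/2: Mean Nuc Int", "2/1: Whole Cell Int-bg"]].to_string(index=False))
print("\nLengths/areas are in pixels (no calibration tag in the TIFF); "
      "nuclear means sit near the planted 2000 counts, and the whole-cell "
      "column is background-subtracted using the channel's modal intensity.")
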