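"""Build a small phantom-defect corpus and inspect its structure.

Generates 4 skull phantoms with 21 carved defects each (3 per anatomical
region, complexity tiers 9/7/5), writes NIfTI volumes and a manifest, and
prints the count tables.  At full scale (125 skulls) the same call emits
2625 defects: 375 per region, 1125 simple / 875 moderate / 625 complex,
and a 100/25 skull-level train/test split.
"""

import tempfile
from pathlib import Path

from sufseg import build_dataset

with tempfile.TemporaryDirectory() as tmp:
    manifest = build_dataset(
        n_skulls=4,
        out_dir=Path(tmp) / "corpus",
        defects_per_skull=21,
        region_counts=(3,) * 7,
        complexity_counts_per_skull=(9, 7, 5),
        test_fraction_of_skulls=0.25,
        seed=1,
        grid_shape=(32, 32, 32),
        spacing_mm=1.0,
    )
    df = manifest.to_frame()
    print(f"records: {len(df)} (expect 4 x 21 = 84)")
    print("\nper region (expect 12 each):")
    print(df["region"].value_counts().to_string())
    print("\nper complexity (expect 36/28/20):")
    print(df["complexity"].value_counts().to_string())
    print("\nsplit by skull:")
    print(df.groupby("split")["skull_id"].nunique().to_string())
    print("\ndefect sizes stay inside the 15-45 mm envelope:")
    print(df["max_diameter_mm"].describe()[["min", "mean", "max"]].to_string())
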