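"""Corpus assembly: many skulls, many defects, a manifest, a skull-level split.

Emulated corpus structure: each skull receives ``defects_per_skull`` defects
split as ``region_counts`` over the seven regions and
``complexity_counts_per_skull`` over the three complexity tiers (defaults
3 per region and 9/7/5, i.e. 21 per skull; 125 skulls then give 2625 defects,
1125/875/625 per tier and 375 per region).  The train/test split is by skull,
never by defect; because every skull has an identical region/complexity
composition, any by-skull split is exactly stratified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import (
    COMPLEXITIES,
    LATERALITIES,
    REGIONS,
    SIZE_RANGE_MM,
    carve_defect,
    generate_skull_phantom,
)
from .volume import Volume, save_nifti

__all__ = ["DefectRecord", "DatasetManifest", "build_dataset", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = [
    "skull_id",
    "defect_id",
    "region",
    "laterality",
    "complexity",
    "max_diameter_mm",
    "volume_mm3",
    "split",
    "defective_path",
    "mask_path",
]


@dataclass
class DefectRecord:
    """One simulated defect and its file locations."""

    skull_id: str
    defect_id: str
    region: str
    laterality: str
    complexity: str
    max_diameter_mm: float
    volume_mm3: float
    split: str
    defective_path: str
    mask_path: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if self.complexity not in COMPLEXITIES:
            raise ValueError(f"unknown complexity {self.complexity!r}")
        lo, hi = SIZE_RANGE_MM
        if not (lo <= self.max_diameter_mm <= hi):
            raise ValueError(
                f"max_diameter_mm {self.max_diameter_mm:.2f} outside [{lo}, {hi}]"
            )


@dataclass
class DatasetManifest:
    """Ordered defect records plus the skull-level train/test split."""

    records: list[DefectRecord]
    split: dict[str, str]
    root: Path | None = None
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=MANIFEST_COLUMNS)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        records = [DefectRecord(**row) for row in df.to_dict("records")]
        split = {r.skull_id: r.split for r in records}
        return cls(records=records, split=split, root=path.parent)

    def subset(self, split: str) -> list[DefectRecord]:
        return [r for r in self.records if r.split == split]

    def validate(self, defects_per_skull: int | None = None) -> None:
        """Check structural invariants (per-skull counts, split by skull)."""
        df = self.to_frame()
        per_skull = df.groupby("skull_id").size()
        if defects_per_skull is not None and not (per_skull == defects_per_skull).all():
            raise ValueError("per-skull defect counts are inconsistent with the request")
        splits_per_skull = df.groupby("skull_id")["split"].nunique()
        if not (splits_per_skull == 1).all():
            raise ValueError("split must be by skull: a skull appears in both sets")


def _derived_seed(ss: np.random.SeedSequence, *keys: int) -> int:
    """Stable per-item integer seed (< 2^31) derived from a seed sequence."""
    child = np.random.SeedSequence(list(ss.entropy if isinstance(ss.entropy, list) else [ss.entropy]) + list(keys))
    return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def build_dataset(
    n_skulls: int,
    out_dir: str | Path,
    defects_per_skull: int = 21,
    region_counts: tuple[int, ...] = (3, 3, 3, 3, 3, 3, 3),
    complexity_counts_per_skull: tuple[int, int, int] = (9, 7, 5),
    test_fraction_of_skulls: float = 0.2,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing_mm: float = 1.0,
    write_volumes: bool = True,
) -> DatasetManifest:
    """Generate phantoms, carve defects, write NIfTI volumes and a manifest.

    Parameters mirror the emulated corpus: with the defaults and
    ``n_skulls=125, test_fraction_of_skulls=0.2`` the output has 2625
    records, 525 of them in the test split, 1125 simple defects and 375
    defects per region.

    ``write_volumes=False`` keeps everything in memory (``meta["volumes"]``
    maps record ids to ``(defective, mask)`` Volume pairs) — used by the
    in-process training pipeline and fast structural checks.
    """
    region_counts = tuple(int(c) for c in region_counts)
    complexity_counts = tuple(int(c) for c in complexity_counts_per_skull)
    if len(region_counts) != 7:
        raise ValueError("region_counts must have 7 components")
    if sum(complexity_counts) != defects_per_skull:
        raise ValueError(
            f"complexity counts {complexity_counts} must sum to defects_per_skull={defects_per_skull}"
        )
    if sum(region_counts) != defects_per_skull:
        raise ValueError(
            f"region counts sum {sum(region_counts)} != defects_per_skull={defects_per_skull}"
        )
    if n_skulls < 1:
        raise ValueError("n_skulls must be >= 1")
    if not (0 <= test_fraction_of_skulls < 1):
        raise ValueError("test_fraction_of_skulls must lie in [0, 1)")

    out_dir = Path(out_dir)
    ss = np.random.SeedSequence([int(seed), 0xDA7A5E7])
    rng = np.random.default_rng(ss)

    n_test = int(round(n_skulls * test_fraction_of_skulls))
    skull_ids = [f"skull{idx:03d}" for idx in range(n_skulls)]
    order = rng.permutation(n_skulls)
    test_set = {skull_ids[i] for i in order[:n_test]}
    split = {sid: ("test" if sid in test_set else "train") for sid in skull_ids}

    extent = min(grid_shape) * spacing_mm
    lo, hi = SIZE_RANGE_MM
    d_hi = max(lo + 1e-6, min(hi, 0.6 * extent))

    records: list[DefectRecord] = []
    volumes: dict[str, tuple[Volume, Volume]] = {}
    for si, sid in enumerate(skull_ids):
        skull = generate_skull_phantom(_derived_seed(ss, 1, si), grid_shape, spacing_mm)
        srng = np.random.default_rng(np.random.SeedSequence([int(seed), 2, si]))

        slots = []  # (region, laterality, complexity) per defect
        regions = [r for r, c in zip(REGIONS, region_counts) for _ in range(c)]
        lats = [LATERALITIES[(k + si) % 3] for k in range(defects_per_skull)]
        comps = [c for c, n in zip(COMPLEXITIES, complexity_counts) for _ in range(n)]
        comps = [comps[k] for k in srng.permutation(defects_per_skull)]
        slots = list(zip(regions, lats, comps))

        for di, (region, lat, comp) in enumerate(slots):
            did = f"{sid}_d{di:02d}"
            target = float(srng.uniform(lo, d_hi))
            defective, mask = carve_defect(
                skull, region, lat, comp, target, seed=_derived_seed(ss, 3, si, di)
            )
            if write_volumes:
                dpath = out_dir / "volumes" / f"{did}_defective.nii.gz"
                mpath = out_dir / "volumes" / f"{did}_mask.nii.gz"
                save_nifti(defective, dpath)
                save_nifti(mask, mpath)
                dstr, mstr = str(dpath), str(mpath)
            else:
                dstr, mstr = f"mem://{did}/defective", f"mem://{did}/mask"
                volumes[did] = (defective, mask)
            records.append(
                DefectRecord(
                    skull_id=sid,
                    defect_id=did,
                    region=region,
                    laterality=lat,
                    complexity=comp,
                    max_diameter_mm=float(mask.meta["max_diameter_mm"]),
                    volume_mm3=float(mask.meta["volume_mm3"]),
                    split=split[sid],
                    defective_path=dstr,
                    mask_path=mstr,
                )
            )

    manifest = DatasetManifest(
        records=records,
        split=split,
        root=out_dir,
        grid_shape=tuple(grid_shape),
        spacing_mm=spacing_mm,
    )
    if not write_volumes:
        manifest.meta["volumes"] = volumes
    manifest.validate(defects_per_skull=defects_per_skull)
    if write_volumes:
        manifest.save(out_dir / "manifest.tsv")
    return manifest
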