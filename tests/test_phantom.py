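"""Skull phantom geometry and defect carving."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sufseg import (
    COMPLEXITIES,
    LATERALITIES,
    PlacementError,
    REGIONS,
    Volume,
    carve_defect,
    deformed_sphere_mask,
    generate_skull_phantom,
)
from sufseg.phantom import mask_max_extent_mm


class TestSkullPhantom:
    def test_binary_closed_shell_with_all_zones(self, phantom32):
        assert phantom32.is_binary()
        assert phantom32.data.sum() > 0
        zones = phantom32.meta["zones"]
        for zid, name in enumerate(REGIONS, start=1):
            assert (zones == zid).sum() > 0, f"zone {name} empty"
        # zones label only bone voxels
        assert not np.any((zones > 0) & (phantom32.data == 0))

    def test_deterministic_for_fixed_seed(self):
        a = generate_skull_phantom(1, (32, 32, 32), 1.0)
        b = generate_skull_phantom(1, (32, 32, 32), 1.0)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.meta["zones"], b.meta["zones"])

    def test_seed_changes_phantom(self):
        a = generate_skull_phantom(1, (32, 32, 32), 1.0)
        b = generate_skull_phantom(2, (32, 32, 32), 1.0)
        assert np.any(a.data != b.data)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_skull_phantom(1, (8, 8, 8), 1.0)

    def test_zones_populated_on_both_sides_of_midline(self, phantom32):
        zones = phantom32.meta["zones"]
        mid = (phantom32.shape[1] - 1) / 2
        for zid in range(1, 8):
            xs = np.argwhere(zones == zid)[:, 1]
            assert (xs < mid).any() and (xs > mid).any()


class TestDeformedSphere:
    def test_exact_sphere_volume_oracle(self):
        # r = 5 mm at 0.5 mm spacing: (4/3)*pi*10^3 ~ 4189 voxels, within 10%
        grid = Volume(np.zeros((48, 48, 48), np.uint8), (0.5, 0.5, 0.5))
        m = deformed_sphere_mask((24, 24, 24), 5.0, 0.0, 0, seed=1, grid=grid)
        analytic = 4.0 / 3.0 * np.pi * 10**3
        assert abs(m.data.sum() - analytic) / analytic < 0.10

    def test_deterministic_and_seed_sensitive(self):
        grid = Volume(np.zeros((32, 32, 32), np.uint8), (1.0, 1.0, 1.0))
        a = deformed_sphere_mask((16, 16, 16), 6.0, 0.3, 3, seed=1, grid=grid)
        b = deformed_sphere_mask((16, 16, 16), 6.0, 0.3, 3, seed=1, grid=grid)
        c = deformed_sphere_mask((16, 16, 16), 6.0, 0.3, 3, seed=2, grid=grid)
        assert np.array_equal(a.data, b.data)
        assert np.any(a.data != c.data)

    def test_center_outside_grid_rejected(self):
        grid = Volume(np.zeros((16, 16, 16), np.uint8), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            deformed_sphere_mask((20, 8, 8), 3.0, 0.0, 0, seed=1, grid=grid)

    def test_zero_amplitude_is_exact_sphere(self):
        grid = Volume(np.zeros((24, 24, 24), np.uint8), (1.0, 1.0, 1.0))
        m = deformed_sphere_mask((12, 12, 12), 5.0, 0.0, 4, seed=9, grid=grid)
        ii, jj, kk = np.mgrid[0:24, 0:24, 0:24]
        ref = ((ii - 12) ** 2 + (jj - 12) ** 2 + (kk - 12) ** 2) <= 25.0
        assert np.array_equal(m.data.astype(bool), ref)


class TestCarveDefect:
    @pytest.mark.parametrize("laterality", LATERALITIES)
    @pytest.mark.parametrize("complexity", COMPLEXITIES)
    def test_partition_and_laterality(self, phantom32, laterality, complexity):
        defective, mask = carve_defect(
            phantom32, "anterior-skull-and-forehead", laterality, complexity, 17.0, seed=11
        )
        skull = phantom32.data.astype(bool)
        d, m = defective.data.astype(bool), mask.data.astype(bool)
        assert np.array_equal(d | m, skull)
        assert not (d & m).any()
        mid = (phantom32.shape[1] - 1) / 2
        xs = np.argwhere(m)[:, 1]
        if laterality == "left":
            assert not (xs > mid).any()
        elif laterality == "right":
            assert not (xs < mid).any()
        else:
            assert (xs < mid).any() and (xs > mid).any()

    def test_size_envelope(self, phantom32):
        _, mask = carve_defect(phantom32, "mandibular-body", "left", "simple", 20.0, seed=3)
        extent = mask_max_extent_mm(mask.data, mask.spacing)
        assert 15.0 <= extent <= 45.0
        assert mask.meta["max_diameter_mm"] == pytest.approx(extent)

    def test_missing_zone_raises_placement_error(self):
        bare = Volume(np.ones((20, 20, 20), np.uint8), (1.0, 1.0, 1.0))
        bare.meta["zones"] = np.zeros((20, 20, 20), np.uint8)
        with pytest.raises(PlacementError):
            carve_defect(bare, "NOE", "left", "simple", 17.0, seed=1)

    def test_deterministic(self, phantom32):
        a = carve_defect(phantom32, "zygomatic-arch", "right", "complex", 16.0, seed=5)
        b = carve_defect(phantom32, "zygomatic-arch", "right", "complex", 16.0, seed=5)
        assert np.array_equal(a[1].data, b[1].data)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        region=st.sampled_from(REGIONS),
        laterality=st.sampled_from(LATERALITIES),
        complexity=st.sampled_from(COMPLEXITIES),
        seed=st.integers(0, 10_000),
    )
    def test_invariants_hold_for_random_defects(self, phantom32, region, laterality, complexity, seed):
        defective, mask = carve_defect(phantom32, region, laterality, complexity, 17.0, seed=seed)
        skull = phantom32.data.astype(bool)
        d, m = defective.data.astype(bool), mask.data.astype(bool)
        assert np.array_equal(d | m, skull) and not (d & m).any()
        assert 15.0 <= mask.meta["max_diameter_mm"] <= 45.0


def test_max_extent_matches_brute_force(rng):
    mask = rng.random((6, 6, 6)) > 0.7
    if not mask.any():
        mask[2, 3, 1] = True
    spacing = (1.0, 2.0, 0.5)
    pts = np.argwhere(mask) * np.asarray(spacing)
    brute = max(
        (np.linalg.norm(p - q) for p in pts for q in pts), default=0.0
    )
    assert mask_max_extent_mm(mask, spacing) == pytest.approx(brute)
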