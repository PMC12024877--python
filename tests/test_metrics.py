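"""Losses and evaluation metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sufseg import (
    bce_loss,
    compound_loss,
    dice_loss,
    dsc,
    evaluate_dataset,
    hd95,
    mse_loss,
    recall,
    tversky_loss,
)
from sufseg.metrics import surface_voxels


# ---------------------------------------------------------------- oracles
def brute_surface(mask):
    """Surface = mask voxel with >= 1 background face-neighbour (loops)."""
    out = np.zeros_like(mask, dtype=bool)
    D, H, W = mask.shape
    for i in range(D):
        for j in range(H):
            for k in range(W):
                if not mask[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ni, nj, nk = i + di, j + dj, k + dk
                    if not (0 <= ni < D and 0 <= nj < H and 0 <= nk < W) or not mask[ni, nj, nk]:
                        out[i, j, k] = True
                        break
    return out


def brute_hd95(P, G, spacing):
    sp = np.argwhere(brute_surface(P)) * np.asarray(spacing)
    sg = np.argwhere(brute_surface(G)) * np.asarray(spacing)
    d_pg = [min(np.linalg.norm(p - q) for q in sg) for p in sp]
    d_gp = [min(np.linalg.norm(q - p) for p in sp) for q in sg]
    return float(np.percentile(np.array(d_pg + d_gp), 95, method="linear"))


def random_nonempty_mask(rng, p=0.3, shape=(6, 6, 6)):
    m = rng.random(shape) < p
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


# ---------------------------------------------------------------- losses
class TestLosses:
    def test_perfect_prediction(self, rng):
        t = (rng.random((2, 4, 4, 4)) > 0.5).astype(float)
        assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-5)
        assert mse_loss(t, t) == 0.0
        assert bce_loss(t, t) == pytest.approx(0.0, abs=1e-5)

    def test_total_miss(self):
        t = np.zeros((2, 3, 3, 3))
        t[:, :2] = 1.0
        p = 1.0 - t
        assert dice_loss(p, t) == pytest.approx(1.0, abs=1e-5)
        assert mse_loss(p, t) == 1.0

    def test_mse_hand_value(self):
        # pred 0.5 everywhere vs half-ones target: mse = 0.25 exactly
        t = np.zeros((2, 2, 2))
        t[0] = 1.0
        assert mse_loss(np.full_like(t, 0.5), t) == 0.25

    def test_compound_is_sum_and_dominates_terms(self, rng):
        p = rng.random((3, 3, 3))
        t = (rng.random((3, 3, 3)) > 0.5).astype(float)
        total = compound_loss(p, t)
        parts = (dice_loss(p, t), bce_loss(p, t), mse_loss(p, t))
        assert total == pytest.approx(sum(parts))
        assert all(total >= x for x in parts)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.empty(0), np.empty(0))


class TestTversky:
    def test_half_half_is_dice(self, rng):
        for _ in range(5):
            p = rng.random((4, 4, 4))
            t = (rng.random((4, 4, 4)) > 0.6).astype(float)
            assert tversky_loss(p, t, 0.5, 0.5) == pytest.approx(dice_loss(p, t), abs=1e-6)

    def test_perfect_prediction(self, rng):
        t = (rng.random((4, 4, 4)) > 0.5).astype(float)
        assert tversky_loss(t, t) == pytest.approx(0.0, abs=1e-4)

    def test_fn_cheaper_than_fp_at_published_weights(self):
        # alpha=0.7 (FP) > beta=0.3 (FN): equal-mass FP hurts more than FN
        t = np.zeros((2, 2, 2))
        t[0] = 1.0
        base = np.where(t > 0, 1.0, 0.0)
        with_fn = base.copy()
        with_fn[0, 0, 0] = 0.6  # 0.4 soft false negative
        with_fp = base.copy()
        with_fp[1, 0, 0] = 0.4  # 0.4 soft false positive
        assert tversky_loss(with_fp, t, 0.7, 0.3) > tversky_loss(with_fn, t, 0.7, 0.3)

    def test_monotone_in_alpha_with_false_positives(self, rng):
        p = rng.random((3, 3, 3))
        t = (rng.random((3, 3, 3)) > 0.5).astype(float)
        losses = [tversky_loss(p, t, a, 0.3) for a in (0.3, 0.5, 0.7, 0.9)]
        assert all(l2 >= l1 for l1, l2 in zip(losses, losses[1:]))


# ---------------------------------------------------------------- metrics
class TestDiceRecall:
    def test_identity_disjoint_and_hand_counts(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2, 0, 0] = True
        assert dsc(a, a) == 1.0
        b = np.zeros_like(a)
        b[3, 3, :2] = True
        assert dsc(a, b) == 0.0
        # |P|=4, |G|=4, overlap 2 -> 0.5
        P = np.zeros((4, 4, 4), bool)
        G = np.zeros_like(P)
        P[0, 0, :4] = True
        G[0, 0, 2:] = True
        G[0, 1, :2] = True
        assert dsc(P, G) == 0.5
        assert dsc(np.zeros_like(P), np.zeros_like(P)) == 1.0

    def test_recall_hand_counts_and_conventions(self):
        G = np.zeros((3, 3, 3), bool)
        G[0, 0, :] = True
        G[1, 0, 0] = True  # |G| = 4
        P = G.copy()
        P[1, 0, 0] = False  # TP=3, FN=1
        assert recall(P, G) == 0.75
        assert recall(np.ones_like(G), G) == 1.0
        assert recall(np.zeros_like(G), G) == 0.0
        assert np.isnan(recall(P, np.zeros_like(G)))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2000))
    def test_against_voxel_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P, G = random_nonempty_mask(rng), random_nonempty_mask(rng)
        tp = int(np.sum(P & G))
        assert dsc(P, G) == pytest.approx(2 * tp / (P.sum() + G.sum()))
        assert dsc(P, G) == dsc(G, P)
        assert recall(P, G) == pytest.approx(tp / G.sum())


class TestHD95:
    def test_identity_zero(self, rng):
        m = random_nonempty_mask(rng)
        assert hd95(m, m, (1.0, 1.0, 1.0)) == 0.0

    def test_two_point_hand_value(self):
        # single voxels 4 steps apart on one axis at 0.5 mm -> 2.0 mm
        P = np.zeros((8, 8, 8), bool)
        G = np.zeros_like(P)
        P[2, 3, 3] = True
        G[6, 3, 3] = True
        assert hd95(P, G, (0.5, 0.5, 0.5)) == pytest.approx(2.0)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_against_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P, G = random_nonempty_mask(rng), random_nonempty_mask(rng)
        spacing = (1.0, 0.5, 2.0)
        assert hd95(P, G, spacing) == pytest.approx(brute_hd95(P, G, spacing), abs=1e-9)
        assert hd95(P, G, spacing) == pytest.approx(hd95(G, P, spacing))

    def test_scales_linearly_with_spacing(self, rng):
        P, G = random_nonempty_mask(rng), random_nonempty_mask(rng)
        a = hd95(P, G, (1.0, 1.0, 1.0))
        b = hd95(P, G, (2.0, 2.0, 2.0))
        assert b == pytest.approx(2 * a)

    def test_empty_conventions(self):
        z = np.zeros((3, 3, 3), bool)
        o = z.copy()
        o[1, 1, 1] = True
        assert hd95(z, z) == 0.0
        assert np.isnan(hd95(o, z))

    def test_surface_extraction_matches_bruteforce(self, rng):
        m = random_nonempty_mask(rng, p=0.5)
        assert np.array_equal(surface_voxels(m), brute_surface(m))


class TestEvaluateDataset:
    def test_perfect_predictions_and_aggregates(self, micro_manifest):
        mem = micro_manifest.meta["volumes"]
        preds = {
            r.defect_id: mem[r.defect_id][1].data.astype(bool)
            for r in micro_manifest.subset("test")
        }
        rep = evaluate_dataset(preds, micro_manifest)
        assert rep.overall["DSC"] == 1.0
        assert rep.overall["RECALL"] == 1.0
        assert rep.overall["HD95"] == 0.0
        assert len(rep.per_region) == 7

    def test_two_record_mean_is_hand_average(self, micro_manifest):
        mem = micro_manifest.meta["volumes"]
        recs = micro_manifest.subset("test")[:2]
        preds, per = {}, []
        for i, r in enumerate(recs):
            gt = mem[r.defect_id][1].data.astype(bool)
            p = gt.copy()
            if i == 1:  # degrade one prediction
                idx = np.argwhere(p)
                p[tuple(idx[0])] = False
            preds[r.defect_id] = p
            per.append(dsc(p, gt))
        rep = evaluate_dataset(preds, micro_manifest, allow_missing=True)
        assert rep.overall["DSC"] == pytest.approx(np.mean(per))

    def test_missing_prediction_fails_unless_allowed(self, micro_manifest):
        with pytest.raises(ValueError):
            evaluate_dataset({}, micro_manifest)
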