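"""Step-uncertainty fusion: hand oracles, loop-literal oracle, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sufseg import (
    StepPrediction,
    entropy_uncertainty,
    fuse_weighted,
    softmax_fusion_weights,
    step_sigmoid_weights,
    sufuse,
    variance_uncertainty,
)


def loop_literal_fusion(passes_per_step, lam):
    """Literal per-voxel reimplementation of the variance/softmax scheme.

    Independent oracle: explicit Python loops over voxels and steps, no
    vectorized reuse of the implementation under test.
    """
    K = len(passes_per_step)
    shape = passes_per_step[0].shape[1:]
    fused = np.zeros(shape)
    for idx in np.ndindex(*shape):
        u = []
        pbar = []
        for t in range(K):
            vals = [passes_per_step[t][(m,) + idx] for m in range(passes_per_step[t].shape[0])]
            mean = sum(vals) / len(vals)
            u.append(sum((v - mean) ** 2 for v in vals) / len(vals))
            pbar.append(mean)
        ws = [math.exp(-lam * ut) for ut in u]
        z = sum(ws)
        fused[idx] = sum(w / z * p for w, p in zip(ws, pbar))
    return fused


class TestVarianceUncertainty:
    def test_identical_passes_zero(self):
        p = np.tile(np.random.default_rng(0).random((1, 3, 3)), (5, 1, 1))
        assert np.all(variance_uncertainty(p) == 0)

    def test_two_pass_hand_value(self):
        # values 0.4 / 0.6: mean 0.5, population variance 0.01
        p = np.array([[[0.4]], [[0.6]]])
        assert variance_uncertainty(p)[0, 0] == pytest.approx(0.01)

    def test_matches_bruteforce_on_outlier_pattern(self):
        vals = np.full(10, 0.3)
        vals[7] = 0.9
        brute = np.mean((vals - vals.mean()) ** 2)
        assert variance_uncertainty(vals.reshape(10, 1))[0] == pytest.approx(brute)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            variance_uncertainty(np.empty((0, 2, 2)))


class TestEntropyUncertainty:
    def test_certainty_and_zero_convention(self):
        u = entropy_uncertainty(np.array([0.0, 1.0]))
        assert np.all(u == 0)

    def test_maximum_at_one_over_e(self):
        assert entropy_uncertainty(np.array([1 / math.e]))[0] == pytest.approx(1 / math.e)
        # numerical check of the maximizer on a dense grid
        p = np.linspace(0, 1, 20001)
        u = entropy_uncertainty(p)
        assert abs(p[np.argmax(u)] - 1 / math.e) < 1e-3
        assert u.max() <= 1 / math.e + 1e-12

    def test_concavity_on_dense_grid(self):
        p = np.linspace(0, 1, 2001)
        u = entropy_uncertainty(p)
        assert np.all(np.diff(u, 2) <= 1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            entropy_uncertainty(np.array([1.2]))


class TestWeights:
    def test_equal_uncertainty_uniform(self):
        u = np.ones((5, 2, 2))
        w = softmax_fusion_weights(u, lam=5.0)
        assert np.allclose(w, 0.2)

    def test_zero_temperature_uniform(self):
        u = np.random.default_rng(0).random((4, 3, 3))
        assert np.allclose(softmax_fusion_weights(u, 0.0), 0.25)

    def test_two_step_hand_value(self):
        # u = (0, ln 4), lam=1: weights (0.8, 0.2)
        u = np.array([[0.0], [np.log(4.0)]])
        w = softmax_fusion_weights(u, 1.0)
        assert np.allclose(w[:, 0], [0.8, 0.2])

    def test_weights_sum_to_one_and_monotone_in_u(self):
        rng = np.random.default_rng(3)
        u = rng.random((5, 2, 2, 2))
        w = softmax_fusion_weights(u, 5.0)
        assert np.allclose(w.sum(axis=0), 1.0)
        u2 = u.copy()
        u2[2, 1, 1, 1] += 0.3  # raising one step's uncertainty lowers its weight
        w2 = softmax_fusion_weights(u2, 5.0)
        assert w2[2, 1, 1, 1] < w[2, 1, 1, 1]

    def test_step_sigmoid_hand_values(self):
        # i/scale = 0 is unreachable for i>=1, so check via large scale limit
        # and the documented algebra at sigmoid(0) = 0.5: w = e^{0.5}*(1-u)
        w = step_sigmoid_weights(0, scale=3.0, u=np.array([0.0]))
        assert w[0] == pytest.approx(math.exp(0.5))
        assert step_sigmoid_weights(2, 3.0, np.array([1.0]))[0] == 0.0
        # monotone in the step index at equal uncertainty
        u = np.array([0.3])
        assert step_sigmoid_weights(4, 3.0, u)[0] > step_sigmoid_weights(1, 3.0, u)[0]

    def test_step_sigmoid_preconditions(self):
        with pytest.raises(ValueError):
            step_sigmoid_weights(1, 0.0, np.array([0.5]))
        with pytest.raises(ValueError):
            step_sigmoid_weights(1, 1.0, np.array([1.5]))


class TestFuseWeighted:
    def test_identity_uniform_and_hand_case(self):
        m = np.random.default_rng(0).random((1, 2, 2))
        assert np.allclose(fuse_weighted(m, np.ones_like(m)), m[0])
        means = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 0.0)])
        weights = np.stack([np.full((2, 2), 0.8), np.full((2, 2), 0.2)])
        assert np.allclose(fuse_weighted(means, weights), 0.8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_weighted(np.zeros((2, 3)), np.zeros((3, 3)))


class TestSufuse:
    def _trajectory(self, rng, K=5, S=10, shape=(4, 4, 4)):
        return [
            StepPrediction(step_index=i + 1, passes=rng.random((S,) + shape))
            for i in range(K)
        ]

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), K=st.integers(1, 5), S=st.integers(1, 10))
    def test_matches_loop_literal_oracle(self, seed, K, S):
        rng = np.random.default_rng(seed)
        traj = self._trajectory(rng, K=K, S=S, shape=(3, 2, 2))
        res = sufuse(traj, variant="softmax", lam=5.0)
        oracle = loop_literal_fusion([sp.passes for sp in traj], lam=5.0)
        assert np.allclose(res.fused, oracle, atol=1e-6)

    def test_softmax_equals_composition_of_primitives(self):
        rng = np.random.default_rng(11)
        traj = self._trajectory(rng)
        res = sufuse(traj, variant="softmax", lam=5.0)
        u = np.stack([variance_uncertainty(sp.passes) for sp in traj])
        w = softmax_fusion_weights(u, 5.0)
        direct = fuse_weighted(np.stack([sp.mean_map for sp in traj]), w)
        assert np.allclose(res.fused, direct)

    @pytest.mark.parametrize("variant", ["softmax", "step-sigmoid"])
    def test_duplicated_steps_reduce_to_single_mean(self, variant):
        rng = np.random.default_rng(4)
        passes = rng.random((6, 3, 3, 3))
        traj = [StepPrediction(i + 1, passes.copy()) for i in range(4)]
        res = sufuse(traj, variant=variant, normalize=True)
        assert np.allclose(res.fused, passes.mean(axis=0), atol=1e-12)

    @pytest.mark.parametrize("variant", ["softmax", "step-sigmoid"])
    def test_single_step_identity(self, variant):
        rng = np.random.default_rng(5)
        traj = self._trajectory(rng, K=1, S=4)
        res = sufuse(traj, variant=variant, normalize=True)
        assert np.allclose(res.fused, traj[0].mean_map)

    def test_step_sigmoid_unnormalized_literal_form(self):
        rng = np.random.default_rng(6)
        traj = self._trajectory(rng, K=3, S=5)
        res = sufuse(traj, variant="step-sigmoid", scale=3.0, normalize=False)
        acc = np.zeros(traj[0].mean_map.shape)
        for i, sp in enumerate(traj, start=1):
            u = entropy_uncertainty(sp.mean_map)
            acc += step_sigmoid_weights(i, 3.0, u) * sp.mean_map
        assert np.allclose(res.fused, acc)

    def test_fused_bounded_by_step_mean_envelope(self):
        rng = np.random.default_rng(8)
        traj = self._trajectory(rng, K=4, S=3)
        res = sufuse(traj, variant="softmax")
        means = np.stack([sp.mean_map for sp in traj])
        assert np.all(res.fused <= means.max(axis=0) + 1e-12)
        assert np.all(res.fused >= means.min(axis=0) - 1e-12)

    def test_unknown_variant_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            sufuse(self._trajectory(rng, K=2), variant="mystery")
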