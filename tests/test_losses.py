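import itertools

import numpy as np
import pytest

from nerveseg.losses import (
    LossConfig,
    compound_loss,
    compound_loss_grad,
    critical_voxel_map,
    cross_entropy,
    dice_loss,
    one_hot,
    softmax,
    topology_loss,
)


def brute_force_critical_map(labels: np.ndarray) -> np.ndarray:
    """O(n * 26) scan flagging every 26-adjacent fascicle/background pair."""
    out = np.zeros(labels.shape, dtype=bool)
    nz, ny, nx = labels.shape
    for z, y, x in itertools.product(range(nz), range(ny), range(nx)):
        if labels[z, y, x] != 1:
            continue
        for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3):
            if dz == dy == dx == 0:
                continue
            z2, y2, x2 = z + dz, y + dy, x + dx
            if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx:
                if labels[z2, y2, x2] == 0:
                    out[z, y, x] = True
                    out[z2, y2, x2] = True
    return out


class TestCriticalVoxelMap:
    def test_wrapped_fascicle_cube_is_compliant(self):
        # fascicle core, 1-voxel epineurium shell, background outside
        labels = np.zeros((7, 7, 7), dtype=np.uint8)
        labels[1:6, 1:6, 1:6] = 2
        labels[2:5, 2:5, 2:5] = 1
        assert not critical_voxel_map(labels).any()

    def test_diagonal_contact_flags_both_voxels(self):
        labels = np.full((3, 3, 3), 2, dtype=np.uint8)
        labels[1, 1, 1] = 1
        labels[0, 0, 0] = 0  # diagonal (26-) neighbor of the fascicle voxel
        v = critical_voxel_map(labels)
        assert v[1, 1, 1] and v[0, 0, 0]
        assert v.sum() == 2

    def test_no_fascicle_means_empty_map(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[1:3] = 2
        assert not critical_voxel_map(labels).any()

    def test_fascicle_epineurium_contact_allowed(self):
        labels = np.full((3, 3, 3), 2, dtype=np.uint8)
        labels[1, 1, 1] = 1
        assert not critical_voxel_map(labels).any()

    def test_matches_brute_force_on_random_volumes(self, rng):
        for _ in range(25):
            labels = rng.integers(0, 3, size=(8, 8, 8)).astype(np.uint8)
            np.testing.assert_array_equal(
                critical_voxel_map(labels), brute_force_critical_map(labels)
            )


def brute_force_dice_loss(p, g, smooth):
    vals = []
    for c in (1, 2):
        inter = (p[c] * g[c]).sum()
        vals.append(1 - (2 * inter + smooth) / (p[c].sum() + g[c].sum() + smooth))
    return float(np.mean(vals))


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        g = one_hot(np.ones((3, 3, 3), dtype=np.uint8))
        assert dice_loss(g, g) < 1e-4

    def test_uniform_prediction_matches_direct_sum(self, rng):
        g = one_hot(rng.integers(0, 3, (3, 3, 3))).astype(np.float64)
        p = np.full_like(g, 1 / 3)
        cfg = LossConfig()
        assert dice_loss(p, g, cfg) == pytest.approx(
            brute_force_dice_loss(p, g, cfg.dice_smooth), abs=1e-9
        )

    def test_disjoint_foreground_near_one(self):
        g = one_hot(np.ones((2, 2, 2), dtype=np.uint8))
        p = one_hot(np.full((2, 2, 2), 2, dtype=np.uint8))
        assert dice_loss(p, g) == pytest.approx(1.0, abs=1e-4)


class TestTopologyLoss:
    def test_empty_map_gives_exact_zero(self, rng):
        g = one_hot(rng.integers(0, 3, (3, 3, 3)))
        p = softmax(rng.normal(0, 1, g.shape), axis=0)
        assert topology_loss(p, g, np.zeros((3, 3, 3), bool)) == 0.0

    def test_full_map_equals_plain_cross_entropy(self, rng):
        g = one_hot(rng.integers(0, 3, (3, 3, 3)))
        p = softmax(rng.normal(0, 1, g.shape), axis=0)
        v = np.ones((3, 3, 3), bool)
        for reduction in ("total", "mean"):
            cfg = LossConfig(topo_reduction=reduction)
            assert topology_loss(p, g, v, cfg) == pytest.approx(
                cross_entropy(p, g), rel=1e-9
            )

    def test_single_flagged_voxel_hand_computed(self):
        g = one_hot(np.zeros((1, 1, 2), dtype=np.uint8)).astype(np.float64)
        p = np.zeros_like(g)
        p[0] = 0.5
        p[1] = 0.3
        p[2] = 0.2
        v = np.zeros((1, 1, 2), bool)
        v[0, 0, 0] = True
        cfg = LossConfig(topo_reduction="mean")
        assert topology_loss(p, g, v, cfg) == pytest.approx(-np.log(0.5), rel=1e-9)


class TestCompoundLoss:
    def _compliant_pair(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[1:5, 1:5, 1:5] = 2
        labels[2:4, 2:4, 2:4] = 1
        g = one_hot(labels)
        p = 0.9 * g + 0.1 / 3  # soft but argmax-compliant
        return p, g

    def test_compliant_prediction_total_is_ce_plus_dice(self):
        p, g = self._compliant_pair()
        res = compound_loss(p, g)
        assert res.topo == 0.0
        assert res.total == pytest.approx(res.ce + res.dice, rel=1e-12)

    def test_lambda_zero_equals_ablation_total(self, rng):
        g = one_hot(rng.integers(0, 3, (4, 4, 4)))
        p = softmax(rng.normal(0, 1, g.shape), axis=0)
        with_zero = compound_loss(p, g, LossConfig(lambda_topo=0.0))
        ablated = compound_loss(p, g, LossConfig(use_topo=False))
        assert with_zero.total == pytest.approx(ablated.total, rel=1e-12)

    def test_violation_penalty_is_lambda_times_topo(self, rng):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[1:3, 1:3, 1:3] = 1  # naked fascicle in background: violation
        g = one_hot(np.full((4, 4, 4), 2, dtype=np.uint8))
        p = 0.97 * one_hot(labels) + 0.03 / 3
        cfg = LossConfig(lambda_topo=1e6)
        res = compound_loss(p, g, cfg)
        assert res.topo > 0
        assert res.total - (res.ce + res.dice) == pytest.approx(1e6 * res.topo, rel=1e-9)

    def test_adding_violating_voxel_strictly_increases_topo(self):
        labels = np.zeros((7, 7, 7), dtype=np.uint8)
        labels[1:6, 1:6, 1:6] = 2
        labels[2:5, 2:5, 2:5] = 1
        g = one_hot(labels)
        p_ok = 0.95 * g + 0.05 / 3
        base = compound_loss(p_ok, g).topo
        bad = labels.copy()
        bad[0, 0, 0] = 1  # fascicle voxel exposed to background
        p_bad = 0.95 * one_hot(bad) + 0.05 / 3
        assert compound_loss(p_bad, g).topo > base == 0.0


class TestGradient:
    def test_matches_finite_differences(self, rng):
        g = one_hot(rng.integers(0, 3, (4, 4, 4)))
        logits = rng.normal(0, 1, g.shape)
        cfg = LossConfig(lambda_topo=0.0)  # smooth part (V constant anyway)
        _, grad = compound_loss_grad(logits, g, cfg)
        eps = 1e-6
        for idx in [(0, 1, 2, 3), (1, 0, 0, 0), (2, 3, 3, 3)]:
            lp = logits.copy()
            lp[idx] += eps
            lm = logits.copy()
            lm[idx] -= eps
            num = (
                compound_loss(softmax(lp), g, cfg).total
                - compound_loss(softmax(lm), g, cfg).total
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-10)

    def test_topo_gradient_pushes_flagged_voxels_toward_truth(self, rng):
        # a violating prediction must receive extra gradient on flagged voxels
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[1:3, 1:3, 1:3] = 1
        g = one_hot(np.full((4, 4, 4), 2, dtype=np.uint8))
        logits = 5.0 * one_hot(labels).astype(np.float64)
        _, grad_with = compound_loss_grad(logits, g, LossConfig())
        _, grad_without = compound_loss_grad(logits, g, LossConfig(use_topo=False))
        v = critical_voxel_map(labels)
        delta = grad_with - grad_without
        assert np.abs(delta[:, v]).sum() > 0
        assert np.abs(delta[:, ~v]).sum() == pytest.approx(0.0, abs=1e-15)
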