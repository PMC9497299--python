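"""Binary STAPLE: hand-worked E-step, recovery, symmetry, cross-check."""

from fractions import Fraction

import numpy as np
import pytest

import consenseg as cs
from consenseg import BinaryMask, ImageGrid, ObserverDelineationSet, StapleModel
from consenseg.simulate import ObserverErrorModel, _ellipsoid_mask, simulate_observers


def _flat_masks(grid, flat_index_sets):
    masks = []
    for flat in flat_index_sets:
        arr = np.zeros(grid.shape, bool)
        arr.flat[list(flat)] = True
        masks.append(BinaryMask(grid, arr))
    return masks


@pytest.fixture
def iid_truth():
    # ~1e5-voxel grid with a large ellipsoid truth (~14% occupancy)
    grid = ImageGrid((50, 50, 40), (4.0, 4.0, 5.0))
    truth = BinaryMask(grid, _ellipsoid_mask(grid, (100, 100, 100), (70, 65, 60)))
    return truth


class TestHandExecutedEStep:
    def test_single_e_step_matches_hand_computation(self):
        """One E-step on a 4x4x1 grid, p=q=0.9, fixed prior 1/2.

        With 3 raters the posterior weight depends only on the vote count k:
        a = γ 0.9^k 0.1^(3-k), b = (1-γ) 0.1^k 0.9^(3-k), so with γ = 1/2
        W(3) = 729/730, W(2) = 9/10, W(1) = 1/10, W(0) = 1/730.
        """
        grid = ImageGrid((4, 4, 1), (1, 1, 1))
        # votes per flat voxel: obs1 -> 0..7, obs2 -> 4..11, obs3 -> 6..13
        masks = _flat_masks(grid, [range(0, 8), range(4, 12), range(6, 14)])
        votes = sum(m.values.astype(int) for m in masks).ravel()
        res = StapleModel(
            masks, prior_mode="fixed", fixed_prior=0.5
        ).fit(max_iter=1)
        expected = {
            3: float(Fraction(729, 730)),
            2: 0.9,
            1: 0.1,
            0: float(Fraction(1, 730)),
        }
        w = res.weights.ravel()
        for i, k in enumerate(votes):
            assert w[i] == pytest.approx(expected[int(k)], abs=1e-9)


class TestUnanimity:
    def test_identical_masks_give_perfect_raters_and_same_consensus(self, grid):
        arr = np.zeros(grid.shape, bool)
        arr[3:8, 3:8, 2:6] = True
        masks = [BinaryMask(grid, arr.copy()) for _ in range(4)]
        res = cs.run_staple(masks)
        assert np.all(res.sensitivity > 1 - 1e-6)
        assert np.all(res.specificity > 1 - 1e-6)
        cons = res.consensus_mask()
        assert np.array_equal(cons.values, arr)

    def test_all_empty_masks_rejected(self, grid):
        empty = [BinaryMask(grid, np.zeros(grid.shape, bool)) for _ in range(3)]
        with pytest.raises(ValueError, match="empty"):
            cs.run_staple(empty)


class TestParameterRecovery:
    def test_planted_sensitivity_specificity_recovered(self, iid_truth):
        rng = np.random.default_rng(123)
        p = tuple(rng.uniform(0.85, 0.99, 5))
        q = tuple(rng.uniform(0.85, 0.99, 5))
        obs = simulate_observers(
            iid_truth,
            ObserverErrorModel(mode="iid_flip", sensitivity=p, specificity=q, seed=9),
            5,
        )
        res = cs.run_staple(obs)
        assert res.converged
        assert np.abs(res.sensitivity - p).max() < 0.02
        assert np.abs(res.specificity - q).max() < 0.02
        assert cs.dice(res.consensus_mask(), iid_truth) > 0.95

    def test_estimation_error_shrinks_with_voxel_count(self):
        """iid errors: recovery at ~1e5 voxels beats recovery at ~1e3."""
        errs = {}
        for shape, spacing, axes in [
            ((12, 10, 9), (8, 8, 8), (34, 30, 28)),
            ((50, 50, 40), (4, 4, 5), (70, 65, 60)),
        ]:
            grid = ImageGrid(shape, spacing)
            centre = tuple(np.asarray(shape) * np.asarray(spacing) / 2)
            truth = BinaryMask(grid, _ellipsoid_mask(grid, centre, axes))
            rng = np.random.default_rng(7)
            p = tuple(rng.uniform(0.85, 0.95, 5))
            q = tuple(rng.uniform(0.85, 0.95, 5))
            obs = simulate_observers(
                truth,
                ObserverErrorModel(
                    mode="iid_flip", sensitivity=p, specificity=q, seed=11
                ),
                5,
            )
            res = cs.run_staple(obs)
            errs[np.prod(shape)] = max(
                np.abs(res.sensitivity - p).max(), np.abs(res.specificity - q).max()
            )
        small, big = sorted(errs)
        assert errs[big] < errs[small]

    def test_label_symmetry_swaps_p_and_q(self, iid_truth):
        """Complementing every mask swaps sensitivity and specificity."""
        rng = np.random.default_rng(42)
        p = tuple(rng.uniform(0.85, 0.97, 4))
        q = tuple(rng.uniform(0.85, 0.97, 4))
        obs = simulate_observers(
            iid_truth,
            ObserverErrorModel(mode="iid_flip", sensitivity=p, specificity=q, seed=3),
            4,
        )
        res = cs.run_staple(obs, bbox_margin=10_000)
        flipped = ObserverDelineationSet(
            entries=[(oid, BinaryMask(m.grid, ~m.values)) for oid, m in obs.entries]
        )
        res_flip = cs.run_staple(flipped, bbox_margin=10_000)
        assert np.allclose(res_flip.sensitivity, res.specificity, atol=5e-3)
        assert np.allclose(res_flip.specificity, res.sensitivity, atol=5e-3)


class TestDegenerateAndContracts:
    def test_two_perfectly_disagreeing_raters_follow_the_prior(self, grid):
        arr = np.zeros(grid.shape, bool)
        arr[2:6, 2:6, 2:5] = True
        a = BinaryMask(grid, arr)
        b = BinaryMask(grid, ~arr)
        res = cs.run_staple([a, b], prior_mode="fixed", fixed_prior=0.3, max_iter=1)
        region = res.weights[res.weights > 0]
        # every voxel has exactly one vote; with p=q at init the E-step
        # reduces to the prior
        assert np.allclose(res.weights, 0.3)
        assert region.size  # defined, not an error

    def test_em_objective_nondecreasing(self, iid_truth):
        obs = simulate_observers(
            iid_truth,
            ObserverErrorModel(
                mode="iid_flip", sensitivity=(0.9,), specificity=(0.9,), seed=1
            ),
            5,
        )
        res = cs.run_staple(obs)
        assert np.all(np.diff(res.loglik_trace) >= -1e-7 * np.abs(res.loglik_trace[:-1]))

    def test_consensus_cutoff_conventions(self, grid):
        res = cs.run_staple(
            [
                BinaryMask(grid, np.zeros(grid.shape, bool)),
                BinaryMask(
                    grid, np.eye(12, dtype=bool)[:, :, None] * np.ones(8, bool)
                ),
            ],
            prior_mode="fixed",
            fixed_prior=0.5,
            max_iter=1,
        )
        with pytest.raises(ValueError):
            res.consensus_mask(cutoff=0.0)
        with pytest.raises(ValueError):
            res.consensus_mask(cutoff=1.5)
        # weights exactly at the cutoff are included
        res.weights[:] = 0.5
        assert res.consensus_mask(cutoff=0.5).n_occupied == res.weights.size

    def test_bbox_margin_insensitivity(self, grid):
        rng = np.random.default_rng(17)
        arr = np.zeros(grid.shape, bool)
        arr[3:8, 4:9, 2:6] = True
        masks = []
        for _ in range(3):
            noisy = arr ^ (rng.random(grid.shape) < 0.05) & arr
            masks.append(BinaryMask(grid, noisy))
        res_small = cs.run_staple(masks, bbox_margin=2)
        res_big = cs.run_staple(masks, bbox_margin=100)
        cons_s = res_small.consensus_mask()
        cons_b = res_big.consensus_mask()
        assert cs.dice(cons_s, cons_b) > 0.99


class TestCrossCheck:
    def test_agrees_with_independent_reference_implementation(self, grid):
        """Consensus and performance levels match SimpleITK's STAPLE filter."""
        sitk = pytest.importorskip("SimpleITK")
        rng = np.random.default_rng(2)
        truth = BinaryMask(grid, _ellipsoid_mask(grid, (24, 24, 20), (16, 14, 12)))
        p = tuple(rng.uniform(0.8, 0.95, 4))
        q = tuple(rng.uniform(0.9, 0.98, 4))
        obs = simulate_observers(
            truth,
            ObserverErrorModel(mode="iid_flip", sensitivity=p, specificity=q, seed=5),
            4,
        )
        mine = cs.run_staple(obs, bbox_margin=10_000)  # full grid, like the filter
        imgs = [
            sitk.GetImageFromArray(
                np.ascontiguousarray(m.values.astype(np.uint8).transpose(2, 1, 0))
            )
            for m in obs.masks
        ]
        f = sitk.STAPLEImageFilter()
        f.SetForegroundValue(1)
        prob = sitk.GetArrayFromImage(f.Execute(imgs)).transpose(2, 1, 0)
        assert np.allclose(mine.sensitivity, f.GetSensitivity(), atol=1e-3)
        assert np.allclose(mine.specificity, f.GetSpecificity(), atol=1e-3)
        theirs = BinaryMask(grid, prob >= 0.5)
        assert cs.dice(mine.consensus_mask(), theirs) > 0.999
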