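"""Network contracts: shapes, ranges, determinism, augmentation, training."""

import numpy as np
import pytest

from cryoab import DensityGrid, TrainConfig, UNet3D, augment, predict_grid, train
from cryoab.codec import GridGeometry, decode_cell, encode_poses
from cryoab.losses import LossWeights, total_loss
from cryoab.model import (
    GRID_ROTATIONS,
    InputSizeError,
    ModelConfig,
    load_checkpoint,
    save_checkpoint,
)

from conftest import sample_poses


def _grid(rng, n=32):
    v = rng.random((n, n, n)).astype(np.float32)
    return DensityGrid(v, np.full(3, 2.0), np.zeros(3))


class TestPredictContracts:
    def test_output_shape_64(self, small_model, rng):
        pred = predict_grid(small_model, _grid(rng, 64))
        assert pred.channels.shape == (10, 16, 16, 16)
        assert pred.geometry.cell_size == pytest.approx(8.0)

    def test_output_shape_non_multiple(self, small_model, rng):
        # 72 voxels: padded internally to 80, prediction cropped to ceil(72/4)=18
        pred = predict_grid(small_model, _grid(rng, 72))
        assert pred.channels.shape == (10, 18, 18, 18)

    def test_sigmoid_channels_in_unit_interval(self, small_model, rng):
        pred = predict_grid(small_model, _grid(rng))
        for ch in (0, 9):
            assert np.all(pred.channels[ch] > 0) and np.all(pred.channels[ch] < 1)

    def test_too_small_input_raises(self, small_model, rng):
        with pytest.raises(InputSizeError):
            predict_grid(small_model, _grid(rng, 8))

    def test_zero_map_prediction_finite(self, small_model):
        grid = DensityGrid(np.zeros((32, 32, 32), np.float32), np.full(3, 2.0), np.zeros(3))
        pred = predict_grid(small_model, grid)
        assert np.all(np.isfinite(pred.channels))

    def test_same_input_same_output(self, small_model, rng):
        g = _grid(rng)
        a = predict_grid(small_model, g)
        b = predict_grid(small_model, g)
        assert np.array_equal(a.channels, b.channels)

    def test_translation_equivariance_at_stride(self, rng):
        # conv/pool/upsample are all equivariant to shifts by whole strides;
        # with normalization off, interior cells whose receptive field avoids
        # the zero-padded borders must reproduce exactly under a 1-cell shift
        model = UNet3D(ModelConfig(depth=2, base_channels=4, use_norm=False, init_seed=7))
        v = np.zeros((48, 48, 48), np.float32)
        v[16:32, 16:32, 16:32] = rng.random((16, 16, 16))
        shifted = np.roll(v, 4, axis=0)
        pa = predict_grid(model, DensityGrid(v, np.full(3, 2.0), np.zeros(3)))
        pb = predict_grid(model, DensityGrid(shifted, np.full(3, 2.0), np.zeros(3)))
        assert np.allclose(
            pb.channels[:, 5:8, 4:8, 4:8], pa.channels[:, 4:7, 4:8, 4:8], atol=1e-5
        )


class TestAugment:
    def _pair(self, rng):
        geom = GridGeometry(shape=(8, 8, 8), cell_size=8.0)
        poses = sample_poses(rng, 3, geom)
        target = encode_poses(poses, geom)
        grid = DensityGrid(rng.random((32, 32, 32)).astype(np.float32), np.full(3, 2.0), np.zeros(3))
        return grid, target

    def test_identity_rotation_zero_crop(self, rng):
        grid, target = self._pair(rng)

        class NoCropRng:
            def integers(self, *a, **k):
                return np.zeros(k.get("size", 1), dtype=int) if "size" in k else 0

        g2, t2 = augment(grid, target, NoCropRng(), max_crop_cells=0, rotation_index=0)
        assert np.array_equal(g2.values, grid.values)
        assert np.allclose(t2.channels, target.channels, atol=1e-9)

    def test_group_law_z90_twice_is_z180(self, rng):
        grid, target = self._pair(rng)

        class NoCrop:
            def integers(self, lo, hi=None, size=None):
                return np.zeros(size, dtype=int) if size else 0

        nc = NoCrop()
        g1, t1 = augment(grid, target, nc, max_crop_cells=0, rotation_index=1)
        g2, t2 = augment(g1, t1, nc, max_crop_cells=0, rotation_index=1)
        g3, t3 = augment(grid, target, nc, max_crop_cells=0, rotation_index=2)
        assert np.array_equal(g2.values, g3.values)
        assert np.allclose(t2.channels, t3.channels, atol=1e-8)

    def test_rotations_form_group_of_eight(self):
        mats = {tuple(np.round(m.ravel()).astype(int)) for m in GRID_ROTATIONS}
        assert len(mats) == 8
        for m in GRID_ROTATIONS:
            assert np.linalg.det(m) == pytest.approx(1.0)

    def test_decoded_poses_valid_after_augmentation(self, rng):
        grid, target = self._pair(rng)
        for _ in range(10):
            g2, t2 = augment(grid, target, rng)
            for cell in t2.occupied_cells():
                pose = decode_cell(t2, cell)  # validates rotation properness
                loc = pose.local_offset(t2.geometry)
                assert np.all(loc >= 0) and np.all(loc < t2.geometry.cell_size)
            assert t2.n_occupied <= target.n_occupied


class TestTraining:
    def _tiny_problem(self, rng):
        geom = GridGeometry(shape=(8, 8, 8), cell_size=8.0)
        poses = sample_poses(rng, 2, geom)
        target = encode_poses(poses, geom)
        v = rng.random((32, 32, 32)).astype(np.float32)
        grid = DensityGrid(v, np.full(3, 2.0), np.zeros(3))
        return [(grid, target)]

    def _loss_fn(self):
        w = LossWeights()
        return lambda pred, target: total_loss(pred, target, w)[0]

    def test_overfit_single_example_decreases_loss(self, rng):
        data = self._tiny_problem(rng)
        model = UNet3D(ModelConfig(base_channels=2, init_seed=1))
        cfg = TrainConfig(epochs=100, learning_rate=3e-3, seed=0, augment=False)
        _, hist = train(model, data, self._loss_fn(), cfg)
        assert hist[-1] < hist[0] * 0.5

    def test_same_seed_identical_history(self, rng):
        data = self._tiny_problem(rng)
        cfg = TrainConfig(epochs=3, learning_rate=1e-3, seed=5, augment=True)
        _, h1 = train(UNet3D(ModelConfig(base_channels=2, init_seed=1)), data, self._loss_fn(), cfg)
        _, h2 = train(UNet3D(ModelConfig(base_channels=2, init_seed=1)), data, self._loss_fn(), cfg)
        assert h1 == h2

    def test_zero_learning_rate_constant_history(self, rng):
        data = self._tiny_problem(rng)
        cfg = TrainConfig(epochs=3, learning_rate=0.0, seed=0, augment=False)
        _, hist = train(UNet3D(ModelConfig(base_channels=2, init_seed=1)), data, self._loss_fn(), cfg)
        assert hist[0] == pytest.approx(hist[1]) == pytest.approx(hist[2])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, small_model, rng, tmp_path):
        g = _grid(rng)
        before = predict_grid(small_model, g)
        path = tmp_path / "w.npz"
        save_checkpoint(small_model, path, extra={"note": "test"})
        loaded, extra = load_checkpoint(path)
        after = predict_grid(loaded, g)
        assert np.array_equal(before.channels, after.channels)
        assert extra["note"] == "test"
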