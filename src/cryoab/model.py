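"""Fully convolutional 3D UNet mapping a density grid to a 10-channel
prediction grid, plus training-time augmentation and the Adam training loop.

The encoder has ``depth`` pooling levels; the decoder stops two levels above
full resolution so one output cell covers ``stride`` input voxels per axis
(default 4, i.e. 8 Å cells on 2 Å maps).  Channels 0 (occupancy) and 9 (VHH
probability) pass through a sigmoid; channels 1-8 are unconstrained pose
regressors.  Being fully convolutional, the network accepts any grid at
least ``2**depth`` voxels per axis: inputs are zero-padded on the high side
to a multiple of ``2**depth`` and the prediction is cropped back to
``ceil(extent / stride)`` cells.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from .codec import GridGeometry, TargetGrid, decode_cell, encode_poses
from .grids import DensityGrid


class InputSizeError(ValueError):
    """Input grid smaller than the network's minimum extent."""


class TrainingDiverged(RuntimeError):
    """The training loss became non-finite."""


@dataclass
class ModelConfig:
    depth: int = 4                # encoder pooling levels
    base_channels: int = 8        # feature width at full resolution
    stride: int = 4               # input voxels per output cell along each axis
    convs_per_block: int = 2
    slim_low_levels: bool = False  # single conv at levels with no decoder skip
    leaky_alpha: float = 0.1
    use_norm: bool = True         # instance normalization in conv blocks
    in_channels: int = 1
    out_channels: int = 10
    init_seed: int = 0

    def cell_size(self, voxel_size: float) -> float:
        return self.stride * voxel_size


def _instance_norm(x: ag.Tensor, gamma: ag.Tensor, beta: ag.Tensor) -> ag.Tensor:
    c = x.shape[0]
    n = x.data[0].size
    mean = (x.sum(axis=3).sum(axis=2).sum(axis=1) * (1.0 / n)).reshape(c, 1, 1, 1)
    centered = x - mean
    var = ((centered**2.0).sum(axis=3).sum(axis=2).sum(axis=1) * (1.0 / n)).reshape(
        c, 1, 1, 1
    )
    return centered * (var + 1e-5) ** -0.5 * gamma.reshape(c, 1, 1, 1) + beta.reshape(
        c, 1, 1, 1
    )


class _ConvBlock:
    def __init__(self, c_in: int, c_out: int, cfg: ModelConfig, rng: np.random.Generator,
                 n_convs: int | None = None):
        self.cfg = cfg
        self.convs = []
        for i in range(n_convs if n_convs is not None else cfg.convs_per_block):
            ci = c_in if i == 0 else c_out
            fan_in = ci * 27
            w = ag.parameter(
                rng.normal(0, np.sqrt(2.0 / fan_in), size=(c_out, ci, 3, 3, 3)).astype(
                    np.float32
                )
            )
            b = ag.parameter(np.zeros(c_out, dtype=np.float32))
            if cfg.use_norm:
                gamma = ag.parameter(np.ones(c_out, dtype=np.float32))
                beta = ag.parameter(np.zeros(c_out, dtype=np.float32))
            else:
                gamma = beta = None
            self.convs.append((w, b, gamma, beta))

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        for w, b, gamma, beta in self.convs:
            x = ag.conv3d(x, w, b)
            if gamma is not None:
                x = _instance_norm(x, gamma, beta)
            x = x.leaky_relu(self.cfg.leaky_alpha)
        return x

    def parameters(self) -> list[ag.Tensor]:
        out = []
        for w, b, gamma, beta in self.convs:
            out += [w, b]
            if gamma is not None:
                out += [gamma, beta]
        return out


class UNet3D:
    """Encoder-decoder over (1, D, H, W) density arrays."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = cfg = config or ModelConfig()
        if 2**cfg.depth % cfg.stride != 0 or cfg.stride > 2**cfg.depth:
            raise ValueError("stride must divide 2**depth")
        rng = np.random.default_rng(cfg.init_seed)
        ch = [cfg.base_channels * 2**l for l in range(cfg.depth + 1)]
        out_level = int(np.log2(cfg.stride))
        self.enc = []
        for l in range(cfg.depth):
            n_convs = (
                1 if (cfg.slim_low_levels and l < out_level) else cfg.convs_per_block
            )
            self.enc.append(
                _ConvBlock(cfg.in_channels if l == 0 else ch[l - 1], ch[l], cfg, rng, n_convs)
            )
        self.bottom = _ConvBlock(ch[cfg.depth - 1], ch[cfg.depth], cfg, rng)
        self._out_level = int(np.log2(cfg.stride))  # decoder stops here
        self.dec = []
        c_up = ch[cfg.depth]
        for l in range(cfg.depth - 1, self._out_level - 1, -1):
            self.dec.append(_ConvBlock(c_up + ch[l], ch[l], cfg, rng))
            c_up = ch[l]
        fan_in = c_up
        self.head_w = ag.parameter(
            rng.normal(0, np.sqrt(1.0 / fan_in), size=(cfg.out_channels, c_up, 1, 1, 1)).astype(
                np.float32
            )
        )
        head_b = np.zeros(cfg.out_channels, dtype=np.float32)
        # low-prior init of the occupancy logit: almost every cell is empty,
        # so start the sigmoid near 0.01 (standard focal-loss detection init)
        head_b[0] = np.log(0.01 / 0.99)
        self.head_b = ag.parameter(head_b)

    def parameters(self) -> list[ag.Tensor]:
        params: list[ag.Tensor] = []
        for blk in [*self.enc, self.bottom, *self.dec]:
            params += blk.parameters()
        params += [self.head_w, self.head_b]
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- forward -----------------------------------------------------------
    def forward(self, values: np.ndarray) -> ag.Tensor:
        """Raw forward pass: (D, H, W) array -> (10, D/s, H/s, W/s) Tensor.

        Spatial extents must be multiples of ``2**depth``.  Sigmoids are
        applied to the occupancy and class channels.
        """
        cfg = self.config
        x = ag.Tensor(values[None].astype(np.float32))
        skips = []
        for blk in self.enc:
            x = blk(x)
            skips.append(x)
            x = ag.maxpool3d(x)
        x = self.bottom(x)
        for blk, skip in zip(self.dec, reversed(skips[self._out_level:])):
            x = ag.upsample3d(x)
            x = ag.concat([x, skip], axis=0)
            x = blk(x)
        y = ag.conv3d(x, self.head_w, self.head_b)
        occ = y[0:1].sigmoid()
        pose = y[1:9]
        cls = y[9:10].sigmoid()
        return ag.concat([occ, pose, cls], axis=0)

    def predict_tensor(self, grid: DensityGrid) -> tuple[ag.Tensor, GridGeometry]:
        """Forward pass with padding/cropping; returns the graph node."""
        cfg = self.config
        shape = np.array(grid.shape)
        if np.any(shape < 2**cfg.depth):
            raise InputSizeError(
                f"input {tuple(shape)} smaller than the receptive minimum "
                f"{2**cfg.depth} voxels per axis"
            )
        mult = 2**cfg.depth
        padded = (np.ceil(shape / mult) * mult).astype(int)
        out_shape = tuple(int(np.ceil(n / cfg.stride)) for n in shape)
        v = grid.values
        pads = padded - shape
        if np.any(pads > 0):
            v = np.pad(v, [(0, int(p)) for p in pads])
        y = self.forward(v)
        y = y[:, : out_shape[0], : out_shape[1], : out_shape[2]]
        geometry = GridGeometry(
            shape=out_shape,
            cell_size=cfg.cell_size(float(grid.voxel_size[0])),
            origin=grid.origin.copy(),
        )
        return y, geometry


class EnsembleModel:
    """Average of independently initialized and trained networks.

    Batch-1 training on a small corpus leaves noticeable seed-to-seed
    variance in the prediction grid; averaging the 10-channel outputs of a
    few members is the standard deep-ensemble remedy and in particular
    suppresses spurious secondary occupancy peaks that individual members
    do not agree on.  Members share the same architecture; the ensemble
    exposes the same prediction interface as a single network.
    """

    def __init__(self, members: list[UNet3D]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    @property
    def config(self) -> ModelConfig:
        return self.members[0].config

    def parameters(self) -> list[ag.Tensor]:
        return [p for m in self.members for p in m.parameters()]

    def predict_tensor(self, grid: DensityGrid):
        outputs = [m.predict_tensor(grid) for m in self.members]
        geometry = outputs[0][1]
        y = outputs[0][0]
        for other, _ in outputs[1:]:
            y = y + other
        return y * (1.0 / len(outputs)), geometry


def predict_grid(model, grid: DensityGrid) -> TargetGrid:
    """Run the network (or an ensemble) on a (normalized) density grid."""
    y, geometry = model.predict_tensor(grid)
    return TargetGrid(y.data.astype(np.float64), geometry)


# ---------------------------------------------------------------------------
# Augmentation

_FLIP_X180 = np.diag([1.0, -1.0, -1.0])


def _grid_rotation_matrices() -> list[np.ndarray]:
    """The 8-element subgroup: 90° rotations about z times the 180° x-flip."""
    rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    mats = []
    for b in range(2):
        for a in range(4):
            m = np.linalg.matrix_power(rz, a) @ np.linalg.matrix_power(_FLIP_X180, b)
            mats.append(np.round(m).astype(float))
    return mats


GRID_ROTATIONS = _grid_rotation_matrices()


def _rotate_array(values: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Apply a signed-permutation rotation to a 3D array about its center."""
    perm = [int(np.flatnonzero(m[i])[0]) for i in range(3)]
    signs = [m[i, perm[i]] for i in range(3)]
    out = np.transpose(values, perm)
    for axis, s in enumerate(signs):
        if s < 0:
            out = np.flip(out, axis=axis)
    return np.ascontiguousarray(out)


def augment(
    grid: DensityGrid,
    target: TargetGrid,
    rng: np.random.Generator,
    max_crop_cells: int = 3,
    rotation_index: int | None = None,
):
    """Random axis-aligned rotation (8-element group) plus random cropping.

    The map and the target grid are rotated together about the map center;
    pose channels are recomputed from the rotated rigid transforms.  Then
    0..``max_crop_cells`` whole cells are cropped per side, dropping
    antibodies whose owner cell is removed.
    """
    m = GRID_ROTATIONS[
        int(rng.integers(len(GRID_ROTATIONS))) if rotation_index is None else rotation_index
    ]
    poses = [decode_cell(target, c) for c in target.occupied_cells()]
    values = _rotate_array(grid.values, m)
    voxel = float(grid.voxel_size[0])
    ctr_old = grid.origin + (np.array(grid.shape) - 1) * grid.voxel_size / 2
    ctr_new = grid.origin + (np.array(values.shape) - 1) * grid.voxel_size / 2
    new_poses = []
    for p in poses:
        t = m @ (p.translation - ctr_old) + ctr_new
        new_poses.append(type(p)(rotation=m @ p.rotation, translation=t, ab_class=p.ab_class))
    cell = target.geometry.cell_size
    stride = int(round(cell / voxel))
    lo = rng.integers(0, max_crop_cells + 1, size=3)
    hi = rng.integers(0, max_crop_cells + 1, size=3)
    n = np.array(values.shape)
    min_extent = 2 ** 4  # keep at least the receptive minimum of a depth-4 net
    lo_vox = np.minimum(lo * stride, np.maximum(n - min_extent, 0))
    hi_vox = np.clip(hi * stride, 0, np.maximum(n - lo_vox - min_extent, 0))
    keep = [slice(int(l), int(n[i] - h)) for i, (l, h) in enumerate(zip(lo_vox, hi_vox))]
    values = values[tuple(keep)]
    new_origin = grid.origin + lo_vox * voxel
    new_grid = DensityGrid(values, grid.voxel_size.copy(), new_origin)
    geometry = GridGeometry.covering(
        new_origin, np.array(values.shape) * voxel, cell_size=cell
    )
    kept = [
        p
        for p in new_poses
        if geometry.contains_cell(geometry.owner_cell(p.translation))
    ]
    return new_grid, encode_poses(kept, geometry)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    epochs: int = 15
    learning_rate: float = 2e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    lr_milestones: tuple = ()     # epochs at which to multiply the lr
    lr_decay: float = 0.3
    augment: bool = True
    augment_until: float = 1.0    # fraction of epochs with augmentation on
    max_crop_cells: int = 3
    polyak_tail: float = 0.0      # average weights over this tail fraction of epochs
    val_fraction: float = 0.0     # tail fraction of the dataset held out
    log_every: int = 0            # epochs between log lines; 0 = silent


class Adam:
    def __init__(self, params: list[ag.Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        c = self.cfg
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = c.beta1 * self.m[i] + (1 - c.beta1) * g
            self.v[i] = c.beta2 * self.v[i] + (1 - c.beta2) * g * g
            mhat = self.m[i] / (1 - c.beta1**self.t)
            vhat = self.v[i] / (1 - c.beta2**self.t)
            p.data = p.data - c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


def train(model: UNet3D, dataset, loss_fn, config: TrainConfig | None = None):
    """Minimize ``loss_fn(pred_tensor, target)`` over a dataset.

    ``dataset`` is a sequence of ``(DensityGrid, TargetGrid)`` pairs;
    ``loss_fn`` maps a prediction Tensor and a TargetGrid to a scalar Tensor
    (the composite detection loss).  Returns ``(model, history)`` where
    history is a list of per-epoch mean losses; when a validation split is
    configured the parameters with the best validation loss are restored.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(dataset)))
    train_set = list(dataset[: len(dataset) - n_val])
    val_set = list(dataset[len(dataset) - n_val :])
    opt = Adam(model.parameters(), cfg)
    history: list[float] = []
    best = (np.inf, None)
    avg_start = int(np.ceil(cfg.epochs * (1.0 - cfg.polyak_tail)))
    avg: list[np.ndarray] | None = None
    n_avg = 0
    lr0 = cfg.learning_rate
    for epoch in range(cfg.epochs):
        cfg.learning_rate = lr0 * cfg.lr_decay ** sum(
            1 for m in cfg.lr_milestones if epoch >= m
        )
        order = rng.permutation(len(train_set))
        total = 0.0
        augment_on = cfg.augment and epoch < cfg.augment_until * cfg.epochs
        for idx in order:
            grid, target = train_set[idx]
            if augment_on:
                grid, target = augment(grid, target, rng, cfg.max_crop_cells)
            pred, geometry = model.predict_tensor(grid)
            loss = loss_fn(pred, TargetGrid(target.channels, geometry))
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss {value} at epoch {epoch}, sample {idx}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            total += value
        history.append(total / max(len(train_set), 1))
        if cfg.polyak_tail > 0 and epoch >= avg_start:
            params = model.parameters()
            if avg is None:
                avg = [p.data.astype(np.float64).copy() for p in params]
            else:
                for a, p in zip(avg, params):
                    a += p.data
            n_avg += 1
        if val_set:
            vloss = 0.0
            for grid, target in val_set:
                pred, geometry = model.predict_tensor(grid)
                vloss += loss_fn(pred, TargetGrid(target.channels, geometry)).item()
            vloss /= len(val_set)
            if vloss < best[0]:
                best = (vloss, [p.data.copy() for p in model.parameters()])
        if cfg.log_every and (epoch + 1) % cfg.log_every == 0:
            print(f"epoch {epoch + 1}/{cfg.epochs}  loss {history[-1]:.4f}")
    cfg.learning_rate = lr0
    if avg is not None and n_avg > 0:
        for p, a in zip(model.parameters(), avg):
            p.data = (a / n_avg).astype(p.data.dtype)
    if best[1] is not None:
        for p, d in zip(model.parameters(), best[1]):
            p.data = d
    return model, history


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(model, path, extra: dict | None = None) -> None:
    """Serialize a single network or an ensemble plus its configuration."""
    members = model.members if isinstance(model, EnsembleModel) else [model]
    arrays = {}
    for mi, member in enumerate(members):
        for i, p in enumerate(member.parameters()):
            arrays[f"m{mi}_param_{i}"] = p.data
    meta = {
        "configs": [asdict(m.config) for m in members],
        "extra": extra or {},
    }
    np.savez_compressed(
        path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays
    )


def load_checkpoint(path):
    """Load a checkpoint; returns ``(model, extra)`` where the model is a
    single network or an :class:`EnsembleModel` as saved."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        members = []
        for mi, cfg in enumerate(meta["configs"]):
            member = UNet3D(ModelConfig(**cfg))
            for i, p in enumerate(member.parameters()):
                p.data = data[f"m{mi}_param_{i}"].copy()
            members.append(member)
    model = members[0] if len(members) == 1 else EnsembleModel(members)
    return model, meta.get("extra", {})
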