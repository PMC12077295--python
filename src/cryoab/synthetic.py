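"""Synthetic density maps with known planted antibody poses.

This module is pure scaffolding for development and testing: it emulates the
statistical structure of a curated cryo-EM antibody corpus (2 Å voxels, a
few rigidly placed antibody-shaped densities per map, antigen-like decoy
blobs, additive noise) without requiring any downloads.  Densities are sums
of atom-centered isotropic Gaussians with ``sigma = resolution / 2.355``
(the FWHM convention), which is a standard resolution proxy, not a physical
image-formation model.

Pseudo-templates are deterministic point clouds: a two-lobe ~200-atom shape
for the Fv of a Fab, a single smaller ~100-atom lobe for a VHH, both
centered with the canonical axis ``u_z`` along the long axis.  The lobes are
deliberately asymmetric across and around the axis so both the direction
``p`` and the in-plane angle ``theta`` are identifiable from density alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .codec import AbPose, GridGeometry, TargetGrid, encode_poses
from .grids import DensityGrid, normalize
from .rotations import random_rotation
from .template import Chain, TemplateStructure

_AA = "ACDEFGHIKLMNPQRSTVWY"


class PlacementError(RuntimeError):
    """Could not place the requested number of poses at the separation."""


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated map."""

    extent: float = 96.0            # Å per axis
    voxel_size: float = 2.0         # Å
    n_antibodies: int | None = None  # None: draw 1..max_antibodies per map
    max_antibodies: int = 4         # upper bound of the random draw (corpus mean ~2.25)
    vhh_fraction: float = 0.2       # VHH share of the corpus (86 of 460 test Abs)
    resolution: float = 9.4         # Å; Gaussian sigma = resolution / 2.355
    n_decoys: int = 2               # antigen-like blobs
    decoy_scale: float = 1.6        # decoy lobe size relative to the Fv lobe
    noise_sd: float = 0.05          # relative to the peak signal
    min_separation: float = 20.0    # Å between antibody centers
    border: float = 16.0            # Å keep-out from the map faces
    cell_size: float = 8.0          # Å, codec geometry

    @property
    def sigma(self) -> float:
        return self.resolution / 2.355

    @property
    def n_voxels(self) -> int:
        return int(round(self.extent / self.voxel_size))


def _lobe(
    rng: np.random.Generator, n: int, center: np.ndarray, semi_axes: np.ndarray
) -> np.ndarray:
    """Deterministic blob of pseudo-atoms filling an ellipsoid."""
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-1, 1, size=(4 * n, 3))
        cand = cand[(cand**2).sum(axis=1) <= 1.0]
        pts.extend(cand)
    pts = np.array(pts[:n]) * semi_axes + center
    return pts


def make_pseudo_template(ab_class: str) -> TemplateStructure:
    """A deterministic antibody-shaped pseudo-atomic template.

    The same object is returned on every call (fixed internal seed).
    """
    if ab_class == "fab":
        rng = np.random.default_rng(20240801)
        # lower lobe wider (breaks the +z/-z symmetry), upper lobe offset in
        # +x (breaks rotational symmetry about the axis)
        lower = _lobe(rng, 110, np.array([0.0, 0.0, -9.0]), np.array([10.0, 8.0, 7.5]))
        upper = _lobe(rng, 90, np.array([3.5, 0.0, 9.5]), np.array([6.5, 6.5, 7.5]))
        coords = np.vstack([lower, upper])
        chain_sizes = [110, 90]
        chain_ids = ["H", "L"]
    elif ab_class == "vhh":
        rng = np.random.default_rng(20240802)
        lower = _lobe(rng, 60, np.array([0.0, 0.0, -4.0]), np.array([7.5, 6.0, 5.5]))
        upper = _lobe(rng, 40, np.array([2.5, 0.0, 5.0]), np.array([5.0, 5.0, 5.5]))
        coords = np.vstack([lower, upper])
        chain_sizes = [60, 40]
        chain_ids = ["N", "N"]
    else:
        raise ValueError("ab_class must be 'fab' or 'vhh'")
    coords = coords - coords.mean(axis=0)
    chains = []
    start = 0
    for cid, size in zip(chain_ids, chain_sizes):
        seq = "".join(rng.choice(list(_AA)) for _ in range(size))
        chains.append(Chain(cid, seq, coords[start : start + size]))
        start += size
    if chain_ids[0] == chain_ids[-1]:  # single-chain VHH
        chains = [Chain(chain_ids[0], chains[0].sequence + chains[1].sequence, coords)]
    return TemplateStructure(
        atom_coords=coords,
        chains=chains,
        ab_class=ab_class,
        atom_names=["CA"] * len(coords),
        residue_names=["GLY"] * len(coords),
    )


def _decoy_atoms(rng: np.random.Generator, scale: float) -> np.ndarray:
    """An antigen-like blob: one diffuse lobe, larger than an Fv lobe."""
    n = 70
    semi = np.array([9.0, 8.0, 7.0]) * scale
    return _lobe(rng, n, np.zeros(3), semi)


def render_density(
    atom_sets: list[np.ndarray], spec: SyntheticSpec
) -> np.ndarray:
    """Sum of atom-centered Gaussians sampled on the voxel lattice."""
    n = spec.n_voxels
    values = np.zeros((n, n, n), dtype=np.float64)
    sigma = spec.sigma
    reach = int(np.ceil(3 * sigma / spec.voxel_size))
    axes = np.arange(n) * spec.voxel_size
    for atoms in atom_sets:
        for atom in atoms:
            ctr = atom / spec.voxel_size
            lo = np.maximum(np.floor(ctr).astype(int) - reach, 0)
            hi = np.minimum(np.floor(ctr).astype(int) + reach + 2, n)
            if np.any(lo >= hi):
                continue
            dx = (axes[lo[0] : hi[0]] - atom[0]) ** 2
            dy = (axes[lo[1] : hi[1]] - atom[1]) ** 2
            dz = (axes[lo[2] : hi[2]] - atom[2]) ** 2
            local = np.exp(
                -(dx[:, None, None] + dy[None, :, None] + dz[None, None, :])
                / (2 * sigma**2)
            )
            values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += local
    return values


def _place_centers(
    rng: np.random.Generator, n: int, spec: SyntheticSpec, max_tries: int = 2000
) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 3))
    lo, hi = spec.border, spec.extent - spec.border
    if hi <= lo:
        raise PlacementError("extent too small for the border keep-out")
    centers: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        cand = rng.uniform(lo, hi, size=3)
        if all(np.linalg.norm(cand - c) >= spec.min_separation for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise PlacementError(
            f"could not place {n} centers >= {spec.min_separation} Å apart"
        )
    return np.array(centers) if centers else np.zeros((0, 3))


def simulate_map(
    spec: SyntheticSpec, seed: int
) -> tuple[DensityGrid, list[AbPose]]:
    """Simulate one map: planted antibodies + decoys + noise, normalized.

    Poses use Haar-uniform random rotations; centers respect the pairwise
    separation invariant.  Returns the normalized grid and the ground truth.
    """
    rng = np.random.default_rng(seed)
    n_ab = (
        int(rng.integers(1, spec.max_antibodies + 1))
        if spec.n_antibodies is None
        else int(spec.n_antibodies)
    )
    templates = {"fab": make_pseudo_template("fab"), "vhh": make_pseudo_template("vhh")}
    centers = _place_centers(rng, n_ab, spec)
    poses: list[AbPose] = []
    atom_sets: list[np.ndarray] = []
    for i in range(n_ab):
        ab_class = "vhh" if rng.random() < spec.vhh_fraction else "fab"
        rot = random_rotation(rng)
        pose = AbPose(rotation=rot, translation=centers[i], ab_class=ab_class)
        poses.append(pose)
        atom_sets.append(templates[ab_class].transformed(rot, centers[i]))
    for _ in range(spec.n_decoys):
        ctr = rng.uniform(spec.border * 0.5, spec.extent - spec.border * 0.5, size=3)
        rot = random_rotation(rng)
        atoms = _decoy_atoms(rng, spec.decoy_scale) @ rot.T + ctr
        atom_sets.append(atoms)
    values = render_density(atom_sets, spec)
    peak = values.max() if values.size else 0.0
    if spec.noise_sd > 0 and peak > 0:
        values = values + rng.normal(0, spec.noise_sd * peak, size=values.shape)
    grid = DensityGrid(
        values.astype(np.float32), np.full(3, spec.voxel_size), np.zeros(3)
    )
    return normalize(grid), poses


def target_geometry(spec: SyntheticSpec) -> GridGeometry:
    return GridGeometry.covering(
        np.zeros(3), np.full(3, float(spec.n_voxels * spec.voxel_size)), spec.cell_size
    )


def make_dataset(
    n_maps: int, spec: SyntheticSpec, seed: int
) -> list[tuple[DensityGrid, TargetGrid, list[AbPose]]]:
    """Generate ``n_maps`` independent simulated maps with encoded targets."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_maps)
    geometry = target_geometry(spec)
    out = []
    for s in seeds:
        for attempt in range(20):
            grid, poses = simulate_map(spec, int(s) + attempt * 1_000_003)
            try:
                target = encode_poses(poses, geometry)
                break
            except (ValueError, PlacementError):
                continue  # rare cell collision despite separation: redraw
        out.append((grid, target, poses))
    return out


def save_ground_truth(poses: list[AbPose], path) -> None:
    """JSON sidecar with the planted poses."""
    data = [
        {
            "rotation": p.rotation.tolist(),
            "translation": p.translation.tolist(),
            "ab_class": p.ab_class,
        }
        for p in poses
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def load_ground_truth(path) -> list[AbPose]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        AbPose(
            rotation=np.array(d["rotation"]),
            translation=np.array(d["translation"]),
            ab_class=d["ab_class"],
        )
        for d in data
    ]
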