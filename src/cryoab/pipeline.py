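"""End-to-end prediction: map file -> preprocessing -> network -> NMS ->
decoded detections -> placed-template PDB.

The only input a prediction needs is the density map itself.  Maps are
resampled to 2 Å voxels and normalized, the network produces the 10-channel
grid, persistence NMS turns the occupancy channel into ranked candidate
cells, and each candidate is decoded into a rigid template placement in the
map's physical (Å) frame, so output PDBs overlay the input map in
visualization tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .codec import AbPose, TargetGrid, decode_cell
from .grids import DensityGrid, normalize, read_map, resample
from .model import UNet3D, load_checkpoint, predict_grid
from .nms import DEFAULT_LIFETIME_THRESHOLD, persistence_components, select_detections
from .template import TemplateStructure

TARGET_VOXEL = 2.0


@dataclass
class Detection:
    """One decoded candidate antibody."""

    pose: AbPose
    occupancy_score: float
    lifetime: float
    vhh_probability: float

    @property
    def center(self) -> np.ndarray:
        return self.pose.translation


def detect_in_grid(
    grid: DensityGrid,
    model: UNet3D,
    num: int | None = None,
    lifetime_threshold: float | None = None,
    min_occupancy: float | None = None,
) -> list[Detection]:
    """Run detection on an already-loaded map (resampling + normalizing it)."""
    if not np.allclose(grid.voxel_size, TARGET_VOXEL):
        grid = resample(grid, TARGET_VOXEL)
    grid = normalize(grid)
    prediction = predict_grid(model, grid)
    return detections_from_prediction(prediction, num, lifetime_threshold, min_occupancy)


def detections_from_prediction(
    prediction: TargetGrid,
    num: int | None = None,
    lifetime_threshold: float | None = None,
    min_occupancy: float | None = None,
    connectivity: int = 26,
) -> list[Detection]:
    """Persistence NMS on the occupancy channel, then per-cell decoding.

    Full 26-connectivity is the default here: two antibody centers can never
    sit in diagonally adjacent cells (their separation would be under the
    cell diagonal of ~14 Å), so diagonal double-peaks are always duplicates
    of one object and should merge during the persistence sweep.
    """
    if num is None and lifetime_threshold is None:
        lifetime_threshold = DEFAULT_LIFETIME_THRESHOLD
    components = persistence_components(prediction.occupancy, connectivity=connectivity)
    selected = select_detections(components, num=num, lifetime_threshold=lifetime_threshold)
    detections = []
    for comp in selected:
        score = float(prediction.occupancy[comp.seed_cell])
        if min_occupancy is not None and score < min_occupancy:
            continue
        pose = decode_cell(prediction, comp.seed_cell)
        detections.append(
            Detection(
                pose=pose,
                occupancy_score=score,
                lifetime=comp.lifetime,
                vhh_probability=float(prediction.channels[9][comp.seed_cell]),
            )
        )
    detections.sort(key=lambda d: -d.lifetime)
    return detections


def detect_antibodies(
    map_path,
    checkpoint_path,
    num: int | None = None,
    lifetime_threshold: float | None = None,
    min_occupancy: float | None = None,
) -> list[Detection]:
    """Full pipeline from a map file and a trained checkpoint.

    ``num`` fixes the number of detections (known-count mode); otherwise all
    candidates with persistence lifetime above ``lifetime_threshold``
    (default 0.2) are returned.  ``min_occupancy`` additionally discards
    detections whose peak occupancy score is below the given value — a
    precision guard for maps that may contain no antibody at all.
    """
    model, _ = load_checkpoint(checkpoint_path)
    grid = read_map(map_path)
    return detect_in_grid(grid, model, num, lifetime_threshold, min_occupancy)


def write_detections_pdb(
    detections: list[Detection],
    templates: dict[str, TemplateStructure],
    out_path,
) -> None:
    """Write one MODEL per detection, template atoms moved by the pose.

    The occupancy column carries the detection's occupancy score and the
    B-factor column its persistence lifetime (clamped to the PDB field
    ranges).  Zero detections produce a valid structure with no models.
    """
    st = gemmi.Structure()
    st.name = "detected antibodies"
    for i, det in enumerate(detections):
        template = templates[det.pose.ab_class]
        coords = template.transformed(det.pose.rotation, det.pose.translation)
        model = gemmi.Model(i + 1)
        names = template.atom_names or ["CA"] * len(coords)
        resnames = template.residue_names or ["GLY"] * len(coords)
        start = 0
        for chain_spec in template.chains:
            chain = gemmi.Chain(chain_spec.chain_id)
            n_res = len(chain_spec.sequence)
            for r in range(n_res):
                res = gemmi.Residue()
                res.name = resnames[start + r]
                res.seqid = gemmi.SeqId(r + 1, " ")
                atom = gemmi.Atom()
                atom.name = names[start + r]
                atom.element = gemmi.Element("C")
                x, y, z = coords[start + r]
                atom.pos = gemmi.Position(x, y, z)
                atom.occ = float(np.clip(det.occupancy_score, 0.0, 1.0))
                atom.b_iso = float(np.clip(det.lifetime * 100.0, 0.0, 999.99))
                res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
            start += n_res
        st.add_model(model)
    doc = st.make_pdb_string()
    with open(out_path, "w") as fh:
        fh.write(doc)


def read_detection_centers(path) -> list[np.ndarray]:
    """Per-MODEL centers of mass from a written detection PDB."""
    st = gemmi.read_structure(str(path))
    centers = []
    for model in st:
        coords = [
            [a.pos.x, a.pos.y, a.pos.z]
            for chain in model
            for res in chain
            for a in res
        ]
        if coords:
            centers.append(np.mean(coords, axis=0))
    return centers
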