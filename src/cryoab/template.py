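"""Antibody template structures and rigid superposition.

The detector does not model antibody atoms directly: it predicts how to
rigidly place a fixed template (an Fv for Fabs, a single domain for VHHs).
The template is stored centered at its center of mass with a canonical
direction ``u_z`` (center of mass toward the CDR tips).  Ground-truth poses
are obtained by superposing the template onto deposited antibody chains:
residues are paired by sequence alignment, then a least-squares rigid fit
(Kabsch) of paired Cα atoms is refined by iterative outlier rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import Align

U_Z = np.array([0.0, 0.0, 1.0])


class AlignmentFailure(ValueError):
    """Too few residues could be paired between template and target chains."""


@dataclass
class Chain:
    """One polypeptide chain reduced to sequence + Cα coordinates."""

    chain_id: str
    sequence: str
    ca_coords: np.ndarray  # (n_res, 3) Å

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if len(self.sequence) != len(self.ca_coords):
            raise ValueError("sequence length must match number of Cα atoms")


@dataclass
class TemplateStructure:
    """A rigid antibody template, centered with canonical axis ``u_z``.

    ``atom_coords`` holds every pseudo-atom / Cα used for density rendering
    and PDB emission; ``chains`` carries per-chain sequences for the
    superposition step.  The center of mass of ``atom_coords`` is the zero
    vector and ``u_z`` is unit length.
    """

    atom_coords: np.ndarray
    chains: list[Chain]
    ab_class: str  # "fab" | "vhh"
    u_z: np.ndarray = field(default_factory=lambda: U_Z.copy())
    atom_names: list[str] | None = None
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, dtype=float).reshape(-1, 3)
        self.u_z = np.asarray(self.u_z, dtype=float).reshape(3)
        com = self.atom_coords.mean(axis=0)
        if np.linalg.norm(com) > 1e-6:
            raise ValueError("template atoms must be centered at the center of mass")
        if abs(np.linalg.norm(self.u_z) - 1) > 1e-6:
            raise ValueError("u_z must be a unit vector")
        if self.ab_class not in ("fab", "vhh"):
            raise ValueError("ab_class must be 'fab' or 'vhh'")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
        """Atom coordinates after the rigid placement x -> R x + t."""
        return self.atom_coords @ np.asarray(rotation).T + np.asarray(translation)


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired points.

    Returns ``(R, t, rmsd)`` minimizing ``||R @ moving_i + t - fixed_i||``.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cf - r @ cm
    resid = moving @ r.T + t - fixed
    rmsd = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return r, t, rmsd


def _pair_residues(template_chain: Chain, target_chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Pair Cα atoms of two chains by global sequence alignment."""
    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "global"
    aln = aligner.align(template_chain.sequence, target_chain.sequence)[0]
    ia, ib = [], []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        ia.extend(range(a0, a1))
        ib.extend(range(b0, b1))
    return template_chain.ca_coords[ia], target_chain.ca_coords[ib]


def superpose_template(
    template: TemplateStructure,
    target_chains: list[Chain],
    min_matched: int = 50,
    outlier_sigma: float = 2.0,
    max_cycles: int = 5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid placement of the template onto an antibody.

    Template chains are greedily matched to target chains (best alignment
    pairing per template chain), paired Cα atoms are superposed with Kabsch,
    and pairs with residual distance beyond ``outlier_sigma`` standard
    deviations are dropped for up to ``max_cycles`` refinement cycles.

    Returns ``(rotation, translation, rmsd)`` with the transform mapping
    template coordinates onto the antibody.
    """
    pairs_m, pairs_f = [], []
    used: set[int] = set()
    for tc in template.chains:
        best = None
        for j, oc in enumerate(target_chains):
            if j in used:
                continue
            m, f = _pair_residues(tc, oc)
            if best is None or len(m) > len(best[1]):
                best = (j, m, f)
        if best is not None and len(best[1]) > 0:
            used.add(best[0])
            pairs_m.append(best[1])
            pairs_f.append(best[2])
    if not pairs_m:
        raise AlignmentFailure("no template chain could be aligned to the target")
    moving = np.concatenate(pairs_m)
    fixed = np.concatenate(pairs_f)
    if len(moving) < min_matched:
        raise AlignmentFailure(
            f"only {len(moving)} residues matched; need >= {min_matched}"
        )
    keep = np.ones(len(moving), dtype=bool)
    r, t, rmsd = kabsch(moving, fixed)
    for _ in range(max_cycles):
        resid = np.linalg.norm(moving @ r.T + t - fixed, axis=1)
        lim = resid[keep].mean() + outlier_sigma * resid[keep].std()
        new_keep = resid <= lim
        new_keep &= keep
        if new_keep.sum() < min_matched or new_keep.sum() == keep.sum():
            break
        keep = new_keep
        r, t, rmsd = kabsch(moving[keep], fixed[keep])
    return r, t, rmsd


# ---------------------------------------------------------------------------
# PDB ingestion helpers

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def template_from_chains(
    chains: list[Chain], ab_class: str, u_z=U_Z
) -> TemplateStructure:
    """Build a centered template from Cα chains (e.g. the Fv of a real Fab)."""
    coords = np.concatenate([c.ca_coords for c in chains])
    com = coords.mean(axis=0)
    centered_chains = [
        Chain(c.chain_id, c.sequence, c.ca_coords - com) for c in chains
    ]
    return TemplateStructure(
        atom_coords=coords - com,
        chains=centered_chains,
        ab_class=ab_class,
        u_z=np.asarray(u_z, float),
        atom_names=["CA"] * len(coords),
        residue_names=["GLY"] * len(coords),
    )


def read_chains(path, chain_ids: list[str] | None = None, max_residues: int | None = None) -> list[Chain]:
    """Extract Cα chains from a PDB/mmCIF file.

    ``max_residues`` truncates each chain (e.g. ~115 to keep only the
    variable domain of a Fab chain).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    out = []
    for chain in st[0]:
        if chain_ids is not None and chain.name not in chain_ids:
            continue
        seq, coords = [], []
        for res in chain:
            if res.name not in _AA3TO1:
                continue
            ca = res.find_atom("CA", "\0")
            if ca is None:
                continue
            seq.append(_AA3TO1[res.name])
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
            if max_residues is not None and len(seq) >= max_residues:
                break
        if seq:
            out.append(Chain(chain.name, "".join(seq), np.array(coords)))
    return out
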