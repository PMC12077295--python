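"""Persistence-diagram non-maximal suppression.

The occupancy channel of a prediction typically lights up several adjacent
cells per antibody.  Instead of zeroing neighborhoods around maxima, we rank
candidate detections by 0-dimensional superlevel-set persistence: sweep a
threshold down from the grid maximum and track connected components (6-
connectivity).  A component is *born* at its peak value; when two components
meet, the one with the lower peak *dies* (elder rule) and records the merge
value as its death.  The lifetime ``birth - death`` measures how prominent a
peak is relative to its surroundings, combining score and spatial isolation
in a single quantity.  The globally surviving component's death is the grid
minimum, so a single-peak grid yields one finite lifetime.

Selection is either ``num`` (keep the top-k lifetimes, the known-count
setting) or ``thresh`` (keep lifetimes above a threshold, default 0.2, the
fully automatic setting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NEIGHBORS_6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)
_NEIGHBORS_26 = np.array(
    [
        [i, j, k]
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


@dataclass
class PersistentComponent:
    seed_cell: tuple[int, int, int]
    birth: float
    death: float

    @property
    def lifetime(self) -> float:
        return self.birth - self.death


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, winner: int, loser: int) -> None:
        self.parent[loser] = winner


def persistence_components(
    occupancy: np.ndarray, connectivity: int = 6
) -> list[PersistentComponent]:
    """0-dim superlevel-set persistence of a 3D scalar grid.

    Returns one component per regional-maximum basin, sorted by lifetime
    descending (ties broken by lexicographic seed index).  Equal values are
    processed in lexicographic index order, making the output deterministic.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.ndim != 3:
        raise ValueError("occupancy must be a 3D array")
    if not np.all(np.isfinite(occ)):
        raise ValueError("occupancy must be finite")
    if connectivity == 6:
        offsets = _NEIGHBORS_6
    elif connectivity == 26:
        offsets = _NEIGHBORS_26
    else:
        raise ValueError("connectivity must be 6 or 26")
    shape = np.array(occ.shape)
    flat = occ.ravel()
    # descending by value, ascending lexicographic index among ties
    order = np.lexsort((np.arange(flat.size), -flat))
    rank = np.empty(flat.size, dtype=np.int64)
    rank[order] = np.arange(flat.size)
    uf = _UnionFind(flat.size)
    visited = np.zeros(flat.size, dtype=bool)
    birth_cell: dict[int, int] = {}
    components: list[PersistentComponent] = []
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    for lin in order:
        idx = np.array(np.unravel_index(lin, occ.shape))
        value = flat[lin]
        neighbor_roots: list[int] = []
        for off in offsets:
            nb = idx + off
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            nlin = int(nb @ strides)
            if visited[nlin]:
                root = uf.find(nlin)
                if root not in neighbor_roots:
                    neighbor_roots.append(root)
        visited[lin] = True
        if not neighbor_roots:
            birth_cell[lin] = lin  # a new component is born at its maximum
            continue
        # elder rule: the component with the higher (earlier-processed) peak
        # survives; ties fall back to lexicographic seed order via `rank`
        winner = min(neighbor_roots, key=lambda r: rank[birth_cell[r]])
        uf.union(winner, lin)
        for root in neighbor_roots:
            if root == winner:
                continue
            seed = birth_cell.pop(root)
            if flat[seed] > value:
                # strictly positive lifetime; plateau cells born and merged at
                # the same level are diagonal points of the diagram, dropped
                components.append(
                    PersistentComponent(
                        seed_cell=tuple(int(v) for v in np.unravel_index(seed, occ.shape)),
                        birth=float(flat[seed]),
                        death=float(value),
                    )
                )
            uf.union(winner, root)
    grid_min = float(flat.min())
    for root, seed in birth_cell.items():
        components.append(
            PersistentComponent(
                seed_cell=tuple(int(v) for v in np.unravel_index(seed, occ.shape)),
                birth=float(flat[seed]),
                death=grid_min,
            )
        )
    components.sort(key=lambda c: (-c.lifetime, c.seed_cell))
    return components


def select_detections(
    components: list[PersistentComponent],
    num: int | None = None,
    lifetime_threshold: float | None = None,
) -> list[PersistentComponent]:
    """Keep the top-``num`` components, or all with lifetime > threshold.

    Exactly one of ``num`` / ``lifetime_threshold`` must be given; the
    fully automatic default is a lifetime threshold of 0.2.
    """
    if (num is None) == (lifetime_threshold is None):
        raise ValueError("specify exactly one of num or lifetime_threshold")
    ranked = sorted(components, key=lambda c: (-c.lifetime, c.seed_cell))
    if num is not None:
        if num < 0:
            raise ValueError("num must be >= 0")
        return ranked[:num]
    if lifetime_threshold < 0:
        raise ValueError("lifetime_threshold must be >= 0")
    return [c for c in ranked if c.lifetime > lifetime_threshold]


DEFAULT_LIFETIME_THRESHOLD = 0.2
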