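"""The composite detection training loss.

Six terms supervise the 10-channel prediction grid:

* L1 — weighted binary focal loss on the occupancy channel, handling the
  extreme class imbalance of a grid with a handful of positive cells;
* L2 — debiased entropic optimal transport (Sinkhorn divergence) between the
  normalized occupancy prediction and target viewed as measures on cell
  centers, giving every cell a gradient that scales with its distance to the
  nearest true antibody;
* L3 — mean squared error on the intra-cell offset;
* L4/L5 — direction and in-plane-angle regressors, each a dot-product term
  plus a soft unit-norm penalty ``1 - <v, v*> + (||v|| - 1)^2``;
* L6 — focal loss on the VHH-vs-Fab channel, weighted by the class ratio.

The pose terms L3-L6 are evaluated only at ground-truth occupied cells.
Total: ``L1 + L2 + lam_s * sum_A (L3 + L4 + L5 + L6)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


from .autograd import Tensor, as_tensor
from .codec import TargetGrid

_EPS = 1e-7


@dataclass
class LossWeights:
    gamma: float = 4.0        # focal exponent
    lam: float = 30.0         # positive-class weight in L1
    lam_s: float = 0.2        # weight of the per-cell pose terms
    lam_n: float = 1000.0 / 400.0  # VHH class weight (VHH:Fab corpus ratio)
    ot_blur: float = 8.0      # entropic scale of the Sinkhorn term, Å
    ot_scaling: float = 0.5   # annealing factor of the entropic scale
    ot_final_iters: int = 5   # extra Sinkhorn sweeps at the final scale

    def __post_init__(self) -> None:
        if not (
            self.gamma >= 0
            and self.lam > 0
            and self.lam_s >= 0
            and self.lam_n > 0
            and self.ot_blur > 0
            and 0 < self.ot_scaling < 1
        ):
            raise ValueError("invalid loss weights")


def focal(pred, target, gamma: float, lam: float) -> Tensor:
    """Weighted binary focal loss, elementwise then summed.

    ``-[lam * y * (1-p)^gamma * log p + (1-y) * p^gamma * log(1-p)]``;
    zero when the prediction matches the (clamped) target, positive otherwise.
    """
    p = as_tensor(pred).clip(_EPS, 1 - _EPS)
    y = np.asarray(target, dtype=float)
    pos = (1 - p) ** gamma * p.log() * y * lam
    neg = p**gamma * (1 - p).log() * (1 - y)
    return -(pos + neg).sum()


def l1_occupancy(pred_grid: Tensor, target_grid: TargetGrid, weights: LossWeights) -> Tensor:
    """Focal loss summed over all occupancy cells."""
    pred_occ = pred_grid[0]
    if pred_occ.shape != target_grid.occupancy.shape:
        raise ValueError("prediction and target grids differ in extent")
    return focal(pred_occ, target_grid.occupancy, weights.gamma, weights.lam)


# ---------------------------------------------------------------------------
# Sinkhorn divergence

_cost_cache: dict[tuple, np.ndarray] = {}


def _cell_cost_matrix(shape: tuple[int, int, int], cell_size: float) -> np.ndarray:
    """Pairwise squared distances between cell centers (translation invariant)."""
    key = (shape, round(cell_size, 9))
    if key not in _cost_cache:
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        pts = (idx + 0.5) * cell_size
        diff = pts[:, None, :] - pts[None, :, :]
        _cost_cache[key] = np.einsum("ijk,ijk->ij", diff, diff)
    return _cost_cache[key]


def _eps_schedule(c_max: float, blur: float, scaling: float) -> list[float]:
    target = blur**2
    eps = max(c_max, target)
    out = [eps]
    while eps > target * 1.0001:
        eps = max(eps * scaling**2, target)
        out.append(eps)
    return out


_SINKHORN_TOL = 1e-9


def _soft_min_rows(c: np.ndarray, potential: np.ndarray, log_w: np.ndarray, eps: float) -> np.ndarray:
    """``-eps * logsumexp(log_w + (potential - c)/eps, axis=1)`` (fused)."""
    m = ((potential + eps * log_w)[None, :] - c) / eps
    mmax = m.max(axis=1)
    np.exp(m - mmax[:, None], out=m)
    return -eps * (mmax + np.log(m.sum(axis=1)))


def _sym_potential(
    c: np.ndarray, log_w: np.ndarray, eps_list, n_final: int
) -> np.ndarray:
    """Symmetric Sinkhorn potential for OT_eps(w, w) on one support."""
    f = np.zeros(len(log_w))
    for eps in eps_list:
        f = 0.5 * (f + _soft_min_rows(c, f, log_w, eps))
    eps = eps_list[-1]
    for _ in range(n_final):
        new = 0.5 * (f + _soft_min_rows(c, f, log_w, eps))
        done = np.abs(new - f).max() < _SINKHORN_TOL
        f = new
        if done:
            break
    return f


def _cross_potentials(
    c: np.ndarray, log_a: np.ndarray, log_b: np.ndarray, eps_list, n_final: int
):
    """Symmetrized (Jacobi, averaged) log-domain updates with eps annealing.

    Both potentials are updated simultaneously from the previous iterates, so
    exchanging the two measures exactly mirrors the trajectory: S(a, b) is
    symmetric at any iteration count, and S(a, a) is exactly zero because the
    iterates coincide with the symmetric single-measure problem.
    """
    f = np.zeros(len(log_a))
    g = np.zeros(len(log_b))
    ct = np.ascontiguousarray(c.T)  # lse over predictions = rows of c.T
    for eps in eps_list:
        g_new = 0.5 * (g + _soft_min_rows(ct, f, log_a, eps))
        f_new = 0.5 * (f + _soft_min_rows(c, g, log_b, eps))
        f, g = f_new, g_new
    eps = eps_list[-1]
    for _ in range(n_final):
        g_new = 0.5 * (g + _soft_min_rows(ct, f, log_a, eps))
        f_new = 0.5 * (f + _soft_min_rows(c, g, log_b, eps))
        done = max(np.abs(f_new - f).max(), np.abs(g_new - g).max()) < _SINKHORN_TOL
        f, g = f_new, g_new
        if done:
            break
    return f, g


def sinkhorn_divergence_weights(
    cost: np.ndarray,
    a_weights: np.ndarray,
    b_weights: np.ndarray,
    blur: float,
    scaling: float = 0.5,
    n_final: int = 200,
):
    """Debiased Sinkhorn divergence S(a, b) on a shared support.

    Returns ``(value, grad_a)`` where ``grad_a = f_ab - f_aa`` is the
    gradient of S with respect to the mass vector ``a`` (dual potentials /
    envelope theorem).  Both weight vectors must sum to 1.
    """
    log_a = np.log(np.maximum(a_weights, 1e-300))
    log_b = np.log(np.maximum(b_weights, 1e-300))
    eps_list = _eps_schedule(float(cost.max()), blur, scaling)
    f_ab, g_ab = _cross_potentials(cost, log_a, log_b, eps_list, n_final)
    f_aa = _sym_potential(cost, log_a, eps_list, n_final)
    g_bb = _sym_potential(cost, log_b, eps_list, n_final)
    grad_a = f_ab - f_aa
    grad_b = g_ab - g_bb
    value = float(np.dot(a_weights, grad_a) + np.dot(b_weights, grad_b))
    return value, grad_a, grad_b


def l2_sinkhorn(pred_grid: Tensor, target_grid: TargetGrid, weights: LossWeights) -> Tensor:
    """Sinkhorn divergence between occupancy prediction and target measures.

    Both channel-0 grids are read as nonnegative measures on cell centers
    (a 1e-8 floor guards all-zero predictions), normalized to unit mass.
    Differentiable through the normalization; the transport gradients come
    from the converged dual potentials.
    """
    geometry = target_grid.geometry
    cost = _cell_cost_matrix(geometry.shape, geometry.cell_size)
    pred_flat = pred_grid[0].reshape(-1) + 1e-8
    a = pred_flat * pred_flat.sum() ** -1.0
    b = target_grid.occupancy.reshape(-1) + 1e-8
    b = b / b.sum()
    _, grad_a, grad_b = sinkhorn_divergence_weights(
        cost, a.data, b, weights.ot_blur, weights.ot_scaling, weights.ot_final_iters
    )
    return (a * grad_a).sum() + float(np.dot(b, grad_b))


# ---------------------------------------------------------------------------
# Per-cell pose terms


def l3_offset(pred: Tensor, t_loc: np.ndarray) -> Tensor:
    """Mean squared error of the intra-cell offset (Å)."""
    d = as_tensor(pred) - np.asarray(t_loc, float)
    return (d**2.0).mean()


def _direction_term(pred: Tensor, target: np.ndarray) -> Tensor:
    pred = as_tensor(pred)
    dot = (pred * np.asarray(target, float)).sum()
    norm = ((pred**2.0).sum() + 1e-12) ** 0.5
    return 1.0 - dot + (norm - 1.0) ** 2.0


def l4_direction(pred: Tensor, p_target: np.ndarray) -> Tensor:
    """Direction loss ``1 - <v, p> + (||v|| - 1)^2`` on the 3-vector channel."""
    return _direction_term(pred, p_target)


def l5_angle(pred: Tensor, u_target: np.ndarray) -> Tensor:
    """Same form in 2D against ``u = (cos theta, sin theta)``."""
    return _direction_term(pred, u_target)


def l6_class(pred, is_vhh: float, weights: LossWeights) -> Tensor:
    """Focal loss on the VHH probability with class-ratio weight lam_n."""
    return focal(pred, np.asarray(float(is_vhh)), weights.gamma, weights.lam_n)


def total_loss(
    pred_grid: Tensor, target_grid: TargetGrid, weights: LossWeights | None = None
) -> tuple[Tensor, dict[str, float]]:
    """Composite loss ``L1 + L2 + lam_s * sum_A (L3 + L4 + L5 + L6)``.

    Pose terms are read at ground-truth occupied cells only.  For a map with
    no antibody the transport term is dropped (no target measure exists) and
    the total reduces to the focal term.
    """
    w = weights or LossWeights()
    terms: dict[str, float] = {}
    l1 = l1_occupancy(pred_grid, target_grid, w)
    total = l1
    terms["l1_focal"] = l1.item()
    if target_grid.n_occupied > 0:
        l2 = l2_sinkhorn(pred_grid, target_grid, w)
        total = total + l2
        terms["l2_sinkhorn"] = l2.item()
    else:
        terms["l2_sinkhorn"] = 0.0
    terms["l3_offset"] = terms["l4_direction"] = terms["l5_angle"] = terms["l6_class"] = 0.0
    cells = target_grid.occupied_cells()
    if cells and w.lam_s > 0:
        pose_sum = None
        for cell in cells:
            i, j, k = cell
            v = pred_grid[:, i, j, k]
            tgt = target_grid.channels[:, i, j, k]
            l3 = l3_offset(v[1:4], tgt[1:4])
            l4 = l4_direction(v[4:7], tgt[4:7])
            l5 = l5_angle(v[7:9], tgt[7:9])
            l6 = l6_class(v[9], tgt[9], w)
            for name, t in (("l3_offset", l3), ("l4_direction", l4), ("l5_angle", l5), ("l6_class", l6)):
                terms[name] += t.item()
            cell_sum = l3 + l4 + l5 + l6
            pose_sum = cell_sum if pose_sum is None else pose_sum + cell_sum
        total = total + w.lam_s * pose_sum
    terms["total"] = total.item()
    return total, terms
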