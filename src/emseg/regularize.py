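"""Markov-random-field label regularization via graph cuts.

The boosting scores are turned into a Potts energy over the voxel grid with
6-connectivity:

    E(l) = sum_x u(x, l_x) + sum_{(x,y)} p(x, y) [l_x != l_y]

The unary cost approximates the minus log posterior of the multinomial
logistic model, u(x, a_j) = max f(x) - f(x)[j] (the log-sum-exp is replaced
by the max), so the argmax class always has cost zero.  The pairwise weight
comes from a dedicated two-class border classifier: edges whose endpoints
are confidently on a structure border are cheap to cut,

    p(x, y) = lambda_s * (-log P(border | f(x)) - log P(border | f(y))).

Binary problems are solved exactly by s-t min-cut; the multi-class problem
by alpha-beta swap moves, each solved as a binary min-cut restricted to the
voxels currently carrying either label, accepted only when the true energy
decreases.  Min-cut itself runs on scipy's maximum-flow solver with
adaptively scaled integer capacities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from emseg.piboost import posterior

#: posteriors are clamped here before taking logs (finite edge weights)
PROB_CLAMP = 1e-12
#: integer capacity budget for the max-flow solver (flows are int32)
_CAP_BUDGET = 2 ** 31 - 2 ** 8


@dataclass
class PairwiseField:
    """Per-voxel border cost plus the global smoothness multiplier.

    The weight of the edge between 6-neighbors x and y is
    ``lambda_s * (node_cost[x] + node_cost[y])`` — symmetric by construction.
    """

    node_cost: np.ndarray     # (z, y, x), -log P(border), >= 0
    lambda_s: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.node_cost)):
            raise ValueError("pairwise node costs must be finite")
        if (self.node_cost < 0).any():
            raise ValueError("pairwise node costs must be non-negative")

    def edge_weight(self, flat_a: np.ndarray, flat_b: np.ndarray) -> np.ndarray:
        cost = self.node_cost.ravel()
        return self.lambda_s * (cost[flat_a] + cost[flat_b])


def unary_costs(scores: np.ndarray) -> np.ndarray:
    """u(x, a_j) = max_k f(x)[k] - f(x)[j]; the argmax class costs zero."""
    f = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(f)):
        raise ValueError("scores contain non-finite values")
    return f.max(axis=-1, keepdims=True) - f


def make_border_labels(labels: np.ndarray, width: int = 2,
                       positive_classes: list[int] | None = None) -> np.ndarray:
    """Binary volume marking a thin strip around structure edges.

    The strip is ``dilate(mask, width) & ~erode(mask, width)`` over the union
    of the positive-class masks (6-connected structuring element).
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    labels = np.asarray(labels)
    if positive_classes is None:
        mask = labels > 0
    else:
        mask = np.isin(labels, positive_classes)
    if not mask.any():
        return np.zeros(labels.shape, dtype=bool)
    dil = ndimage.binary_dilation(mask, iterations=width)
    ero = ndimage.binary_erosion(mask, iterations=width)
    return dil & ~ero


def pairwise_costs(border_scores: np.ndarray, lambda_s: float = 1.0
                   ) -> PairwiseField:
    """Edge weights from the 2-class border classifier's scores.

    ``border_scores`` has shape (z, y, x, 2) with class 1 = border.  The
    border posterior is clamped away from zero so weights stay finite.
    """
    f = np.asarray(border_scores, dtype=np.float64)
    if f.shape[-1] != 2:
        raise ValueError("border scores must have two classes")
    p_border = posterior(f)[..., 1]
    node_cost = -np.log(np.clip(p_border, PROB_CLAMP, None))
    return PairwiseField(node_cost, lambda_s)


def grid_edges(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Flat-index endpoint arrays of all 6-neighborhood edges of a grid."""
    idx = np.arange(int(np.prod(shape))).reshape(shape)
    pairs_a, pairs_b = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pairs_a.append(idx[tuple(sl_a)].ravel())
        pairs_b.append(idx[tuple(sl_b)].ravel())
    return np.concatenate(pairs_a), np.concatenate(pairs_b)


def potts_energy(labels: np.ndarray, unary: np.ndarray,
                 pairwise: PairwiseField) -> float:
    """Total Potts energy of a labeling."""
    labels = np.asarray(labels)
    flat_l = labels.ravel()
    flat_u = unary.reshape(-1, unary.shape[-1])
    e_unary = float(flat_u[np.arange(flat_l.size), flat_l].sum())
    a, b = grid_edges(labels.shape)
    w = pairwise.edge_weight(a, b)
    e_pair = float(w[flat_l[a] != flat_l[b]].sum())
    return e_unary + e_pair


def _binary_mincut(u0: np.ndarray, u1: np.ndarray, edges_a: np.ndarray,
                   edges_b: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Exact minimizer of a binary submodular Potts energy.

    ``u0``/``u1`` are per-node costs of labels 0/1; edges pay ``weights``
    when their endpoints disagree.  Returns 0/1 labels per node.
    """
    n = u0.size
    base = np.minimum(u0, u1)
    cap_s = u1 - base          # cut when the node takes label 1
    cap_t = u0 - base          # cut when the node takes label 0
    total = cap_s.sum() + cap_t.sum() + 2 * weights.sum()
    scale = min(2 ** 20, _CAP_BUDGET / max(total, 1e-9))

    src, dst = n, n + 1
    rows = np.concatenate([np.full(n, src), np.arange(n), edges_a, edges_b])
    cols = np.concatenate([np.arange(n), np.full(n, dst), edges_b, edges_a])
    caps = np.concatenate([cap_s, cap_t, weights, weights])
    icaps = np.round(caps * scale).astype(np.int64)
    keep = icaps > 0
    graph = csr_matrix((icaps[keep].astype(np.int32),
                        (rows[keep], cols[keep])), shape=(n + 2, n + 2))
    flow = maximum_flow(graph, src, dst).flow
    residual = graph - flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, src, directed=True,
                                   return_predecessors=False)
    labels = np.ones(n, dtype=np.int64)
    reachable = reachable[reachable < n]
    labels[reachable] = 0
    return labels


def graphcut_two_class(unary2: np.ndarray, pairwise: PairwiseField) -> np.ndarray:
    """Global binary minimizer over the full grid.

    ``unary2`` has shape (z, y, x, 2); the result is a 0/1 volume (1 = the
    positive class of the restricted problem).
    """
    unary2 = np.asarray(unary2, dtype=np.float64)
    if unary2.shape[-1] != 2:
        raise ValueError("two-class unary field required")
    shape = unary2.shape[:-1]
    a, b = grid_edges(shape)
    w = pairwise.edge_weight(a, b)
    flat = unary2.reshape(-1, 2)
    labels = _binary_mincut(flat[:, 0], flat[:, 1], a, b, w)
    return labels.reshape(shape)


def alpha_beta_swap(unary: np.ndarray, pairwise: PairwiseField,
                    init_labels: np.ndarray | None = None,
                    max_sweeps: int = 20) -> np.ndarray:
    """Multi-class Potts minimization by alpha-beta swap moves.

    Starting from the per-voxel unary argmin (the classifier's argmax
    labeling), iterate over class pairs solving a binary min-cut restricted
    to voxels currently labeled alpha or beta.  A swap is accepted only when
    it strictly decreases the true energy; sweeps stop when none does.
    """
    unary = np.asarray(unary, dtype=np.float64)
    c = unary.shape[-1]
    shape = unary.shape[:-1]
    flat_u = unary.reshape(-1, c)
    if init_labels is None:
        labels = np.argmin(flat_u, axis=1)
    else:
        labels = np.asarray(init_labels).ravel().copy()
    a_all, b_all = grid_edges(shape)
    w_all = pairwise.edge_weight(a_all, b_all)
    energy = _flat_energy(labels, flat_u, a_all, b_all, w_all)

    for _ in range(max_sweeps):
        improved = False
        for alpha, beta in combinations(range(c), 2):
            in_set = (labels == alpha) | (labels == beta)
            if not in_set.any():
                continue
            nodes = np.nonzero(in_set)[0]
            remap = np.full(labels.size, -1, dtype=np.int64)
            remap[nodes] = np.arange(nodes.size)
            # edges with neighbors outside {alpha, beta} contribute the same
            # Potts cost for either choice, so only in-set edges matter
            both_in = in_set[a_all] & in_set[b_all]
            ea, eb = remap[a_all[both_in]], remap[b_all[both_in]]
            ew = w_all[both_in]
            sub = _binary_mincut(flat_u[nodes, alpha], flat_u[nodes, beta],
                                 ea, eb, ew)
            candidate = labels.copy()
            candidate[nodes] = np.where(sub == 0, alpha, beta)
            cand_energy = _flat_energy(candidate, flat_u, a_all, b_all, w_all)
            if cand_energy < energy - 1e-12:
                labels = candidate
                energy = cand_energy
                improved = True
        if not improved:
            break
    return labels.reshape(shape)


def _flat_energy(labels, flat_u, a, b, w) -> float:
    e = float(flat_u[np.arange(labels.size), labels].sum())
    return e + float(w[labels[a] != labels[b]].sum())


def regularize_two_class_mode(scores: np.ndarray, pairwise: PairwiseField
                              ) -> np.ndarray:
    """One-vs-rest binary graph cuts for every positive class.

    Each positive class j is cut against the rest with
    u(x, j) = max f - f[j] and u(x, rest) = max f - max_{k != j} f[k].
    When several one-vs-rest problems claim the same voxel, the class with
    the larger score component wins (consistent with the argmax rule).
    """
    f = np.asarray(scores, dtype=np.float64)
    c = f.shape[-1]
    shape = f.shape[:-1]
    fmax = f.max(axis=-1)
    out = np.zeros(shape, dtype=np.int64)
    best_score = np.full(shape, -np.inf)
    for j in range(1, c):
        rest = np.delete(f, j, axis=-1).max(axis=-1)
        unary2 = np.stack([fmax - rest, fmax - f[..., j]], axis=-1)
        pos = graphcut_two_class(unary2, pairwise).astype(bool)
        claim = pos & (f[..., j] > best_score)
        out[claim] = j
        best_score[claim] = f[..., j][claim]
    return out
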