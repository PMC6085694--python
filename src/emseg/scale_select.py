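"""Greedy multi-class boosting selection of GRIMS scales.

Structures of interest (mitochondria, synapses, membranes) live at very
different sizes, and cross-validating over candidate scale subsets is
prohibitively expensive.  Instead, a boosting round is played over the
candidate scales themselves: each candidate contributes the 5-component
GRIMS block at its sigma, each separator (one-vs-rest binary problem of the
multi-class coding) trains a shallow tree on that block under the current
sample weights, and the candidate with the smallest combined weighted error
wins the round.  The winning learners then update each separator's weights
with the boosting rule, so subsequent rounds favour scales carrying
information *independent* of those already chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emseg.channels import GrimsConfig, grims_channels
from emseg.piboost import ClassCode, WeakTree, _one_vs_rest_groups, optimal_beta
from emseg.stack_io import VoxelStack


@dataclass
class ScaleCandidateSet:
    """Per-candidate 5-column GRIMS feature blocks for the training voxels.

    ``blocks[j]`` has shape (n_samples, 5) and holds the GRIMS 5-vector at
    scale ``scales[j]`` for every training voxel.
    """

    scales: list[float]
    blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.blocks):
            raise ValueError("one block per candidate scale required")
        for s, b in zip(self.scales, self.blocks):
            if b.ndim != 2 or b.shape[1] != 5:
                raise ValueError(f"block for scale {s} must be (n, 5), got {b.shape}")


@dataclass
class SelectionResult:
    """Scales in pick order with the per-round errors behind each pick."""

    scales: list[float]
    errors: list[float]                      # combined weighted error per pick
    separator_errors: list[list[float]]      # per-pick, per-separator errors


def candidate_blocks(stack: VoxelStack, voxels: np.ndarray,
                     scales: list[float], spacing_aware: bool = False
                     ) -> ScaleCandidateSet:
    """Sample GRIMS 5-vectors at the given voxels for every candidate scale.

    Channels are computed one scale at a time and immediately reduced to the
    sampled voxels, so the full candidate grid never has to be resident.
    """
    voxels = np.asarray(voxels)
    blocks = []
    for sigma in scales:
        cs = grims_channels(stack, GrimsConfig([sigma], spacing_aware))
        block = cs.channels[:, voxels[:, 0], voxels[:, 1], voxels[:, 2]].T
        blocks.append(np.ascontiguousarray(block))
    return ScaleCandidateSet(list(scales), blocks)


def default_grid(start: float = 1.0, stop: float = 50.0, count: int = 50
                 ) -> list[float]:
    """Equally distributed candidate scales, endpoints inclusive.

    The default is 50 values from 1 to 50 (step 1).  An alternative finer
    grid in 0.4 steps (``default_grid(0.4, 20.0, 50)``) is useful when the
    target structures are only a few voxels across.
    """
    return list(np.linspace(start, stop, count))


def select_scales(candidates: ScaleCandidateSet, labels: np.ndarray, k: int = 4,
                  tree_depth: int = 2, seed: int = 0) -> SelectionResult:
    """Greedily pick ``k`` distinct scales with smallest weighted error.

    Each round trains one depth-limited tree per separator on every
    still-unselected candidate block, scores the candidate by the sum of the
    separators' weighted training errors, picks the argmin (ties to the
    smaller sigma), and updates each separator's weights with its own winning
    learner so the next round looks for complementary information.
    """
    y = np.asarray(labels)
    n_cand = len(candidates.scales)
    if n_cand < 1:
        raise ValueError("need at least one candidate scale")
    if not (1 <= k <= n_cand):
        raise ValueError(f"k={k} out of range for {n_cand} candidates")
    c = int(y.max() + 1)
    if c < 2:
        raise ValueError("need at least two classes")
    code = ClassCode(c)
    groups = _one_vs_rest_groups(c)
    n = y.size
    rng = np.random.default_rng(seed)

    sep_state = []
    for group in groups:
        v = code.group_vector(group)
        sep_state.append({
            "group": group,
            "w": np.full(n, 1.0 / n),
            "target": np.where(np.isin(y, group), 1.0, -1.0),
            "class_margin": code.label_vectors @ v,
        })

    order = np.argsort(candidates.scales)  # tie rule: smaller sigma first
    selected: list[int] = []
    errors: list[float] = []
    sep_errors_out: list[list[float]] = []

    for _ in range(k):
        best = None
        for j in order:
            if j in selected:
                continue
            X = candidates.blocks[j]
            trees, errs = [], []
            for st in sep_state:
                tree = WeakTree.fit(X, st["target"], max_depth=tree_depth,
                                    seed=int(rng.integers(2 ** 31 - 1)))
                h = tree.predict(X)
                err = float(np.dot(st["w"], h != st["target"]))
                trees.append((tree, h))
                errs.append(err)
            combined = float(sum(errs))
            if best is None or combined < best[0]:
                best = (combined, j, trees, errs)
        combined, j_star, trees, errs = best
        selected.append(int(j_star))
        errors.append(combined)
        sep_errors_out.append(errs)
        # boosting-style re-weighting with each separator's own winning tree
        for st, (tree, h) in zip(sep_state, trees):
            z = h * st["class_margin"][y]
            beta = optimal_beta(st["w"], z)
            w_new = st["w"] * np.exp(-beta * z)
            st["w"] = w_new / w_new.sum()

    return SelectionResult([candidates.scales[j] for j in selected],
                           errors, sep_errors_out)
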