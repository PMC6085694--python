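"""Multi-class boosting with binary weak-learners.

The classifier keeps a vector-valued additive model f(x) in R^c obeying the
sum-to-zero condition f(x)' 1 = 0.  Each boosting iteration trains, for every
*separator* (here: one positive group of classes against the rest, restricted
to one-vs-rest singletons), a binary decision tree h(x) in {-1, +1}.  The
tree's vote enters the model through the group response vector v_A, which is
+1/|A| on the group and -1/(c - |A|) off it, scaled by a coefficient beta:

    f_m(x) = f_{m-1}(x) + beta_m * h_m(x) * v_A

beta minimizes the weighted vector-exponential loss

    L(beta) = sum_i w_i * exp(-beta * z_i),      z_i = y_{l_i}' (h(x_i) v_A)

where y_l is the sum-to-zero margin coding of the true class (+1 at l,
-1/(c-1) elsewhere).  Sample weights are then updated multiplicatively with
exp(-beta z_i) and renormalized, so each separator concentrates on the
samples it still gets wrong.  A voxel is finally assigned to the class with
the maximum component of f(x) (ties to the lowest index, background first).

Weak-learners are trained on a weighted sub-sample (default 10% of the data,
drawn without replacement proportionally to the weights), which prioritizes
hard examples and keeps training affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.tree import DecisionTreeClassifier

#: beta is capped here when a weak-learner separates its sample perfectly
#: (the loss then decreases monotonically in beta and has no finite argmin).
BETA_CAP = 15.0


@dataclass
class ClassCode:
    """Sum-to-zero margin coding for ``c`` classes.

    ``label_vectors[l]`` has +1 at position ``l`` and ``-1/(c-1)`` elsewhere,
    so every row sums to zero.
    """

    c: int

    def __post_init__(self) -> None:
        if self.c < 2:
            raise ValueError("need at least two classes")
        self.label_vectors = np.full((self.c, self.c), -1.0 / (self.c - 1))
        np.fill_diagonal(self.label_vectors, 1.0)

    def group_vector(self, group: tuple[int, ...]) -> np.ndarray:
        """Response vector v_A: +1/|A| on the group, -1/(c-|A|) off it."""
        v = np.full(self.c, -1.0 / (self.c - len(group)))
        v[list(group)] = 1.0 / len(group)
        return v


class WeakTree:
    """A depth-limited binary decision tree exported to plain arrays.

    Fitting goes through scikit-learn; prediction is a vectorized node
    descent over the exported arrays so that models round-trip exactly
    through JSON.
    """

    __slots__ = ("children_left", "children_right", "feature", "threshold", "leaf_sign")

    def __init__(self, children_left, children_right, feature, threshold, leaf_sign):
        self.children_left = np.asarray(children_left, dtype=np.int64)
        self.children_right = np.asarray(children_right, dtype=np.int64)
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.leaf_sign = np.asarray(leaf_sign, dtype=np.float64)

    @classmethod
    def fit(cls, X: np.ndarray, t: np.ndarray, max_depth: int, seed: int,
            max_features: int | None = None) -> "WeakTree":
        """Fit on binary targets t in {-1, +1}.

        ``max_features`` limits the split search to a random feature subset
        per node (the pooled-feature bank is highly redundant, so this
        sacrifices little accuracy for a large training speedup).
        """
        if max_features is not None:
            max_features = min(max_features, X.shape[1])
        clf = DecisionTreeClassifier(max_depth=max_depth, random_state=seed,
                                     max_features=max_features)
        clf.fit(X, t)
        tree = clf.tree_
        counts = tree.value[:, 0, :] if tree.value.ndim == 3 else tree.value
        winner = clf.classes_[np.argmax(counts, axis=1)]
        return cls(tree.children_left, tree.children_right, tree.feature,
                   tree.threshold, winner.astype(np.float64))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorized descent; returns values in {-1, +1}."""
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        active = self.children_left[node] >= 0
        while active.any():
            idx = np.nonzero(active)[0]
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.children_left[cur],
                                 self.children_right[cur])
            active[idx] = self.children_left[node[idx]] >= 0
        return self.leaf_sign[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "leaf_sign": self.leaf_sign.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeakTree":
        return cls(d["children_left"], d["children_right"], d["feature"],
                   d["threshold"], d["leaf_sign"])


@dataclass
class Separator:
    """One positive group of classes, its response vector and learner stack."""

    group: tuple[int, ...]
    v: np.ndarray
    learners: list[tuple[WeakTree, float]] = field(default_factory=list)


@dataclass
class BoostConfig:
    """Training hyperparameters; defaults follow the experimental protocol
    (50 iterations of depth-10 trees, 10% weighted sub-sampling)."""

    n_iterations: int = 50
    tree_depth: int = 10
    subsample_fraction: float = 0.10
    #: random feature subset searched per split; None searches all features
    max_features: int | None = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class BoostEnsemble:
    """Trained additive model: one learner stack per separator."""

    code: ClassCode
    separators: list[Separator]
    config: BoostConfig
    class_names: list[str] | None = None
    loss_history: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return self.code.c

    def to_dict(self) -> dict:
        return {
            "n_classes": self.code.c,
            "class_names": self.class_names,
            "config": {
                "n_iterations": self.config.n_iterations,
                "tree_depth": self.config.tree_depth,
                "subsample_fraction": self.config.subsample_fraction,
                "max_features": self.config.max_features,
                "seed": self.config.seed,
            },
            "separators": [
                {
                    "group": list(sep.group),
                    "learners": [
                        {"tree": tree.to_dict(), "beta": float(beta)}
                        for tree, beta in sep.learners
                    ],
                }
                for sep in self.separators
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostEnsemble":
        code = ClassCode(d["n_classes"])
        seps = []
        for s in d["separators"]:
            group = tuple(s["group"])
            sep = Separator(group, code.group_vector(group))
            sep.learners = [(WeakTree.from_dict(e["tree"]), float(e["beta"]))
                            for e in s["learners"]]
            seps.append(sep)
        cfg = BoostConfig(**d["config"])
        return cls(code, seps, cfg, d.get("class_names"))


def _one_vs_rest_groups(c: int) -> list[tuple[int, ...]]:
    # for c == 2 the two singleton groups coincide up to sign: keep one
    if c == 2:
        return [(1,)]
    return [(l,) for l in range(c)]


def optimal_beta(weights: np.ndarray, margins: np.ndarray,
                 cap: float = BETA_CAP) -> float:
    """Minimizer over [0, cap] of L(beta) = sum_i w_i exp(-beta z_i).

    An uninformative learner (weighted error 1/2 under symmetric margins)
    yields beta = 0, i.e. no model change; a perfect learner hits the cap.
    """
    def loss(beta: float) -> float:
        return float(np.dot(weights, np.exp(-beta * margins)))

    res = minimize_scalar(loss, bounds=(0.0, cap), method="bounded",
                          options={"xatol": 1e-12})
    beta = float(res.x)
    # the bounded solver never returns the exact endpoints; snap when flat
    for endpoint in (0.0, cap):
        if loss(endpoint) <= res.fun + 1e-15:
            return endpoint
    return beta


def fit(features: np.ndarray, labels: np.ndarray, config: BoostConfig | None = None,
        n_classes: int | None = None,
        class_names: list[str] | None = None) -> BoostEnsemble:
    """Train the multi-class boosting ensemble.

    Parameters
    ----------
    features:
        (n_samples, n_features) matrix; must be finite.
    labels:
        Integer class per sample in ``0..c-1``; every class must appear.
    config:
        :class:`BoostConfig`; defaults used when omitted.
    n_classes:
        Total class count; inferred as ``labels.max() + 1`` when omitted.
    """
    config = config or BoostConfig()
    X = np.asarray(features)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    c = int(n_classes if n_classes is not None else y.max() + 1)
    present = np.unique(y)
    if c < 2:
        raise ValueError("need at least two classes")
    if len(present) != c or present[0] != 0 or present[-1] != c - 1:
        raise ValueError(f"all {c} classes must appear in training data, "
                         f"found {present.tolist()}")
    code = ClassCode(c)
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]

    separators = []
    states = []  # (weights, in_group margin per class)
    for group in _one_vs_rest_groups(c):
        sep = Separator(group, code.group_vector(group))
        separators.append(sep)
        # margin of a sample of class l when the tree votes +1:
        #   y_l' v_A  (sign flips with the vote)
        class_margin = code.label_vectors @ sep.v
        states.append({"w": np.full(n, 1.0 / n), "class_margin": class_margin,
                       "loss": 1.0})

    loss_history = []
    m_sub = max(1, int(round(config.subsample_fraction * n)))
    for _ in range(config.n_iterations):
        for sep, st in zip(separators, states):
            w = st["w"]
            idx = _weighted_subsample(rng, w, m_sub)
            target = np.where(np.isin(y[idx], sep.group), 1.0, -1.0)
            tree = WeakTree.fit(X[idx], target,
                                max_depth=config.tree_depth,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                max_features=config.max_features)
            h = tree.predict(X)
            z = h * st["class_margin"][y]
            beta = optimal_beta(w, z)
            sep.learners.append((tree, beta))
            w_new = w * np.exp(-beta * z)
            Z = w_new.sum()
            st["loss"] *= Z
            st["w"] = w_new / Z
        loss_history.append(sum(st["loss"] for st in states))

    return BoostEnsemble(code, separators, config, class_names,
                         np.asarray(loss_history))


def _weighted_subsample(rng: np.random.Generator, w: np.ndarray, m: int) -> np.ndarray:
    """Sample m indices without replacement, proportional to the weights."""
    p = np.maximum(w, 0.0)
    total = p.sum()
    if total <= 0:
        p = np.full_like(w, 1.0 / len(w))
    else:
        p = p / total
    nonzero = int(np.count_nonzero(p))
    if nonzero < m:
        # too few samples carry weight: take all of them plus uniform filler
        extra = rng.choice(len(w), size=m - nonzero, replace=False)
        return np.unique(np.concatenate([np.nonzero(p)[0], extra]))
    return rng.choice(len(w), size=m, replace=False, p=p)


try:
    from numba import njit

    @njit(cache=True)
    def _descend_forest(CL, CR, FT, TH, LS, X, out):  # pragma: no cover
        n = X.shape[0]
        T = CL.shape[0]
        for i in range(n):
            for t in range(T):
                node = 0
                while CL[t, node] >= 0:
                    if X[i, FT[t, node]] <= TH[t, node]:
                        node = CL[t, node]
                    else:
                        node = CR[t, node]
                out[t, i] = LS[t, node]

except ImportError:  # pragma: no cover
    _descend_forest = None


def _forest_votes(trees: list[WeakTree], X: np.ndarray) -> np.ndarray:
    """(n_trees, n_samples) votes in {-1, +1}, all trees advanced together.

    Stacking the node arrays lets one descent pass serve the whole forest,
    which is what makes dense voxel scoring affordable.  A compiled
    sample-major kernel is used when available (each sample's feature row
    stays cache-resident while every tree walks it); a vectorized numpy
    level-by-level descent is the fallback.
    """
    T, N = len(trees), X.shape[0]
    max_nodes = max(t.feature.size for t in trees)
    CL = np.full((T, max_nodes), -1, dtype=np.int32)
    CR = np.full((T, max_nodes), -1, dtype=np.int32)
    FT = np.zeros((T, max_nodes), dtype=np.int32)
    # thresholds stay float64: sklearn's split rule compares float32 data
    # against float64 midpoints, and rounding them would misroute boundary
    # samples
    TH = np.zeros((T, max_nodes), dtype=np.float64)
    LS = np.zeros((T, max_nodes), dtype=np.float32)
    for t, tree in enumerate(trees):
        m = tree.feature.size
        CL[t, :m] = tree.children_left
        CR[t, :m] = tree.children_right
        FT[t, :m] = np.maximum(tree.feature, 0)
        TH[t, :m] = tree.threshold
        LS[t, :m] = tree.leaf_sign
    if _descend_forest is not None:
        Xc = np.ascontiguousarray(X, dtype=np.float32)
        out = np.empty((T, N), dtype=np.float32)
        _descend_forest(CL, CR, FT, TH, LS, Xc, out)
        return out.astype(np.float64)
    CLf, CRf = CL.ravel(), CR.ravel()
    FTf, THf, LSf = FT.ravel(), TH.ravel(), LS.ravel()
    base = (np.arange(T, dtype=np.int64) * max_nodes)[:, None]
    node = np.zeros((T, N), dtype=np.int64)
    rows = np.arange(N)
    while True:
        fi = node + base
        cl = CLf[fi]
        internal = cl >= 0
        if not internal.any():
            return LSf[fi]
        xv = X[rows[None, :], FTf[fi]]
        go_left = xv <= THf[fi]
        nxt = np.where(go_left, cl, CRf[fi])
        node = np.where(internal, nxt, node)


def predict_scores(ensemble: BoostEnsemble, features: np.ndarray) -> np.ndarray:
    """Evaluate the additive model: (n_samples, c) score matrix.

    Scores satisfy the sum-to-zero condition per sample by construction.
    """
    X = np.asarray(features)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    f = np.zeros((X.shape[0], ensemble.n_classes))
    if X.shape[0] == 0:
        return f
    X = np.ascontiguousarray(X, dtype=np.float32)
    for sep in ensemble.separators:
        if not sep.learners:
            continue
        n_feat = _tree_width(sep.learners[0][0])
        if n_feat is not None and X.shape[1] <= n_feat:
            raise ValueError(
                f"feature width {X.shape[1]} incompatible with trained trees")
        votes = _forest_votes([tree for tree, _ in sep.learners], X)
        betas = np.array([beta for _, beta in sep.learners])
        acc = betas @ votes
        f += acc[:, None] * sep.v[None, :]
    return f


def _tree_width(tree: WeakTree) -> int | None:
    used = tree.feature[tree.feature >= 0]
    return int(used.max()) if used.size else None


def predict_class(scores: np.ndarray) -> np.ndarray:
    """Argmax class per sample; ties resolve to the lowest class index."""
    scores = np.asarray(scores)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    return np.argmax(scores, axis=-1)


def posterior(scores: np.ndarray) -> np.ndarray:
    """Multinomial-logistic class posteriors: softmax of f with
    max-subtraction for numerical stability."""
    scores = np.asarray(scores, dtype=np.float64)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def fit_border_classifier(features: np.ndarray, border_labels: np.ndarray,
                          config: BoostConfig | None = None) -> BoostEnsemble:
    """Two-class ensemble scoring border vs non-border voxels.

    ``border_labels`` is binary with 1 = border; class 1 of the returned
    ensemble is the border class, so P(border) = posterior(f)[..., 1].
    """
    border_labels = np.asarray(border_labels)
    if not np.isin(border_labels, (0, 1)).all():
        raise ValueError("border labels must be binary")
    return fit(features, border_labels.astype(np.int64), config,
               n_classes=2, class_names=["no_border", "border"])


def balance_training_set(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices keeping all positive-class samples and a random half of the
    background (class-0) samples; counters background dominance."""
    labels = np.asarray(labels)
    bg = np.nonzero(labels == 0)[0]
    pos = np.nonzero(labels != 0)[0]
    if bg.size == 0:
        return np.arange(labels.size)
    keep_bg = rng.choice(bg, size=bg.size // 2, replace=False)
    return np.sort(np.concatenate([pos, keep_bg]))
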