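"""k-means for longitudinal percent-reduction trajectories.

A from-scratch Lloyd's algorithm over the per-patient vectors of corrected
percent reductions at the follow-up weeks (week 0 is identically zero and is
excluded as uninformative). Each restart begins from a *uniform random
assignment* of patients to clusters — matching the "assign arbitrarily, then
iterate centroid update / nearest-centroid reassignment until convergence"
description of longitudinal k-means — and the best of ``n_restarts`` runs by
within-cluster sum of squares is kept. The cluster count is chosen over
k = 2..6 by maximising the Calinski-Harabasz index.

Distances are plain Euclidean: all dimensions share units of percent, so no
standardisation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTableError, InvalidKError
from .metrics import TrajectoryMatrix


def _as_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, TrajectoryMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


@dataclass
class ClusterModel:
    """A fitted k-means partition of the trajectory matrix."""

    k: int
    centroids: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,) integers in [0, k)
    objective: float  # total within-cluster sum of squared distances
    ch_index: float
    n_restarts: int = 1
    restart_objectives: list[float] = field(default_factory=list)
    seed: int | None = None
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "centroids": self.centroids.tolist(),
            "objective": float(self.objective),
            "ch_index": float(self.ch_index),
            "n_restarts": int(self.n_restarts),
            "restart_objectives": [float(o) for o in self.restart_objectives],
            "seed": self.seed,
            "n_iter": int(self.n_iter),
            "cluster_sizes": np.bincount(self.assignments, minlength=self.k).tolist(),
        }


def _objective(X: np.ndarray, centroids: np.ndarray, assign: np.ndarray) -> float:
    return float(((X - centroids[assign]) ** 2).sum())


def kmeans_single(
    matrix,
    k: int,
    init_assignments,
    max_iter: int = 200,
) -> ClusterModel:
    """One Lloyd run from an explicit initial assignment.

    Alternates centroid update (cluster mean) and nearest-centroid
    reassignment under squared Euclidean distance until the assignment vector
    is a fixed point or ``max_iter`` is reached. An emptied cluster is
    re-seeded with the point currently farthest from its own centroid. The
    objective is non-increasing across iterations.
    """
    X = _as_matrix(matrix)
    n = X.shape[0]
    if k < 1 or k > n:
        raise InvalidKError(f"k={k} incompatible with n={n}")
    assign = np.asarray(init_assignments, dtype=int).copy()
    if assign.shape != (n,):
        raise InvalidKError("init_assignments must have one entry per patient")
    if len(np.unique(assign)) != k or assign.min() < 0 or assign.max() >= k:
        raise InvalidKError("init_assignments must cover all k clusters")

    centroids = np.empty((k, X.shape[1]))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for c in range(k):
            members = assign == c
            if members.any():
                centroids[c] = X[members].mean(axis=0)
            else:
                # Re-seed an emptied cluster with the worst-fitted point.
                dist_own = ((X - centroids[assign]) ** 2).sum(axis=1)
                far = int(np.argmax(dist_own))
                centroids[c] = X[far]
                assign[far] = c
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    obj = _objective(X, centroids, assign)
    ch = calinski_harabasz(X, assign) if len(np.unique(assign)) >= 2 and n > k else np.nan
    return ClusterModel(
        k=k,
        centroids=centroids.copy(),
        assignments=assign,
        objective=obj,
        ch_index=ch,
        n_iter=n_iter,
    )


def random_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random initial assignment guaranteed to cover all k clusters."""
    assign = rng.integers(0, k, size=n)
    anchors = rng.permutation(n)[:k]
    assign[anchors] = np.arange(k)
    return assign


def kml_fit(
    matrix,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
) -> ClusterModel:
    """Best-of-``n_restarts`` k-means, each restart from an independent
    uniform random assignment. Ties in the final objective are broken by the
    smaller restart index; the same seed always returns the same model."""
    X = _as_matrix(matrix)
    if n_restarts < 1:
        raise InvalidKError("n_restarts must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best: ClusterModel | None = None
    objectives: list[float] = []
    for child in children:
        rng = np.random.default_rng(child)
        init = random_assignments(X.shape[0], k, rng)
        model = kmeans_single(X, k, init, max_iter=max_iter)
        objectives.append(model.objective)
        if best is None or model.objective < best.objective - 1e-12:
            best = model
    assert best is not None
    best.n_restarts = n_restarts
    best.restart_objectives = objectives
    best.seed = seed
    return best


def calinski_harabasz(matrix, assignments) -> float:
    """Calinski-Harabasz index: [tr(B)/(k-1)] / [tr(W)/(n-k)].

    ``B`` is the between-cluster scatter (cluster sizes times squared
    distances of centroids to the grand mean) and ``W`` the within-cluster
    scatter. Larger values indicate tighter, better-separated clusters. A
    partition with zero within-cluster scatter returns +inf with a warning.
    """
    X = _as_matrix(matrix)
    labels = np.asarray(assignments, dtype=int)
    uniq = np.unique(labels)
    k, n = len(uniq), X.shape[0]
    if k < 2:
        raise DegenerateTableError("Calinski-Harabasz undefined for k < 2")
    if n <= k:
        raise DegenerateTableError("Calinski-Harabasz requires n > k")
    grand = X.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for c in uniq:
        members = X[labels == c]
        centroid = members.mean(axis=0)
        tr_b += len(members) * float(((centroid - grand) ** 2).sum())
        tr_w += float(((members - centroid) ** 2).sum())
    if tr_w == 0.0:
        warnings.warn(
            "zero within-cluster scatter; Calinski-Harabasz index is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return (tr_b / (k - 1)) / (tr_w / (n - k))


@dataclass
class ModelSelection:
    """Best model per candidate k and the k maximising the CH index."""

    candidate_models: dict[int, ClusterModel]
    selected_k: int

    @property
    def selected(self) -> ClusterModel:
        return self.candidate_models[self.selected_k]

    def to_dict(self) -> dict:
        return {
            "selected_k": int(self.selected_k),
            "candidates": {str(k): m.to_dict() for k, m in self.candidate_models.items()},
        }


def select_k(
    matrix,
    k_range=range(2, 7),
    n_restarts: int = 20,
    seed: int = 0,
) -> ModelSelection:
    """Fit each candidate k and select the argmax of the CH index.

    Ties are broken toward smaller k (parsimony). Each k gets an independent
    RNG stream derived from ``seed`` so results are stable under changes to
    the candidate range."""
    X = _as_matrix(matrix)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or max(ks) >= X.shape[0]:
        raise InvalidKError("max(k_range) must be < n_patients")
    children = np.random.SeedSequence((seed, 0x6B6D6C)).spawn(len(ks))
    candidates: dict[int, ClusterModel] = {}
    best_k = None
    for k, child in zip(ks, children):
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        model = kml_fit(X, k, n_restarts=n_restarts, seed=sub_seed)
        candidates[k] = model
        if best_k is None or model.ch_index > candidates[best_k].ch_index:
            best_k = k
    assert best_k is not None
    return ModelSelection(candidate_models=candidates, selected_k=best_k)


def label_trajectories(model: ClusterModel) -> dict[int, str]:
    """Name clusters by their final-week centroid.

    For k = 2 the cluster with the larger final-week centroid is ``"high"``
    and the other ``"low"``; for k > 2 clusters are ranked ascending by
    final-week centroid and named ``cluster_1 .. cluster_k``. Exact ties are
    broken by the preceding weeks' centroids (final week first, then earlier
    weeks in reverse order).
    """
    # lexsort: last key is primary -> final week dominates, earlier weeks break ties
    keys = tuple(model.centroids[:, j] for j in range(model.centroids.shape[1]))
    order = np.lexsort(keys)  # ascending by final week, ties by earlier weeks
    if model.k == 2:
        names = ["low", "high"]
    else:
        names = [f"cluster_{r + 1}" for r in range(model.k)]
    return {int(c): names[rank] for rank, c in enumerate(order)}


def assignment_labels(model: ClusterModel) -> np.ndarray:
    """Per-patient string labels under :func:`label_trajectories`."""
    mapping = label_trajectories(model)
    return np.asarray([mapping[int(c)] for c in model.assignments], dtype=object)
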