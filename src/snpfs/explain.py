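"""Feature assessments: permutation importance, kernel SHAP, SHAP clustering.

The kernel SHAP solver here is model-agnostic: the Shapley value of feature
i for one prediction is recovered by solving the weighted least-squares
system over feature coalitions z, with the kernel weight

    w(z) = (M - 1) / (C(M, |z|) * |z| * (M - |z|)),   0 < |z| < M,

where absent features are imputed by averaging the model output over a
weighted background (k-means centroids of the training set), and the sum
constraint base_value + sum(phi) = f(x) (local accuracy) is imposed by
eliminating one unknown. With all 2^M coalitions enumerated the solution is
the exact Shapley value; with sampled coalitions (paired with complements)
it is an estimate that still satisfies local accuracy by construction.

Well-predicted cases are then clustered on their SHAP vectors (k selected by
the Dunn index unless overridden) to dissect heterogeneity: which SNPs drive
the model's output for which subgroup of cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import accuracy_score, r2_score


# ---------------------------------------------------------------------------
# Well-predicted case selection


def select_well_predicted(
    predictions: np.ndarray,
    truth: np.ndarray,
    mode: str,
    case_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of cases the model predicts well.

    Classification: cases (truth == 1) whose predicted probability crosses
    the 0.5 threshold. Regression: among case rows (``case_mask``, all rows
    if omitted), those in the bottom quartile of |observed - predicted|;
    ties at the quartile boundary are all included, so the count may exceed
    ceil(n/4).
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if mode == "classification":
        idx = np.flatnonzero((truth == 1) & (predictions >= 0.5))
    elif mode == "regression":
        cases = (
            np.flatnonzero(np.asarray(case_mask).astype(bool))
            if case_mask is not None
            else np.arange(len(truth))
        )
        if len(cases) == 0:
            raise ValueError("empty case set")
        err = np.abs(truth[cases] - predictions[cases])
        k = int(np.ceil(len(cases) / 4))
        cutoff = np.sort(err)[k - 1]
        idx = cases[err <= cutoff]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(idx) == 0:
        raise ValueError("empty case set")
    return idx


# ---------------------------------------------------------------------------
# Permutation importance


@dataclass
class ImportanceTable:
    table: pd.DataFrame  # feature, mean_drop, std
    n_repeats: int
    metric: str


def permutation_importance(
    model, X: np.ndarray, y: np.ndarray, metric: str = "accuracy",
    n_repeats: int = 10, seed: int = 0,
) -> ImportanceTable:
    """Mean drop in held-out score when one feature column is shuffled.

    The model is already fitted elsewhere; shuffling happens within the
    evaluation set, per repeat, with a seeded generator.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to permute")

    def score(Xs):
        pred = model.predict(Xs)
        return accuracy_score(y, pred) if metric == "accuracy" else r2_score(y, pred)

    rng = np.random.default_rng(seed)
    baseline = score(X)
    # one shuffle per repeat, shared across features: importances are then
    # exactly invariant to the order of the feature columns
    perms = [rng.permutation(X.shape[0]) for _ in range(n_repeats)]
    rows = []
    for j in range(X.shape[1]):
        drops = []
        for perm in perms:
            Xp = X.copy()
            Xp[:, j] = Xp[perm, j]
            drops.append(baseline - score(Xp))
        rows.append((j, float(np.mean(drops)), float(np.std(drops))))
    table = pd.DataFrame(rows, columns=["feature", "mean_drop", "std"])
    return ImportanceTable(table, n_repeats, metric)


# ---------------------------------------------------------------------------
# Dunn index and k selection


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Minimum inter-cluster distance over maximum intra-cluster diameter.

    Single-linkage inter-cluster distance and complete diameter, Euclidean.
    If every cluster is a singleton (all diameters 0) the index is +inf.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    groups = [points[labels == u] for u in uniq]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty cluster")
    min_inter = min(
        cdist(a, b).min() for a, b in combinations(groups, 2)
    )
    max_diam = max(pdist(g).max() if len(g) > 1 else 0.0 for g in groups)
    if max_diam == 0.0:
        return float("inf")
    return float(min_inter / max_diam)


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    dunn: float
    seed: int


def select_k_by_dunn(
    points: np.ndarray, k_range, seed: int = 0, n_init: int = 10
) -> tuple[int, ClusterAssignment, pd.DataFrame]:
    """k-means for each k in range; keep the k with the highest Dunn index.

    Ties go to the smallest k. Returns (k, assignment, report of Dunn vs k) —
    the report is always produced so the choice can be inspected.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k range")
    points = np.asarray(points, dtype=float)
    best = None
    rows = []
    for k in sorted(k_range):
        if not 2 <= k <= len(points) - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
        d = dunn_index(points, km.labels_)
        rows.append((k, d))
        if best is None or d > best[1]:
            best = (k, d, km.labels_)
    k, d, labels = best
    return k, ClusterAssignment(labels, k, d, seed), pd.DataFrame(rows, columns=["k", "dunn"])


# ---------------------------------------------------------------------------
# Kernel SHAP


@dataclass
class Background:
    """Weighted k-means summary of the training set used for imputation."""

    centroids: np.ndarray  # k x n_features
    weights: np.ndarray  # per-centroid training-sample counts
    k: int


def kmeans_background(X_train: np.ndarray, k: int, seed: int = 0) -> Background:
    """k-means centroids with cluster-size weights, each centroid coordinate
    snapped to the nearest observed value of that feature (keeps dosage-like
    features on their support)."""
    X_train = np.asarray(X_train, dtype=float)
    if k >= len(X_train):
        raise ValueError(f"k={k} must be < n_train={len(X_train)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X_train)
    centroids = km.cluster_centers_.copy()
    for j in range(X_train.shape[1]):
        observed = np.unique(X_train[:, j])
        nearest = np.searchsorted(observed, centroids[:, j]).clip(1, len(observed) - 1)
        lo, hi = observed[nearest - 1], observed[nearest]
        centroids[:, j] = np.where(
            np.abs(centroids[:, j] - lo) <= np.abs(hi - centroids[:, j]), lo, hi
        )
    weights = np.bincount(km.labels_, minlength=k).astype(float)
    return Background(centroids, weights, k)


def _kernel_weight(M: int, s: int) -> float:
    return (M - 1) / (comb(M, s) * s * (M - s))


def _masked_outputs(
    predict_fn, x: np.ndarray, Z: np.ndarray, background: Background
) -> np.ndarray:
    """Background-weighted model output per coalition row of Z (bool mask)."""
    k, M = background.centroids.shape
    n = len(Z)
    # One batched predict call over n_coalitions x k imputed instances.
    tiles = np.repeat(background.centroids[None, :, :], n, axis=0)  # n x k x M
    mask = Z[:, None, :].astype(bool)
    tiles = np.where(mask, x[None, None, :], tiles)
    out = np.asarray(predict_fn(tiles.reshape(n * k, M)), dtype=float).reshape(n, k)
    w = background.weights / background.weights.sum()
    return out @ w


def _sample_coalitions(
    M: int, budget: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Paired coalition sampling by kernel mass per size.

    Coalitions are drawn with probability proportional to their kernel
    weight (uniform within a size class), each paired with its complement,
    and deduplicated; the returned regression weights are the draw counts,
    since the sampling distribution already carries the kernel.
    """
    sizes = np.arange(1, M)
    mass = np.array([_kernel_weight(M, s) * comb(M, s) for s in sizes])
    mass = mass / mass.sum()
    counts: dict[tuple, int] = {}
    n_pairs = max(M, budget // 2)
    for _ in range(n_pairs):
        s = int(rng.choice(sizes, p=mass))
        members = rng.choice(M, size=s, replace=False)
        z = np.zeros(M, dtype=bool)
        z[members] = True
        for cand in (z, ~z):
            t = tuple(cand)
            counts[t] = counts.get(t, 0) + 1
    Z = np.array([list(t) for t in counts], dtype=bool)
    W = np.array([counts[tuple(row)] for row in Z], dtype=float)
    return Z, W


def kernel_shap(
    predict_fn,
    x: np.ndarray,
    background: Background,
    n_coalitions="all",
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Solve the kernel system for one instance; returns (phi, base_value).

    ``predict_fn`` maps an (n, M) matrix to n model outputs (case probability
    for classifiers, prediction for regressors). With ``n_coalitions="all"``
    every non-trivial coalition is enumerated and the result is the exact
    Shapley value; an integer budget samples coalitions in complement pairs.
    The sum constraint (local accuracy) holds in both modes.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = len(x)
    if M == 0:
        raise ValueError("no features to explain")
    if background.centroids.size == 0:
        raise ValueError("empty background")
    w_bg = background.weights / background.weights.sum()
    base_value = float(
        np.asarray(predict_fn(background.centroids), dtype=float) @ w_bg
    )
    fx = float(np.asarray(predict_fn(x[None, :]), dtype=float)[0])

    if M == 1:
        return np.array([fx - base_value]), base_value

    if n_coalitions == "all":
        Z = np.array(
            [
                [bool(size & (1 << j)) for j in range(M)]
                for size in range(1, 2**M - 1)
            ]
        )
        W = np.array([_kernel_weight(M, int(s)) for s in Z.sum(axis=1)])
    else:
        rng = np.random.default_rng(seed)
        Z, W = _sample_coalitions(M, int(n_coalitions), rng)
    ey = _masked_outputs(predict_fn, x, Z, background)

    # Impose sum(phi) = fx - base by eliminating the last unknown.
    Zf = Z.astype(float)
    ey_adj = (ey - base_value) - Zf[:, -1] * (fx - base_value)
    A = Zf[:, :-1] - Zf[:, [-1]]
    Aw = A * W[:, None]
    phi_head, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ ey_adj, rcond=None)
    phi = np.empty(M)
    phi[:-1] = phi_head
    phi[-1] = (fx - base_value) - phi_head.sum()
    return phi, base_value


def brute_force_shapley(
    predict_fn, x: np.ndarray, background: Background
) -> tuple[np.ndarray, float]:
    """Exact Shapley values by enumerating all 2^M subsets (test oracle).

    v(S) is the background-imputed expected model output with features in S
    set to x. Independent of the kernel solver code path.
    """
    x = np.asarray(x, dtype=float).ravel()
    M = len(x)
    w_bg = background.weights / background.weights.sum()

    def value(subset: frozenset) -> float:
        imputed = background.centroids.copy()
        for j in subset:
            imputed[:, j] = x[j]
        return float(np.asarray(predict_fn(imputed), dtype=float) @ w_bg)

    cache: dict[frozenset, float] = {}

    def v(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = value(subset)
        return cache[subset]

    phi = np.zeros(M)
    others = list(range(M))
    from math import factorial

    for i in range(M):
        rest = [j for j in others if j != i]
        for r in range(M):
            for S in combinations(rest, r):
                S = frozenset(S)
                wgt = factorial(len(S)) * factorial(M - len(S) - 1) / factorial(M)
                phi[i] += wgt * (v(S | {i}) - v(S))
    return phi, v(frozenset())


@dataclass
class ShapMatrix:
    case_ids: list
    feature_ids: list[str]
    values: np.ndarray  # cases x features
    base_value: float

    def model_output(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)


def shap_matrix(
    predict_fn,
    cases: np.ndarray,
    background: Background,
    seed: int = 0,
    case_ids=None,
    feature_ids=None,
    n_coalitions="all",
) -> ShapMatrix:
    """One kernel-SHAP row per case, sharing a single base value."""
    cases = np.asarray(cases, dtype=float)
    if cases.ndim != 2 or len(cases) == 0:
        raise ValueError("cases must be a non-empty 2-D matrix")
    rows = []
    base = None
    for i, x in enumerate(cases):
        phi, base = kernel_shap(predict_fn, x, background, n_coalitions, seed + i)
        rows.append(phi)
    return ShapMatrix(
        case_ids=list(case_ids) if case_ids is not None else list(range(len(cases))),
        feature_ids=list(feature_ids)
        if feature_ids is not None
        else [f"f{j}" for j in range(cases.shape[1])],
        values=np.array(rows),
        base_value=base,
    )


# ---------------------------------------------------------------------------
# SHAP clustering and rankings


def cluster_cases_by_shap(
    S: ShapMatrix, k_range=range(2, 11), seed: int = 0, k_override: int | None = None
) -> ClusterAssignment:
    """k-means on SHAP rows; k by Dunn maximization unless overridden
    (the override mirrors an analyst's manual force-plot inspection)."""
    n = len(S.case_ids)
    if n < 2:
        raise ValueError("need at least 2 cases")
    if k_override is not None:
        if not 2 <= k_override <= n - 1:
            raise ValueError(f"k_override={k_override} outside [2, n-1]")
        km = KMeans(n_clusters=k_override, n_init=10, random_state=seed).fit(S.values)
        return ClusterAssignment(km.labels_, k_override, dunn_index(S.values, km.labels_), seed)
    _, assignment, _ = select_k_by_dunn(S.values, k_range, seed)
    return assignment


def rank_features_per_cluster(
    S: ShapMatrix, clusters: ClusterAssignment, top_m: int | None = None
) -> dict:
    """Per cluster, features sorted by mean |SHAP| descending (ties by id).

    When ``top_m`` is given the result also carries the union of each
    cluster's top-m features.
    """
    if len(clusters.labels) != len(S.case_ids):
        raise ValueError("cluster labels do not cover the SHAP matrix rows")
    out = {"clusters": {}}
    union: list[str] = []
    for c in np.unique(clusters.labels):
        rows = S.values[clusters.labels == c]
        if len(rows) == 0:
            raise ValueError(f"empty cluster {c}")
        impact = np.abs(rows).mean(axis=0)
        order = sorted(range(len(impact)), key=lambda j: (-impact[j], S.feature_ids[j]))
        ranking = [(S.feature_ids[j], float(impact[j])) for j in order]
        out["clusters"][int(c)] = ranking
        if top_m is not None:
            for f, _ in ranking[:top_m]:
                if f not in union:
                    union.append(f)
    if top_m is not None:
        out["top_union"] = union
    return out


def _seriation_order(values: np.ndarray) -> np.ndarray:
    """Greedy nearest-neighbour chain over SHAP rows (places likes together)."""
    n = len(values)
    if n <= 2:
        return np.arange(n)
    D = squareform(pdist(values))
    visited = [0]
    remaining = set(range(1, n))
    while remaining:
        last = visited[-1]
        nxt = min(remaining, key=lambda j: (D[last, j], j))
        visited.append(nxt)
        remaining.remove(nxt)
    return np.array(visited)


def export_force_matrix(S: ShapMatrix, order="seriation") -> pd.DataFrame:
    """Long-format attribution table for external force-plot rendering.

    Columns: case, feature, shap, base_value, model_output, case_order.
    ``order`` is "seriation" (nearest-neighbour chain) or a caller-provided
    index array over cases.
    """
    if len(S.case_ids) == 0:
        raise ValueError("empty SHAP matrix")
    if isinstance(order, str):
        if order != "seriation":
            raise ValueError(f"unknown ordering {order!r}")
        positions = _seriation_order(S.values)
    else:
        positions = np.asarray(order)
    rank = np.empty(len(S.case_ids), dtype=int)
    rank[positions] = np.arange(len(S.case_ids))
    outputs = S.model_output()
    records = []
    for i, cid in enumerate(S.case_ids):
        for j, fid in enumerate(S.feature_ids):
            records.append(
                (cid, fid, float(S.values[i, j]), S.base_value, float(outputs[i]), int(rank[i]))
            )
    return pd.DataFrame(
        records,
        columns=["case", "feature", "shap", "base_value", "model_output", "case_order"],
    )
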