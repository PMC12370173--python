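"""From-scratch k-means and silhouette machinery.

The clustering step is implemented directly from its defining recursions
rather than delegated, because the downstream decisions (cluster-number
selection by the least-drop rule, greedy silhouette-guided feature
removal) depend on the exact conventions used: ambiguous (equidistant)
points go to the lowest cluster index, convergence means assignments
unchanged between consecutive iterations, and singleton clusters
contribute a silhouette of exactly 0.

Distances are Euclidean throughout.  Because MFI-scale and percent-scale
markers differ by orders of magnitude, callers are expected to z-score
columns first (see :func:`standardize`); the functions themselves operate
on whatever matrix they are given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


def standardize(X: np.ndarray) -> np.ndarray:
    """Column-wise z-score using the rows being clustered.

    Constant columns (zero variance) are mapped to zeros rather than
    NaN so that degenerate markers (e.g. day-1-normalized proliferation,
    identically 1) simply carry no weight in the distance.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


@dataclass
class KMeansResult:
    assignments: np.ndarray  # cluster index per row, 0-based, values in 0..G-1
    centroids: np.ndarray  # G x n
    n_iter: int
    sse: float  # within-cluster sum of squared Euclidean distances
    seed: int
    restarts_used: int


def _plusplus_init(X: np.ndarray, G: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted draw of G initial centroids from the data points."""
    N = X.shape[0]
    centroids = [X[rng.integers(N)]]
    for _ in range(1, G):
        d2 = np.min(cdist(X, np.array(centroids), "sqeuclidean"), axis=1)
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centroids
            centroids.append(X[rng.integers(N)])
            continue
        centroids.append(X[rng.choice(N, p=d2 / total)])
    return np.array(centroids)


def _sse(X: np.ndarray, assignments: np.ndarray, centroids: np.ndarray) -> float:
    return float(((X - centroids[assignments]) ** 2).sum())


def _lloyd(
    X: np.ndarray,
    G: int,
    centroids: np.ndarray,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    assignments = np.full(X.shape[0], -1)
    prev_sse = np.inf
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centroids, "sqeuclidean")
        # argmin resolves equidistant points to the lowest cluster index
        new_assignments = np.argmin(d2, axis=1)
        # re-seed any emptied cluster at the point farthest from its centroid
        for g in range(G):
            if not np.any(new_assignments == g):
                far = int(np.argmax(np.min(d2, axis=1)))
                new_assignments[far] = g
                d2[far, :] = np.inf
                d2[far, g] = 0.0
        for g in range(G):
            centroids[g] = X[new_assignments == g].mean(axis=0)
        cur_sse = _sse(X, new_assignments, centroids)
        if cur_sse > prev_sse + 1e-9:
            raise AssertionError("k-means SSE increased between iterations")
        prev_sse = cur_sse
        if np.array_equal(new_assignments, assignments):
            return assignments, centroids, it
        assignments = new_assignments
    return assignments, centroids, max_iter


def _hartigan_pass(X: np.ndarray, assignments: np.ndarray, G: int) -> bool:
    """One pass of single-point moves that strictly decrease the SSE.

    Moving x from cluster a (size n_a) to b changes the SSE by
    n_b/(n_b+1)*||x - mu_b||^2 - n_a/(n_a-1)*||x - mu_a||^2, which can be
    negative even when x is nearer mu_a, so this escapes Lloyd-stable
    local optima.  Returns whether any move was applied.
    """
    counts = np.bincount(assignments, minlength=G).astype(float)
    sums = np.zeros((G, X.shape[1]))
    for g in range(G):
        sums[g] = X[assignments == g].sum(axis=0)
    moved = False
    for i in range(X.shape[0]):
        a = assignments[i]
        if counts[a] <= 1:
            continue
        x = X[i]
        mu_a = sums[a] / counts[a]
        loss_a = counts[a] / (counts[a] - 1) * float(((x - mu_a) ** 2).sum())
        best_gain, best_g = -1e-12, -1
        for g in range(G):
            if g == a:
                continue
            mu_g = sums[g] / counts[g]
            gain_g = counts[g] / (counts[g] + 1) * float(((x - mu_g) ** 2).sum())
            delta = gain_g - loss_a
            if delta < best_gain:
                best_gain, best_g = delta, g
        if best_g >= 0:
            sums[a] -= x
            counts[a] -= 1
            sums[best_g] += x
            counts[best_g] += 1
            assignments[i] = best_g
            moved = True
    return moved


def _kmeans_single(
    X: np.ndarray, G: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int]:
    centroids = _plusplus_init(X, G, rng)
    assignments, centroids, n_iter = _lloyd(X, G, centroids, max_iter)
    # polish: alternate exact single-point refinement with Lloyd re-descent
    # until neither changes anything; the result is again a fixed point of
    # the assignment/update recursion
    for _ in range(max_iter):
        work = assignments.copy()
        if not _hartigan_pass(X, work, G):
            break
        for g in range(G):
            centroids[g] = X[work == g].mean(axis=0)
        assignments, centroids, extra = _lloyd(X, G, centroids, max_iter)
        n_iter += extra
    return assignments, centroids, n_iter


def kmeans(
    X: np.ndarray,
    G: int,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 300,
) -> KMeansResult:
    """Lloyd-style k-means with multiple restarts.

    Alternates nearest-centroid assignment and centroid update until the
    assignments are unchanged between iterations (or ``max_iter``).  Among
    ``restarts`` independent distance-weighted initializations the run
    with minimal within-cluster SSE is returned.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    N = X.shape[0]
    if G < 1:
        raise ValueError("G must be >= 1")
    if G > N:
        raise ValueError(f"cannot form G={G} clusters from N={N} records")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(restarts):
        assignments, centroids, n_iter = _kmeans_single(X, G, rng, max_iter)
        sse = _sse(X, assignments, centroids)
        if best is None or sse < best.sse - 1e-12:
            best = KMeansResult(
                assignments=assignments,
                centroids=centroids,
                n_iter=n_iter,
                sse=sse,
                seed=seed,
                restarts_used=restarts,
            )
    assert best is not None
    return best


@dataclass
class SilhouetteReport:
    per_sample: np.ndarray  # s(x_i) in [-1, 1]
    per_cluster: dict[int, float]  # mean s over each cluster
    global_score: float  # mean s over all samples


def silhouette(X: np.ndarray, assignments: np.ndarray) -> SilhouetteReport:
    """Silhouette index with the singleton convention s = 0.

    For each sample, cohesion ``a_i`` is the mean distance to the other
    members of its cluster and separation ``b_i`` the smallest mean
    distance to any other cluster; ``s_i = (b_i - a_i)/max(a_i, b_i)``.
    Members of singleton clusters score exactly 0.  The headline score is
    the mean of ``s_i`` over all samples; per-cluster means are reported
    alongside.
    """
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if len(labels) < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    if X.shape[0] != assignments.shape[0]:
        raise ValueError("X and assignments disagree on N")
    D = cdist(X, X)
    s = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        g = assignments[i]
        own = assignments == g
        if own.sum() == 1:
            s[i] = 0.0
            continue
        a_i = D[i, own].sum() / (own.sum() - 1)  # excludes self (distance 0)
        b_i = min(D[i, assignments == l].mean() for l in labels if l != g)
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    per_cluster = {int(l): float(s[assignments == l].mean()) for l in labels}
    return SilhouetteReport(
        per_sample=s, per_cluster=per_cluster, global_score=float(s.mean())
    )


def select_num_clusters(
    X: np.ndarray,
    k_max: int = 6,
    epsilon: float = 0.01,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[int, dict[int, float]]:
    """Choose the cluster count by the least-drop rule.

    Evaluates the global silhouette for k = 2..k_max and returns the
    smallest k whose score is within ``epsilon`` of the maximum, trading
    a negligible drop in separation quality for fewer groups.
    """
    X = np.asarray(X, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if X.shape[0] <= k_max:
        raise ValueError("need N > k_max records")
    scores: dict[int, float] = {}
    for k in range(2, k_max + 1):
        result = kmeans(X, k, seed=seed, restarts=restarts)
        scores[k] = silhouette(X, result.assignments).global_score
    best = max(scores.values())
    k_star = min(k for k, v in scores.items() if v >= best - epsilon)
    return k_star, scores


def backward_eliminate(
    X: np.ndarray,
    feature_names: list[str],
    k: int,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[list[str], list[float]]:
    """Greedy feature removal guided by the silhouette score.

    At each step the single feature whose removal yields the largest
    silhouette increase is dropped; the loop stops as soon as no removal
    improves the score.  Returns the surviving features and the (monotone
    non-decreasing) score trace, starting with the all-features score.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length must match X columns")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")

    def score(cols: list[int]) -> float:
        sub = X[:, cols]
        result = kmeans(sub, k, seed=seed, restarts=restarts)
        return silhouette(sub, result.assignments).global_score

    cols = list(range(X.shape[1]))
    trace = [score(cols)]
    while len(cols) > 1:
        candidates = []
        for j in cols:
            remaining = [c for c in cols if c != j]
            candidates.append((score(remaining), j))
        best_score, drop = max(candidates, key=lambda t: (t[0], -t[1]))
        if best_score <= trace[-1]:
            break
        cols = [c for c in cols if c != drop]
        trace.append(best_score)
    return [feature_names[c] for c in cols], trace
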