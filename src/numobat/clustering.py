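"""Nest-centroid clustering: UPGMA dendrograms, cluster-number
estimation by recursive gap-statistic thresholding (PART), the
two-engine consensus rule, and PCA ordination.

The exploratory species hypothesis is built by clustering nest-sample
mean vectors. A UPGMA (average linkage) dendrogram displays the
hierarchical structure; the number of clusters is estimated by
Partitioning Based on Recursive Thresholding: at every node the gap
statistic (Tibshirani et al. 2001, reference data uniform over the
principal-axis-aligned bounding box) picks a local k; k = 1 stops the
recursion, k > 1 splits the node by the engine (average-linkage tree cut
or k-means, best of several restarts) and recurses into each part.
Terminal groups smaller than ``min_size`` are labelled 0 (outliers).
A partition is accepted as a species hypothesis only when the
hierarchical and the k-means engine arrive at the same conclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage, to_tree
from scipy.cluster.vq import kmeans2
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "Dendrogram",
    "upgma",
    "gap_select_k",
    "part",
    "PartitionResult",
    "consensus",
    "ConsensusVerdict",
    "pca_ordination",
    "PCAOrdination",
]


# ---------------------------------------------------------------------------
# UPGMA dendrogram


@dataclass
class Dendrogram:
    """Average-linkage merge tree over named leaves.

    Wraps a scipy linkage matrix; merge heights are the average
    inter-cluster distances (non-decreasing toward the root), and the
    cophenetic matrix is ultrametric.
    """

    linkage_matrix: np.ndarray
    ids: list[str]

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(cophenet(self.linkage_matrix))
        return pd.DataFrame(d, index=self.ids, columns=self.ids)

    def cut(self, k: int) -> np.ndarray:
        """Flat labels (0..k-1) from cutting the tree into k clusters."""
        return cut_tree(self.linkage_matrix, n_clusters=k).ravel()

    def to_newick(self) -> str:
        """Newick string with merge heights as node heights (branch
        length = parent height − child height)."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def upgma(distance: pd.DataFrame | np.ndarray, ids: list[str] | None = None) -> Dendrogram:
    """UPGMA tree from a symmetric zero-diagonal distance matrix."""
    if isinstance(distance, pd.DataFrame):
        ids = [str(i) for i in distance.index]
        mat = distance.to_numpy(dtype=float)
    else:
        mat = np.asarray(distance, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(len(mat))]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
        raise ValueError("need a square matrix over at least 2 items")
    if np.isnan(mat).any():
        raise ValueError("NaN distances")
    if np.abs(mat - mat.T).max() > 1e-9:
        raise ValueError("distance matrix asymmetric beyond 1e-9")
    if np.any(mat < 0) or np.abs(np.diag(mat)).max() > 1e-12:
        raise ValueError("distances must be non-negative with zero diagonal")
    z = linkage(squareform(mat, checks=False), method="average")
    return Dendrogram(z, ids)


# ---------------------------------------------------------------------------
# Engines


def _kmeans_labels(X: np.ndarray, k: int, rng: np.random.Generator, restarts: int) -> np.ndarray:
    """Best-inertia k-means labels over ``restarts`` seeded runs."""
    import warnings

    best_labels, best_inertia = None, np.inf
    for _ in range(restarts):
        seed = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            # an empty cluster in a restart is acceptable: it simply
            # scores a higher inertia and loses the restart comparison
            warnings.simplefilter("ignore", UserWarning)
            centroids, labels = kmeans2(X, k, minit="++", seed=seed)
        inertia = float(((X - centroids[labels]) ** 2).sum())
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels
    return best_labels


def _hclust_labels(X: np.ndarray, k: int) -> np.ndarray:
    # Ward linkage for the split engine: it recovers compact equal-sized
    # clusters far more reliably than average linkage, which chains and
    # sheds singletons on touching clusters. The display dendrogram
    # (upgma) is unaffected.
    z = linkage(pdist(X), method="ward")
    return cut_tree(z, n_clusters=k).ravel()


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster sum of squared deviations from centroids."""
    w = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def _batched_kmeans_w(
    Xs: np.ndarray, k: int, rng: np.random.Generator, restarts: int = 10, iters: int = 30
) -> np.ndarray:
    """Best-of-restarts within-cluster dispersion W for a batch of
    datasets, by vectorized Lloyd iterations (random-subset init).

    ``Xs`` has shape (B, n, d); returns W of shape (B,). Used by the gap
    statistic so the observed data and every reference dataset get the
    identical clustering treatment.
    """
    B, n, d = Xs.shape
    xx = (Xs**2).sum(-1)  # (B, n)
    best = np.full(B, np.inf)
    eye = np.arange(k)
    for _ in range(restarts):
        pick = rng.random((B, n)).argsort(axis=1)[:, :k]
        C = np.take_along_axis(Xs, pick[:, :, None], axis=1)  # (B, k, d)
        labels_prev = None
        for _ in range(iters):
            cc = (C**2).sum(-1)  # (B, k)
            d2 = xx[:, :, None] - 2.0 * np.einsum("bnd,bkd->bnk", Xs, C) + cc[:, None, :]
            labels = d2.argmin(-1)  # (B, n)
            if labels_prev is not None and (labels == labels_prev).all():
                break
            labels_prev = labels
            member = labels[:, :, None] == eye  # (B, n, k)
            counts = member.sum(axis=1)  # (B, k)
            sums = np.einsum("bnk,bnd->bkd", member.astype(float), Xs)
            with np.errstate(invalid="ignore"):
                C_new = sums / counts[:, :, None]
            empty = counts == 0
            if empty.any():
                C_new[empty] = C[empty]  # keep the old centroid for empty clusters
            C = C_new
        w = np.take_along_axis(d2, labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
        best = np.minimum(best, np.maximum(w, 0.0))
    return best


def _reference_sampler(X: np.ndarray):
    """Uniform sampler over the principal-axis-aligned bounding box of X
    (the second reference variant of the gap statistic)."""
    mu = X.mean(axis=0)
    centered = X - mu
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)

    def sample(rng: np.random.Generator, B: int = 1) -> np.ndarray:
        u = rng.uniform(lo, hi, size=(B,) + proj.shape)
        return u @ vt + mu

    return sample


def gap_select_k(
    X: np.ndarray,
    kmax: int,
    B: int,
    engine: str = "kmeans",
    rng: np.random.Generator | int | None = None,
    restarts: int = 25,
    reference_restarts: int = 20,
    criterion: str = "globalSEmax",
) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters in 1..kmax by the gap statistic.

    gap(k) = E*[log W_k] − log W_k against B reference datasets drawn
    uniformly over the PCA-aligned bounding box. Two selection rules:

    * ``"globalSEmax"`` (default): smallest k whose gap reaches the
      global gap maximum minus one standard error — robust when several
      adjacent clusters make the gap curve dip before its real peak.
    * ``"firstSE"``: the original one-standard-error rule, smallest k
      with gap(k) ≥ gap(k+1) − s(k+1); conservative, known to
      underestimate k for many touching clusters.

    Degenerate input (all rows identical) gives k = 1.
    Returns (k, gap table).
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(rng)
    n = len(X)
    if kmax < 2:
        raise ValueError("kmax must be ≥ 2")
    if B < 1:
        raise ValueError("B must be ≥ 1")
    kmax = min(kmax, n - 1) if n > 2 else 1
    if kmax < 2 or np.allclose(X, X[0]):
        return 1, pd.DataFrame()

    ks = np.arange(1, kmax + 1)
    sample = _reference_sampler(X)
    refs = sample(rng, B)  # (B, n, d)

    if engine == "kmeans":
        # identical batched treatment for the data and every reference
        stack = np.concatenate([X[None], refs], axis=0)
        log_w_all = np.empty((1 + B, len(ks)))
        log_w_all[:, 0] = np.log(
            np.maximum(((stack - stack.mean(axis=1, keepdims=True)) ** 2).sum((1, 2)), 1e-300)
        )
        for j, k in enumerate(ks[1:], start=1):
            w = _batched_kmeans_w(stack, int(k), rng, restarts=reference_restarts)
            log_w_all[:, j] = np.log(np.maximum(w, 1e-300))
        log_w, log_w_ref = log_w_all[0], log_w_all[1:]
    elif engine == "hierarchical":
        def tree_log_w(data: np.ndarray) -> np.ndarray:
            z = linkage(pdist(data), method="ward")
            out = np.empty(len(ks))
            for j, k in enumerate(ks):
                labels = (np.zeros(len(data), dtype=int) if k == 1
                          else cut_tree(z, n_clusters=int(k)).ravel())
                out[j] = np.log(max(_within_dispersion(data, labels), 1e-300))
            return out

        log_w = tree_log_w(X)
        log_w_ref = np.stack([tree_log_w(refs[b]) for b in range(B)])
    else:
        raise ValueError(f"unknown engine {engine!r}")

    gap = log_w_ref.mean(axis=0) - log_w
    sk = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    table = pd.DataFrame({"k": ks, "log_w": log_w, "gap": gap, "s": sk})

    if criterion == "firstSE":
        chosen = int(ks[-1])
        for j in range(len(ks) - 1):
            if gap[j] >= gap[j + 1] - sk[j + 1]:
                chosen = int(ks[j])
                break
    elif criterion == "globalSEmax":
        g = int(np.argmax(gap))
        thr = gap[g] - sk[g]
        chosen = int(ks[np.flatnonzero(gap >= thr)[0]])
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return chosen, table


# ---------------------------------------------------------------------------
# PART recursion


@dataclass
class PartitionResult:
    """Flat partition from recursive thresholding.

    ``labels`` maps nest id → cluster id; 0 marks outliers (terminal
    groups below ``min_size``). ``k`` counts non-outlier clusters.
    """

    engine: str
    labels: pd.Series
    k: int
    B: int
    min_size: int
    seed: int | None
    gap_trace: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "engine": self.engine,
            "k": self.k,
            "B": self.B,
            "min_size": self.min_size,
            "seed": self.seed,
            "labels": {str(i): int(v) for i, v in self.labels.items()},
        }


def part(
    X: pd.DataFrame | np.ndarray,
    engine: str = "kmeans",
    B: int = 1000,
    min_size: int = 5,
    kmax: int = 8,
    seed: int | None = None,
    ids: list[str] | None = None,
    restarts: int = 25,
    reference_restarts: int = 20,
    criterion: str = "globalSEmax",
) -> PartitionResult:
    """Partitioning Based on Recursive Thresholding.

    At each node the gap statistic picks a local k over that node's rows;
    k = 1 makes the node a terminal cluster, otherwise the node is split
    into k groups by the engine and each group is re-tested. Terminal
    groups smaller than ``min_size`` become outliers (label 0).
    """
    if kmax < 2:
        raise ValueError("kmax must be ≥ 2")
    if isinstance(X, pd.DataFrame):
        ids = [str(i) for i in X.index]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(len(mat))]
    if len(mat) < min_size:
        raise ValueError(f"need at least min_size={min_size} rows")

    rng = np.random.default_rng(seed)
    labels = np.zeros(len(mat), dtype=int)
    trace: list[dict] = []
    next_label = [1]

    def recurse(rows: np.ndarray, depth: int) -> None:
        sub = mat[rows]
        if len(rows) < 2 * min_size or len(rows) < 3:
            k = 1
        else:
            k, _ = gap_select_k(
                sub, kmax=kmax, B=B, engine=engine, rng=rng,
                restarts=restarts, reference_restarts=reference_restarts,
                criterion=criterion,
            )
        trace.append({"depth": depth, "n": int(len(rows)), "k": int(k)})
        if k == 1:
            if len(rows) >= min_size:
                labels[rows] = next_label[0]
                next_label[0] += 1
            # else: stays 0 (outlier group below min_size)
            return
        if engine == "kmeans":
            sub_labels = _kmeans_labels(sub, k, rng, restarts)
        else:
            sub_labels = _hclust_labels(sub, k)
        for lab in np.unique(sub_labels):
            recurse(rows[sub_labels == lab], depth + 1)

    recurse(np.arange(len(mat)), 0)
    labels = _refine_partition(mat, labels, engine, rng, restarts, min_size)
    series = pd.Series(labels, index=ids, name="cluster")
    k = int(len(set(labels) - {0}))
    return PartitionResult(engine, series, k, B, min_size, seed, trace)


def _gaussian_score(mat: np.ndarray, labels: np.ndarray) -> float:
    """Classification-likelihood score (lower = better) of a hard
    partition under per-cluster diagonal Gaussians shrunk toward the
    pooled within-cluster variance — the consolidation objective."""
    active = sorted(set(labels) - {0})
    if len(active) < 2:
        return np.inf
    cents = np.stack([mat[labels == lab].mean(axis=0) for lab in active])
    within = np.stack([
        ((mat[labels == lab] - c) ** 2).mean(axis=0) for lab, c in zip(active, cents)
    ])
    pooled = within.mean(axis=0)
    var = np.maximum(0.5 * within + 0.5 * pooled[None, :], 1e-12)
    total = 0.0
    for i, lab in enumerate(active):
        dev = mat[labels == lab] - cents[i]
        total += ((dev**2) / var[i]).sum() + (labels == lab).sum() * np.log(var[i]).sum()
    return float(total)


def _refine_partition(
    mat: np.ndarray,
    labels: np.ndarray,
    engine: str,
    rng: np.random.Generator,
    restarts: int,
    min_size: int,
    n_extra: int = 4,
) -> np.ndarray:
    """Polish the recursion's partition at its chosen k.

    The recursion fixes each sample at the level where its branch split,
    which strands boundary samples; and greedy splits can land in a poor
    local optimum. Several candidate assignments at the same k (the
    recursion labels, a fresh engine cut, and a few seeded k-means
    starts) are each consolidated by nearest-Gaussian reassignment and
    the best-scoring stable partition wins. k never changes; outlier
    labels (0) are preserved.
    """
    k = len(set(labels) - {0})
    if k < 2:
        return labels
    outliers = labels == 0
    candidates = [labels.copy()]
    core = mat[~outliers]
    fresh = (_hclust_labels(core, k) if engine == "hierarchical"
             else _kmeans_labels(core, k, rng, restarts)) + 1
    for extra in range(n_extra):
        candidates.append(_embed(fresh if extra == 0 else
                                 _kmeans_labels(core, k, rng, max(restarts // 5, 2)) + 1,
                                 outliers))
    best, best_score = None, np.inf
    for cand in candidates:
        if len(set(cand) - {0}) != k:
            continue
        _consolidate(mat, cand)
        if len(set(cand) - {0}) != k or _too_small(cand, min_size):
            continue
        score = _gaussian_score(mat, cand)
        if score < best_score:
            best, best_score = cand, score
    return best if best is not None else labels


def _embed(core_labels: np.ndarray, outliers: np.ndarray) -> np.ndarray:
    out = np.zeros(len(outliers), dtype=int)
    out[~outliers] = core_labels
    return out


def _too_small(labels: np.ndarray, min_size: int) -> bool:
    return any((labels == lab).sum() < min_size for lab in set(labels) - {0})


def _consolidate(mat: np.ndarray, labels: np.ndarray, max_iter: int = 20) -> None:
    """Nearest-centroid reassignment of non-outlier samples until stable.

    Greedy recursive splits fix each sample's cluster at the level where
    its branch separated; a sample near a boundary can end up closer to
    another terminal cluster's centroid. This consolidation pass (in
    place) repairs those boundary assignments without changing k.
    """
    active = sorted(set(labels) - {0})
    if len(active) < 2:
        return
    nonout = labels != 0
    for _ in range(max_iter):
        centroids = np.stack([mat[labels == lab].mean(axis=0) for lab in active])
        # diagonal per-cluster variances, shrunk halfway toward the pooled
        # within-cluster variance: a Gaussian-likelihood boundary that lets
        # a diffuse cluster keep its tails against a tight neighbour while
        # staying estimable from few members per cluster
        within = np.stack([
            ((mat[labels == lab] - c) ** 2).mean(axis=0)
            for lab, c in zip(active, centroids)
        ])
        pooled = within.mean(axis=0)
        var = np.maximum(0.5 * within + 0.5 * pooled[None, :], 1e-12)  # (k, d)
        diff2 = (mat[nonout, None, :] - centroids[None, :, :]) ** 2
        score = (diff2 / var[None, :, :]).sum(axis=2) + np.log(var).sum(axis=1)[None, :]
        new = np.asarray(active)[np.argmin(score, axis=1)]
        if (new == labels[nonout]).all():
            break
        labels[nonout] = new
        if len(set(labels) - {0}) < len(active):  # a cluster emptied: undo-safe stop
            break


# ---------------------------------------------------------------------------
# Consensus


@dataclass
class ConsensusVerdict:
    """Agreement between the two engines' partitions."""

    accepted: bool
    k_a: int
    k_b: int
    ari: float
    merged_labels: pd.Series | None = None
    mode: str = "strict"

    def to_json_dict(self) -> dict:
        out = {
            "accepted": self.accepted,
            "k_hierarchical": self.k_a,
            "k_kmeans": self.k_b,
            "ari": self.ari,
            "mode": self.mode,
        }
        if self.merged_labels is not None:
            out["labels"] = {str(i): int(v) for i, v in self.merged_labels.items()}
        return out


def _identical_up_to_permutation(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff the two labelings define the same partition."""
    table = pd.crosstab(a, b).to_numpy()
    return bool(((table > 0).sum(axis=0) == 1).all() and ((table > 0).sum(axis=1) == 1).all())


def consensus(
    a: PartitionResult, b: PartitionResult, strict: bool = True, ari_threshold: float = 0.95
) -> ConsensusVerdict:
    """Accept the partition only when both engines reached the same
    conclusion: equal k and (strict mode) identical partitions up to
    label permutation over the samples neither engine called outliers.
    Merged labels are taken from the hierarchical engine when available.
    """
    if list(a.labels.index) != list(b.labels.index):
        raise ValueError("partitions cover different nest ids")
    mask = (a.labels != 0) & (b.labels != 0)
    la = a.labels[mask].to_numpy()
    lb = b.labels[mask].to_numpy()
    ari = float(adjusted_rand_score(la, lb)) if mask.any() else 0.0
    same_k = a.k == b.k
    if strict:
        accepted = same_k and mask.any() and _identical_up_to_permutation(la, lb)
    else:
        accepted = same_k and ari >= ari_threshold
    merged = None
    if accepted:
        merged = (a if a.engine == "hierarchical" else b).labels
    return ConsensusVerdict(accepted, a.k, b.k, ari, merged, "strict" if strict else "relaxed")


# ---------------------------------------------------------------------------
# PCA ordination


@dataclass
class PCAOrdination:
    """Centered PCA with supplementary-point projection.

    Used to place type specimens into the morphospace of a reference
    cloud and to flag peripheral (outlier) positions by Mahalanobis
    distance in score space.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series

    def transform(self, new: pd.DataFrame) -> pd.DataFrame:
        centered = new[self.loadings.index] - self.mean
        return pd.DataFrame(
            centered.to_numpy() @ self.loadings.to_numpy(),
            index=new.index, columns=self.scores.columns,
        )

    def peripheral_report(
        self,
        new: pd.DataFrame,
        labels: pd.Series | None = None,
        threshold_sd: float = 3.0,
    ) -> pd.DataFrame:
        """Mahalanobis distance of projected points to each reference
        cluster in score space; a point farther than ``threshold_sd``
        from every cluster is flagged peripheral."""
        proj = self.transform(new)
        groups = (
            {lab: self.scores[labels == lab] for lab in labels.unique()}
            if labels is not None
            else {"all": self.scores}
        )
        rows = []
        for idx, point in proj.iterrows():
            dists = {}
            for lab, cloud in groups.items():
                cov = np.cov(cloud.to_numpy(), rowvar=False)
                cov = np.atleast_2d(cov) + 1e-9 * np.eye(cloud.shape[1])
                delta = point.to_numpy() - cloud.mean(axis=0).to_numpy()
                dists[lab] = float(np.sqrt(delta @ np.linalg.solve(cov, delta)))
            nearest = min(dists, key=dists.get)
            rows.append(
                {
                    "id": idx,
                    "nearest_cluster": nearest,
                    "mahalanobis": dists[nearest],
                    "peripheral": dists[nearest] > threshold_sd,
                }
            )
        return pd.DataFrame(rows).set_index("id")


def pca_ordination(X: pd.DataFrame, n_components: int = 2) -> PCAOrdination:
    """Centered (not scaled) PCA of complete-case rows.

    Rank-deficient input truncates the component count with a warning
    rather than failing.
    """
    from sklearn.decomposition import PCA

    complete = X.dropna()
    if len(complete) < n_components + 1:
        raise ValueError("need at least n_components + 1 complete rows")
    rank = int(np.linalg.matrix_rank(complete - complete.mean()))
    if rank < n_components:
        import warnings

        warnings.warn(f"rank-deficient input: truncating to {rank} components", stacklevel=2)
        n_components = rank
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(complete.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAOrdination(
        scores=pd.DataFrame(scores, index=complete.index, columns=cols),
        loadings=pd.DataFrame(pca.components_.T, index=complete.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pd.Series(pca.mean_, index=complete.columns),
    )
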