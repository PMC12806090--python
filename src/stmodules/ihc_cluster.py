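"""Iterative hierarchical clustering of genes on Spearman distances.

Genes are clustered from their fitted basis-coefficient rows.  For each
threshold α on a grid spanning the observed pairwise Spearman
correlations: average-linkage clusters are cut at distance 1−α, cluster
centers are themselves re-clustered and merged, members poorly
correlated with their center are pruned into singletons, and
merge/prune repeats to a fixpoint followed by merge-only passes until
all between-center correlations drop below α.  The α maximizing the
mean silhouette wins.  Every step is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MAX_PASSES = 100


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class GeneDistance:
    """Pairwise Spearman correlations and the derived distance matrix."""

    rho: np.ndarray
    dist: np.ndarray
    alpha_min: float
    alpha_max: float


@dataclass
class ClusterState:
    """A partition of the genes with current cluster centers."""

    labels: np.ndarray          # gene -> cluster id (0-based, dense)
    centers: np.ndarray         # (n_clusters, K) mean coefficient rows
    n_cut: int = 0              # P: clusters after the initial cut
    n_merged: int = 0           # R: clusters after merging
    n_pruned: int = 0           # S: singletons created by the last prune


@dataclass
class StihcResult:
    """Final gene-module assignment with threshold diagnostics."""

    labels: np.ndarray
    alpha_opt: float
    per_alpha: list[dict]       # (alpha, n_clusters, mean_silhouette)
    per_gene_sil: np.ndarray
    gene_ids: tuple[str, ...] | None = None

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, X)


def _spearman_matrix(X: np.ndarray, *, constant_ok: bool = False,
                     names: tuple[str, ...] | None = None) -> np.ndarray:
    """Pairwise Spearman correlation between rows of ``X``.

    Average ranks within rows, then Pearson on the ranks.  Constant rows
    are an error unless ``constant_ok`` (then their correlations are 0).
    """
    X = np.asarray(X, dtype=float)
    const = np.ptp(X, axis=1) == 0
    if np.any(const) and not constant_ok:
        idx = np.flatnonzero(const)
        label = names[idx[0]] if names is not None else f"row {idx[0]}"
        raise ClusterError(
            f"constant coefficient row ({label}): Spearman correlation undefined"
        )
    R = _rank_rows(X)
    R = R - R.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.einsum("ij,ij->i", R, R))
    safe = np.where(norm > 0, norm, 1.0)
    Rn = R / safe[:, None]
    rho = Rn @ Rn.T
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    rho[const] = 0.0
    rho[:, const] = 0.0
    np.fill_diagonal(rho, 1.0)
    return rho


def spearman_distance(C: np.ndarray, gene_ids: tuple[str, ...] | None = None
                      ) -> GeneDistance:
    """Distance ``d_ij = 1 − ρ_ij`` between genes' coefficient rows."""
    C = np.asarray(getattr(C, "C", C), dtype=float)
    if C.shape[0] < 2:
        raise ClusterError("need at least 2 genes")
    if C.shape[1] < 3:
        raise ClusterError("need at least 3 coefficients per gene")
    rho = _spearman_matrix(C, names=gene_ids)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    off = rho[~np.eye(rho.shape[0], dtype=bool)]
    return GeneDistance(
        rho=rho, dist=dist,
        alpha_min=float(off.min()), alpha_max=float(off.max()),
    )


def make_alpha_grid(gd: GeneDistance, U: int) -> np.ndarray:
    """``U`` equally spaced thresholds spanning ``[α_min, α_max]``."""
    if U < 1:
        raise ClusterError("U must be >= 1")
    if gd.alpha_min == gd.alpha_max:
        warnings.warn("alpha_min == alpha_max: degenerate single-value grid",
                      RuntimeWarning, stacklevel=2)
        return np.array([gd.alpha_min])
    if U == 1:
        return np.array([gd.alpha_max])
    return np.linspace(gd.alpha_min, gd.alpha_max, U)


def _relabel_first_seen(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids by order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping)
        out[i] = mapping[l]
    return out


def cut_hierarchy(dist: np.ndarray, alpha: float) -> np.ndarray:
    """Average-linkage agglomeration cut at linkage distance ``1 − α``.

    Merging proceeds while the smallest average-linkage distance is
    ≤ 1−α (ties at the threshold merge).  Tied merge candidates are
    resolved toward the pair whose clusters contain the smallest gene
    indices, making the procedure fully deterministic.  Returns 0-based
    labels renumbered by first-gene order.
    """
    dist = np.asarray(dist, dtype=float)
    G = dist.shape[0]
    if G == 1:
        return np.zeros(1, dtype=int)
    threshold = 1.0 - alpha
    # slot g holds the cluster whose smallest member gene is g; merging
    # j into i < j preserves that, so the row-major argmin implements
    # the smallest-gene-index tie-break
    D = dist.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    sizes = np.ones(G)
    slot = np.arange(G)
    for _ in range(G - 1):
        flat = int(np.argmin(D))
        i, j = divmod(flat, G)
        if D[i, j] > threshold:
            break
        if j < i:
            i, j = j, i
        ni, nj = sizes[i], sizes[j]
        new = (ni * D[i] + nj * D[j]) / (ni + nj)
        D[i, :] = new
        D[:, i] = new
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] += sizes[j]
        slot[slot == j] = i
    return _relabel_first_seen(slot)


def compute_centers(labels: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Cluster centers = arithmetic mean of member coefficient rows."""
    labels = np.asarray(labels)
    C = np.asarray(C, dtype=float)
    n_clusters = int(labels.max()) + 1
    centers = np.empty((n_clusters, C.shape[1]))
    for p in range(n_clusters):
        members = labels == p
        if not members.any():
            raise ClusterError(f"empty cluster {p}")
        centers[p] = C[members].mean(axis=0)
    return centers


def _medoid_centers(labels: np.ndarray, C: np.ndarray, dist: np.ndarray
                    ) -> np.ndarray:
    """Medoid variant: member minimizing summed distance to co-members."""
    n_clusters = int(labels.max()) + 1
    centers = np.empty((n_clusters, C.shape[1]))
    for p in range(n_clusters):
        idx = np.flatnonzero(labels == p)
        sub = dist[np.ix_(idx, idx)]
        centers[p] = C[idx[int(np.argmin(sub.sum(axis=1)))]]
    return centers


def _new_state(labels: np.ndarray, C: np.ndarray, center: str,
               dist: np.ndarray | None = None) -> ClusterState:
    labels = _relabel_first_seen(labels)
    if center == "medoid":
        centers = _medoid_centers(labels, C, dist)
    else:
        centers = compute_centers(labels, C)
    return ClusterState(labels=labels, centers=centers)


def merge_step(state: ClusterState, alpha: float, C: np.ndarray,
               center: str = "mean", dist: np.ndarray | None = None
               ) -> ClusterState:
    """Re-cluster the centers at the same α and union co-clustered groups."""
    n_clusters = state.centers.shape[0]
    if n_clusters <= 1:
        return state
    rho_c = _spearman_matrix(state.centers, constant_ok=True)
    d_c = 1.0 - rho_c
    np.fill_diagonal(d_c, 0.0)
    group_of = cut_hierarchy(d_c, alpha)
    if int(group_of.max()) + 1 == n_clusters:
        return state
    labels = group_of[state.labels]
    out = _new_state(labels, C, center, dist)
    out.n_merged = int(out.labels.max()) + 1
    return out


def prune_step(state: ClusterState, alpha: float, C: np.ndarray,
               center: str = "mean", dist: np.ndarray | None = None
               ) -> ClusterState:
    """Split off members whose Spearman correlation with their cluster
    center (as of entry to the pass) falls below α.

    All offenders across all clusters are evaluated against the entry
    centers and removed simultaneously, then centers are recomputed once.
    """
    labels = state.labels.copy()
    C = np.asarray(C, dtype=float)
    sizes = np.bincount(labels)
    removed = 0
    next_id = int(labels.max()) + 1
    # correlate every gene with its own cluster's entry center
    for p in np.flatnonzero(sizes > 1):
        idx = np.flatnonzero(state.labels == p)
        rows = np.vstack([state.centers[p][None, :], C[idx]])
        rho = _spearman_matrix(rows, constant_ok=True)[0, 1:]
        for g in idx[rho < alpha]:
            labels[g] = next_id
            next_id += 1
            removed += 1
    if removed == 0:
        out = ClusterState(labels=state.labels, centers=state.centers)
        out.n_pruned = 0
        return out
    out = _new_state(labels, C, center, dist)
    out.n_pruned = removed
    return out


def _all_centers_below(state: ClusterState, alpha: float) -> bool:
    if state.centers.shape[0] <= 1:
        return True
    rho_c = _spearman_matrix(state.centers, constant_ok=True)
    off = rho_c[~np.eye(rho_c.shape[0], dtype=bool)]
    return bool(np.all(off < alpha))


def iterate_to_convergence(state: ClusterState, alpha: float, C: np.ndarray,
                           center: str = "mean",
                           dist: np.ndarray | None = None) -> ClusterState:
    """Merge+prune to a labels fixpoint, then merge-only until every
    pair of cluster centers has correlation < α."""
    for _ in range(MAX_PASSES):
        nxt = merge_step(state, alpha, C, center, dist)
        nxt = prune_step(nxt, alpha, C, center, dist)
        if np.array_equal(nxt.labels, state.labels):
            state = nxt
            break
        state = nxt
    else:
        logger.warning("merge/prune did not converge in %d passes", MAX_PASSES)
    for _ in range(MAX_PASSES):
        if _all_centers_below(state, alpha):
            break
        nxt = merge_step(state, alpha, C, center, dist)
        if np.array_equal(nxt.labels, state.labels):
            # no merge possible yet centers remain correlated: stop
            logger.warning("final merge stalled with correlated centers")
            break
        state = nxt
    else:
        logger.warning("final merge did not converge in %d passes", MAX_PASSES)
    return state


def silhouette_scores(labels: np.ndarray, dist: np.ndarray
                      ) -> tuple[np.ndarray, float]:
    """Per-gene silhouette ``(b−a)/max(a,b)`` on the given distances.

    Singletons score 0 (neutral).  A single-cluster partition has mean
    silhouette −1 so it can never be selected.
    """
    labels = np.asarray(labels)
    dist = np.asarray(dist, dtype=float)
    G = labels.shape[0]
    ids = np.unique(labels)
    if ids.size == 1:
        return np.zeros(G), -1.0
    sil = np.zeros(G)
    members = {int(p): np.flatnonzero(labels == p) for p in ids}
    for i in range(G):
        own = members[int(labels[i])]
        if own.size == 1:
            sil[i] = 0.0
            continue
        a = dist[i, own[own != i]].mean()
        b = min(dist[i, members[int(p)]].mean() for p in ids if p != labels[i])
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return sil, float(sil.mean())


def cluster_at_alpha(gd: GeneDistance, alpha: float, C: np.ndarray,
                     center: str = "mean") -> ClusterState:
    """One full pass of the procedure at a fixed threshold α."""
    labels = cut_hierarchy(gd.dist, alpha)
    state = _new_state(labels, C, center, gd.dist)
    state.n_cut = int(labels.max()) + 1
    return iterate_to_convergence(state, alpha, C, center, gd.dist)


def run_stihc(C, U: int = 20, center: str = "mean",
              gene_ids: tuple[str, ...] | None = None) -> StihcResult:
    """Full threshold sweep: α maximizing mean silhouette wins.

    Ties break toward the larger α (finer partitions).  Deterministic:
    repeated runs on the same input are identical.
    """
    if gene_ids is None:
        gene_ids = getattr(C, "gene_ids", None)
    Cmat = np.asarray(getattr(C, "C", C), dtype=float)
    gd = spearman_distance(Cmat, gene_ids)
    grid = make_alpha_grid(gd, U)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    per_alpha: list[dict] = []
    for alpha in grid:
        state = cluster_at_alpha(gd, float(alpha), Cmat, center)
        sil, mean_sil = silhouette_scores(state.labels, gd.dist)
        per_alpha.append({
            "alpha": float(alpha),
            "n_clusters": int(state.labels.max()) + 1,
            "mean_silhouette": mean_sil,
        })
        # >= so later (larger) alphas win ties
        if best is None or mean_sil >= best[0]:
            best = (mean_sil, state.labels, sil, float(alpha))
    assert best is not None
    _, labels, sil, alpha_opt = best
    return StihcResult(
        labels=labels, alpha_opt=alpha_opt, per_alpha=per_alpha,
        per_gene_sil=sil, gene_ids=gene_ids,
    )
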