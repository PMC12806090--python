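"""Partition evaluation: adjusted Rand index, Davies–Bouldin index and
cluster mean spatial expression patterns."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import comb

from stmodules.mesh_basis import BasisSystem, evaluate_basis


class MetricError(ValueError):
    pass


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Chance-corrected pair-counting agreement: 1 for identical
    partitions (up to relabeling), ~0 for random agreement.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.shape[0] != b.shape[0]:
        raise MetricError(
            f"label lengths differ: {a.shape[0]} vs {b.shape[0]}"
        )
    n = a.shape[0]
    if n < 2:
        raise MetricError("need at least 2 items")
    table = _contingency(a, b)
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def davies_bouldin(features: np.ndarray, labels) -> float:
    """Davies–Bouldin index on the given feature rows.

    Per-cluster scatter is the mean Euclidean distance of members to
    their centroid; the index is the mean over clusters of the worst
    ratio ``(σ_p + σ_q) / ||μ_p − μ_q||``.  Lower is better.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels).ravel()
    if X.shape[0] != labels.shape[0]:
        raise MetricError("features and labels length mismatch")
    ids = np.unique(labels)
    if ids.size < 2:
        raise MetricError("Davies-Bouldin needs at least 2 clusters")
    centroids = np.vstack([X[labels == p].mean(axis=0) for p in ids])
    scatter = np.array([
        np.linalg.norm(X[labels == p] - centroids[k], axis=1).mean()
        for k, p in enumerate(ids)
    ])
    sep = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    off = ~np.eye(ids.size, dtype=bool)
    if np.any(sep[off] == 0):
        pairs = np.argwhere((sep == 0) & off)
        raise MetricError(
            f"coincident centroids for cluster pairs {pairs[:5].tolist()}"
        )
    ratio = (scatter[:, None] + scatter[None, :]) / np.where(off, sep, np.inf)
    return float(np.max(ratio, axis=1).mean())


def cluster_mean_patterns(
    Y: np.ndarray,
    labels,
    basis: BasisSystem | None = None,
    *,
    standardize: bool = True,
    smooth_lambda: float | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-cluster mean expression profile across spots.

    Genes are standardized to zero mean / unit variance across spots
    before averaging (so affine rescalings of a pattern coincide).
    Zero-variance genes are excluded with a warning.  If ``basis`` and
    ``smooth_lambda`` are given, a smoothed surface for each mean
    profile is returned as basis coefficients refit through the mesh.
    """
    from stmodules.spatial_fit import fit_gene, FitConfig  # local: avoid cycle

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    labels = np.asarray(labels).ravel()
    if Y.shape[0] != labels.shape[0]:
        raise MetricError("Y rows and labels length mismatch")
    sd = Y.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance gene(s)",
            RuntimeWarning, stacklevel=2,
        )
    Z = Y.copy()
    if standardize:
        Z = (Y - Y.mean(axis=1, keepdims=True)) / np.where(keep, sd, 1.0)[:, None]
    ids = np.unique(labels)
    means = np.vstack([
        Z[(labels == p) & keep].mean(axis=0) if ((labels == p) & keep).any()
        else np.full(Y.shape[1], np.nan)
        for p in ids
    ])
    surfaces = None
    if basis is not None and smooth_lambda is not None:
        phi = evaluate_basis(basis.mesh, basis.mesh.nodes)
        cfg = FitConfig(family="normal")
        surfaces = np.vstack([
            fit_gene(row, basis, phi, smooth_lambda, cfg).coefficients
            for row in means
        ])
    return means, surfaces
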