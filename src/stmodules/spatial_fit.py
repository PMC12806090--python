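"""Penalized spatial regression per gene with a unified GCV-selected λ.

Each gene's expression is modeled as ``g(μ) = φ(s) c`` with the penalized
log-likelihood ``Σ_j l(y_j; c) − (λ/2) cᵀPc`` where ``P`` discretizes the
integrated squared Laplacian of the fitted field (the ½ makes the normal
family reduce to the usual ridge-type system).  The normal family has
the closed form ``(φᵀφ + λP)c = φᵀy``; the poisson family is solved by
penalized iteratively reweighted least squares (PIRLS) with step-halving.
A single λ is chosen for the whole gene set by minimizing the summed
generalized cross-validation criterion over a grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from stmodules.mesh_basis import BasisSystem, evaluate_basis

logger = logging.getLogger(__name__)

_FAMILIES = ("normal", "poisson")


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class FitConfig:
    """Solver settings for the per-gene penalized fits."""

    family: str = "normal"
    lambda_grid: tuple[float, ...] | None = None
    pirls_tol: float = 1e-8
    pirls_max_iter: int = 50
    max_halvings: int = 20

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise FitError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.lambda_grid is not None:
            grid = tuple(float(l) for l in self.lambda_grid)
            if any(l <= 0 for l in grid):
                raise FitError("lambda_grid values must be positive")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise FitError("lambda_grid must be strictly increasing")
            object.__setattr__(self, "lambda_grid", grid)
        if self.pirls_tol <= 0:
            raise FitError("pirls_tol must be > 0")
        if self.pirls_max_iter < 1:
            raise FitError("pirls_max_iter must be >= 1")


@dataclass
class GeneFit:
    """Result of a single-gene penalized fit."""

    coefficients: np.ndarray
    fitted_mean: np.ndarray
    edf: float
    deviance: float
    gcv: float
    converged: bool
    n_iter: int
    lam: float


@dataclass
class CoefficientMatrix:
    """Fitted basis coefficients for all genes at the unified λ."""

    C: np.ndarray
    lambda_opt: float
    gene_ids: tuple[str, ...]
    per_gene_gcv: np.ndarray  # (G, n_lambda)
    lambda_grid: tuple[float, ...]
    edf: np.ndarray | None = None
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape[0] != len(self.gene_ids):
            raise FitError("row count does not match gene_ids")
        if not np.all(np.isfinite(self.C)):
            raise FitError("non-finite coefficients")


def default_lambda_grid(phi: np.ndarray, penalty: np.ndarray, size: int = 25
                        ) -> tuple[float, ...]:
    """Scale-normalized log-spaced λ grid.

    Centered on ``σ_P = median diag(φᵀφ) / median diag(P)`` and spanning
    ``[1e−6·σ_P, 1e6·σ_P]``.  Medians (not means) because boundary
    slivers in jittered meshes inflate a few penalty diagonal entries by
    many orders of magnitude.
    """
    num = float(np.median(np.einsum("ij,ij->j", phi, phi)))
    den = float(np.median(np.diag(penalty)))
    sigma = num / den if den > 0 else 1.0
    return tuple(np.geomspace(1e-6 * sigma, 1e6 * sigma, size))


def _normal_solve(y, phi, lam, penalty, *, xtx=None, xty=None):
    """Closed-form normal-family solve; returns (c, cho_factor of system)."""
    if xtx is None:
        xtx = phi.T @ phi
    if xty is None:
        xty = phi.T @ y
    S = xtx + lam * penalty
    try:
        cf = cho_factor(S, lower=True)
    except LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(S)))
        warnings.warn(
            f"singular penalized system; adding ridge jitter {jitter:.3e}",
            RuntimeWarning, stacklevel=3,
        )
        cf = cho_factor(S + jitter * np.eye(S.shape[0]), lower=True)
    return cho_solve(cf, xty), cf


def _edf_from_factor(cf, xtwx: np.ndarray) -> float:
    """tr(H) = tr((φᵀWφ + λP)⁻¹ φᵀWφ) via one factorized solve."""
    return float(np.trace(cho_solve(cf, xtwx)))


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log-gamma term dropped: constant in c
    return float(np.sum(y * eta - np.exp(eta)))


def fit_gene(
    y: np.ndarray,
    basis: BasisSystem,
    phi: np.ndarray,
    lam: float,
    config: FitConfig | None = None,
) -> GeneFit:
    """Fit one gene's spatial field at smoothing level ``lam``.

    Normal family solves ``(φᵀφ + λP)c = φᵀy`` directly; poisson runs
    PIRLS with step-halving so the penalized log-likelihood never
    decreases across accepted iterations.  λ = 0 is accepted only when
    the unpenalized system is invertible.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float)
    n = y.shape[0]
    if phi.shape[0] != n:
        raise FitError(f"phi has {phi.shape[0]} rows for {n} observations")
    if not np.all(np.isfinite(y)):
        raise FitError("non-finite response")
    if lam < 0:
        raise FitError("lam must be >= 0")
    P = basis.penalty

    if config.family == "normal":
        c, cf = _normal_solve(y, phi, lam, P)
        mu = phi @ c
        rss = float(np.sum((y - mu) ** 2))
        edf = _edf_from_factor(cf, phi.T @ phi)
        gcv = _gcv(n, rss, edf)
        return GeneFit(c, mu, edf, rss, gcv, True, 1, lam)

    # poisson, log link
    if np.any(y < 0):
        raise FitError("negative counts under poisson family")
    # initialize from the data on the link scale
    eta = np.log(np.maximum(y, 0.0) + 0.5)
    c, _ = _normal_solve(eta, phi, max(lam, 1e-8), P)
    eta = phi @ c
    obj = _poisson_loglik(y, eta) - 0.5 * lam * float(c @ P @ c)
    converged = False
    it = 0
    cf = None
    xtwx = None
    for it in range(1, config.pirls_max_iter + 1):
        mu = np.exp(eta)
        w = mu
        z = eta + (y - mu) / mu
        wphi = phi * w[:, None]
        xtwx = phi.T @ wphi
        c_new, cf = _normal_solve(None, None, lam, P, xtx=xtwx, xty=wphi.T @ z)
        # step-halving keeps the penalized log-likelihood non-decreasing
        step = 1.0
        for _ in range(config.max_halvings + 1):
            c_try = c + step * (c_new - c)
            eta_try = phi @ c_try
            obj_try = _poisson_loglik(y, eta_try) - 0.5 * lam * float(c_try @ P @ c_try)
            if np.isfinite(obj_try) and obj_try >= obj - 1e-12 * max(1.0, abs(obj)):
                break
            step *= 0.5
        else:
            # even a tiny step decreases the objective: numerically at
            # the optimum unless the decrease is substantial
            if abs(obj_try - obj) <= 1e-6 * max(1.0, abs(obj)):
                converged = True
            else:
                logger.warning(
                    "PIRLS step-halving exhausted at iteration %d", it
                )
            break
        rel = abs(obj_try - obj) / max(1.0, abs(obj))
        c, eta, obj = c_try, eta_try, obj_try
        if rel < config.pirls_tol:
            converged = True
            break
    if not converged:
        logger.warning("PIRLS did not converge in %d iterations", it)
    mu = np.exp(eta)
    # edf from the hat matrix of the final weighted system
    w = mu
    xtwx = phi.T @ (phi * w[:, None])
    _, cf = _normal_solve(None, None, lam, P, xtx=xtwx, xty=np.zeros(phi.shape[1]))
    edf = _edf_from_factor(cf, xtwx)
    dev = _poisson_deviance(y, mu)
    gcv = _gcv(n, dev, edf)
    return GeneFit(c, mu, edf, dev, gcv, converged, it, lam)


def _gcv(n: int, deviance: float, edf: float) -> float:
    if edf >= n:
        raise FitError("model saturated; increase lambda")
    return n * deviance / (n - edf) ** 2


def gcv_score(fit: GeneFit, n: int) -> float:
    """Generalized cross-validation score ``n·D/(n − tr H)²``.

    ``D`` is the residual sum of squares (normal) or the deviance
    (poisson); ``tr H`` is the effective degrees of freedom of the final
    weighted system.
    """
    return _gcv(n, fit.deviance, fit.edf)


def select_lambda(
    Y: np.ndarray,
    basis: BasisSystem,
    phi: np.ndarray,
    config: FitConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Choose one λ for all genes by minimizing the summed GCV.

    Returns ``(lambda_opt, per_gene_gcv)`` with the table shaped
    ``(G, n_lambda)``.  Grid points where every gene's GCV is non-finite
    are excluded with a warning; ties go to the smaller λ.
    """
    config = config or FitConfig()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    if G < 1:
        raise FitError("need at least one gene")
    grid = config.lambda_grid or default_lambda_grid(phi, basis.penalty)
    P = basis.penalty

    table = np.full((G, len(grid)), np.nan)
    if config.family == "normal":
        # shared factorization per λ: solve all genes at once
        xtx = phi.T @ phi
        xtY = phi.T @ Y.T  # (K, G)
        for j, lam in enumerate(grid):
            Cj, cf = _normal_solve(None, None, lam, P, xtx=xtx, xty=xtY)
            edf = _edf_from_factor(cf, xtx)
            if edf >= n:
                continue
            resid = Y.T - phi @ Cj
            rss = np.einsum("ij,ij->j", resid, resid)
            table[:, j] = n * rss / (n - edf) ** 2
    else:
        for j, lam in enumerate(grid):
            for i in range(G):
                try:
                    table[i, j] = fit_gene(Y[i], basis, phi, lam, config).gcv
                except FitError:
                    table[i, j] = np.nan

    sums = np.full(len(grid), np.inf)
    for j in range(len(grid)):
        col = table[:, j]
        if np.all(np.isfinite(col)):
            sums[j] = col.sum()
        else:
            warnings.warn(
                f"lambda={grid[j]:.3e} excluded: non-finite GCV", RuntimeWarning,
                stacklevel=2,
            )
    if not np.any(np.isfinite(sums)):
        raise FitError("GCV non-finite at every lambda grid point")
    # argmin with ties toward the smaller λ (grid is increasing)
    lambda_opt = float(grid[int(np.argmin(sums))])
    return lambda_opt, table


def fit_all(
    Y: np.ndarray,
    basis: BasisSystem,
    config: FitConfig | None = None,
    gene_ids: list[str] | tuple[str, ...] | None = None,
    phi: np.ndarray | None = None,
) -> CoefficientMatrix:
    """Fit every gene at the unified GCV-selected λ.

    ``Y`` is genes×spots with columns aligned to the mesh nodes' spot
    order.  With nodes at the spots ``phi`` defaults to evaluating the
    basis at the nodes (the identity permutation).
    """
    config = config or FitConfig()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    if gene_ids is None:
        gene_ids = tuple(f"gene_{i}" for i in range(G))
    gene_ids = tuple(str(g) for g in gene_ids)
    if len(gene_ids) != G:
        raise FitError("gene_ids length does not match Y rows")
    if phi is None:
        phi = evaluate_basis(basis.mesh, basis.mesh.nodes)

    constant = np.ptp(Y, axis=1) == 0
    if np.any(constant):
        logger.info(
            "%d constant gene(s) fitted as constants", int(constant.sum())
        )

    grid = config.lambda_grid or default_lambda_grid(phi, basis.penalty)
    config = FitConfig(
        family=config.family,
        lambda_grid=tuple(grid),
        pirls_tol=config.pirls_tol,
        pirls_max_iter=config.pirls_max_iter,
        max_halvings=config.max_halvings,
    )
    lambda_opt, table = select_lambda(Y, basis, phi, config)

    K = phi.shape[1]
    C = np.empty((G, K))
    edf = np.empty(G)
    conv = np.zeros(G, dtype=bool)
    if config.family == "normal":
        xtx = phi.T @ phi
        Cj, cf = _normal_solve(None, None, lambda_opt, basis.penalty,
                               xtx=xtx, xty=phi.T @ Y.T)
        C[:] = Cj.T
        edf[:] = _edf_from_factor(cf, xtx)
        conv[:] = True
    else:
        for i in range(G):
            f = fit_gene(Y[i], basis, phi, lambda_opt, config)
            C[i] = f.coefficients
            edf[i] = f.edf
            conv[i] = f.converged
    return CoefficientMatrix(
        C=C, lambda_opt=lambda_opt, gene_ids=gene_ids,
        per_gene_gcv=table, lambda_grid=tuple(grid), edf=edf, converged=conv,
    )
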