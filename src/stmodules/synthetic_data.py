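"""Synthetic spatial expression with known module structure.

Generates a jittered spot lattice, a small inventory of well-separated
smooth spatial mean patterns (Gaussian bumps, bands, plateaus, rings),
and per-gene counts whose mean mixes the spatial pattern with a
spatially scrambled copy of itself:

    mean(s) = w * pattern(s) + (1 - w) * pattern(perm(s))

where ``w`` is the spatial-variability fraction.  At ``w = 1`` genes are
fully spatial; at ``w = 0`` the marginal intensity distribution is kept
but all spatial structure is destroyed.  Noise is negative binomial
(dispersion θ) or normal.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from stmodules.ihc_cluster import _spearman_matrix
from stmodules.mesh_basis import SpotSet


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimScenario:
    """Recipe for one simulated dataset."""

    nx: int = 30
    ny: int = 30
    jitter: float = 0.1
    n_patterns: int | None = None   # defaults to len(module_sizes)
    module_sizes: tuple[int, ...] = (25, 25, 25, 25)
    noise: str = "nb"               # "nb" or "normal"
    dispersion: float = 10.0        # θ for nb
    sigma: float = 0.1              # σ for normal noise
    mean_depth: float = 5.0         # target mean counts per spot
    spatial_fraction: float = 1.0
    n_spots_subsample: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        if self.n_patterns is None:
            object.__setattr__(self, "n_patterns", len(self.module_sizes))
        if len(self.module_sizes) != self.n_patterns:
            raise SimulationError("module_sizes length must equal n_patterns")
        if any(s < 1 for s in self.module_sizes):
            raise SimulationError("module sizes must be >= 1")
        if not 0.0 <= self.spatial_fraction <= 1.0:
            raise SimulationError("spatial_fraction must be in [0, 1]")
        if self.noise not in ("nb", "normal"):
            raise SimulationError("noise must be 'nb' or 'normal'")
        if self.dispersion <= 0 or self.sigma <= 0:
            raise SimulationError("dispersion and sigma must be > 0")


@dataclass
class SimResult:
    """Simulated expression with ground truth."""

    expression: np.ndarray          # (G, n)
    truth_labels: np.ndarray        # gene -> module index
    patterns: np.ndarray            # (n_patterns, n) mean fields
    spots: SpotSet
    gene_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def G(self) -> int:
        return self.expression.shape[0]

    @property
    def n(self) -> int:
        return self.expression.shape[1]


def make_spot_grid(nx: int, ny: int, jitter: float = 0.0,
                   seed: int | None = None) -> SpotSet:
    """``nx × ny`` lattice on the unit square with optional uniform jitter."""
    if nx < 2 or ny < 2:
        raise SimulationError("nx and ny must be >= 2")
    xs = np.linspace(0.0, 1.0, nx)
    ys = np.linspace(0.0, 1.0, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    if jitter:
        rng = np.random.default_rng(seed)
        coords = coords + rng.uniform(-jitter, jitter, size=coords.shape) / max(
            nx - 1, ny - 1
        )
        if pdist(coords).min() < 1e-9:
            raise SimulationError("jitter collided spots; reduce jitter")
    ids = tuple(f"spot_{i:05d}" for i in range(coords.shape[0]))
    return SpotSet(coords=coords, spot_ids=ids)


def _field(kind: str, coords: np.ndarray, rng: np.random.Generator
           ) -> np.ndarray:
    x, y = coords[:, 0], coords[:, 1]
    cx, cy = rng.uniform(0.2, 0.8, size=2)
    if kind == "bump":
        w = rng.uniform(0.10, 0.18)
        return np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * w**2))
    if kind == "band":
        theta = rng.uniform(0, np.pi)
        proj = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
        w = rng.uniform(0.08, 0.15)
        return np.exp(-(proj**2) / (2 * w**2))
    if kind == "plateau":
        # circular region plateau: high inside a disk, low outside
        r0 = rng.uniform(0.2, 0.35)
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        return 1.0 / (1.0 + np.exp((r - r0) / 0.04))
    if kind == "ring":
        r0 = rng.uniform(0.25, 0.4)
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        w = rng.uniform(0.06, 0.1)
        return np.exp(-((r - r0) ** 2) / (2 * w**2))
    raise SimulationError(f"unknown pattern kind {kind!r}")


_KINDS = ("bump", "band", "plateau", "ring")

#: patterns must be mutually distinct: max allowed |Spearman correlation|
PATTERN_MAX_RHO = 0.5

#: the generator aims below this before falling back to PATTERN_MAX_RHO
_PATTERN_TARGET_RHO = 0.3


def make_patterns(spots: SpotSet, n_patterns: int,
                  seed: int | None = None) -> np.ndarray:
    """Smooth nonnegative mean fields, pairwise |Spearman ρ| ≤ 0.5.

    Fields are drawn deterministically from the seed and accepted
    greedily: each candidate placement is redrawn until it decorrelates
    from all previously accepted fields (aiming for |ρ| ≤ 0.3, relaxing
    to the 0.5 bound after 200 attempts per field).
    """
    if n_patterns < 1:
        raise SimulationError("n_patterns must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    for k in range(n_patterns):
        kind = _KINDS[k % len(_KINDS)]
        best: tuple[float, np.ndarray] | None = None
        for attempt in range(200):
            f = _field(kind, spots.coords, rng)
            if not accepted:
                best = (0.0, f)
                break
            rho = _spearman_matrix(np.vstack([f, *accepted]),
                                   constant_ok=True)[0, 1:]
            worst = float(np.max(np.abs(rho)))
            if best is None or worst < best[0]:
                best = (worst, f)
            if worst <= _PATTERN_TARGET_RHO:
                break
        assert best is not None
        if best[0] > PATTERN_MAX_RHO:
            raise SimulationError(
                "could not achieve pattern separation in 200 attempts"
            )
        accepted.append(best[1])
    return np.vstack(accepted)


def simulate_genes(
    patterns: np.ndarray,
    module_sizes: tuple[int, ...],
    spots: SpotSet,
    *,
    noise: str = "nb",
    dispersion: float = 10.0,
    sigma: float = 0.1,
    mean_depth: float = 5.0,
    spatial_fraction: float = 1.0,
    seed: int | None = None,
) -> SimResult:
    """Draw noisy per-gene expression around mixed spatial means.

    The non-spatial component is a single seed-fixed permutation of the
    spot axis applied to each module's pattern, preserving marginal
    intensity while destroying spatial structure.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if len(module_sizes) != patterns.shape[0]:
        raise SimulationError("module_sizes length must match pattern count")
    n = patterns.shape[1]
    if n != spots.n:
        raise SimulationError("patterns and spots disagree on spot count")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    w = float(spatial_fraction)

    genes = []
    labels = []
    for m, size in enumerate(module_sizes):
        mu_s = patterns[m]
        mu_mix = w * mu_s + (1.0 - w) * mu_s[perm]
        # scale so the mean count per spot is ~mean_depth
        base = mu_mix + 0.05 * mu_mix.max() if mu_mix.max() > 0 else mu_mix + 1.0
        mu = base * (mean_depth / base.mean())
        for _ in range(size):
            if noise == "nb":
                p = dispersion / (dispersion + mu)
                genes.append(rng.negative_binomial(dispersion, p).astype(float))
            else:
                genes.append(mu + rng.normal(0.0, sigma, size=n))
            labels.append(m)
    expr = np.vstack(genes)
    gene_ids = tuple(
        f"gene_m{labels[i]}_{i:04d}" for i in range(expr.shape[0])
    )
    return SimResult(
        expression=expr,
        truth_labels=np.asarray(labels),
        patterns=patterns,
        spots=spots,
        gene_ids=gene_ids,
    )


def subsample_spots(result: SimResult, m: int,
                    seed: int | None = None) -> SimResult:
    """Keep a uniform random subset of ``m`` spot columns."""
    n = result.n
    if m > n:
        raise SimulationError(f"cannot sample {m} of {n} spots")
    if m < 3:
        raise SimulationError("need at least 3 spots for meshing")
    if m == n:
        return result
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=m, replace=False))
    spots = SpotSet(
        coords=result.spots.coords[keep],
        spot_ids=tuple(result.spots.spot_ids[i] for i in keep),
    )
    return SimResult(
        expression=result.expression[:, keep],
        truth_labels=result.truth_labels,
        patterns=result.patterns[:, keep],
        spots=spots,
        gene_ids=result.gene_ids,
    )


#: canonical scenario shapes: balanced, imbalanced, sparse-imbalanced
SCENARIO_PRESETS: dict[str, SimScenario] = {
    "balanced": SimScenario(module_sizes=(25, 25, 25, 25)),
    "imbalanced": SimScenario(module_sizes=(6, 2, 16, 25)),
    "sparse": SimScenario(module_sizes=(6, 2, 16, 25), n_spots_subsample=260),
}


def simulate_scenario(scenario: SimScenario | str,
                      seed: int | None = None) -> SimResult:
    """Run a full scenario (grid → patterns → genes → optional subsample)."""
    if isinstance(scenario, str):
        try:
            scenario = SCENARIO_PRESETS[scenario]
        except KeyError:
            raise SimulationError(
                f"unknown preset {scenario!r}; choose from "
                f"{sorted(SCENARIO_PRESETS)}"
            ) from None
    if seed is None:
        seed = scenario.seed
    spots = make_spot_grid(scenario.nx, scenario.ny, scenario.jitter, seed)
    patterns = make_patterns(spots, scenario.n_patterns, seed + 1)
    result = simulate_genes(
        patterns, scenario.module_sizes, spots,
        noise=scenario.noise, dispersion=scenario.dispersion,
        sigma=scenario.sigma, mean_depth=scenario.mean_depth,
        spatial_fraction=scenario.spatial_fraction, seed=seed + 2,
    )
    if scenario.n_spots_subsample is not None:
        result = subsample_spots(result, scenario.n_spots_subsample, seed + 3)
    return result
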