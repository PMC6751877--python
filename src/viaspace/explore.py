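"""Iterative PCA-directed local sampling of viable parameter regions.

Starting from the GA harvest nu(0), each iteration draws Gaussian samples
along the principal components of the current viable set, scaled by a
variance factor lambda that anneals linearly from ``lambda_start`` down to
``lambda_end`` over the iteration budget (wide early exploration, tight
late refinement).  Newly viable candidates are unioned with the set, the
PCA basis is refit, and a Frobenius-norm convergence score between
consecutive bases is tracked.

Poorly connected regions are separated by K-means, with the number of
clusters chosen by the gap statistic against a uniform reference over the
PCA-aligned bounding box of the data.  Clustering is only attempted when
one of three triggers fires (iteration budget exhausted, a sharp drop in
newly found viable points, or a large jump of the principal components),
and the root region may split at most once; child regions are explored
independently with a fresh iteration budget and never re-split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .ga import ViableSet
from .models import ParameterSpace

__all__ = [
    "PCABasis",
    "SamplerConfig",
    "Region",
    "fit_pca",
    "sample_candidates",
    "lambda_at",
    "convergence_norm",
    "gap_statistic",
    "should_cluster",
    "explore",
]


@dataclass(frozen=True)
class PCABasis:
    """Mean, orthonormal principal directions (rows) and per-component sdevs."""

    mean: np.ndarray  # (p,)
    components: np.ndarray  # (p, p), rows = principal directions
    sdevs: np.ndarray  # (p,), non-increasing
    degenerate: bool = False  # rank-deficient cloud, basis completed

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class SamplerConfig:
    n_samples: int = 100_000
    iterations: int = 10
    lambda_start: float = 4.0
    lambda_end: float = 2.0
    shrink_ratio: float = 10.0
    convergence_threshold: float | None = None  # C0; default 0.2*sqrt(p)
    stop_threshold: float = 0.0  # stop a region early when C falls below
    max_clusters: int = 2
    gap_n_ref: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_start >= self.lambda_end >= 1.0:
            raise ValueError("need lambda_start >= lambda_end >= 1")
        if self.n_samples <= 0 or self.iterations < 1:
            raise ValueError("invalid sampling budget")

    def c0(self, p: int) -> float:
        if self.convergence_threshold is not None:
            return self.convergence_threshold
        return 0.2 * math.sqrt(p)


@dataclass
class Region:
    """One viable region under exploration."""

    viable: ViableSet
    basis: PCABasis | None = None
    convergence_history: list[float] = field(default_factory=list)
    new_counts: list[int] = field(default_factory=list)  # viable found per iter
    explored_iterations: int = 0
    split_count: int = 0
    can_split: bool = False
    mode_tag: str = ""
    retired: bool = False

    def majority_tag(self) -> str:
        labels = [l for l in self.viable.labels if l]
        if not labels:
            return self.mode_tag
        vals, counts = np.unique(labels, return_counts=True)
        return str(vals[np.argmax(counts)])


def fit_pca(points: np.ndarray) -> PCABasis:
    """PCA of a point cloud via SVD of the centered data matrix.

    Requires at least p+1 points.  For rank-deficient clouds the SVD right
    singular vectors already complete an orthonormal basis; the missing
    directions carry (numerically) zero standard deviation and the basis is
    flagged degenerate.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least p+1={p + 1} points, got {n}")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=True)
    sdevs = np.zeros(p)
    k = min(n, p)
    sdevs[:k] = s[:k] / math.sqrt(n - 1)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    return PCABasis(mean=mean, components=vt, sdevs=sdevs, degenerate=rank < p)


def sample_candidates(
    basis: PCABasis,
    lam: float,
    n: int,
    space: ParameterSpace,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian proposals along the principal components.

    Each candidate is mean + sum_j components_j * (lam * sdev_j * z_j) with
    independent standard normal z.  Returns the full proposal matrix and a
    boolean mask of proposals inside the feasible box; out-of-bounds
    proposals are meant to be discarded before evaluation.
    """
    if lam < 1.0:
        raise ValueError("lambda must be >= 1 (scaled variance >= initial)")
    z = rng.standard_normal((n, basis.dim))
    cands = basis.mean + (z * (lam * basis.sdevs)) @ basis.components
    return cands, space.contains(cands)


def lambda_at(iteration: int, cfg: SamplerConfig) -> float:
    """Linear anneal of the variance scaling factor over the iteration budget."""
    if not 1 <= iteration <= cfg.iterations:
        raise ValueError("iteration out of range")
    if cfg.iterations == 1:
        return cfg.lambda_start
    frac = (iteration - 1) / (cfg.iterations - 1)
    return cfg.lambda_start + frac * (cfg.lambda_end - cfg.lambda_start)


def convergence_norm(current: PCABasis, previous: PCABasis) -> float:
    """Frobenius norm of the change in principal components.

    Principal directions are defined up to sign, and components of (near-)
    equal variance up to relabeling, so rows are first matched by maximal
    absolute inner product (Hungarian assignment) and sign-aligned; the norm
    is computed on the aligned difference.
    """
    a = current.components
    b = previous.components
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    dots = a @ b.T
    row, col = linear_sum_assignment(-np.abs(dots))
    aligned = np.empty_like(a)
    for r, c in zip(row, col):
        sign = 1.0 if dots[r, c] >= 0 else -1.0
        aligned[c] = sign * a[r]
    return float(np.linalg.norm(aligned - b))


def _log_wk(X: np.ndarray, k: int, seed: int) -> float:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return math.log(max(km.inertia_, np.finfo(float).tiny))


def gap_statistic(
    points: np.ndarray,
    k_max: int = 2,
    n_ref: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Optimal cluster count by the gap statistic.

    G(k) = E*[log W_k] - log W_k, with W_k the within-cluster sum of squares
    from K-means and the expectation estimated from ``n_ref`` uniform draws
    over the PCA-aligned bounding box of the data (rotation invariant).

    The cluster count is chosen with the reference-spread guard of the
    original estimator: the smallest k with G(k) >= G(k+1) - s_{k+1}, where
    s_k is the reference standard deviation inflated by sqrt(1 + 1/n_ref).
    A bare argmax of G systematically overestimates k on unimodal but
    non-uniform (e.g. center-dense) clouds.  Returns (k, G values).
    """
    rng = rng or np.random.default_rng(0)
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, p = X.shape
    if n < k_max * (p + 1):
        raise ValueError("too few points for requested k_max")
    mean = X.mean(axis=0)
    _, _, vt = np.linalg.svd(X - mean, full_matrices=True)
    proj = (X - mean) @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    gaps = np.empty(k_max)
    spreads = np.empty(k_max)
    for k in range(1, k_max + 1):
        seed = int(rng.integers(2**31 - 1))
        logw = _log_wk(X, k, seed)
        ref_logs = []
        for _ in range(n_ref):
            u = rng.uniform(lo, hi, size=(n, p))
            ref = mean + u @ vt
            ref_logs.append(_log_wk(ref, k, int(rng.integers(2**31 - 1))))
        gaps[k - 1] = float(np.mean(ref_logs)) - logw
        spreads[k - 1] = float(np.std(ref_logs)) * math.sqrt(1.0 + 1.0 / n_ref)
    for k in range(1, k_max):
        if gaps[k - 1] >= gaps[k] - spreads[k]:
            return k, gaps
    return k_max, gaps


def should_cluster(region: Region, cfg: SamplerConfig, p: int) -> bool:
    """Clustering trigger: any of the three criteria.

    (1) the iteration budget is exhausted; (2) the viable yield collapsed,
    i.e. this iteration found ``shrink_ratio`` times fewer viable points
    than the previous one; (3) the principal components jumped by more than
    C0 between consecutive iterations.
    """
    if region.explored_iterations >= cfg.iterations:
        return True
    counts = region.new_counts
    if len(counts) >= 2 and counts[-1] < counts[-2] / cfg.shrink_ratio:
        return True
    if region.convergence_history and region.convergence_history[-1] > cfg.c0(p):
        return True
    return False


def _run_iteration(
    region: Region,
    evaluators: list,
    space: ParameterSpace,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    n_samples: int,
) -> None:
    """One sample -> evaluate -> accumulate -> refit-PCA step for a region."""
    if region.basis is None:
        region.basis = fit_pca(region.viable.points)
    lam = lambda_at(min(region.explored_iterations + 1, cfg.iterations), cfg)
    cands, inb = sample_candidates(region.basis, lam, n_samples, space, rng)
    new_pts, new_costs, new_labels = [], [], []
    for x in cands[inb]:
        for ev in evaluators:
            cv = ev(x)
            if cv.viable:
                new_pts.append(x)
                new_costs.append(cv.value)
                new_labels.append(ev.tag)
                break
    region.new_counts.append(len(new_pts))
    if new_pts:
        region.viable = region.viable.merged(
            ViableSet(points=np.array(new_pts), costs=np.array(new_costs),
                      labels=new_labels)
        )
    prev = region.basis
    region.basis = fit_pca(region.viable.points)
    region.convergence_history.append(convergence_norm(region.basis, prev))
    region.explored_iterations += 1


def explore(
    nu0: ViableSet,
    evaluators,
    space: ParameterSpace,
    cfg: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> list[Region]:
    """Explore the viable space starting from the GA harvest.

    ``evaluators`` is one viability predicate or a list of them (multi-mode
    runs evaluate every candidate against each cost until one accepts, and
    tag the point with the accepting cost).  After a split, each child
    region keeps only the evaluator matching its majority tag and receives
    a fresh iteration budget.
    """
    if len(nu0) == 0:
        raise ValueError("initial viable set is empty")
    if not isinstance(evaluators, (list, tuple)):
        evaluators = [evaluators]
    evaluators = list(evaluators)
    rng = rng or np.random.default_rng(cfg.seed)
    p = space.dim

    # seed the yield history with |nu0| so the shrink trigger can compare the
    # first local iteration against the GA harvest
    root = Region(viable=nu0, can_split=True, new_counts=[len(nu0)])
    finished: list[Region] = []
    queue: list[Region] = [root]
    clustering_spent = False

    while queue:
        region = queue.pop(0)
        evs = evaluators
        if region.mode_tag:
            tagged = [e for e in evaluators if e.tag == region.mode_tag]
            evs = tagged or evaluators
        split_children: list[Region] | None = None
        while region.explored_iterations < cfg.iterations:
            try:
                _run_iteration(region, evs, space, cfg, rng, cfg.n_samples)
            except ValueError:  # too few points to even fit a basis
                region.retired = True
                break
            if (
                not clustering_spent
                and region.can_split
                and should_cluster(region, cfg, p)
            ):
                clustering_spent = True
                split_children = _try_split(region, cfg, rng, space)
                if split_children:
                    break
            if (
                cfg.stop_threshold > 0
                and region.convergence_history
                and region.convergence_history[-1] < cfg.stop_threshold
            ):
                break
        if split_children:
            queue.extend(split_children)
        else:
            region.mode_tag = region.majority_tag()
            finished.append(region)
    return finished


def _try_split(
    region: Region,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    space: ParameterSpace,
) -> list[Region] | None:
    """Gap-statistic split of a region; None when one cluster is optimal.

    Clustering operates on coordinates standardized by the feasible-box
    span so that nM-scaled parameters do not dominate the h^-1-scaled ones
    in the Euclidean metric.
    """
    X = region.viable.points
    p = X.shape[1]
    if X.shape[0] < cfg.max_clusters * (p + 1):
        return None
    Xs = X / (space.upper - space.lower)
    k, _ = gap_statistic(Xs, k_max=cfg.max_clusters, n_ref=cfg.gap_n_ref, rng=rng)
    if k < 2:
        return None
    km = KMeans(n_clusters=k, n_init=10,
                random_state=int(rng.integers(2**31 - 1))).fit(Xs)
    children = []
    for c in range(k):
        mask = km.labels_ == c
        vs = ViableSet(
            points=X[mask],
            costs=region.viable.costs[mask],
            labels=[region.viable.labels[i] for i in np.flatnonzero(mask)]
            if region.viable.labels
            else [],
        )
        child = Region(viable=vs, can_split=False, split_count=region.split_count + 1)
        child.mode_tag = child.majority_tag()
        children.append(child)
    return children
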