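"""Monte-Carlo estimation of viable-region volumes.

Robustness of a circuit model is scored by the volume of its viable
parameter region: the larger the volume, the wider the kinetic
perturbations the behavior survives.  Each region's volume is estimated by
rejection sampling inside the bounding hyper-box aligned with the region's
principal components (the box hugs an elongated, rotated cloud far tighter
than an axis-aligned box would, so far fewer samples are wasted), and
normalized by the volume of the full feasible box for model-to-model
comparison.

The required sample count for a confidence radius delta at level beta
follows from the central limit theorem applied to the Bernoulli hit
indicator with worst-case variance 1/4:

    |S| >= | Phi^{-1}((beta - 1) / 2) * Vol(B) / (2 * delta) |^2
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .explore import PCABasis, Region
from .models import ParameterSpace

__all__ = [
    "BoundingBox",
    "VolumeEstimate",
    "bounding_box",
    "mc_volume",
    "relative_volume",
    "required_samples",
]


@dataclass(frozen=True)
class BoundingBox:
    """Hyper-box aligned with a PCA basis, spanning a region's viable points."""

    basis: PCABasis
    lo: np.ndarray  # per-component minima of the projected points
    hi: np.ndarray
    volume: float  # product of edge lengths

    @property
    def degenerate(self) -> bool:
        return bool(np.any(self.hi <= self.lo))


@dataclass(frozen=True)
class VolumeEstimate:
    viable_count: int
    total_count: int
    vol_abs: float  # product of feasible-range units
    vol_rel: float | None  # fraction of the full feasible box, if normalized
    delta: float  # achieved confidence radius at level beta
    beta: float

    @property
    def hit_fraction(self) -> float:
        return self.viable_count / self.total_count


def bounding_box(region: Region) -> BoundingBox:
    """PCA-aligned bounding box of a region's viable points.

    Because the principal directions are orthonormal, the box volume is the
    product of the projected edge lengths.  Degenerate (zero-length) edges
    yield volume 0.
    """
    if region.basis is None:
        raise ValueError("region has no fitted PCA basis")
    X = region.viable.points
    proj = (X - region.basis.mean) @ region.basis.components.T
    lo = proj.min(axis=0)
    hi = proj.max(axis=0)
    return BoundingBox(basis=region.basis, lo=lo, hi=hi,
                       volume=float(np.prod(hi - lo)))


def mc_volume(
    box: BoundingBox,
    oracle,
    n_samples: int,
    rng: np.random.Generator,
    space: ParameterSpace | None = None,
    beta: float = 0.95,
    batch: int = 4096,
) -> VolumeEstimate:
    """Estimate the viable volume inside a bounding box by rejection sampling.

    Samples are drawn uniformly in box (component) coordinates, mapped back
    to parameter space and passed to ``oracle`` (any callable returning a
    truthy viability verdict, e.g. an :class:`~viaspace.cost.Evaluator`
    whose ``CostValue.viable`` is read).  Samples outside the feasible box
    of ``space`` count as non-viable without being evaluated; oracle
    failures count as non-viable.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    hits = 0
    done = 0
    while done < n_samples:
        m = min(batch, n_samples - done)
        u = rng.uniform(box.lo, box.hi, size=(m, box.lo.size))
        cands = box.basis.mean + u @ box.basis.components
        ok = np.ones(m, dtype=bool)
        if space is not None:
            ok = space.contains(cands)
        for x in cands[ok]:
            try:
                verdict = oracle(x)
            except Exception:
                continue
            viable = getattr(verdict, "viable", verdict)
            if viable:
                hits += 1
        done += m
    vol_abs = (hits / n_samples) * box.volume
    delta = achieved_delta(n_samples, box.volume, beta)
    return VolumeEstimate(viable_count=hits, total_count=n_samples,
                          vol_abs=vol_abs, vol_rel=None, delta=delta, beta=beta)


def achieved_delta(n_samples: int, vol_box: float, beta: float) -> float:
    """Confidence radius achieved by n samples at level beta (CLT bound)."""
    # the textbook bound quotes Phi^-1((beta-1)/2); as a CDF inverse its
    # argument must lie in (0,1), so the magnitude is Phi^-1((1-beta)/2)
    z = abs(norm.ppf((1.0 - beta) / 2.0))
    return z * vol_box / (2.0 * math.sqrt(n_samples))


def relative_volume(est: VolumeEstimate, space: ParameterSpace) -> float:
    """Viable volume as a fraction of the full feasible box over free parameters."""
    total = space.volume()
    if total <= 0:
        raise ValueError("feasible box has non-positive volume")
    return est.vol_abs / total


def required_samples(delta: float, beta: float, vol_box: float) -> int:
    """Minimum Monte-Carlo sample count for confidence radius delta at level beta.

    Uses the worst-case Bernoulli variance 1/4; for beta = 0.95 the bound
    reduces to |S| >= (0.98 * Vol(B) / delta)^2.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be positive")
    z = abs(norm.ppf((1.0 - beta) / 2.0))
    return max(1, math.ceil((z * vol_box / (2.0 * delta)) ** 2))
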