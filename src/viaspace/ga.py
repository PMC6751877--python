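"""Global estimation of viable parameter regions with a generational GA.

Unlike a conventional GA hunting a single optimum, every viable individual
encountered in any generation is recorded; their union forms the initial
viable set nu(0) that seeds the local sampling stage.  The GA is therefore
a biased global harvester, deliberately stopped early (few generations) so
it only sketches the viable regions rather than collapsing onto one point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cost import CostValue
from .models import ParameterSpace

__all__ = [
    "GAConfig",
    "ViableSet",
    "NoViableSeed",
    "init_population",
    "mutate",
    "crossover",
    "tournament_select",
    "run_ga",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 5000
    generations: int = 10
    mutation_prob: float = 0.75
    mutation_range: tuple[float, float] = (0.8, 1.2)
    tournament_size: int | None = None  # default: population_size // 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be in [0, 1]")
        lo, hi = self.mutation_range
        if not lo < hi:
            raise ValueError("mutation_range must be (low, high) with low < high")
        k = self.k_tournament
        if not 1 <= k <= self.population_size:
            raise ValueError("tournament size must be in [1, population_size]")

    @property
    def k_tournament(self) -> int:
        if self.tournament_size is not None:
            return self.tournament_size
        return max(1, self.population_size // 10)


@dataclass
class ViableSet:
    """Deduplicated collection of viable parameter points with their costs."""

    points: np.ndarray  # (m, p)
    costs: np.ndarray  # (m,)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.costs = np.asarray(self.costs, dtype=float)
        if self.points.shape[0] != self.costs.shape[0]:
            raise ValueError("points/costs length mismatch")
        if self.labels and len(self.labels) != self.points.shape[0]:
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return self.points.shape[0]

    @staticmethod
    def empty(p: int) -> "ViableSet":
        return ViableSet(points=np.empty((0, p)), costs=np.empty(0), labels=[])

    def merged(self, other: "ViableSet") -> "ViableSet":
        """Union of two sets, deduplicated on exact coordinate equality."""
        pts = np.vstack([self.points, other.points])
        costs = np.concatenate([self.costs, other.costs])
        labels = (self.labels or [""] * len(self)) + (
            other.labels or [""] * len(other)
        )
        _, idx = np.unique(pts, axis=0, return_index=True)
        idx = np.sort(idx)
        return ViableSet(points=pts[idx], costs=costs[idx],
                         labels=[labels[i] for i in idx])


class NoViableSeed(RuntimeError):
    """The GA finished all generations without a single viable individual."""


def init_population(space: ParameterSpace, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random population within the feasible box (linear scale)."""
    if n <= 0:
        raise ValueError("population size must be positive")
    return space.sample_uniform(n, rng)


def mutate(
    theta: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
    space: ParameterSpace,
) -> np.ndarray:
    """Multiplicative per-coordinate mutation, clipped to the feasible box.

    Each coordinate is independently, with probability ``mutation_prob``,
    multiplied by a uniform factor from ``mutation_range``.
    """
    theta = np.asarray(theta, dtype=float)
    hit = rng.random(theta.shape) < cfg.mutation_prob
    lo, hi = cfg.mutation_range
    factors = np.where(hit, rng.uniform(lo, hi, size=theta.shape), 1.0)
    return space.clip(theta * factors)


def crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two-point crossover: the middle segment [i, j) is exchanged."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parents must have equal dimension")
    p = a.size
    if p < 2:
        return a.copy(), b.copy()
    i, j = np.sort(rng.choice(p + 1, size=2, replace=False))
    c1, c2 = a.copy(), b.copy()
    c1[i:j], c2[i:j] = b[i:j], a[i:j]
    return c1, c2


def tournament_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> int:
    """Index of the best (lowest-cost) of k individuals drawn without replacement."""
    n = population.shape[0]
    if not 1 <= k <= n:
        raise ValueError("tournament size must be in [1, population size]")
    contenders = rng.choice(n, size=k, replace=False)
    return int(contenders[np.argmin(fitnesses[contenders])])


def run_ga(
    evaluator,
    space: ParameterSpace,
    cfg: GAConfig,
    rng: np.random.Generator | None = None,
) -> ViableSet:
    """Run the GA and return the union of all viable individuals seen.

    ``evaluator`` maps a parameter vector to a :class:`CostValue`; lower
    cost is fitter.  Non-finite costs (failed simulations) are ranked worst.
    Raises :class:`NoViableSeed` when no generation produced any viable
    individual.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    pop = init_population(space, cfg.population_size, rng)
    harvest = ViableSet.empty(space.dim)
    for gen in range(cfg.generations):
        costs = np.empty(cfg.population_size)
        viable = np.zeros(cfg.population_size, dtype=bool)
        for i in range(cfg.population_size):
            cv: CostValue = evaluator(pop[i])
            costs[i] = cv.value
            viable[i] = cv.viable
        if viable.any():
            harvest = harvest.merged(
                ViableSet(points=pop[viable], costs=costs[viable])
            )
        if gen == cfg.generations - 1:
            break
        fitness = np.where(np.isfinite(costs), costs, np.inf)
        selected = np.array(
            [
                tournament_select(pop, fitness, cfg.k_tournament, rng)
                for _ in range(cfg.population_size)
            ]
        )
        parents = pop[selected]
        children = np.empty_like(parents)
        for i in range(0, cfg.population_size - 1, 2):
            children[i], children[i + 1] = crossover(parents[i], parents[i + 1], rng)
        if cfg.population_size % 2 == 1:
            children[-1] = parents[-1]
        for i in range(cfg.population_size):
            children[i] = mutate(children[i], cfg, rng, space)
        pop = children
    if len(harvest) == 0:
        raise NoViableSeed(
            f"no viable individual in {cfg.generations} generations of "
            f"{cfg.population_size}"
        )
    return harvest
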