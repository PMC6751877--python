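"""Pipeline orchestration and synthetic test fixtures.

``run_pipeline`` chains the three stages — GA harvest, PCA-directed local
exploration, Monte-Carlo volume estimation — with per-stage seeds spawned
deterministically from one master seed, and writes every artifact plus a
JSON manifest sufficient to re-run the pipeline bit-identically.

``make_fixture`` builds the synthetic point clouds and analytic viability
oracles (Gaussian blobs, uniform boxes, disjoint box pairs, inscribed
spheres) used to test the clustering, exploration and volume machinery
against known ground truth.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cost import Evaluator, scenario
from .explore import Region, SamplerConfig, explore
from .ga import GAConfig, ViableSet, run_ga
from .io import save_manifest, save_viable_set
from .models import ModelSpec, ParameterSpace, get_model, parameter_space
from .volume import bounding_box, mc_volume, relative_volume

__all__ = [
    "RunConfig",
    "run_pipeline",
    "make_fixture",
    "region_volume",
]

# scenario ids per named experiment
_EXPERIMENTS = {
    "repressilator_s1": ("repressilator", ["repressilator_s1"]),
    "repressilator_s2": ("repressilator", ["repressilator_s2"]),
    "acdc_dual": ("acdc", ["acdc_bistable", "acdc_oscillatory"]),
    "acdc_oscillatory": ("acdc", ["acdc_oscillatory"]),
    "acdc_bistable": ("acdc", ["acdc_bistable"]),
    "dflipflop": ("dflipflop", ["dflipflop"]),
}


@dataclass
class RunConfig:
    """Full configuration of one glocal analysis run."""

    experiment: str  # key of _EXPERIMENTS
    omega1: int = 1  # flip-flop functional form flags
    omega2: int = 1
    ga: GAConfig = field(default_factory=GAConfig)
    # per-mode GA budget overrides, keyed by evaluator tag; modes differ
    # hugely in how hard they are to seed
    ga_overrides: dict = field(default_factory=dict)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    volume_samples: int | None = None  # default: required for delta_frac/beta
    delta_frac: float = 0.01  # confidence radius as a fraction of Vol(B)
    beta: float = 0.95
    duration: float | None = None  # evaluation horizon override (h)
    dt_out: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def model(self) -> ModelSpec:
        model_id, _ = _EXPERIMENTS[self.experiment]
        return get_model(model_id, self.omega1, self.omega2)

    def evaluators(self, model: ModelSpec) -> list[Evaluator]:
        _, scenario_ids = _EXPERIMENTS[self.experiment]
        return [
            scenario(sid, model, duration=self.duration, dt_out=self.dt_out)
            for sid in scenario_ids
        ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute ga -> explore -> volume with chained seeds; return the manifest.

    The manifest records the configuration, per-stage seeds and timings, the
    region tree with convergence histories, and per-region volume estimates.
    When ``config.out_dir`` is set, the initial viable set, per-region CSVs
    and the manifest are written there.
    """
    if config.experiment not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {config.experiment!r}")
    model = config.model()
    space = parameter_space(model)
    evaluators = config.evaluators(model)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_ga, rng_explore, rng_vol = (np.random.default_rng(s) for s in seeds)

    manifest: dict = {
        "experiment": config.experiment,
        "model": model.id,
        "omega1": model.omega1,
        "omega2": model.omega2,
        "seed": config.seed,
        "parameters": list(space.names),
        "stages": {},
    }
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # stage 1: GA harvest, one run per cost function
    t0 = time.perf_counter()
    nu0 = ViableSet.empty(space.dim)
    for ev in evaluators:
        ga_cfg = config.ga_overrides.get(ev.tag, config.ga)
        vs = run_ga(ev, space, ga_cfg, rng=rng_ga)
        vs.labels = [ev.tag] * len(vs)
        nu0 = nu0.merged(vs)
    manifest["stages"]["ga"] = {
        "viable_count": len(nu0),
        "population_size": config.ga.population_size,
        "generations": config.ga.generations,
        "wall_s": time.perf_counter() - t0,
    }
    if out:
        save_viable_set(nu0, space, out / "nu0.csv")

    # stage 2: PCA-directed local exploration with region splitting
    t0 = time.perf_counter()
    regions = explore(nu0, evaluators, space, config.sampler, rng=rng_explore)
    manifest["stages"]["explore"] = {
        "n_regions": len(regions),
        "wall_s": time.perf_counter() - t0,
        "regions": [
            {
                "mode_tag": r.mode_tag,
                "viable_count": len(r.viable),
                "iterations": r.explored_iterations,
                "convergence_history": [float(c) for c in r.convergence_history],
                "new_counts": r.new_counts,
                "retired": r.retired,
            }
            for r in regions
        ],
    }

    # stage 3: Monte-Carlo volume per region
    t0 = time.perf_counter()
    vols = []
    for i, region in enumerate(regions):
        ev = _region_evaluator(region, evaluators)
        est = region_volume(region, ev, space, rng_vol,
                            n_samples=config.volume_samples,
                            delta_frac=config.delta_frac, beta=config.beta)
        vols.append(
            {
                "region": i,
                "mode_tag": region.mode_tag,
                "vol_abs": est.vol_abs,
                "vol_rel": est.vol_rel,
                "delta": est.delta,
                "beta": est.beta,
                "n_samples": est.total_count,
                "viable_count": est.viable_count,
            }
        )
        if out:
            save_viable_set(region.viable, space, out / f"region_{i}.csv")
    manifest["stages"]["volume"] = {
        "wall_s": time.perf_counter() - t0,
        "estimates": vols,
    }
    if out:
        save_manifest(manifest, out / "manifest.json")
    return manifest


def _region_evaluator(region: Region, evaluators: list[Evaluator]) -> Evaluator:
    tagged = [e for e in evaluators if e.tag == region.mode_tag]
    return tagged[0] if tagged else evaluators[0]


def region_volume(
    region: Region,
    evaluator: Evaluator,
    space: ParameterSpace,
    rng: np.random.Generator,
    n_samples: int | None = None,
    delta_frac: float = 0.01,
    beta: float = 0.95,
):
    """Bounding-box Monte-Carlo volume of one region, normalized in place."""
    from .volume import required_samples

    box = bounding_box(region)
    if n_samples is None:
        n_samples = required_samples(delta_frac * box.volume, beta, box.volume)
    est = mc_volume(box, evaluator, n_samples, rng, space=space, beta=beta)
    rel = relative_volume(est, space)
    return type(est)(
        viable_count=est.viable_count, total_count=est.total_count,
        vol_abs=est.vol_abs, vol_rel=rel, delta=est.delta, beta=est.beta,
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures with analytic ground truth
# ---------------------------------------------------------------------------


def make_fixture(kind: str, rng: np.random.Generator, **params):
    """Reproducible synthetic data / oracles with documented ground truth.

    ``gaussian_blobs``: ``k`` isotropic Gaussian clouds with centers
    ``separation * sigma`` apart; returns (points, labels).
    ``uniform_box``: uniform cloud in a given box; returns points.
    ``two_boxes_oracle``: viability oracle true inside either of two
    disjoint axis-aligned boxes; returns (oracle, true_volume, boxes).
    ``sphere_oracle``: oracle true inside the sphere inscribed in the unit
    cube centered at 0.5^p; for p=3 the true fraction of the cube is pi/6.
    """
    if kind == "gaussian_blobs":
        k = params.get("k", 2)
        n = params.get("n_per_blob", 200)
        p = params.get("p", 2)
        sigma = params.get("sigma", 1.0)
        sep = params.get("separation", 20.0)
        pts, labels = [], []
        for i in range(k):
            center = np.zeros(p)
            center[0] = i * sep * sigma
            pts.append(rng.normal(center, sigma, size=(n, p)))
            labels.extend([i] * n)
        return np.vstack(pts), np.array(labels)
    if kind == "uniform_box":
        n = params.get("n", 1000)
        lo = np.asarray(params.get("lo", [0.0, 0.0]), dtype=float)
        hi = np.asarray(params.get("hi", [1.0, 1.0]), dtype=float)
        return rng.uniform(lo, hi, size=(n, lo.size))
    if kind == "two_boxes_oracle":
        lo1 = np.asarray(params["lo1"], dtype=float)
        hi1 = np.asarray(params["hi1"], dtype=float)
        lo2 = np.asarray(params["lo2"], dtype=float)
        hi2 = np.asarray(params["hi2"], dtype=float)

        def oracle(x):
            x = np.asarray(x, dtype=float)
            in1 = bool(np.all(x >= lo1) and np.all(x <= hi1))
            in2 = bool(np.all(x >= lo2) and np.all(x <= hi2))
            return in1 or in2

        true_vol = float(np.prod(hi1 - lo1) + np.prod(hi2 - lo2))
        return oracle, true_vol, ((lo1, hi1), (lo2, hi2))
    if kind == "sphere_oracle":
        p = params.get("p", 3)
        center = np.full(p, 0.5)
        radius = 0.5

        def oracle(x):
            return bool(np.sum((np.asarray(x, dtype=float) - center) ** 2)
                        <= radius**2)

        true_fraction = (math.pi ** (p / 2)) / math.gamma(p / 2 + 1) * radius**p
        return oracle, true_fraction
    raise ValueError(f"unknown fixture kind {kind!r}")
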