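import numpy as np
import pytest

import viaspace as v
from viaspace.cost import CostValue
from viaspace.explore import PCABasis, Region, should_cluster
from viaspace.ga import ViableSet


def unit_space(p):
    return v.ParameterSpace(
        names=tuple(f"p{i}" for i in range(p)),
        lower=np.zeros(p),
        upper=np.ones(p),
    )


class BoxOracle:
    """Analytic viability oracle: true inside any of the given boxes."""

    def __init__(self, boxes, tag="box"):
        self.boxes = [(np.asarray(lo, float), np.asarray(hi, float))
                      for lo, hi in boxes]
        self.tag = tag

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        ok = any(np.all(x >= lo) and np.all(x <= hi) for lo, hi in self.boxes)
        return CostValue(value=0.0 if ok else 1.0, viable=ok)


class TestFitPCA:
    def test_aligned_with_largest_variance_axis(self, rng):
        # oracle: eigendecomposition of the generating covariance
        cov = np.diag([25.0, 1.0, 0.04])
        X = rng.multivariate_normal(np.zeros(3), cov, size=5000)
        basis = v.fit_pca(X)
        assert abs(basis.components[0] @ np.array([1.0, 0.0, 0.0])) > 0.99
        assert np.allclose(basis.components @ basis.components.T, np.eye(3),
                           atol=1e-8)
        assert np.all(np.diff(basis.sdevs) <= 1e-12)

    def test_sdev_recovery_within_five_percent(self, rng):
        true_sd = np.array([5.0, 1.0, 0.2])
        X = rng.normal(0.0, true_sd, size=(10_000, 3))
        basis = v.fit_pca(X)
        assert np.allclose(basis.sdevs, true_sd, rtol=0.05)

    def test_points_on_a_line_are_degenerate(self):
        t = np.linspace(0.0, 1.0, 50)
        X = np.column_stack([t, 2 * t, -t])
        basis = v.fit_pca(X)
        assert basis.degenerate
        assert np.sum(basis.sdevs > 1e-10) == 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            v.fit_pca(np.zeros((3, 3)))


class TestSampleCandidates:
    def test_degenerate_basis_collapses_to_mean(self, rng):
        basis = PCABasis(mean=np.full(3, 0.5), components=np.eye(3),
                         sdevs=np.zeros(3), degenerate=True)
        cands, ok = v.sample_candidates(basis, 2.0, 100, unit_space(3), rng)
        assert np.allclose(cands, 0.5)
        assert ok.all()

    def test_covariance_recovery(self, rng):
        # oracle: sample covariance must match components' scaled spectrum
        sd = np.array([0.3, 0.1, 0.05])
        basis = PCABasis(mean=np.zeros(3), components=np.eye(3), sdevs=sd)
        lam = 2.0
        cands, _ = v.sample_candidates(basis, lam, 100_000, unit_space(3), rng)
        emp = np.cov(cands.T)
        expected = np.diag((lam * sd) ** 2)
        assert np.allclose(emp, expected, atol=0.03 * expected.max())

    def test_bounds_filter_retains_interior_cloud(self, rng):
        basis = PCABasis(mean=np.full(3, 0.5), components=np.eye(3),
                         sdevs=np.full(3, 0.01))
        _, ok = v.sample_candidates(basis, 1.5, 10_000, unit_space(3), rng)
        assert ok.mean() >= 0.99

    def test_lambda_below_one_rejected(self, rng):
        basis = PCABasis(mean=np.zeros(2), components=np.eye(2),
                         sdevs=np.ones(2))
        with pytest.raises(ValueError):
            v.sample_candidates(basis, 0.5, 10, unit_space(2), rng)


class TestLambdaSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = v.SamplerConfig(iterations=10)
        assert v.lambda_at(1, cfg) == 4.0
        assert v.lambda_at(10, cfg) == 2.0
        # linearity: the schedule midpoint lies halfway
        vals = [v.lambda_at(i, cfg) for i in range(1, 11)]
        assert np.allclose(np.diff(vals), vals[1] - vals[0])
        assert (v.lambda_at(5, cfg) + v.lambda_at(6, cfg)) / 2 == pytest.approx(3.0)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            v.SamplerConfig(lambda_start=2.0, lambda_end=4.0)
        with pytest.raises(ValueError):
            v.SamplerConfig(lambda_start=4.0, lambda_end=0.5)


class TestConvergenceNorm:
    def _basis(self, comps):
        p = comps.shape[0]
        return PCABasis(mean=np.zeros(p), components=comps, sdevs=np.ones(p))

    def test_identical_bases_zero(self):
        b = self._basis(np.eye(3))
        assert v.convergence_norm(b, b) == 0.0

    def test_sign_flip_invariance(self):
        a = self._basis(np.eye(3))
        flipped = np.eye(3)
        flipped[1] *= -1
        assert v.convergence_norm(self._basis(flipped), a) == pytest.approx(0.0)

    def test_equal_variance_relabeling_invariance(self):
        a = self._basis(np.eye(3))
        swapped = np.eye(3)[[1, 0, 2]]
        assert v.convergence_norm(self._basis(swapped), a) == pytest.approx(0.0)

    @pytest.mark.parametrize("phi", [0.05, 0.2, 0.5])
    def test_small_rotation_matches_direct_norm(self, phi):
        # oracle: direct Frobenius norm of R(phi) - I
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        got = v.convergence_norm(self._basis(R), self._basis(np.eye(2)))
        assert got == pytest.approx(np.linalg.norm(R - np.eye(2)), abs=1e-12)


class TestGapStatistic:
    def test_two_separated_blobs(self, rng):
        pts, _ = v.make_fixture("gaussian_blobs", rng, k=2, n_per_blob=150,
                                p=2, separation=20.0)
        k, _ = v.gap_statistic(pts, k_max=2, rng=rng)
        assert k == 2

    def test_single_uniform_cloud(self, rng):
        pts = v.make_fixture("uniform_box", rng, n=400, lo=[0, 0], hi=[1, 1])
        k, gaps = v.gap_statistic(pts, k_max=2, rng=rng)
        assert k == 1
        assert gaps[0] > gaps[1]

    def test_single_gaussian_cloud(self, rng):
        pts = rng.normal(0.0, 1.0, size=(400, 2))
        k, _ = v.gap_statistic(pts, k_max=2, rng=rng)
        assert k == 1


class TestShouldCluster:
    def _region(self, **kw):
        vs = ViableSet(points=np.zeros((3, 2)), costs=np.zeros(3))
        return Region(viable=vs, **kw)

    def test_iteration_budget_trigger(self):
        cfg = v.SamplerConfig(iterations=5)
        assert should_cluster(self._region(explored_iterations=5), cfg, p=2)

    def test_shrink_trigger(self):
        cfg = v.SamplerConfig(iterations=10, shrink_ratio=10)
        r = self._region(explored_iterations=1, new_counts=[6000, 500])
        assert should_cluster(r, cfg, p=2)

    def test_stable_region_no_trigger(self):
        cfg = v.SamplerConfig(iterations=10)
        r = self._region(explored_iterations=3, new_counts=[1000, 900, 950],
                         convergence_history=[0.05, 0.04])
        assert not should_cluster(r, cfg, p=2)

    def test_pc_jump_trigger(self):
        cfg = v.SamplerConfig(iterations=10)
        r = self._region(explored_iterations=2, new_counts=[100, 100],
                         convergence_history=[2.0])
        assert should_cluster(r, cfg, p=2)


class TestExplore:
    def _nu0(self, oracle, space, rng, n=60):
        pts = []
        while len(pts) < n:
            x = space.sample_uniform(1, rng)[0]
            if oracle(x).viable:
                pts.append(x)
        pts = np.array(pts)
        return ViableSet(points=pts, costs=np.zeros(len(pts)),
                         labels=[oracle.tag] * len(pts))

    def test_single_box_recovery(self, rng):
        space = unit_space(2)
        oracle = BoxOracle([([0.2, 0.3], [0.6, 0.8])])
        nu0 = self._nu0(oracle, space, rng)
        cfg = v.SamplerConfig(n_samples=1500, iterations=5, seed=4)
        regions = v.explore(nu0, oracle, space, cfg)
        assert len(regions) == 1
        pts = regions[0].viable.points
        inside = np.all((pts >= [0.2, 0.3]) & (pts <= [0.6, 0.8]), axis=1)
        assert inside.mean() >= 0.95
        assert len(pts) > len(nu0)

    def test_two_disjoint_boxes_split(self, rng):
        space = unit_space(2)
        oracle = BoxOracle([([0.05, 0.05], [0.25, 0.25]),
                            ([0.75, 0.75], [0.95, 0.95])])
        nu0 = self._nu0(oracle, space, rng, n=80)
        cfg = v.SamplerConfig(n_samples=1500, iterations=5, seed=4)
        regions = v.explore(nu0, oracle, space, cfg)
        assert len(regions) == 2
        centers = sorted(r.viable.points.mean(axis=0)[0] for r in regions)
        assert centers[0] < 0.3 and centers[1] > 0.7

    def test_seeded_reproducibility(self, rng):
        space = unit_space(2)
        oracle = BoxOracle([([0.2, 0.2], [0.7, 0.7])])
        nu0 = self._nu0(oracle, space, np.random.default_rng(2))
        cfg = v.SamplerConfig(n_samples=500, iterations=3, seed=11)
        r1 = v.explore(nu0, oracle, space, cfg)
        r2 = v.explore(nu0, oracle, space, cfg)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.viable.points, b.viable.points)

    def test_viable_counts_nondecreasing(self, rng):
        space = unit_space(2)
        oracle = BoxOracle([([0.3, 0.3], [0.7, 0.7])])
        nu0 = self._nu0(oracle, space, rng)
        cfg = v.SamplerConfig(n_samples=800, iterations=4, seed=6)
        regions = v.explore(nu0, oracle, space, cfg)
        # accumulation semantics: the viable set only grows within a region
        counts = regions[0].new_counts
        assert len(regions[0].viable) >= len(nu0)
        assert all(c >= 0 for c in counts)

    def test_empty_seed_rejected(self):
        space = unit_space(2)
        with pytest.raises(ValueError):
            v.explore(ViableSet.empty(2), BoxOracle([]), space,
                      v.SamplerConfig(n_samples=10, iterations=1))
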