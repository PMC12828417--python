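import numpy as np
import pytest
from scipy import stats

from esomaug import (
    GmmFit,
    bayes_boundary,
    critical_radius,
    fit_bimodal_gmm,
    gabriel_graph,
    make_chainlink,
    train_esom,
)
from esomaug.radius import DegenerateFitError

from conftest import make_grid


def brute_force_gabriel(points: np.ndarray) -> set:
    """Literal definition: edge iff no other point is inside or on the
    sphere with the segment as diameter."""
    points = np.asarray(points, dtype=float)
    p = len(points)
    edges = set()
    for i in range(p):
        for j in range(i + 1, p):
            mid = (points[i] + points[j]) / 2
            r2 = np.sum((points[i] - points[j]) ** 2) / 4
            ok = True
            for k in range(p):
                if k in (i, j):
                    continue
                if np.sum((points[k] - mid) ** 2) <= r2 * (1 + 1e-12):
                    ok = False
                    break
            if ok:
                edges.add((i, j))
    return edges


class TestGabrielGraph:
    def test_two_points_single_edge(self):
        edges = gabriel_graph(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert edges.tolist() == [[0, 1]]

    def test_collinear_middle_point_blocks(self):
        edges = gabriel_graph(np.array([[0.0], [1.0], [2.0]]))
        assert {tuple(e) for e in edges} == {(0, 1), (1, 2)}

    def test_unit_square_has_sides_but_no_diagonals(self):
        corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        edges = {tuple(e) for e in gabriel_graph(corners)}
        assert edges == {(0, 1), (1, 2), (2, 3), (0, 3)}

    def test_duplicates_deduplicated_and_too_few_rejected(self):
        edges = gabriel_graph(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
        assert edges.tolist() == [[0, 1]]
        with pytest.raises(ValueError):
            gabriel_graph(np.array([[1.0, 1.0], [1.0, 1.0]]))

    @pytest.mark.parametrize("seed,n,dim", [(0, 60, 2), (1, 40, 5)])
    def test_matches_brute_force_on_random_points(self, seed, n, dim):
        rng = np.random.default_rng(seed)
        points = rng.standard_normal((n, dim))
        got = {tuple(e) for e in gabriel_graph(points)}
        assert got == brute_force_gabriel(points)


class TestBimodalGmm:
    def test_recovers_well_separated_modes(self):
        rng = np.random.default_rng(1)
        heights = np.concatenate(
            [rng.normal(0.0, 0.5, 2500), rng.normal(8.0, 0.5, 2500)]
        )
        fit = fit_bimodal_gmm(heights, seed=0)
        assert not fit.degenerate
        assert abs(fit.means[0] - 0.0) < 0.1
        assert abs(fit.means[1] - 8.0) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_bimodal_gmm(np.full(50, 3.0))

    def test_single_gaussian_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        fit = fit_bimodal_gmm(rng.normal(5.0, 1.0, 2000), seed=0)
        assert fit.degenerate

    def test_too_few_heights_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_bimodal_gmm(np.arange(5.0))


class TestBayesBoundary:
    def test_symmetric_mixture_splits_at_midpoint(self):
        gmm = GmmFit(weights=np.array([0.5, 0.5]), means=np.array([0.0, 10.0]), sds=np.array([1.0, 1.0]))
        assert bayes_boundary(gmm) == pytest.approx(5.0, abs=1e-10)

    def test_heavier_left_component_pushes_boundary_right(self):
        gmm = GmmFit(weights=np.array([0.9, 0.1]), means=np.array([0.0, 10.0]), sds=np.array([1.0, 1.0]))
        assert bayes_boundary(gmm) > 5.0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_dense_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mu1 = rng.uniform(-2, 0)
        mu2 = rng.uniform(3, 8)
        gmm = GmmFit(
            weights=np.array([0.5, 0.5]) + rng.uniform(-0.3, 0.3) * np.array([1, -1]),
            means=np.array([mu1, mu2]),
            sds=rng.uniform(0.5, 2.0, size=2),
        )
        x = np.linspace(mu1, mu2, 2_000_001)
        diff = np.abs(
            gmm.weights[0] * stats.norm.pdf(x, gmm.means[0], gmm.sds[0])
            - gmm.weights[1] * stats.norm.pdf(x, gmm.means[1], gmm.sds[1])
        )
        oracle = x[np.argmin(diff)]
        assert bayes_boundary(gmm) == pytest.approx(oracle, abs=1e-5)


class TestCriticalRadius:
    def test_boundary_separates_two_prototype_clusters(self):
        # two 4x4 point grids of spacing ~1, 10 apart: short within-
        # cluster edges and a handful of length-10 bridges
        rng = np.random.default_rng(3)
        base = np.array([[i, j] for i in range(4) for j in range(4)], dtype=float)
        jitter = rng.normal(0.0, 0.02, size=(32, 2))
        data = np.vstack([base, base + [13.0, 0.0]]) + jitter
        grid = make_grid(data, rows=4, cols=8)
        grid.bmu = np.arange(32)  # every neuron occupied by one point
        estimate = critical_radius(grid, seed=0)
        assert not estimate.degenerate
        assert 1.5 < estimate.r < 13.0

    def test_chainlink_radius_below_inter_ring_gap(self):
        data = make_chainlink(n_per_class=150, seed=4)
        grid = train_esom(data, rows=10, cols=15, epochs=8, seed=4)
        estimate = critical_radius(grid, seed=4)
        Z = grid.scaler.transform(data.values)
        z1, z2 = Z[data.labels == 1], Z[data.labels == 2]
        gap = min(
            np.linalg.norm(z1[i] - z2, axis=1).min() for i in range(0, len(z1), 5)
        )
        assert estimate.r > 0
        assert estimate.r < max(gap, np.median(estimate.au_heights) * 4)

    def test_degenerate_blob_falls_back_to_median(self):
        rng = np.random.default_rng(6)
        prototypes = rng.normal(0.0, 1.0, size=(60, 3))
        grid = make_grid(prototypes, rows=6, cols=10)
        grid.bmu = np.arange(60)
        estimate = critical_radius(grid, seed=0)
        assert estimate.degenerate
        assert estimate.r == pytest.approx(float(np.median(estimate.au_heights)))

    def test_single_occupied_bmu_rejected(self):
        grid = make_grid(np.zeros((4, 2)), rows=2, cols=2)
        grid.bmu = np.zeros(10, dtype=int)
        with pytest.raises(ValueError):
            critical_radius(grid)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(7)
        prototypes = np.vstack(
            [rng.normal(0.0, 0.1, size=(30, 2)), rng.normal(4.0, 0.1, size=(30, 2))]
        )
        for s in (1.0, 3.0):
            grid = make_grid(prototypes * s, rows=6, cols=10)
            grid.bmu = np.arange(60)
            est = critical_radius(grid, seed=1)
            if s == 1.0:
                base = est
            else:
                np.testing.assert_allclose(np.sort(est.au_heights), np.sort(base.au_heights) * s, rtol=1e-9)
                assert est.r == pytest.approx(base.r * s, rel=1e-5)
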