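import math

import numpy as np
import pytest

from retidiv import (
    PointPattern,
    clark_evans,
    default_bandwidth,
    kde,
    nn_distances,
    simulate_csr,
)


class TestNNDistances:
    def test_two_points(self):
        pp = PointPattern([[0, 0], [3, 0]], (0, 0, 10, 10))
        assert nn_distances(pp).tolist() == [3.0, 3.0]

    def test_unit_spaced_collinear_triple(self):
        pp = PointPattern([[1, 5], [2, 5], [3, 5]], (0, 0, 10, 10))
        assert nn_distances(pp).tolist() == [1.0, 1.0, 1.0]

    def test_duplicate_coordinates_give_zero(self):
        pp = PointPattern([[1, 1], [1, 1], [5, 5]], (0, 0, 10, 10))
        assert nn_distances(pp).min() == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            nn_distances(PointPattern([[1, 1]], (0, 0, 10, 10)))

    def test_accelerated_equals_brute_force(self, rng):
        pts = simulate_csr(200, (0, 0, 50, 50), rng)
        pp = PointPattern(pts, (0, 0, 50, 50))
        assert np.array_equal(nn_distances(pp, "kdtree"), nn_distances(pp, "brute"))


class TestClarkEvans:
    def test_square_lattice_approaches_R_of_two(self):
        # lattice NN distance = spacing; CSR expectation = spacing/2
        k, s = 30, 1.0
        xs, ys = np.meshgrid(np.arange(k) * s, np.arange(k) * s)
        pts = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5])
        win = (0, 0, k * s, k * s)
        res = clark_evans(PointPattern(pts, win), guard_width=s)
        assert res.R == pytest.approx(2.0, rel=0.05)
        assert res.p < 1e-10  # strongly regular

    def test_guard_zero_matches_classical_uncorrected_ratio(self, rng):
        pts = simulate_csr(300, (30, 30, 70, 70), rng)
        pp = PointPattern(pts, (0, 0, 100, 100))
        res = clark_evans(pp, guard_width=0.0)
        nn = nn_distances(pp)
        lam = 300 / 10_000
        assert res.R == pytest.approx(nn.mean() / (0.5 / math.sqrt(lam)))
        assert res.n_focal == 300

    def test_translation_and_scale_invariance(self, rng):
        pts = simulate_csr(150, (0, 0, 20, 20), rng)
        r1 = clark_evans(PointPattern(pts, (0, 0, 20, 20)), guard_width=1.0)
        c = 3.7
        moved = pts * c + np.array([100.0, -40.0])
        r2 = clark_evans(
            PointPattern(moved, (100, -40, 100 + 20 * c, -40 + 20 * c)),
            guard_width=1.0 * c,
        )
        assert r2.R == pytest.approx(r1.R)
        assert r2.z == pytest.approx(r1.z)
        assert r2.p == pytest.approx(r1.p)

    def test_auto_guard_uses_mean_nn_distance(self, rng):
        pts = simulate_csr(200, (0, 0, 30, 30), rng)
        pp = PointPattern(pts, (0, 0, 30, 30))
        res = clark_evans(pp)
        assert res.guard_width == pytest.approx(nn_distances(pp).mean())
        assert res.n_focal < pp.n

    def test_emptying_guard_rejected(self):
        pp = PointPattern([[5, 5], [6, 6]], (0, 0, 10, 10))
        with pytest.raises(ValueError, match="smaller guard"):
            clark_evans(pp, guard_width=4.9)

    def test_clustered_vs_inhibited_sign(self, rng):
        """Clustered patterns push R below 1, lattice-jitter patterns above."""
        from retidiv import simulate_thomas

        win = (0, 0, 30, 30)
        below = above = 0
        for i in range(20):
            cl = simulate_thomas(win, 0.02, 15.0, 0.4, 5000 + i)
            if len(cl) >= 10:
                below += clark_evans(PointPattern(cl, win)).R < 1
            # jittered lattice filling the window: inhibited pattern
            g = np.array(
                [(x + 1.0, y + 1.0) for x in range(28) for y in range(28)]
            )
            g += rng.uniform(-0.2, 0.2, g.shape)
            above += clark_evans(PointPattern(g, win), guard_width=1.0).R > 1
        assert below >= 18 and above == 20


class TestKDE:
    def test_single_point_peaks_at_nearest_node(self):
        pp = PointPattern([[50.0, 50.0]], (0, 0, 100, 100))
        grid = kde(pp, bandwidth=5.0, grid=(64, 64))
        iy, ix = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        assert abs(grid.x[ix] - 50.0) <= (grid.x[1] - grid.x[0])
        assert abs(grid.y[iy] - 50.0) <= (grid.y[1] - grid.y[0])

    def test_mass_conservation_for_interior_pattern(self, rng):
        pts = simulate_csr(40, (30, 30, 70, 70), rng)
        pp = PointPattern(pts, (0, 0, 100, 100))
        grid = kde(pp, bandwidth=3.0, grid=(150, 150))
        assert grid.total_mass == pytest.approx(40, rel=0.02)

    def test_mirror_symmetric_input_gives_mirror_symmetric_grid(self):
        pp = PointPattern([[30.0, 50.0], [70.0, 50.0]], (0, 0, 100, 100))
        grid = kde(pp, bandwidth=8.0, grid=(80, 80))
        assert np.allclose(grid.values, grid.values[:, ::-1], atol=1e-12)

    def test_linearity_over_pattern_union(self, rng):
        win = (0, 0, 50, 50)
        a = simulate_csr(15, win, rng)
        b = simulate_csr(25, win, rng)
        ga = kde(PointPattern(a, win), 2.0, (40, 40)).values
        gb = kde(PointPattern(b, win), 2.0, (40, 40)).values
        gu = kde(PointPattern(np.vstack([a, b]), win), 2.0, (40, 40)).values
        assert np.allclose(ga + gb, gu, atol=1e-10)

    def test_nonpositive_bandwidth_rejected(self):
        pp = PointPattern([[1, 1], [2, 2]], (0, 0, 10, 10))
        with pytest.raises(ValueError, match="bandwidth"):
            kde(pp, bandwidth=0.0)


class TestDefaultBandwidth:
    def test_silverman_rule_on_standard_normal_points(self, rng):
        pts = rng.standard_normal((100, 2))
        pp = PointPattern(pts, (-10, -10, 10, 10))
        assert default_bandwidth(pp) == pytest.approx(0.9 * 100 ** (-0.2), rel=0.2)

    def test_scaling_homogeneity(self, rng):
        pts = rng.random((50, 2)) * 10
        pp1 = PointPattern(pts, (0, 0, 10, 10))
        pp2 = PointPattern(pts * 4, (0, 0, 40, 40))
        assert default_bandwidth(pp2) == pytest.approx(4 * default_bandwidth(pp1))

    def test_degenerate_zero_variance_axis_rejected(self):
        pts = [[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]
        with pytest.raises(ValueError, match="variance"):
            default_bandwidth(PointPattern(pts, (0, 0, 10, 10)))
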