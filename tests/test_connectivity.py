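"""Resistance transforms and the raster circuit solver, checked against
closed-form circuit laws and a dense Laplacian-pseudoinverse oracle."""

import numpy as np
import pytest

from habconn.connectivity import (
    DisconnectedError,
    NodeRegion,
    ResistanceTransform,
    cumulative_current,
    grid_to_graph,
    quantile_classify,
    solve_pair,
    suitability_to_resistance,
)
from habconn.geodata import Grid


def chain_grid(resistances):
    """1 x n grid whose cells give per-edge resistance = neighbors' mean."""
    return Grid(np.array([resistances], float), 30.0)


def region(shape, cells, label="r"):
    m = np.zeros(shape, bool)
    for ij in cells:
        m[ij] = True
    return NodeRegion(label, m)


class TestResistanceTransform:
    @pytest.mark.parametrize("c", [2.0, 8.0])
    def test_endpoints_exponential(self, c):
        tr = ResistanceTransform("exponential", c)
        assert tr(0.0) == pytest.approx(100.0, abs=1e-12)
        assert tr(1.0) == pytest.approx(1.0, abs=1e-12)

    def test_endpoints_linear(self):
        tr = ResistanceTransform("linear")
        assert tr(0.0) == 100.0 and tr(1.0) == 1.0

    def test_midpoint_c2_hand_value(self):
        # (1 - e^-1) / (1 - e^-2) = 0.731059; 100 - 99 * 0.731059 = 27.625
        tr = ResistanceTransform("exponential", 2.0)
        assert tr(0.5) == pytest.approx(27.625, abs=1e-3)

    @pytest.mark.parametrize("kind,c", [("linear", 0.0), ("exponential", 2.0),
                                        ("exponential", 8.0)])
    def test_strictly_decreasing_into_1_100(self, kind, c):
        tr = ResistanceTransform(kind, c if c else 2.0) if kind == "exponential" \
            else ResistanceTransform("linear")
        H = np.linspace(0, 1, 101)
        R = tr(H)
        assert np.all(np.diff(R) < 0)
        assert R.min() == pytest.approx(1.0) and R.max() == pytest.approx(100.0)

    def test_c_zero_rejected(self):
        with pytest.raises(ValueError, match="linear"):
            ResistanceTransform("exponential", 0.0)

    def test_out_of_range_clipped_with_warning(self):
        g = Grid(np.array([[0.5, 1.2], [-0.1, 0.0]]), 30.0)
        with pytest.warns(UserWarning, match="clipped"):
            R = suitability_to_resistance(g, ResistanceTransform("linear"))
        assert R.values[0, 1] == 1.0 and R.values[1, 0] == 100.0


class TestGridToGraph:
    def test_uniform_grid_equal_cardinal_conductances(self):
        g = grid_to_graph(Grid(np.full((4, 4), 2.0), 30.0))
        cards = g.conductance[np.isclose(g.conductance, 0.5)]
        diags = g.conductance[np.isclose(g.conductance, 0.5 / np.sqrt(2))]
        assert len(cards) + len(diags) == len(g.conductance)

    def test_3x3_edge_count(self):
        g = grid_to_graph(Grid(np.ones((3, 3)), 30.0))
        assert len(g.conductance) == 20  # 12 cardinal + 8 diagonal

    def test_nodata_cell_isolated(self):
        v = np.ones((3, 3))
        v[1, 1] = -9999.0
        g = grid_to_graph(Grid(v, 30.0, nodata=-9999.0))
        center_missing = g.node_index[1, 1]
        assert center_missing == -1
        assert len(g.conductance) == 20 - 8  # center touched all 8 neighbors

    def test_all_nodata_rejected(self):
        v = np.full((3, 3), -9999.0)
        with pytest.raises(ValueError, match="nodata"):
            grid_to_graph(Grid(v, 30.0, nodata=-9999.0))


class TestSolvePair:
    def test_series_chain(self):
        """1x3 chain with unit edge resistances: R_eff = 2, middle cell
        carries the full unit current."""
        g = grid_to_graph(chain_grid([1, 1, 1]), neighborhood=4)
        cur, reff = solve_pair(g, region((1, 3), [(0, 0)], "A"),
                               region((1, 3), [(0, 2)], "B"))
        assert reff == pytest.approx(2.0, abs=1e-10)
        assert cur.values[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_parallel_paths(self):
        """Two disjoint 2-resistance paths in parallel: R_eff = 1."""
        v = np.array([[1.0, 1.0, 1.0], [-1.0, -1.0, -1.0], [1.0, 1.0, 1.0]])
        g = grid_to_graph(Grid(np.where(v > 0, 1.0, -9999.0), 30.0, nodata=-9999.0),
                          neighborhood=4)
        # contract left column vs right column: two series-2 paths in parallel
        A = region((3, 3), [(0, 0), (2, 0)], "A")
        B = region((3, 3), [(0, 2), (2, 2)], "B")
        cur, reff = solve_pair(g, A, B)
        assert reff == pytest.approx(1.0, abs=1e-10)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(1, 50, (6, 3))
        v = np.hstack([half, half[:, ::-1]])
        g = grid_to_graph(Grid(v, 30.0))
        A = region(v.shape, [(2, 0), (3, 0)], "A")
        B = region(v.shape, [(2, 5), (3, 5)], "B")
        cur, _ = solve_pair(g, A, B)
        np.testing.assert_allclose(cur.values, cur.values[:, ::-1], atol=1e-8)

    def test_disconnected_regions_reported(self):
        v = np.ones((3, 3))
        v[:, 1] = -9999.0
        g = grid_to_graph(Grid(v, 30.0, nodata=-9999.0))
        with pytest.raises(DisconnectedError, match="disconnected"):
            solve_pair(g, region((3, 3), [(1, 0)], "A"), region((3, 3), [(1, 2)], "B"))

    def test_current_conservation_interior(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(1, 100, (10, 10))
        g = grid_to_graph(Grid(v, 30.0))
        A = region(v.shape, [(0, 0)], "A")
        B = region(v.shape, [(9, 9)], "B")
        # recompute signed node balance from potentials
        from habconn.connectivity import _contract
        na, nb = g.region_nodes(A.mask), g.region_nodes(B.mask)
        cur, reff = solve_pair(g, A, B)
        # conservation check via solve internals: rebuild potentials
        # (indirect: interior currents are conserved iff the per-cell current
        # of a throughflow node equals in=out; assert via a fine balance)
        relabel, _ = _contract(g, na, nb)
        # direct balance: solve again and compute signed sums
        import scipy.sparse as sp
        m = g.n_nodes
        L = sp.coo_matrix(
            (np.r_[g.conductance, g.conductance],
             (np.r_[g.edges_u, g.edges_v], np.r_[g.edges_v, g.edges_u])),
            shape=(m, m),
        ).tocsr()
        deg = np.asarray(L.sum(axis=1)).ravel()
        Lap = sp.diags(deg) - L
        rhs = np.zeros(m)
        rhs[na[0]] = 1.0
        rhs[nb[0]] = -1.0
        keep = np.arange(m) != nb[0]
        pot = np.zeros(m)
        pot[keep] = sp.linalg.spsolve(Lap[np.ix_(keep, keep)].tocsc(), rhs[keep])
        balance = Lap @ pot
        interior = np.ones(m, bool)
        interior[na] = interior[nb] = False
        assert np.max(np.abs(balance[interior])) < 1e-8

    def test_matches_dense_pseudoinverse_oracle(self):
        """Effective resistance A-B equals e^T L^+ e on 50 random grids."""
        rng = np.random.default_rng(2)
        for rep in range(50):
            nr = int(rng.integers(3, 8))
            nc = int(rng.integers(3, 8))
            v = rng.uniform(1, 100, (nr, nc))
            g = grid_to_graph(Grid(v, 30.0))
            A = region((nr, nc), [(0, 0)], "A")
            B = region((nr, nc), [(nr - 1, nc - 1)], "B")
            _, reff = solve_pair(g, A, B)
            m = g.n_nodes
            L = np.zeros((m, m))
            for u, w, c in zip(g.edges_u, g.edges_v, g.conductance):
                L[u, u] += c
                L[w, w] += c
                L[u, w] -= c
                L[w, u] -= c
            Lp = np.linalg.pinv(L, rcond=1e-13, hermitian=True)
            a = g.node_index[0, 0]
            b = g.node_index[nr - 1, nc - 1]
            expect = Lp[a, a] + Lp[b, b] - 2 * Lp[a, b]
            assert reff == pytest.approx(expect, abs=1e-8)

    def test_rayleigh_monotonicity(self):
        """Lowering any one cell's resistance cannot raise R_eff."""
        rng = np.random.default_rng(3)
        v = rng.uniform(10, 90, (7, 7))
        base_graph = grid_to_graph(Grid(v, 30.0))
        A = region(v.shape, [(0, 0)], "A")
        B = region(v.shape, [(6, 6)], "B")
        _, r0 = solve_pair(base_graph, A, B)
        for _ in range(20):
            i, j = rng.integers(0, 7, 2)
            v2 = v.copy()
            v2[i, j] = v[i, j] * rng.uniform(0.1, 0.9)
            _, r1 = solve_pair(grid_to_graph(Grid(v2, 30.0)), A, B)
            assert r1 <= r0 + 1e-10

    def test_uniform_scaling_of_resistance(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(1, 50, (6, 6))
        A = region(v.shape, [(0, 0)], "A")
        B = region(v.shape, [(5, 5)], "B")
        cur1, r1 = solve_pair(grid_to_graph(Grid(v, 30.0)), A, B)
        cur3, r3 = solve_pair(grid_to_graph(Grid(3 * v, 30.0)), A, B)
        assert r3 == pytest.approx(3 * r1, rel=1e-10)
        np.testing.assert_allclose(cur1.values, cur3.values, atol=1e-10)


@pytest.fixture(scope="module")
def graph():
    rng = np.random.default_rng(5)
    return grid_to_graph(Grid(rng.uniform(1, 30, (12, 12)), 30.0))


class TestCumulativeCurrent:

    def test_two_regions_equal_solve_pair(self, graph):
        A = region((12, 12), [(0, 0)], "A")
        B = region((12, 12), [(11, 11)], "B")
        cm = cumulative_current(graph, [A, B])
        cur, reff = solve_pair(graph, A, B)
        np.testing.assert_allclose(cm.grid.values, cur.values)
        assert cm.effective_resistance[("A", "B")] == reff

    def test_five_regions_ten_pairs(self, graph):
        regs = [region((12, 12), [(i, j)], f"r{k}") for k, (i, j) in
                enumerate([(0, 0), (0, 11), (11, 0), (11, 11), (6, 6)])]
        cm = cumulative_current(graph, regs)
        assert len(cm.pairs) == 10

    def test_region_order_irrelevant(self, graph):
        regs = [region((12, 12), [(i, j)], f"r{k}") for k, (i, j) in
                enumerate([(0, 0), (0, 11), (11, 11)])]
        a = cumulative_current(graph, regs)
        b = cumulative_current(graph, regs[::-1])
        np.testing.assert_allclose(a.grid.values, b.grid.values, atol=1e-10)


class TestQuantileClassify:
    def test_bin_of_95_in_1_to_100(self):
        g = Grid(np.arange(1.0, 101.0).reshape(10, 10), 30.0)
        bins = quantile_classify(g, 10)
        assert bins.values[g.values == 95.0] == 10

    def test_equal_count_bins(self):
        rng = np.random.default_rng(6)
        g = Grid(rng.random((20, 20)) + 0.01, 30.0)
        bins = quantile_classify(g, 10)
        counts = np.bincount(bins.values.astype(int).ravel(), minlength=11)[1:]
        assert counts.max() - counts.min() <= 1

    def test_monotone_in_current(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = Grid(rng.random((15, 15)) + 0.01, 30.0)
            bins = quantile_classify(g, 10)
            v = g.values.ravel()
            b = bins.values.ravel()
            order = np.argsort(v)
            assert np.all(np.diff(b[order]) >= 0)

    def test_too_few_distinct_values_rejected(self):
        g = Grid(np.tile([1.0, 2.0], (3, 3))[:3, :3], 30.0)
        with pytest.raises(ValueError, match="distinct"):
            quantile_classify(g, 10)
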