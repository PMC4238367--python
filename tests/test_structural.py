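"""Directional features, heat kernel, and structural distances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import vonmises
from skimage.draw import line_aa

from meaprior import (ContractError, DimensionError, ElectrodeGrid,
                      HoughConfig, Segment, VonMisesComponent,
                      build_adjacency, build_structural_graph,
                      detect_segments, discretize_vmm, fit_vmm, heat_kernel,
                      partition_image, propagate_and_normalize,
                      structural_distances)
from meaprior.structural import _vm_sector_mass, segment_endpoints


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

class TestPartition:
    def test_exact_tiling(self):
        grid = ElectrodeGrid(n_rows=2, n_cols=2, pitch_um=42, px_per_um=1.0)
        patches = partition_image(np.zeros((84, 84)), grid)
        assert len(patches) == 4
        assert all(p.shape == (42, 42) for p in patches)
        # non-overlapping cover of the active area
        seen = np.zeros((84, 84), dtype=int)
        for p in patches:
            seen[p.r0:p.r1, p.c0:p.c1] += 1
        assert (seen == 1).all()

    def test_full_chip_partition(self):
        grid = ElectrodeGrid.fit_image((2985, 2982), n_rows=64, n_cols=64)
        patches = partition_image(np.zeros((2985, 2982)), grid)
        assert len(patches) == 64 * 64
        assert patches[-1].r1 <= 2985 and patches[-1].c1 <= 2982

    def test_registration_offset(self):
        grid = ElectrodeGrid(n_rows=2, n_cols=2, pitch_um=10, px_per_um=1.0,
                             offset_row_px=3, offset_col_px=5)
        patches = partition_image(np.zeros((30, 30)), grid)
        assert (patches[0].r0, patches[0].c0) == (3, 5)

    def test_too_small_image_raises(self):
        grid = ElectrodeGrid(n_rows=4, n_cols=4, pitch_um=42, px_per_um=1.0)
        with pytest.raises(DimensionError):
            partition_image(np.zeros((100, 100)), grid)


# ---------------------------------------------------------------------------
# segment detection
# ---------------------------------------------------------------------------

def _draw_line(shape, r0, c0, r1, c1):
    img = np.zeros(shape)
    rr, cc, val = line_aa(r0, c0, r1, c1)
    img[rr, cc] = val
    return img


class TestDetectSegments:
    def test_blank_patch(self):
        assert detect_segments(np.zeros((32, 32))) == []
        assert detect_segments(np.full((32, 32), 0.7)) == []

    @pytest.mark.parametrize("angle_deg", [0, 30, 45, 90, 120])
    def test_single_line_orientation(self, angle_deg):
        n = 48
        theta = np.radians(angle_deg)
        cr = cc = n // 2
        dr, dc = -np.sin(theta), np.cos(theta)
        r0, c0 = int(cr - 20 * dr), int(cc - 20 * dc)
        r1, c1 = int(cr + 20 * dr), int(cc + 20 * dc)
        img = _draw_line((n, n), r0, c0, r1, c1)
        segs = detect_segments(img, HoughConfig(line_length=10), rng=0)
        assert segs
        angles = []
        for s in segs:
            a = np.degrees(np.arctan2(-(s.p1[0] - s.p0[0]), s.p1[1] - s.p0[1]))
            angles.append(a % 180)
        err = min(abs(((a - angle_deg) + 90) % 180 - 90) for a in angles)
        assert err < 5

    def test_two_crossing_lines(self):
        n = 48
        img = _draw_line((n, n), 24, 2, 24, 45) + _draw_line((n, n), 2, 24, 45, 24)
        segs = detect_segments(np.clip(img, 0, 1), HoughConfig(line_length=10), rng=0)
        assert len(segs) >= 2
        angles = {round(np.degrees(np.arctan2(-(s.p1[0] - s.p0[0]),
                                              s.p1[1] - s.p0[1])) % 180 / 45)
                  for s in segs}
        assert len(angles) >= 2


# ---------------------------------------------------------------------------
# Von Mises mixture
# ---------------------------------------------------------------------------

class TestFitVMM:
    def test_horizontal_segment_symmetry(self):
        # full-width horizontal segment through the patch center
        seg = Segment(p0=(20.5, 0), p1=(20.5, 41), votes=10)
        comps = fit_vmm([seg], (42, 42))
        assert len(comps) == 2
        mus = sorted(c.mean for c in comps)
        assert mus[0] == pytest.approx(np.pi, abs=1e-6) or \
            mus[0] == pytest.approx(0.0, abs=1e-6)
        assert {round(c.mean / np.pi, 3) for c in comps} == {0.0, 1.0}
        assert all(c.weight == pytest.approx(0.5) for c in comps)

    def test_boundary_endpoint_max_concentration(self):
        seg = Segment(p0=(0, 20), p1=(20, 20), votes=1)
        comps = fit_vmm([seg], (41, 41), kappa_scale=10.0, kappa_eps=1.0)
        # endpoint on the boundary: d = 0 -> kappa = scale / eps
        assert comps[0].kappa == pytest.approx(10.0)

    def test_kappa_capped(self):
        seg = Segment(p0=(0, 20), p1=(20, 20), votes=1)
        comps = fit_vmm([seg], (41, 41), kappa_scale=1e9, kappa_eps=1e-6,
                        kappa_max=1e4)
        assert comps[0].kappa == 1e4

    def test_vote_weighted_mixture(self):
        s1 = Segment(p0=(10, 0), p1=(10, 40), votes=30)
        s2 = Segment(p0=(0, 10), p1=(40, 10), votes=10)
        comps = fit_vmm([s1, s2], (41, 41))
        assert [c.weight for c in comps] == pytest.approx(
            [0.375, 0.375, 0.125, 0.125])

    def test_no_segments(self):
        assert fit_vmm([], (41, 41)) == []

    def test_kappa_scale_must_be_positive(self):
        with pytest.raises(ContractError):
            fit_vmm([Segment((0, 0), (1, 1), 1)], (8, 8), kappa_scale=0.0)


class TestDiscretize:
    def test_uniform_component(self):
        comps = [VonMisesComponent(mean=1.0, kappa=0.0, weight=1.0)]
        assert discretize_vmm(comps) == pytest.approx(np.full(8, 0.125))

    def test_concentrated_east(self):
        comps = [VonMisesComponent(mean=0.0, kappa=1e4, weight=1.0)]
        probs = discretize_vmm(comps)
        assert probs[0] > 0.999
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_mixture_zero_vector(self):
        assert (discretize_vmm([]) == 0).all()

    def test_matches_quadrature(self):
        comps = [VonMisesComponent(mean=0.0, kappa=2.0, weight=1.0)]
        probs = discretize_vmm(comps)
        for k in range(8):
            c = k * np.pi / 4
            f = lambda th: vonmises.pdf((th - 0.0 + np.pi) % (2 * np.pi) - np.pi, 2.0)
            expected = quad(f, c - np.pi / 8, c + np.pi / 8, limit=200)[0]
            assert probs[k] == pytest.approx(expected, abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(0, 2 * np.pi - 1e-9), st.floats(0, 100))
    def test_sector_masses_sum_to_one(self, mu, kappa):
        total = sum(
            _vm_sector_mass(mu, kappa, k * np.pi / 4 - np.pi / 8,
                            k * np.pi / 4 + np.pi / 8)
            for k in range(8))
        assert total == pytest.approx(1.0, abs=1e-9)


def test_endpoint_geometry_quadrants():
    # endpoint up-right of center must have a bearing in (0, pi/2)
    eps = segment_endpoints([Segment(p0=(5, 30), p1=(30, 5), votes=1)], (41, 41))
    assert 0 < eps[0].angle < np.pi / 2
    assert np.pi < eps[1].angle < 3 * np.pi / 2


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

class TestAdjacency:
    def test_zero_features(self):
        grid = ElectrodeGrid(n_rows=3, n_cols=3)
        A = build_adjacency(np.zeros((3, 3, 8)), grid)
        assert (A == 0).all()

    def test_directed_sum_rule(self):
        grid = ElectrodeGrid(n_rows=1, n_cols=2)
        f = np.zeros((1, 2, 8))
        f[0, 0, 0] = 0.4  # x East toward y
        f[0, 1, 4] = 0.3  # y West toward x
        A = build_adjacency(f, grid)
        assert A[0, 1] == pytest.approx(0.7)
        assert A[1, 0] == pytest.approx(0.7)

    def test_non_adjacent_zero(self):
        grid = ElectrodeGrid(n_rows=1, n_cols=3)
        f = np.ones((1, 3, 8))
        A = build_adjacency(f, grid)
        assert A[0, 2] == 0  # two steps apart on the lattice

    def test_symmetric_zero_diagonal(self, rng):
        grid = ElectrodeGrid(n_rows=4, n_cols=5)
        f = rng.random((4, 5, 8))
        A = build_adjacency(f, grid)
        assert np.allclose(A, A.T)
        assert (np.diag(A) == 0).all()


# ---------------------------------------------------------------------------
# heat kernel
# ---------------------------------------------------------------------------

def _random_adjacency(rng, n):
    M = rng.random((n, n))
    A = (M + M.T) / 2
    np.fill_diagonal(A, 0.0)
    return A


class TestHeatKernel:
    def test_t0_identity(self, rng):
        A = _random_adjacency(rng, 7)
        assert np.allclose(heat_kernel(A, 0.0).heat, np.eye(7), atol=1e-10)

    def test_two_node_closed_form(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        h = heat_kernel(A, 1.0).heat
        assert h[0, 1] == pytest.approx((1 - np.exp(-2)) / 2, abs=1e-12)

    def test_heat_conservation_and_symmetry(self, rng):
        A = _random_adjacency(rng, 12)
        for t in (0.1, 1.0, 25.0):
            h = heat_kernel(A, t).heat
            assert np.allclose(h.sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(h, h.T, atol=1e-12)
            assert h.min() > -1e-12

    def test_semigroup(self, rng):
        A = _random_adjacency(rng, 8)
        h1 = heat_kernel(A, 0.6).heat
        h2 = heat_kernel(A, 1.7).heat
        h3 = heat_kernel(A, 2.3).heat
        assert np.allclose(h1 @ h2, h3, atol=1e-8)

    def test_large_t_uniform_limit(self, rng):
        A = _random_adjacency(rng, 9) + 0.1  # strictly positive -> connected
        np.fill_diagonal(A, 0.0)
        h = heat_kernel(A, 500.0).heat
        assert np.allclose(h, 1.0 / 9, atol=1e-9)

    def test_eig_vs_expm_agree(self, rng):
        A = _random_adjacency(rng, 10)
        h1 = heat_kernel(A, 3.0, method="eig").heat
        h2 = heat_kernel(A, 3.0, method="expm").heat
        assert np.allclose(h1, h2, atol=1e-8)

    def test_asymmetric_rejected(self):
        A = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ContractError):
            heat_kernel(A, 1.0)

    def test_monotone_graph_exploration(self):
        # growing t never shrinks the set of pairs receiving heat above eps
        grid = ElectrodeGrid(n_rows=8, n_cols=8)
        f = np.full((8, 8, 8), 0.1)
        A = build_adjacency(f, grid)
        eps = 1e-4
        counts = []
        for t in (1.0, 5.0, 25.0):
            h = heat_kernel(A, t).heat
            counts.append(int((h > eps).sum()))
        assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# propagation, normalization, distances
# ---------------------------------------------------------------------------

class TestPropagate:
    def test_single_seed_empty_map(self, rng):
        A = _random_adjacency(rng, 5)
        hk = heat_kernel(A, 1.0)
        seeds, norm = propagate_and_normalize(hk, [2])
        assert norm.shape == (1, 1) and norm[0, 0] == 0

    def test_max_is_one(self, rng):
        A = _random_adjacency(rng, 6)
        hk = heat_kernel(A, 1.0)
        _, norm = propagate_and_normalize(hk, [0, 2, 4])
        assert norm.max() == pytest.approx(1.0)
        assert (np.diag(norm) == 0).all()

    def test_empty_seed_set_rejected(self, rng):
        hk = heat_kernel(_random_adjacency(rng, 4), 1.0)
        with pytest.raises(ContractError):
            propagate_and_normalize(hk, [])

    def test_radial_decay_on_homogeneous_lattice(self):
        n = 9
        grid = ElectrodeGrid(n_rows=n, n_cols=n)
        A = build_adjacency(np.full((n, n, 8), 0.125), grid)
        h = heat_kernel(A, 2.0).heat
        center = grid.node_index(4, 4)
        ring = {}
        for r in range(n):
            for c in range(n):
                d = max(abs(r - 4), abs(c - 4))
                ring.setdefault(d, []).append(h[center, grid.node_index(r, c)])
        means = [np.mean(ring[d]) for d in sorted(ring)]
        assert all(a > b for a, b in zip(means, means[1:]))


class TestStructuralDistances:
    def _graph(self, strengths, grid, thr=0.5):
        n = grid.n_electrodes
        seeds = np.arange(n)
        sc = build_structural_graph(seeds, strengths, grid, thr)
        return structural_distances(sc)

    def test_axial_and_diagonal_pitch(self):
        grid = ElectrodeGrid(n_rows=2, n_cols=2, pitch_um=42.0)
        s = np.ones((4, 4)) - np.eye(4)
        sc = self._graph(s, grid)
        # nodes 0=(0,0), 1=(0,1), 2=(1,0), 3=(1,1)
        assert sc.distance_um[0, 1] == pytest.approx(42.0)
        assert sc.distance_um[0, 3] == pytest.approx(42.0 * np.sqrt(2))

    def test_matches_bruteforce_path_enumeration(self, rng):
        import networkx as nx
        grid = ElectrodeGrid(n_rows=3, n_cols=3)
        s = np.zeros((9, 9))
        # random lattice-consistent strengths above/below threshold
        full = build_adjacency(np.full((3, 3, 8), 0.125), grid)
        mask = (full > 0)
        s[mask] = rng.random((mask.sum(),))
        s = np.maximum(s, s.T)
        s[0, 1] = s[1, 0] = 0.0  # knock out one edge
        sc = self._graph(s, grid, thr=0.3)
        g = nx.Graph()
        g.add_nodes_from(range(9))
        for a, b in sc.edges:
            g.add_edge(int(a), int(b),
                       weight=float(grid.euclid_um(sc.seeds[a], sc.seeds[b])))
        for x, y in itertools.combinations(range(9), 2):
            best = np.inf
            if nx.has_path(g, x, y):
                for path in nx.all_simple_paths(g, x, y):
                    w = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
                    best = min(best, w)
            assert sc.distance_um[x, y] == pytest.approx(best)

    def test_triangle_inequality_and_lower_bound(self, rng):
        grid = ElectrodeGrid(n_rows=3, n_cols=3)
        s = build_adjacency(np.full((3, 3, 8), 0.125), grid)
        sc = self._graph(s / s.max(), grid, thr=0.1)
        d = sc.distance_um
        n = 9
        for x, y, z in itertools.permutations(range(n), 3):
            assert d[x, y] <= d[x, z] + d[z, y] + 1e-9
        for x, y in itertools.combinations(range(n), 2):
            assert d[x, y] >= grid.euclid_um(x, y) - 1e-9
        assert (np.diag(d) == 0).all()

    def test_unreachable_pairs_flagged(self):
        grid = ElectrodeGrid(n_rows=1, n_cols=4)
        s = np.zeros((4, 4))
        s[0, 1] = s[1, 0] = 1.0  # single edge; nodes 2, 3 isolated
        sc = self._graph(s, grid)
        assert not sc.reachable[0, 2]
        assert sc.distance_norm[0, 2] == 1.0
        assert np.isinf(sc.distance_um[0, 2])
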