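"""Partition learning: divergence, geometry, cut optimization, pyramid baseline."""

import math

import numpy as np
import pytest

from braincbir import (
    CutLine,
    PartitionConfig,
    PartitionTree,
    cut_objective,
    extract_feature,
    learn_partition,
    optimize_cut,
    region_histograms,
    side_of_line,
    skl_divergence,
    spatial_pyramid_partition,
)
from braincbir.bovw import EncodedROI
from braincbir.errors import NoFeasibleCutError
from braincbir.partition import canonical_cut, clip_halfplane


def _skl_oracle(h1, h2, eps):
    """Direct two-term summation of KL(p||q) + KL(q||p)."""
    p = np.asarray(h1, float) + eps
    p = p / p.sum()
    q = np.asarray(h2, float) + eps
    q = q / q.sum()
    return sum(pi * math.log(pi / qi) for pi, qi in zip(p, q)) + sum(
        qi * math.log(qi / pi) for pi, qi in zip(p, q)
    )


class TestSklDivergence:
    def test_identical_histograms_give_zero(self):
        assert skl_divergence([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0)

    def test_closed_form_ln3(self):
        got = skl_divergence([0.75, 0.25], [0.25, 0.75], eps=1e-12)
        assert got == pytest.approx(math.log(3.0), abs=1e-6)

    def test_matches_summation_oracle_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            h1 = rng.uniform(size=1000)
            h2 = rng.uniform(size=1000)
            assert skl_divergence(h1, h2) == pytest.approx(_skl_oracle(h1, h2, 1e-10))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            skl_divergence([1.0, 0.0], [1.0, 0.0, 0.0])


class TestSideOfLine:
    def test_vertical_cut_example(self):
        assert side_of_line(np.array([0.25, 0.9]), CutLine(0.0, 0.5))[0]

    def test_boundary_point_goes_to_side_a(self):
        assert side_of_line(np.array([0.5, 0.3]), CutLine(0.0, 0.5))[0]

    def test_matches_sign_oracle_on_random_points(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(size=(1000, 2))
        cut = CutLine(theta=1.1, r=0.4)
        got = side_of_line(pts, cut)
        expected = pts[:, 0] * math.cos(1.1) + pts[:, 1] * math.sin(1.1) <= 0.4
        np.testing.assert_array_equal(got, expected)


def _uniform_grid_encoded(rng, n=200, V=8, word_of=None):
    pts = rng.uniform(size=(n, 2))
    codes = np.zeros((n, V))
    for i, (x, y) in enumerate(pts):
        w = word_of(x, y, rng) if word_of else rng.integers(0, V)
        codes[i, w] = 1.0
    return EncodedROI(points=pts, codes=codes)


class TestRegionHistograms:
    def test_single_leaf_equals_whole_roi_average_code(self):
        rng = np.random.default_rng(2)
        enc = _uniform_grid_encoded(rng)
        hists, empty = region_histograms(enc, PartitionTree.unit_square())
        np.testing.assert_allclose(hists[0], enc.codes.mean(0))
        assert not empty.any()

    def test_identical_halves_give_near_zero_divergence(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(400, 2))
        codes = np.zeros((400, 4))
        codes[:, 2] = 1.0  # same content everywhere
        tree = PartitionTree.unit_square()
        tree.split(0, CutLine(0.0, 0.5))
        hists, _ = region_histograms(EncodedROI(pts, codes), tree)
        assert skl_divergence(hists[0], hists[1]) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_match_closed_form(self):
        """Left half uses word 0, right half word 1; vertical cut; the
        eps-smoothed divergence has a closed form."""
        x = np.linspace(0.05, 0.95, 10)
        pts = np.stack(np.meshgrid(x, x), axis=-1).reshape(-1, 2)
        codes = np.zeros((100, 2))
        codes[pts[:, 0] <= 0.5, 0] = 1.0
        codes[pts[:, 0] > 0.5, 1] = 1.0
        tree = PartitionTree.unit_square()
        tree.split(0, CutLine(0.0, 0.5))
        eps = 1e-10
        hists, _ = region_histograms(EncodedROI(pts, codes), tree)
        # p = (1, eps)/(1+2eps) vs q = (eps, 1)/(1+2eps), so D = 2(1-eps')ln(1/eps')
        a, b = (1 + eps) / (1 + 2 * eps), eps / (1 + 2 * eps)
        closed = 2 * (a - b) * math.log(a / b)
        assert skl_divergence(hists[0], hists[1], eps) == pytest.approx(closed, rel=1e-9)

    def test_empty_leaf_flagged_uniform(self):
        pts = np.full((5, 2), 0.1)
        codes = np.zeros((5, 3))
        codes[:, 0] = 1.0
        tree = PartitionTree.unit_square()
        tree.split(0, CutLine(0.0, 0.5))
        hists, empty = region_histograms(EncodedROI(pts, codes), tree)
        assert not empty[0] and empty[1]
        np.testing.assert_allclose(hists[1], 1.0 / 3)


class TestCutObjective:
    def test_cut_outside_region_is_minus_inf(self):
        tree = PartitionTree.unit_square()
        enc = _uniform_grid_encoded(np.random.default_rng(4))
        obj = cut_objective(CutLine(0.0, 2.0), tree.leaves[0], [(enc.points, enc.codes)], 1.0)
        assert obj == -math.inf

    def test_symmetric_cut_of_homogeneous_region(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(2000, 2))
        codes = np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (2000, 1))
        tree = PartitionTree.unit_square()
        obj = cut_objective(CutLine(0.0, 0.5), tree.leaves[0], [(pts, codes)], 1.0)
        assert obj == pytest.approx(0.0, abs=1e-6)  # area term 0, divergence ~0

    def test_matches_composition_of_oracles(self):
        rng = np.random.default_rng(6)
        encs = [_uniform_grid_encoded(rng, n=50, V=4) for _ in range(2)]
        cut = CutLine(0.7, 0.55)
        square = PartitionTree.unit_square().leaves[0]
        lam, eps = 2.0, 1e-10
        got = cut_objective(cut, square, [(e.points, e.codes) for e in encs], lam, eps)
        # independent composition: sign-rule split + summation oracle + clipped areas
        sa = clip_halfplane(square, cut, True).area
        sb = clip_halfplane(square, cut, False).area
        expected = -lam * 2 * abs(sa - sb)
        for e in encs:
            proj = e.points[:, 0] * math.cos(0.7) + e.points[:, 1] * math.sin(0.7)
            ha = e.codes[proj <= 0.55].mean(0)
            hb = e.codes[proj > 0.55].mean(0)
            expected += _skl_oracle(ha / ha.sum(), hb / hb.sum(), eps)
        assert got == pytest.approx(expected, rel=1e-9)


def _left_right_dataset(seed, n_images=6, n_points=300, V=10):
    """Images whose left/right halves use disjoint word sets."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        pts = rng.uniform(size=(n_points, 2))
        w = np.where(
            pts[:, 0] <= 0.5,
            rng.integers(0, V // 2, n_points),
            rng.integers(V // 2, V, n_points),
        )
        codes = np.zeros((n_points, V))
        codes[np.arange(n_points), w] = 1.0
        out.append((pts, codes))
    return out


class TestOptimizeCut:
    def test_recovers_known_vertical_cut_over_seeds(self):
        square = PartitionTree.unit_square().leaves[0]
        for seed in range(5):
            subsets = _left_right_dataset(seed)
            cut, _ = optimize_cut(square, subsets, PartitionConfig(t_max=100), lam=1.0)
            c = canonical_cut(cut)
            angle_err = min(c.theta, math.pi - c.theta)
            r_eff = c.r if c.theta < math.pi / 2 else -c.r
            assert angle_err < 0.1
            assert abs(r_eff - 0.5) < 0.05

    def test_objective_at_solution_beats_all_grid_initializers(self):
        square = PartitionTree.unit_square().leaves[0]
        subsets = _left_right_dataset(1)
        cfg = PartitionConfig(t_max=50)
        cut, history = optimize_cut(square, subsets, cfg, lam=1.0)
        final = history[-1]
        verts = np.asarray(square.exterior.coords)
        for i in range(cfg.grid_thetas):
            theta = i * math.pi / cfg.grid_thetas
            proj = verts[:, 0] * math.cos(theta) + verts[:, 1] * math.sin(theta)
            for r in np.linspace(proj.min(), proj.max(), cfg.grid_offsets + 2)[1:-1]:
                assert cut_objective(CutLine(theta, float(r)), square, subsets, 1.0) <= final + 1e-9

    def test_matches_exhaustive_fine_grid_within_one_percent(self):
        square = PartitionTree.unit_square().leaves[0]
        subsets = _left_right_dataset(2, n_images=2, n_points=150)
        cut, history = optimize_cut(square, subsets, PartitionConfig(t_max=100), lam=1.0)
        best_grid = -math.inf
        for theta in np.linspace(0, math.pi, 60, endpoint=False):
            for r in np.linspace(-1.0, 1.5, 120):
                v = cut_objective(CutLine(float(theta), float(r)), square, subsets, 1.0)
                best_grid = max(best_grid, v)
        assert history[-1] >= best_grid * 0.99

    def test_accepted_objective_never_decreases(self):
        subsets = _left_right_dataset(3)
        _, history = optimize_cut(
            PartitionTree.unit_square().leaves[0], subsets, PartitionConfig(t_max=60), lam=1.0
        )
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_no_feasible_cut_raises(self):
        from shapely.geometry import Polygon

        tiny = Polygon([(0, 0), (0.01, 0), (0.01, 0.01), (0, 0.01)])
        with pytest.raises(NoFeasibleCutError):
            optimize_cut(tiny, _left_right_dataset(4, n_images=1), PartitionConfig())


class TestLearnPartition:
    def test_k0_is_the_unit_square(self):
        tree = learn_partition([], PartitionConfig(k=0))
        assert tree.n_leaves == 1
        assert tree.areas[0] == pytest.approx(1.0)

    def test_k_cuts_give_k_plus_1_leaves_with_conserved_area(self):
        rng = np.random.default_rng(7)
        encs = [_uniform_grid_encoded(rng, n=150, V=6) for _ in range(3)]
        cfg = PartitionConfig(k=3, t_max=20)
        tree = learn_partition(encs, cfg)
        assert tree.n_leaves == 4
        assert abs(tree.areas.sum() - 1.0) < 1e-9
        assert (tree.areas > 0).all()

    def test_every_point_maps_to_exactly_one_leaf(self):
        rng = np.random.default_rng(8)
        encs = [_uniform_grid_encoded(rng, n=100, V=5) for _ in range(2)]
        tree = learn_partition(encs, PartitionConfig(k=2, t_max=15))
        pts = rng.uniform(size=(500, 2))
        labels = tree.assign(pts)
        assert labels.min() >= 0 and labels.max() < tree.n_leaves

    def test_json_roundtrip_preserves_assignment(self, tmp_path):
        rng = np.random.default_rng(9)
        encs = [_uniform_grid_encoded(rng, n=100, V=5) for _ in range(2)]
        tree = learn_partition(encs, PartitionConfig(k=2, t_max=15))
        tree.to_json(tmp_path / "tree.json")
        back = PartitionTree.from_json(tmp_path / "tree.json")
        pts = rng.uniform(size=(200, 2))
        np.testing.assert_array_equal(back.assign(pts), tree.assign(pts))
        np.testing.assert_allclose(back.areas, tree.areas)


class TestSpatialPyramid:
    def test_three_levels_give_21_regions(self):
        assert spatial_pyramid_partition(3).n_regions == 21

    def test_one_level_matches_k0_partition(self):
        rng = np.random.default_rng(10)
        enc = _uniform_grid_encoded(rng, n=60, V=4)
        f_pyr = extract_feature(enc, spatial_pyramid_partition(1))
        f_tree = extract_feature(enc, PartitionTree.unit_square())
        np.testing.assert_array_equal(f_pyr, f_tree)

    def test_cell_areas_are_four_to_minus_level(self):
        pyr = spatial_pyramid_partition(3)
        for l, areas in enumerate(pyr.cell_areas()):
            np.testing.assert_allclose(areas, 4.0 ** (-l))
            assert areas.size == 4**l


class TestExtractFeature:
    def test_pyramid_feature_length_is_regions_times_words(self):
        rng = np.random.default_rng(11)
        enc = _uniform_grid_encoded(rng, n=80, V=50)
        assert extract_feature(enc, spatial_pyramid_partition(3)).shape == (21 * 50,)

    def test_learned_partition_length_is_leaves_times_words(self):
        rng = np.random.default_rng(12)
        encs = [_uniform_grid_encoded(rng, n=100, V=8) for _ in range(2)]
        tree = learn_partition(encs, PartitionConfig(k=2, t_max=10))
        assert extract_feature(encs[0], tree).shape == (3 * 8,)

    def test_single_region_single_code_returns_that_code(self):
        code = np.array([[0.2, 0.8, 0.0]])
        enc = EncodedROI(points=np.array([[0.4, 0.4]]), codes=code)
        np.testing.assert_allclose(extract_feature(enc, PartitionTree.unit_square()), code[0])

    def test_unit_square_invariance_across_roi_pixel_sizes(self):
        """Identical ROI content sampled on a 10x10 and a 3x-rescaled 30x30
        grid maps to the same unit-square coordinates, hence the same feature."""
        rng = np.random.default_rng(13)
        rr, cc = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        centers = np.stack([rr.ravel(), cc.ravel()], axis=1)
        codes = rng.uniform(size=(100, 5))
        tree = PartitionTree.unit_square()
        tree.split(0, CutLine(0.3, 0.4))
        # (c + 0.5)/10 == (3c + 1 + 0.5)/30 exactly
        pts_small = np.stack(
            [(centers[:, 1] + 0.5) / 10, (centers[:, 0] + 0.5) / 10], axis=1
        )
        pts_big = np.stack(
            [(3 * centers[:, 1] + 1.5) / 30, (3 * centers[:, 0] + 1.5) / 30], axis=1
        )
        f1 = extract_feature(EncodedROI(pts_small, codes), tree)
        f2 = extract_feature(EncodedROI(pts_big, codes), tree)
        np.testing.assert_array_equal(f1, f2)
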