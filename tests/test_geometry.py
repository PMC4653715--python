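import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opermorph import (
    LandmarkConfiguration,
    axis_shape_model,
    broken_stick,
    centroid_size,
    detect_start_point,
    form_pca,
    gpa,
    make_template_outline,
    procrustes_distance,
    resample_outline,
    shape_pca,
    species_mean_shapes,
)


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def random_polygon(rng, n=12):
    """Simple star-shaped polygon around the origin, counterclockwise."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(0.5, 1.5, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


class TestResampling:
    def test_unit_square_corners(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        cfg = resample_outline(sq, 4, start=0)
        assert {tuple(p) for p in np.round(cfg.coords, 9)} == {
            (0, 0), (1, 0), (1, 1), (0, 1)
        }

    def test_idempotent_on_equally_spaced_polygon(self):
        theta = -2 * np.pi * np.arange(16) / 16  # clockwise regular 16-gon
        poly = np.column_stack([np.cos(theta), np.sin(theta)])
        cfg = resample_outline(poly, 16, start=0)
        np.testing.assert_allclose(cfg.coords, poly, atol=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_equal_arc_gaps_by_brute_force(self, seed, k):
        """Oracle: brute-force arc-length positions along the source polygon."""
        rng = np.random.default_rng(seed)
        poly = random_polygon(rng, n=int(rng.integers(5, 25)))
        cfg = resample_outline(poly, k, start=0)
        # traversal used by the implementation: start at vertex 0, clockwise
        src = poly if _area(poly) < 0 else np.vstack([poly[:1], poly[1:][::-1]])
        closed = np.vstack([src, src[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        perimeter = cum[-1]
        # dense arc-length sampling of the source curve
        dense_s = np.linspace(0, perimeter, 200001)
        dense = np.column_stack(
            [np.interp(dense_s, cum, closed[:, 0]), np.interp(dense_s, cum, closed[:, 1])]
        )
        arc_pos = np.empty(k)
        for j, p in enumerate(cfg.coords):
            arc_pos[j] = dense_s[np.argmin(((dense - p) ** 2).sum(axis=1))]
        gaps = np.diff(np.concatenate([arc_pos, [perimeter]]))
        tol = 2 * perimeter / 200000  # dense-grid resolution
        np.testing.assert_allclose(gaps, perimeter / k, atol=tol + 1e-9)

    def test_clockwise_orientation_enforced(self):
        ccw = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)
        cfg = resample_outline(ccw, 8, start=0)
        assert _area(cfg.coords) < 0
        assert np.allclose(cfg.coords[0], [1, 0])

    def test_degenerate_outline_rejected(self):
        with pytest.raises(ValueError):
            resample_outline(np.zeros((5, 2)), 10, start=0)

    def test_k_bounds(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        with pytest.raises(ValueError):
            resample_outline(sq, 2, start=0)
        with pytest.raises(ValueError):
            resample_outline(sq, 50000, start=0)


def _area(p):
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


class TestStartPoint:
    def test_sharp_dorsal_notch_found_by_brute_force_match(self):
        # rounded rectangle with one sharp spike on the top edge
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([1.5 * np.cos(t), np.sin(t)])
        spike = np.argmin(np.abs(t - np.pi / 2))
        pts[spike] *= 1.4  # sharp dorsal protrusion
        assert detect_start_point(pts, smooth=1) == spike

    def test_circle_tie_breaks_to_lowest_index(self):
        t = -2 * np.pi * np.arange(40) / 40
        circle = np.column_stack([np.cos(t), np.sin(t)])
        idx = detect_start_point(circle, smooth=1)
        dorsal = np.flatnonzero(circle[:, 1] >= circle[:, 1].mean())
        assert idx == dorsal.min()

    def test_user_index_bypasses_detection(self):
        tpl = make_template_outline(40)
        cfg = resample_outline(tpl, 40, start=7)
        np.testing.assert_allclose(cfg.coords[0], tpl[7], atol=1e-9)

    def test_collinear_rejected(self):
        line = np.column_stack([np.arange(6.0), np.zeros(6)])
        with pytest.raises(ValueError):
            detect_start_point(line, smooth=1)

    def test_template_start_is_dorsal_apex(self):
        tpl = make_template_outline(100)
        i = detect_start_point(tpl)
        assert i == 0  # construction places the bump apex first
        assert tpl[i, 1] == tpl[:, 1].max()


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert centroid_size(sq) == pytest.approx(np.sqrt(2))

    def test_scaling_is_linear(self, rng):
        pts = rng.normal(size=(100, 2))
        assert centroid_size(3 * pts) == pytest.approx(3 * centroid_size(pts))

    def test_matches_direct_sum_oracle(self, rng):
        pts = rng.normal(size=(100, 2))
        c = pts.mean(axis=0)
        oracle = np.sqrt(sum(((p - c) ** 2).sum() for p in pts))
        assert centroid_size(pts) == pytest.approx(oracle, rel=1e-12)

    def test_single_point_is_zero(self):
        assert centroid_size([[2.0, 3.0]]) == 0.0


class TestGPA:
    def test_similarity_transform_removed(self, rng):
        base = random_polygon(rng, 30)
        other = 3.0 * base @ rot(np.deg2rad(37)).T + [5.0, -2.0]
        assert procrustes_distance(base, other) < 1e-10
        al = gpa([base, other])
        assert np.sqrt(((al.aligned[0] - al.aligned[1]) ** 2).sum()) < 1e-8

    def test_mirror_image_not_removed(self, rng):
        base = random_polygon(rng, 30)
        mirror = base * [-1.0, 1.0]
        assert procrustes_distance(base, mirror) > 1e-3

    def test_two_shape_alignment_matches_svd_oracle(self, rng):
        """Ordinary (two-configuration) Procrustes has a closed form."""
        a = random_polygon(rng, 25)
        b = random_polygon(rng, 25)
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        ac /= np.sqrt((ac**2).sum())
        bc /= np.sqrt((bc**2).sum())
        U, s, Vt = np.linalg.svd(bc.T @ ac)
        if np.linalg.det(U @ Vt) < 0:
            s = s.copy()
            s[-1] = -s[-1]
        oracle = np.sqrt(max(2.0 - 2.0 * s.sum(), 0.0))
        assert procrustes_distance(a, b) == pytest.approx(oracle, abs=1e-10)

    def test_distance_vs_rotation_grid_oracle(self, rng):
        tri_a = rng.normal(size=(3, 2))
        tri_b = rng.normal(size=(3, 2))
        ac = tri_a - tri_a.mean(0)
        bc = tri_b - tri_b.mean(0)
        ac /= np.sqrt((ac**2).sum())
        bc /= np.sqrt((bc**2).sum())
        thetas = np.arange(0, 2 * np.pi, 1e-4)
        best = min(
            np.sqrt(((ac - bc @ rot(t).T) ** 2).sum()) for t in thetas
        )
        assert procrustes_distance(tri_a, tri_b) == pytest.approx(best, abs=1e-4)

    def test_distance_symmetry_and_triangle_inequality(self, rng):
        shapes = [random_polygon(rng, 15) for _ in range(6)]
        for a in shapes:
            for b in shapes:
                dab = procrustes_distance(a, b)
                assert dab == pytest.approx(procrustes_distance(b, a), abs=1e-12)
        for a, b, c in zip(shapes, shapes[1:], shapes[2:]):
            assert procrustes_distance(a, c) <= (
                procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-8
            )

    def test_unit_cs_and_idempotence(self, rng):
        shapes = [random_polygon(rng, 20) for _ in range(8)]
        al = gpa(shapes)
        assert al.converged
        for cfg in al.aligned:
            assert abs(np.sqrt((cfg**2).sum()) - 1.0) < 1e-8
            assert np.abs(cfg.mean(axis=0)).max() < 1e-8
        al2 = gpa(list(al.aligned), tol=1e-12)
        # re-running on its own output barely moves the consensus
        assert procrustes_distance(al.mean_shape, al2.mean_shape) < 1e-8

    def test_scores_invariant_to_global_similarity(self, rng):
        shapes = [random_polygon(rng, 20) for _ in range(10)]
        R = rot(1.1)
        moved = [5.0 * s @ R.T + [1.0, 2.0] for s in shapes]
        s1 = shape_pca(gpa(shapes)).scores
        s2 = shape_pca(gpa(moved)).scores
        m = min(4, s1.shape[1])
        for j in range(m):
            c = np.corrcoef(s1[:, j], s2[:, j])[0, 1]
            assert abs(c) > 1 - 1e-6


class TestOrdination:
    def test_planted_single_axis_dominates(self, rng):
        tpl = make_template_outline(40)
        from opermorph import make_deformation_basis

        basis = make_deformation_basis(tpl, 2)
        shapes = [
            (tpl.reshape(-1) + amp * basis[0]).reshape(40, 2)
            for amp in np.linspace(-0.3, 0.3, 15)
        ]
        space = shape_pca(gpa(shapes))
        assert space.proportions[0] > 0.999

    def test_reconstruction_from_all_pcs(self, rng):
        shapes = [random_polygon(rng, 12) for _ in range(8)]
        al = gpa(shapes)
        space = shape_pca(al)
        X = al.flattened()
        recon = space.mean + space.scores @ space.loadings
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_proportions_and_orthonormality(self, rng):
        shapes = [random_polygon(rng, 12) for _ in range(10)]
        space = shape_pca(gpa(shapes))
        assert space.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        G = space.loadings @ space.loadings.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-8)
        assert np.abs(space.scores.mean(axis=0)).max() < 1e-9

    def test_form_space_with_equal_sizes_matches_shape_space(self, rng):
        shapes = [random_polygon(rng, 12) for _ in range(8)]
        al = gpa(shapes)
        al.centroid_sizes = np.full(al.n, 2.5)
        fs = form_pca(al)
        ss = shape_pca(al)
        m = min(3, ss.n_axes)
        for j in range(m):
            c = np.corrcoef(fs.scores[:, j], ss.scores[:, j])[0, 1]
            assert abs(c) > 1 - 1e-8

    def test_form_space_dominant_size_loads_on_lncs(self, rng):
        shapes = [random_polygon(rng, 12) for _ in range(10)]
        al = gpa(shapes)
        al.centroid_sizes = np.exp(rng.uniform(0, np.log(10), al.n))
        fs = form_pca(al)
        assert fs.is_form_space
        assert np.abs(fs.loadings[0, -1]) > np.abs(fs.loadings[0, :-1]).max()

    def test_form_space_rejects_nonpositive_cs(self, rng):
        shapes = [random_polygon(rng, 12) for _ in range(5)]
        al = gpa(shapes)
        al.centroid_sizes = np.zeros(al.n)
        with pytest.raises(ValueError):
            form_pca(al)


class TestBrokenStick:
    def test_three_axis_expectations(self):
        expected, _ = broken_stick([1.0, 1.0, 1.0])
        np.testing.assert_allclose(expected, [0.6111, 0.2778, 0.1111], atol=1e-4)
        assert expected.sum() == pytest.approx(1.0)

    def test_significance_example(self):
        expected, signif = broken_stick([3.0, 1.0, 0.0])
        assert signif.tolist() == [True, False, False]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            broken_stick([])


class TestSpeciesMeans:
    def test_identity_and_midpoint(self, rng):
        shapes = [random_polygon(rng, 10) for _ in range(4)]
        al = gpa(shapes)
        al.species_codes = ["a", "a", "b", "c"]
        configs, mean_cs = species_mean_shapes(al)
        assert [c.species_code for c in configs] == ["a", "b", "c"]
        mid = al.aligned[:2].mean(axis=0)
        mid -= mid.mean(axis=0)
        np.testing.assert_allclose(configs[0].coords, mid, atol=1e-9)
        np.testing.assert_allclose(
            mean_cs["a"], al.centroid_sizes[:2].mean(), atol=1e-12
        )

    def test_unlabeled_specimen_rejected(self, rng):
        shapes = [random_polygon(rng, 10) for _ in range(3)]
        al = gpa(shapes)
        with pytest.raises(ValueError):
            species_mean_shapes(al)


class TestAxisShapeModel:
    def test_score_zero_and_symmetry(self, rng):
        mean = random_polygon(rng, 10)
        loading = rng.normal(size=20)
        loading /= np.linalg.norm(loading)
        np.testing.assert_allclose(axis_shape_model(mean, loading, 0.0), mean)
        plus = axis_shape_model(mean, loading, 0.4)
        minus = axis_shape_model(mean, loading, -0.4)
        np.testing.assert_allclose((plus + minus) / 2, mean, atol=1e-12)
        disp = (plus - mean).reshape(-1)
        np.testing.assert_allclose(disp, 0.4 * loading, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            axis_shape_model(random_polygon(rng, 10), np.ones(7), 1.0)
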