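"""Unit tests for polygon shape descriptors and the statistics layer."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import ConvexHull

import heterophylly as h

SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
RECT41 = np.array([[0, 0], [4, 0], [4, 1], [0, 1]], float)


def rotate(verts, angle, center=None):
    c = np.asarray(center if center is not None else verts.mean(axis=0))
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return (verts - c) @ rot.T + c


def ngon(n, r=1.0):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return r * np.column_stack([np.cos(theta), np.sin(theta)])


def star(n_points=5, r_outer=1.0, r_inner=0.4):
    theta = np.linspace(0, 2 * np.pi, 2 * n_points, endpoint=False)
    r = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


class TestAreaPerimeter:
    def test_unit_square(self):
        assert h.area_perimeter(SQUARE) == pytest.approx((1.0, 4.0))

    def test_fine_circle_approximates_pi(self):
        area, _ = h.area_perimeter(ngon(512))
        assert area == pytest.approx(np.pi, rel=1e-3)

    def test_vertex_order_reversal_invariant(self):
        assert h.area_perimeter(SQUARE[::-1]) == h.area_perimeter(SQUARE)

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float)
        with pytest.raises(ValueError, match="simple"):
            h.area_perimeter(bowtie)


class TestCircularity:
    def test_square_closed_form(self):
        assert h.circularity(SQUARE) == pytest.approx(np.pi / 4)

    def test_fine_circle_clips_to_one(self):
        assert h.circularity(ngon(1024)) == pytest.approx(1.0, abs=1e-3)
        assert h.circularity(ngon(1024)) <= 1.0

    def test_elongation_at_fixed_area_decreases_circularity(self):
        values = []
        for aspect in (1.0, 2.0, 4.0, 8.0):
            a, b = np.sqrt(aspect), 1 / np.sqrt(aspect)  # area pi throughout
            theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
            ellipse = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
            values.append(h.circularity(ellipse))
        assert all(x > y for x, y in zip(values, values[1:]))


class TestSolidity:
    @pytest.mark.parametrize("poly", [SQUARE, RECT41, ngon(17)])
    def test_convex_polygons_have_unit_solidity(self, poly):
        assert h.solidity(poly) == pytest.approx(1.0, abs=1e-12)

    def test_star_matches_independent_hull_oracle(self):
        s = star()
        hull = ConvexHull(s)
        area, _ = h.area_perimeter(s)
        expected = area / hull.volume  # 2-D ConvexHull "volume" is area
        assert h.solidity(s) == pytest.approx(expected, abs=1e-12)
        assert h.solidity(s) < 1.0

    def test_lobe_amplitude_sweep_is_monotone(self):
        theta = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        values = []
        for amp in (0.05, 0.15, 0.25, 0.35, 0.45):
            r = 1.0 + amp * np.sin(8 * theta)
            values.append(h.solidity(np.column_stack([r * np.cos(theta), r * np.sin(theta)])))
        assert all(x > y for x, y in zip(values, values[1:]))


class TestEllipseAspectRatio:
    def test_four_to_one_rectangle(self):
        assert h.ellipse_aspect_ratio(RECT41) == pytest.approx(4.0, abs=1e-9)

    def test_circle_is_one(self):
        assert h.ellipse_aspect_ratio(ngon(512)) == pytest.approx(1.0, abs=1e-3)

    def test_rotation_invariant(self):
        for angle in (0.3, 1.1, 2.7):
            assert h.ellipse_aspect_ratio(rotate(RECT41, angle)) == pytest.approx(4.0, abs=1e-9)


class TestMinBoundingRectangle:
    def test_axis_aligned_rectangle(self):
        assert h.min_bounding_rectangle(RECT41) == pytest.approx((4.0, 1.0))

    def test_rotated_rectangle_recovered(self):
        rot = rotate(RECT41, np.pi / 6)
        length, width = h.min_bounding_rectangle(rot)
        assert (length, width) == pytest.approx((4.0, 1.0), abs=1e-9)

    @staticmethod
    def sweep(hull, angles):
        best, best_angle, sides = np.inf, 0.0, (0.0, 0.0)
        for angle in angles:
            rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
            proj = hull @ rot.T
            extent = proj.max(axis=0) - proj.min(axis=0)
            area = extent[0] * extent[1]
            if area < best:
                best, best_angle, sides = area, angle, sorted(extent, reverse=True)
        return best, best_angle, sides

    def test_matches_angle_sweep_oracle(self, rng):
        step = np.pi / 2 / 3600
        for _ in range(10):
            pts = rng.normal(size=(12, 2))
            hull = pts[ConvexHull(pts).vertices]
            best, angle, _ = self.sweep(hull, np.arange(0, np.pi / 2, step))
            # refine around the coarse optimum so the oracle's own angle
            # quantization error drops below the comparison tolerance
            best, _, sides = self.sweep(hull, np.linspace(angle - step, angle + step, 3600))
            length, width = h.min_bounding_rectangle(hull)
            assert length * width <= best + 1e-9  # exact minimum undercuts any grid
            assert length * width == pytest.approx(best, rel=1e-6)
            assert (length, width) == pytest.approx(tuple(sides), rel=1e-4)


class TestDescriptorInvariances:
    def test_translation_rotation_and_scaling_laws(self, rng):
        s = star(7, 1.3, 0.6)
        base = h.shape_descriptors(s)
        moved = rotate(s, 0.77) + np.array([13.0, -4.0])
        trans = h.shape_descriptors(moved)
        for key in ("area", "perimeter", "circularity", "solidity", "aspect_ratio", "length", "width"):
            assert trans[key] == pytest.approx(base[key], abs=1e-9), key
        scale = 2.5
        scaled = h.shape_descriptors(s * scale)
        assert scaled["area"] == pytest.approx(base["area"] * scale**2, rel=1e-9)
        assert scaled["perimeter"] == pytest.approx(base["perimeter"] * scale, rel=1e-9)
        assert scaled["length"] == pytest.approx(base["length"] * scale, rel=1e-9)
        assert scaled["width"] == pytest.approx(base["width"] * scale, rel=1e-9)
        for key in ("circularity", "solidity", "aspect_ratio"):
            assert scaled[key] == pytest.approx(base[key], abs=1e-9)

    def test_generated_populations_reproduce_cell_type_contrast(self):
        lobed = h.ContourSpec("lobed", 1.0, lobe_amplitude=0.3, lobe_count=8, n_vertices=128)
        circle = h.ContourSpec("circle", 1.0, n_vertices=128)
        elong = h.ContourSpec("ellipse", 1.0, aspect=4.0, n_vertices=128)
        pavement, _ = h.generate_cell_population(lobed, 30, 0.05, 1, group="pavement")
        palisade, _ = h.generate_cell_population(circle, 30, 0.05, 2, group="palisade")
        elongated, _ = h.generate_cell_population(elong, 30, 0.05, 3, group="elongated")
        table = h.descriptor_table(pavement + palisade + elongated)
        sol = table.groupby("group")["solidity"].mean()
        ar = table.groupby("group")["aspect_ratio"].mean()
        assert sol["pavement"] < sol["palisade"]
        assert ar["elongated"] > ar["pavement"] and ar["elongated"] > ar["palisade"]
        g = h.hedges_g(
            table.loc[table["group"] == "pavement", "solidity"],
            table.loc[table["group"] == "palisade", "solidity"],
        )
        assert abs(g) > 1.0


# ---------------------------------------------------------------------------
# statistics layer


def welch_by_hand(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelchT:
    def test_identical_groups(self):
        t, _, p = h.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=6)
        t1, df1, p1 = h.welch_t(a, b)
        t2, df2, p2 = h.welch_t(b, a)
        assert t1 == pytest.approx(-t2) and df1 == pytest.approx(df2) and p1 == pytest.approx(p2)

    def test_matches_hand_computation(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2.0, size=int(rng.integers(3, 12)))
            expected = welch_by_hand(a, b)
            observed = h.welch_t(a, b)
            assert observed == pytest.approx(expected, abs=1e-10)

    def test_degenerate_equal_constants(self):
        t, _, p = h.welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)


class TestHedgesG:
    def test_identical_groups_give_zero(self):
        assert h.hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_correction_vanishes_for_large_samples(self, rng):
        a = rng.normal(size=5000)
        b = rng.normal(1.0, 1.0, size=5000)
        d = (a.mean() - b.mean()) / np.sqrt(
            ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        )
        assert h.hedges_g(a, b) == pytest.approx(d, rel=1e-3)

    def test_small_sample_simulation_recovers_unit_shift(self, rng):
        gs = [h.hedges_g(rng.normal(1.0, 1.0, 3), rng.normal(0.0, 1.0, 3)) for _ in range(1000)]
        assert 0.7 <= np.mean(gs) <= 1.0

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError):
            h.hedges_g([1.0, 1.0], [2.0, 2.0])


class TestTukeyHSD:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        a, b = rng.normal(size=6), rng.normal(1, 1, size=7)
        table = h.tukey_hsd({"a": a, "b": b})
        _, p = stats.ttest_ind(a, b, equal_var=True)
        assert table["pvalue"].iloc[0] == pytest.approx(p, abs=1e-6)

    def test_group_order_permutation_invariant(self, rng):
        groups = {k: rng.normal(size=5) for k in "abc"}
        t1 = h.tukey_hsd(groups)
        t2 = h.tukey_hsd({k: groups[k] for k in "cab"})
        lookup = {frozenset((r["group_a"], r["group_b"])): r["pvalue"] for _, r in t2.iterrows()}
        for _, r in t1.iterrows():
            assert r["pvalue"] == pytest.approx(lookup[frozenset((r["group_a"], r["group_b"]))])

    def test_null_familywise_error_near_nominal(self, rng):
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {k: rng.normal(size=5) for k in "abcd"}
            if (h.tukey_hsd(groups)["pvalue"] < 0.05).any():
                rejections += 1
        assert rejections / n_sim <= 0.07  # ~0.05 familywise by construction

    def test_letter_display_separates_distinct_group(self, rng):
        groups = {"lo1": rng.normal(0, 0.1, 6), "lo2": rng.normal(0, 0.1, 6), "hi": rng.normal(5, 0.1, 6)}
        _, letters = h.tukey_hsd(groups, letters=True)
        assert letters["lo1"] == letters["lo2"]
        assert set(letters["hi"]) & set(letters["lo1"]) == set()


class TestPCA:
    def test_dominant_axis_drives_first_component(self, rng):
        import pandas as pd

        # after standardization PC1 reflects correlation structure: an
        # elongation axis shared by AR and cell length, with solidity noise
        n = 60
        ar = np.linspace(1, 8, n) + rng.normal(0, 0.1, n)
        table = pd.DataFrame(
            {
                "aspect_ratio": ar,
                "length": 2.0 * ar + rng.normal(0, 0.2, n),
                "solidity": 0.9 + rng.normal(0, 0.01, n),
            }
        )
        scores, loadings, ev = h.pca_scores(table)
        pc1 = loadings["PC1"].abs()
        assert pc1["solidity"] < min(pc1["aspect_ratio"], pc1["length"])
        assert ev[0] > 1.8  # the elongation axis carries most variance
        assert (np.diff(ev) <= 1e-12).all()

    def test_explained_variance_sums_to_descriptor_count(self, rng):
        import pandas as pd

        table = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        _, _, ev = h.pca_scores(table)
        assert ev.sum() == pytest.approx(5.0)

    def test_scores_reconstruct_standardized_data(self, rng):
        import pandas as pd

        table = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("wxyz"))
        scores, loadings, _ = h.pca_scores(table)
        z = (table - table.mean()) / table.std(ddof=1)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy(), atol=1e-10)

    def test_zero_variance_descriptor_dropped_with_warning(self, rng):
        import pandas as pd

        table = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10), "c": 1.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            scores, loadings, _ = h.pca_scores(table)
        assert "c" not in loadings.index
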