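"""Centres of mass, overlap matrices and angular group comparisons."""

import numpy as np
import pytest
from scipy import stats as sps

from vagusmap import (
    OverlapMatrix,
    PixelMap,
    angular_group_comparison,
    angular_separation_summary,
    center_of_mass,
    cross_technique_overlap,
    overlap_matrix,
    relative_overlap,
)
from vagusmap.mapping import GROUPS, template_coords, unit_disc_mask
from vagusmap.reference import MICROCT_MATRIX, SVNS_MATRIX
from vagusmap.stats import CoM, circular_mean_separation, watson_williams


def _map_from(grid, group="laryngeal"):
    g = np.asarray(grid, dtype=float)
    g[~unit_disc_mask(g.shape[0])] = 0.0
    return PixelMap(grid=g, group=group)


def _random_binary_maps(rng, w=32):
    return {
        g: _map_from(rng.random((w, w)) < 0.3, group=g) for g in GROUPS
    }


class TestCenterOfMass:
    def test_uniform_disc_is_degenerate(self):
        m = _map_from(np.ones((128, 128)))
        com = center_of_mass(m)
        assert com.degenerate
        assert com.angle == 0.0
        assert com.radius < 2.0 / 128

    def test_single_pixel_point_mass(self):
        w = 128
        x, y = template_coords(w)
        target = (0.5 * np.sin(np.deg2rad(90)), 0.5 * np.cos(np.deg2rad(90)))
        d2 = (x - target[0]) ** 2 + (y - target[1]) ** 2
        grid = np.zeros((w, w))
        grid[np.unravel_index(np.argmin(d2), d2.shape)] = 1.0
        com = center_of_mass(_map_from(grid))
        assert com.angle == pytest.approx(90.0, abs=2 * 360 / (np.pi * w))
        assert com.radius == pytest.approx(0.5, abs=2.0 / w)

    def test_matches_direct_summation_oracle(self, rng):
        w = 7
        x, y = template_coords(w)
        for _ in range(500):
            grid = rng.random((w, w)) * (rng.random((w, w)) < 0.5)
            grid[~unit_disc_mask(w)] = 0.0
            if grid.sum() == 0:
                continue
            m = _map_from(grid)
            com = center_of_mass(m)
            cx = (grid * x).sum() / grid.sum()
            cy = (grid * y).sum() / grid.sum()
            assert com.radius == pytest.approx(min(np.hypot(cx, cy), 1.0), abs=1e-12)
            if not com.degenerate:
                expected = np.mod(np.degrees(np.arctan2(cx, cy)), 360)
                assert com.angle == pytest.approx(expected, abs=1e-9)

    def test_empty_map_raises(self):
        with pytest.raises(ValueError, match="empty"):
            center_of_mass(_map_from(np.zeros((16, 16))))


class TestOverlapMatrix:
    def test_identical_maps_offdiag_equals_diag(self, rng):
        w = 32
        base = rng.random((w, w)) < 0.4
        maps = {g: _map_from(base.copy(), group=g) for g in GROUPS}
        m = overlap_matrix(maps)
        for g in GROUPS:
            for h in GROUPS:
                assert m.offdiag(g, h) == pytest.approx(m.diag(g))

    def test_disjoint_maps_offdiag_zero(self):
        w = 32
        top = np.zeros((w, w))
        top[: w // 2] = 1.0
        bottom = np.zeros((w, w))
        bottom[w // 2 :] = 1.0
        maps = {
            "laryngeal": _map_from(top, "laryngeal"),
            "pulmonary": _map_from(bottom, "pulmonary"),
            "cardiac_efferent": _map_from(top, "cardiac_efferent"),
            "cardiac_afferent": _map_from(bottom, "cardiac_afferent"),
        }
        m = overlap_matrix(maps)
        assert m.offdiag("laryngeal", "pulmonary") == 0.0
        assert m.offdiag("cardiac_efferent", "cardiac_afferent") == 0.0

    def test_matches_set_intersection_oracle(self, rng):
        mask = unit_disc_mask(32)
        for _ in range(200):
            maps = _random_binary_maps(rng)
            m = overlap_matrix(maps)
            pixel_sets = {
                g: set(zip(*np.nonzero(maps[g].grid > 0))) for g in GROUPS
            }
            denom = int(mask.sum())
            for g in GROUPS:
                assert m.diag(g) == pytest.approx(len(pixel_sets[g]) / denom)
                for h in GROUPS:
                    inter = len(pixel_sets[g] & pixel_sets[h])
                    assert m.offdiag(g, h) == pytest.approx(inter / denom)

    def test_invariants_hold(self, rng):
        for _ in range(50):
            m = overlap_matrix(_random_binary_maps(rng))
            mat = m.matrix
            assert np.allclose(mat, mat.T)
            for i in range(4):
                for j in range(4):
                    assert mat[i, j] <= min(mat[i, i], mat[j, j]) + 1e-12


class TestRelativeOverlap:
    @pytest.mark.parametrize(
        "matrix,a,b,expected",
        [
            (MICROCT_MATRIX, "cardiac_afferent", "cardiac_efferent", 0),
            (MICROCT_MATRIX, "pulmonary", "cardiac_afferent", 48),
            (MICROCT_MATRIX, "cardiac_efferent", "pulmonary", 30),
            (SVNS_MATRIX, "pulmonary", "cardiac_efferent", 52),
        ],
    )
    def test_reference_worked_examples(self, matrix, a, b, expected):
        assert relative_overlap(matrix, a, b) == expected

    def test_self_overlap_is_100(self):
        assert relative_overlap(MICROCT_MATRIX, "pulmonary", "pulmonary") == 100

    def test_zero_area_raises(self):
        m = OverlapMatrix(technique="microct", matrix=np.zeros((4, 4)))
        with pytest.raises(ValueError, match="zero area"):
            relative_overlap(m, "laryngeal", "pulmonary")

    def test_consistency_identity(self, rng):
        """relative_overlap(A,B) * diag(A) equals
        relative_overlap(B,A) * diag(B) up to integer rounding."""
        for _ in range(50):
            m = overlap_matrix(_random_binary_maps(rng))
            for a in GROUPS:
                for b in GROUPS:
                    if a == b or m.diag(a) == 0 or m.diag(b) == 0:
                        continue
                    lhs = relative_overlap(m, a, b) * m.diag(a)
                    rhs = relative_overlap(m, b, a) * m.diag(b)
                    tol = 0.5 * (m.diag(a) + m.diag(b))  # rounding slack
                    assert abs(lhs - rhs) <= tol


class TestCrossTechniqueOverlap:
    def test_identical_maps(self, rng):
        grid = (rng.random((32, 32)) < 0.4).astype(float)
        a = _map_from(grid.copy(), "pulmonary")
        b = _map_from(grid.copy(), "pulmonary")
        m = overlap_matrix({g: _map_from(grid.copy(), g) for g in GROUPS})
        assert cross_technique_overlap(a, b, tau=0.5) == pytest.approx(
            m.diag("pulmonary")
        )

    def test_disjoint_maps(self):
        w = 32
        top = np.zeros((w, w)); top[: w // 2] = 1.0
        bottom = np.zeros((w, w)); bottom[w // 2 :] = 1.0
        assert cross_technique_overlap(
            _map_from(top, "pulmonary"), _map_from(bottom, "pulmonary"), 0.5
        ) == 0.0


class TestAngularGroupComparison:
    def test_identical_groups_give_null_result(self):
        res = angular_group_comparison(
            {"laryngeal": [10.0, 20.0, 30.0], "pulmonary": [10.0, 20.0, 30.0]}
        )
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_opposite_groups_strongly_separated(self, rng):
        groups = {
            "cardiac_efferent": rng.normal(0, 5, 5) % 360,
            "cardiac_afferent": rng.normal(180, 5, 5) % 360,
        }
        res = angular_group_comparison(groups)
        assert res.pairwise[0].p_adjusted < 0.001

    def test_seam_straddling_cluster_not_split(self, rng):
        """A group whose angles straddle 0/360 is treated as one tight
        cluster, not two clusters at opposite ends of the line."""
        groups = {
            "cardiac_efferent": np.array([355.0, 356.0, 2.0, 5.0]),
            "cardiac_afferent": np.array([175.0, 185.0, 179.0, 181.0]),
        }
        res = angular_group_comparison(groups)
        assert res.pairwise[0].p_adjusted < 0.001

    def test_matches_permutation_oracle(self, rng):
        groups = {k: rng.normal(90, 30, 6) % 360 for k in ("a", "b", "c")}
        res = angular_group_comparison(groups)
        values = np.concatenate([groups[k] for k in sorted(groups)])
        labels = np.repeat([0, 1, 2], 6)
        count = 0
        n_perm = 10000
        perm_rng = np.random.default_rng(2)
        for _ in range(n_perm):
            shuffled = perm_rng.permutation(labels)
            f = sps.f_oneway(*[values[shuffled == i] for i in range(3)])[0]
            if f >= res.f_statistic:
                count += 1
        assert res.p_value == pytest.approx(count / n_perm, abs=0.02)

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = angular_group_comparison(
                {"a": [1.0, 2.0, 3.0], "b": [5.0, 6.0, 7.0], "c": [9.0]}
            )
        assert set(res.groups) == {"a", "b"}

    def test_bonferroni_adjustment(self, rng):
        groups = {k: rng.normal(90, 30, 5) % 360 for k in ("a", "b", "c")}
        res = angular_group_comparison(groups, method="bonferroni")
        for c in res.pairwise:
            assert c.p_adjusted == pytest.approx(min(c.p_value * 3, 1.0))

    def test_watson_williams_flag(self, rng):
        groups = {
            "a": rng.normal(10, 8, 8) % 360,
            "b": rng.normal(170, 8, 8) % 360,
        }
        res = angular_group_comparison(groups, circular=True)
        assert res.method == "watson_williams"
        assert res.p_value < 0.001
        f, p = watson_williams(groups)
        assert res.f_statistic == pytest.approx(f)


class TestSeparationSummary:
    def _coms(self, angles, group):
        return [
            CoM(group, f"animal_{i}", "microct", a % 360, 0.5)
            for i, a in enumerate(angles)
        ]

    def test_identical_coms(self):
        a = self._coms([10, 50, 90], "cardiac_efferent")
        b = self._coms([10, 50, 90], "cardiac_afferent")
        assert angular_separation_summary(a, b) == (0.0, 0.0)

    def test_constant_180_separation(self):
        a = self._coms([0, 40, 90, 200, 300], "cardiac_efferent")
        b = self._coms([180, 220, 270, 20, 120], "cardiac_afferent")
        mean, sd = angular_separation_summary(a, b)
        assert mean == pytest.approx(180.0)
        assert sd == pytest.approx(0.0)

    def test_circular_mean_separation_unbiased_at_seam(self):
        """Per-animal offsets straddling the 180-degree fold average to 180
        in the circular estimate, while the wrapped mean is biased low."""
        a = self._coms([0, 0, 0, 0], "cardiac_efferent")
        b = self._coms([150, 210, 160, 200], "cardiac_afferent")
        circ = circular_mean_separation(a, b)
        wrapped_mean, _ = angular_separation_summary(a, b)
        assert circ == pytest.approx(180.0, abs=1e-9)
        assert wrapped_mean < 180.0

    def test_no_shared_animals_raises(self):
        a = [CoM("cardiac_efferent", "x", "microct", 0.0, 0.5)]
        b = [CoM("cardiac_afferent", "y", "microct", 0.0, 0.5)]
        with pytest.raises(ValueError, match="shared"):
            angular_separation_summary(a, b)
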