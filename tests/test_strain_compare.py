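"""Strain tensors, HARP-layout sampling, and comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import special_ortho_group

from warpstrain.lvmesh import build_lv_mesh, local_frames
from warpstrain.strain_compare import (
    MetricError,
    bland_altman,
    compare_tables,
    green_lagrange,
    paired_ttest,
    percent_rmse,
    project_strain,
    r_squared,
    sample_harp_grid,
)


class TestGreenLagrange:
    def test_identity(self):
        np.testing.assert_array_equal(green_lagrange(np.eye(3)), np.zeros((3, 3)))

    @pytest.mark.parametrize("lam", [0.8, 1.0, 1.3])
    def test_uniaxial_closed_form(self, lam):
        E = green_lagrange(np.diag([lam, 1.0, 1.0]))
        assert E[0, 0] == pytest.approx((lam**2 - 1) / 2, rel=1e-14)
        assert E[1, 1] == E[2, 2] == 0.0

    def test_rigid_rotation_invariance(self):
        for seed in range(5):
            Q = special_ortho_group.rvs(3, random_state=seed)
            np.testing.assert_allclose(green_lagrange(Q), 0.0, atol=1e-12)

    def test_batched(self, rng):
        F = np.eye(3) + 0.1 * rng.standard_normal((7, 3, 3))
        E = green_lagrange(F)
        np.testing.assert_allclose(E[3], green_lagrange(F[3]), atol=1e-15)


class TestProjection:
    def test_diagonal_pickoff(self):
        E = np.diag([0.3, -0.1, 0.05])
        assert project_strain(E, [1.0, 0, 0]) == pytest.approx(0.3)

    def test_sign_invariance_of_direction(self, rng):
        E = rng.standard_normal((3, 3))
        E = (E + E.T) / 2
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        assert project_strain(E, d) == pytest.approx(project_strain(E, -d), rel=1e-14)

    def test_matches_double_contraction(self, rng):
        E = rng.standard_normal((3, 3))
        E = (E + E.T) / 2
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        expected = sum(d[i] * E[i, j] * d[j] for i in range(3) for j in range(3))
        assert project_strain(E, d) == pytest.approx(expected, abs=1e-14)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            project_strain(np.eye(3), [1.0, 1.0, 0.0])


class TestHarpSampling:
    @pytest.fixture(scope="class")
    def mesh_frames(self):
        mesh = build_lv_mesh(divisions=(8, 3, 3))
        return mesh, local_frames(mesh)

    def test_twelve_rows_per_direction_per_slice(self, mesh_frames):
        mesh, frames = mesh_frames
        E = np.tile(np.eye(3) * 0.1, (mesh.n_elems, 8, 1, 1))
        tab = sample_harp_grid(E, frames, mesh)
        one = tab[tab["slice"] == 0]
        assert len(one[one.direction == "circumferential"]) == 12
        assert len(one[one.direction == "radial"]) == 12
        assert len(tab) == 24 * len(np.unique(mesh.slice_index))

    def test_uniform_field_constant_rows(self, mesh_frames):
        mesh, frames = mesh_frames
        c = 0.07
        E = np.tile(c * np.eye(3), (mesh.n_elems, 8, 1, 1))
        tab = sample_harp_grid(E, frames, mesh)
        np.testing.assert_allclose(tab["value"], c, rtol=1e-12)

    def test_sampled_truth_close_to_cell_centroid_value(self, phantom_pair, default_spec):
        """Cell averages track the analytic strain at cell centroids."""
        from warpstrain.phantom import analytic_deformation

        truth, mesh = phantom_pair[2], phantom_pair[3]
        frames = local_frames(mesh)
        # evaluate the analytic circumferential strain at one cell centroid
        row = truth[(truth["slice"] == 4) & (truth.region == "anterior")
                    & (truth.depth == "midwall")
                    & (truth.direction == "circumferential")].iloc[0]
        emask = (mesh.slice_index == 4) & (mesh.region == "anterior")
        depth_gp = mesh.depth_at_gauss()[emask]
        X = mesh.gauss_coords()[emask]
        sel = (depth_gp >= 1 / 3) & (depth_gp < 2 / 3)
        # geometric cell center: mean height/depth of the cell, on the wall
        # surface at the anterior (+y) sector center
        geo = mesh.geometry
        z_mid = X[sel][:, 2].mean()
        r_mid = geo.wall_radius(z_mid, depth_gp[sel].mean())
        centroid = np.array([0.0, r_mid, z_mid])
        _, F = analytic_deformation(centroid[None], default_spec)
        E = green_lagrange(F[0])
        cvec = np.array([1.0, 0.0, 0.0])  # circumferential at +y
        assert row.value == pytest.approx(project_strain(E, cvec), abs=0.02)


class TestPercentRmse:
    def test_perfect_prediction(self):
        v, n = percent_rmse([0.2, -0.15, 0.3], [0.2, -0.15, 0.3])
        assert v == 0.0 and n == 0

    def test_single_pair_arithmetic(self):
        v, _ = percent_rmse([0.2], [0.1])
        assert v == pytest.approx(0.5)

    def test_equal_references_both_groupings_agree(self):
        v, _ = percent_rmse([0.2, 0.2], [0.1, 0.3])
        v2, _ = percent_rmse([0.2, 0.2], [0.1, 0.3], ratio_of_sums=True)
        assert v == pytest.approx(0.5) and v2 == pytest.approx(0.5)

    def test_exclusion_floor(self):
        v, n_excl = percent_rmse([0.2, 0.001], [0.1, 5.0])
        assert n_excl == 1
        assert v == pytest.approx(0.5)
        with pytest.raises(MetricError):
            percent_rmse([0.001], [0.5])

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        ref = np.array([0.2, -0.3, 0.15, 0.4])
        pred = np.array([0.25, -0.2, 0.1, 0.5])
        v1, _ = percent_rmse(ref, pred)
        v2, _ = percent_rmse(k * ref, k * pred)
        assert v2 == pytest.approx(v1, rel=1e-9)


class TestRSquared:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2, 3, 4])
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)

    def test_null_simulation(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        assert r_squared(x, y) < 0.01

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(40)
        y = 0.6 * x + 0.3 * rng.standard_normal(40)
        r2 = r_squared(x, y)
        assert r_squared(3 * x - 1, y) == pytest.approx(r2, rel=1e-10)
        assert r_squared(x, -2 * y + 5) == pytest.approx(r2, rel=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(MetricError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(MetricError):
            r_squared([1.0, 2.0], [1.0, 2.0])


class TestBlandAltman:
    def test_identical_methods(self):
        ba = bland_altman([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert ba.mean_difference == 0.0
        assert ba.lower_limit == ba.upper_limit == 0.0
        assert ba.slope == 0.0

    def test_constant_shift(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        ba = bland_altman(x, x + 0.1)
        assert ba.mean_difference == pytest.approx(0.1)
        assert ba.sd_difference == pytest.approx(0.0, abs=1e-15)

    def test_proportional_underestimation_negative_slope(self):
        """y = 0.8 x: closed-form regression of d = y - x = -0.2 x on
        m = 0.9 x gives slope -0.2/0.9."""
        x = np.linspace(0.1, 0.5, 20)
        ba = bland_altman(x, 0.8 * x)
        assert ba.slope == pytest.approx(-0.2 / 0.9, rel=1e-10)
        assert ba.slope < 0

    def test_limits_symmetric_about_bias(self, rng):
        x = rng.standard_normal(50)
        y = x + 0.05 + 0.1 * rng.standard_normal(50)
        ba = bland_altman(x, y)
        assert ba.upper_limit - ba.mean_difference == pytest.approx(
            ba.mean_difference - ba.lower_limit, rel=1e-12
        )
        assert ba.upper_limit - ba.mean_difference == pytest.approx(
            1.96 * ba.sd_difference, rel=1e-12
        )


class TestPairedTTest:
    def test_identical_p_one(self):
        assert paired_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 1.0

    def test_constant_shift_zero_sentinel(self):
        assert paired_ttest([0.1, 0.2, 0.3], [0.2, 0.3, 0.4]) == 0.0

    def test_power_on_shift_with_noise(self, rng):
        x = rng.standard_normal(50)
        y = x + 0.5 + 0.01 * rng.standard_normal(50)
        assert paired_ttest(x, y) < 0.01

    def test_textbook_formula_on_fixed_pairs(self):
        x = np.array([0.12, 0.18, 0.25, 0.31, 0.40])
        y = np.array([0.10, 0.21, 0.22, 0.35, 0.38])
        d = y - x
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist

        expected = 2 * tdist.sf(abs(t), len(d) - 1)
        assert paired_ttest(x, y) == pytest.approx(expected, abs=1e-10)


class TestCompareTables:
    def _table(self, values):
        rows = []
        i = 0
        for sl in range(2):
            for region in ("anterior", "posterior", "septal", "lateral"):
                for depth in ("epicardial", "midwall", "endocardial"):
                    for direction in ("circumferential", "radial"):
                        rows.append((sl, region, depth, direction, values[i]))
                        i += 1
        return pd.DataFrame(
            rows, columns=["slice", "region", "depth", "direction", "value"]
        )

    def test_identical_tables_degenerate_safe(self, rng):
        vals = rng.uniform(0.05, 0.4, 48)
        ref = self._table(vals)
        out = compare_tables(ref, ref.copy())
        for stats in out.values():
            assert stats.r_squared == pytest.approx(1.0)
            assert stats.percent_rmse == 0.0
            assert stats.bland_altman.mean_difference == 0.0
            assert stats.t_test_p == 1.0

    def test_constant_tables_report_nan_r2(self):
        ref = self._table(np.full(48, 0.2))
        out = compare_tables(ref, ref.copy())
        for stats in out.values():
            assert np.isnan(stats.r_squared)

    def test_mismatched_layout_rejected(self, rng):
        ref = self._table(rng.uniform(0.1, 0.3, 48))
        bad = ref.copy()
        bad["slice"] = bad["slice"] + 10
        with pytest.raises(ValueError, match="layout"):
            compare_tables(ref, bad)
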