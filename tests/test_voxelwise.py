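import dataclasses

import numpy as np
import pytest

from cascn import io as cio, voxelwise
from cascn.errors import DegenerateInputError, DesignError
from cascn.simulate import generate_cohort
from cascn.voxelwise import build_pseudo_series, gca_map, signed_path_gca

from conftest import make_pts, small_spec


def ols_oracle(x, y, covariates=None, order=1):
    """Independent normal-equations solution of the same regression."""
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    n = len(x)
    cols = [np.ones(n - order)]
    cols += [y[order - l:n - l] for l in range(1, order + 1)]
    cols += [x[order - l:n - l] for l in range(1, order + 1)]
    if covariates is not None:
        cols.append(covariates[order:])
    X = np.column_stack(cols)
    beta = np.linalg.inv(X.T @ X) @ X.T @ y[order:]
    return float(beta[1 + order:1 + 2 * order].sum())


class TestPseudoTimeSeries:
    def test_sorted_low_to_high_by_severity(self, small_cohort):
        pts = build_pseudo_series(small_cohort.patients())
        assert np.all(np.diff(pts.key_values) >= 0)

    def test_three_subject_order_example(self):
        spec = small_spec(n_patients=8, n_controls=2, rng_seed=9)
        coh = generate_cohort(spec)
        pats = coh.patients()
        pats.participants.loc[:, "ahs_score"] = [30, 14, 25, 40, 20, 35, 18, 28]
        pts = build_pseudo_series(pats)
        ids = pats.participants["subject_id"]
        assert pts.subject_ids[:3] == [ids[1], ids[6], ids[4]]

    def test_input_permutation_invariance(self, small_cohort):
        pats = small_cohort.patients()
        pts1 = build_pseudo_series(pats)
        rng = np.random.default_rng(0)
        perm = rng.permutation(pats.n_subjects)
        pts2 = build_pseudo_series(pats.subset(perm))
        np.testing.assert_array_equal(pts1.series, pts2.series)
        np.testing.assert_array_equal(pts1.covariate_matrix, pts2.covariate_matrix)
        assert pts1.subject_ids == pts2.subject_ids

    def test_constant_key_warns(self, small_cohort):
        pats = small_cohort.patients()
        pats.participants.loc[:, "ahs_score"] = 20
        with pytest.warns(UserWarning, match="no information"):
            build_pseudo_series(pats)

    def test_seed_series_is_sphere_mean(self):
        series = np.array([[1.0, 2.0, 3.0, 9.0], [4.0, 5.0, 6.0, 9.0]])
        pts = make_pts(series)
        sphere = np.array([True, True, True, False]).reshape(4, 1, 1)
        np.testing.assert_allclose(
            voxelwise.extract_seed_series(pts, sphere), [2.0, 5.0]
        )

    def test_empty_sphere_is_error(self):
        pts = make_pts(np.ones((3, 4)) + np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(DegenerateInputError):
            voxelwise.extract_seed_series(pts, np.zeros((4, 1, 1), bool))


class TestSignedPathGCA:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for i in range(40):
            n = rng.integers(30, 500)
            ncov = rng.integers(0, 4)
            x = rng.standard_normal(n)
            y = 0.3 * np.roll(x, 1) + rng.standard_normal(n)
            cov = rng.standard_normal((n, ncov)) if ncov else None
            got = signed_path_gca(x, y, covariates=cov)
            assert got.coef == pytest.approx(ols_oracle(x, y, cov), abs=1e-8)

    def test_order_two_sums_both_lag_coefficients(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        y = 0.3 * np.roll(x, 1) + 0.2 * np.roll(x, 2) + rng.standard_normal(300)
        got = signed_path_gca(x, y, order=2)
        assert got.coef == pytest.approx(ols_oracle(x, y, order=2), abs=1e-8)

    def test_recovers_known_coupling(self):
        # y_t = 0.5 x_{t-1} + 0.5 y_{t-1} + e;  standardized coefficient is
        # 0.5 * sd_x / sd_y with sd_y^2 = (0.25 + 1) / (1 - 0.25)
        rng = np.random.default_rng(2)
        want = 0.5 * np.sqrt(1.0 / (1.25 / 0.75))
        coefs = []
        for _ in range(300):
            e = rng.standard_normal(400)
            x = rng.standard_normal(400)
            y = np.zeros(400)
            for t in range(1, 400):
                y[t] = 0.5 * x[t - 1] + 0.5 * y[t - 1] + e[t]
            coefs.append(signed_path_gca(x, y).coef)
        assert np.mean(coefs) == pytest.approx(want, abs=0.02)

    def test_sign_preserved_for_negative_coupling(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = -0.6 * np.roll(x, 1) + 0.3 * rng.standard_normal(500)
        assert signed_path_gca(x, y).coef < -0.3

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            signed_path_gca(np.ones(50), np.random.default_rng(0).normal(size=50))

    def test_too_short_series_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(DesignError):
            signed_path_gca(rng.normal(size=4), rng.normal(size=4))


class TestGCAMap:
    def test_map_equals_per_voxel_direct_computation(self, small_cohort):
        pats = small_cohort.patients()
        pts = build_pseudo_series(pats)
        rng = np.random.default_rng(0)
        x = pts.series[:, 10]
        gcm = gca_map(pts, x)
        cols = rng.choice(pts.series.shape[1], 25, replace=False)
        flat_gc = gcm.gc[pts.mask]
        for c in cols:
            direct = signed_path_gca(
                x, pts.series[:, c], covariates=pts.covariate_matrix
            )
            assert flat_gc[c] == pytest.approx(direct.coef, abs=1e-8)

    def test_seed_sphere_voxels_excluded(self, small_cohort):
        pats = small_cohort.patients()
        pts = build_pseudo_series(pats)
        sphere = cio.sphere_mask(
            cio.SeedSpec((0.0, -23.0, 2.0), 4.0), small_cohort.shape,
            small_cohort.affine, gm_mask=small_cohort.mask,
        )
        seed = voxelwise.extract_seed_series(pts, sphere)
        gcm = gca_map(pts, seed, seed_sphere=sphere)
        assert np.isnan(gcm.gc[sphere]).all()
        assert np.isfinite(gcm.gc[small_cohort.mask & ~sphere]).all()

    def test_pure_noise_map_centred_at_zero(self):
        rng = np.random.default_rng(5)
        pts = make_pts(rng.standard_normal((60, 800)))
        gcm = gca_map(pts, rng.standard_normal(60))
        vals = gcm.gc[np.isfinite(gcm.gc)]
        assert abs(vals.mean()) < 0.02
        assert vals.std() == pytest.approx(1 / np.sqrt(60), rel=0.3)

    def test_excessive_degenerate_voxels_raise(self):
        rng = np.random.default_rng(6)
        series = rng.standard_normal((40, 100))
        series[:, :30] = 1.0  # 30% constant
        pts = make_pts(series)
        with pytest.raises(DegenerateInputError, match="degenerate"):
            gca_map(pts, rng.standard_normal(40))

    def test_cascade_children_exceed_background(self, fixture_cohort, fixture_spec):
        pats = fixture_cohort.patients()
        pts = build_pseudo_series(pats)
        origin = fixture_spec.origin_region()
        sphere = cio.sphere_mask(
            cio.SeedSpec(tuple(origin.center_mm), 6.0), fixture_cohort.shape,
            fixture_cohort.affine, gm_mask=fixture_cohort.mask,
        )
        seed = voxelwise.extract_seed_series(pts, sphere)
        gcm = gca_map(pts, seed, seed_sphere=sphere)
        child_means = []
        for name in ("trans_a", "term_d"):
            r = fixture_spec.region_by_name(name)
            m = cio.sphere_mask(
                cio.SeedSpec(tuple(r.center_mm), r.radius_mm),
                fixture_cohort.shape, fixture_cohort.affine,
                gm_mask=fixture_cohort.mask,
            )
            child_means.append(np.nanmean(gcm.gc[m]))
        background = fixture_cohort.mask.copy()
        for r in fixture_cohort.ground_truth.regions:
            m = cio.sphere_mask(
                cio.SeedSpec(tuple(r.center_mm), r.radius_mm + 8),
                fixture_cohort.shape, fixture_cohort.affine,
            )
            background &= ~m
        bg_mean = np.nanmean(gcm.gc[background])
        assert min(child_means) > bg_mean + 0.2


class TestZTransform:
    def test_plain_transform_normalizes_exactly(self):
        rng = np.random.default_rng(7)
        gc = rng.normal(0.2, 0.1, (6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        zm = voxelwise.z_transform_map(
            voxelwise.GCMap(gc, None, 1), mask, robust=False
        )
        assert abs(zm.z[mask].mean()) < 1e-12
        assert zm.z[mask].std() == pytest.approx(1.0, abs=1e-12)

    def test_outlier_keeps_maximal_z(self):
        gc = np.full((5, 5, 5), 0.1)
        gc += np.random.default_rng(8).normal(0, 1e-3, gc.shape)
        gc[2, 2, 2] = 2.0
        mask = np.ones((5, 5, 5), bool)
        zm = voxelwise.z_transform_map(voxelwise.GCMap(gc, None, 1), mask)
        assert np.argmax(zm.z) == np.argmax(gc)

    def test_transform_is_affine(self):
        rng = np.random.default_rng(9)
        gc = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        zm = voxelwise.z_transform_map(voxelwise.GCMap(gc, None, 1), mask)
        m, sd = zm.transform
        np.testing.assert_allclose(zm.z, (gc - m) / sd)
        # a value sitting 3.29 scale units above the location maps to z=3.29
        assert (m + 3.29 * sd - m) / sd == pytest.approx(3.29)

    def test_rank_preservation(self):
        rng = np.random.default_rng(10)
        gc = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        zm = voxelwise.z_transform_map(voxelwise.GCMap(gc, None, 1), mask)
        np.testing.assert_array_equal(
            np.argsort(gc.ravel()), np.argsort(zm.z.ravel())
        )

    def test_zero_variance_rejected(self):
        gc = np.ones((3, 3, 3))
        with pytest.raises(DegenerateInputError):
            voxelwise.z_transform_map(
                voxelwise.GCMap(gc, None, 1), np.ones((3, 3, 3), bool)
            )
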