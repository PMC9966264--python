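"""PCA subspace, sqrt(2) scaling, Mahalanobis distances, distance table."""

import numpy as np
import pytest

import ramanheal as rh
from ramanheal.chemometrics import ScaledPCSpace
from ramanheal.spectra_core import SampleMeta, SpectrumSet


def _set_from_matrix(m, grid_start=2800.0):
    grid = grid_start + np.arange(m.shape[1], dtype=float)
    metas = [SampleMeta("healthy")] * m.shape[0]
    return SpectrumSet(grid, m, metas)


def _scaled_space(coords, metas):
    coords = np.asarray(coords, float)
    return ScaledPCSpace(components=(2, 3), sigma2=1.0, sigma3=1.0,
                         scale2=1.0, scale3=1.0, r=np.sqrt(2.0),
                         coords=coords, metas=tuple(metas))


def _ref_identity():
    coords = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    return rh.HealthyReference(coords, np.eye(2), np.eye(2), False)


class TestFitPCA:
    def test_matches_eigendecomposition(self, rng):
        m = rng.normal(size=(5, 10))
        p = rh.fit_pca(_set_from_matrix(m), (2800.0, 2809.0))
        # oracle: explicit eigendecomposition of the sample covariance
        X = m - m.mean(axis=0)
        cov = X.T @ X / (m.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        ncomp = p.loadings.shape[0]
        for k in range(min(4, ncomp)):  # nonzero eigenpairs
            assert np.var(p.scores[:, k], ddof=1) == pytest.approx(
                evals[k], abs=1e-8)
            dot = abs(p.loadings[k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal_scores_centered(self, rng):
        m = rng.normal(size=(20, 15))
        p = rh.fit_pca(_set_from_matrix(m), (2800.0, 2814.0))
        gram = p.loadings @ p.loadings.T
        assert np.max(np.abs(gram - np.eye(gram.shape[0]))) < 1e-8
        assert np.max(np.abs(p.scores.mean(axis=0))) < 1e-8
        variances = p.scores.var(axis=0, ddof=1)
        assert np.all(np.diff(variances) <= 1e-10)

    def test_explained_variance_sums_to_one(self, rng):
        m = rng.normal(size=(8, 12))
        p = rh.fit_pca(_set_from_matrix(m), (2800.0, 2811.0))
        assert p.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_rows_share_scores(self, rng):
        row = rng.normal(size=12)
        m = np.vstack([row, rng.normal(size=12), row, rng.normal(size=12)])
        p = rh.fit_pca(_set_from_matrix(m), (2800.0, 2811.0))
        assert np.allclose(p.scores[0], p.scores[2], atol=1e-10)

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            rh.fit_pca(_set_from_matrix(rng.normal(size=(2, 5))), (2800.0, 2804.0))
        with pytest.raises(ValueError, match="constant"):
            rh.fit_pca(_set_from_matrix(np.ones((5, 5))), (2800.0, 2804.0))


class TestScalePC23:
    def test_healthy_radius_is_sqrt2(self, tiny_cohort):
        sset, _ = tiny_cohort
        proc, _ = rh.preprocess_set(sset)
        for rng_lohi in ((2800.0, 3000.0), (1200.0, 1750.0)):
            p = rh.fit_pca(proc, rng_lohi)
            sp = rh.scale_pc23(p)
            assert sp.r == pytest.approx(np.sqrt(2.0), abs=1e-9)
            # scaled healthy SDs are exactly 1 on both axes
            mask = [m.group == "healthy" for m in sp.metas]
            h = sp.coords[mask]
            assert h[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
            assert h[:, 1].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_unit_sd_scores_give_unit_scales(self, rng):
        m = rng.normal(size=(40, 10))
        p = rh.fit_pca(_set_from_matrix(m), (2800.0, 2809.0))
        # force healthy score SDs to 1 by pre-normalizing the scores
        scores = p.scores.copy()
        scores[:, 1] /= scores[:, 1].std(ddof=1)
        scores[:, 2] /= scores[:, 2].std(ddof=1)
        p2 = rh.PCASubspace(p.range, p.grid, p.mean_spectrum, p.loadings,
                            scores, p.explained_variance_ratio, p.metas)
        sp = rh.scale_pc23(p2)
        assert sp.scale2 == pytest.approx(1.0, abs=1e-12)
        assert sp.scale3 == pytest.approx(1.0, abs=1e-12)

    def test_reciprocal_scales(self, rng):
        m = rng.normal(size=(30, 8))
        p = rh.fit_pca(_set_from_matrix(m), (2800.0, 2807.0))
        scores = p.scores.copy()
        scores[:, 1] *= 2.0 / scores[:, 1].std(ddof=1)
        scores[:, 2] *= 0.5 / scores[:, 2].std(ddof=1)
        p2 = rh.PCASubspace(p.range, p.grid, p.mean_spectrum, p.loadings,
                            scores, p.explained_variance_ratio, p.metas)
        sp = rh.scale_pc23(p2)
        assert sp.scale2 == pytest.approx(0.5, rel=1e-9)
        assert sp.scale3 == pytest.approx(2.0, rel=1e-9)


class TestBuildReference:
    def test_hand_computable_covariance(self):
        coords = [[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]]
        sp = _scaled_space(coords, [SampleMeta("healthy")] * 4)
        ref = rh.build_reference(sp)
        assert np.allclose(ref.C, np.diag([2.0 / 3.0, 2.0 / 3.0]), atol=1e-12)
        assert not ref.regularized

    def test_large_sample_approaches_identity(self, rng):
        coords = rng.standard_normal((200, 2))
        sp = _scaled_space(coords, [SampleMeta("healthy")] * 200)
        ref = rh.build_reference(sp)
        assert np.max(np.abs(ref.C - np.eye(2))) < 0.2
        assert np.max(np.abs(ref.C_inv @ ref.C - np.eye(2))) < 1e-6

    def test_collinear_coords_take_ridge_path(self):
        t = np.linspace(-1, 1, 10)
        coords = np.column_stack([t, 2.0 * t])  # rank 1
        sp = _scaled_space(coords, [SampleMeta("healthy")] * 10)
        ref = rh.build_reference(sp)
        assert ref.regularized
        assert np.all(np.isfinite(ref.C_inv))

    def test_needs_three_points(self):
        sp = _scaled_space([[0.0, 0.0], [1.0, 1.0]], [SampleMeta("healthy")] * 2)
        with pytest.raises(ValueError, match="at least 3"):
            rh.build_reference(sp)


class TestMahalanobis:
    def test_identical_points(self):
        ref = _ref_identity()
        assert rh.mahalanobis_pair([1.0, 2.0], [1.0, 2.0], ref) == 0.0

    def test_printed_form_is_squared(self):
        ref = _ref_identity()
        assert rh.mahalanobis_pair([3.0, 4.0], [0.0, 0.0], ref) == pytest.approx(25.0)
        assert rh.mahalanobis_pair([3.0, 4.0], [0.0, 0.0], ref,
                                   squared=False) == pytest.approx(5.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="2-vectors"):
            rh.mahalanobis_pair([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], _ref_identity())

    def test_pair_against_matrix_oracle(self, rng):
        for _ in range(25):
            A = rng.normal(size=(2, 2))
            C = A @ A.T + 0.5 * np.eye(2)
            C_inv = np.linalg.inv(C)
            ref = rh.HealthyReference(np.zeros((3, 2)), C, C_inv, False)
            xi, xj = rng.normal(size=2), rng.normal(size=2)
            d = xi - xj
            expected = sum(d[a] * C_inv[a, b] * d[b]
                           for a in range(2) for b in range(2))
            assert rh.mahalanobis_pair(xi, xj, ref) == pytest.approx(
                expected, abs=1e-12)


class TestSetDistances:
    def test_singleton_reference(self):
        ref = _ref_identity()
        x = np.array([1.0, 1.0])
        sh = np.array([[0.0, 0.0]])
        assert rh.point_to_set(x, sh, ref) == pytest.approx(
            rh.mahalanobis_pair(x, sh[0], ref))

    def test_duplication_invariance(self, rng):
        ref = _ref_identity()
        x = rng.normal(size=2)
        sh = rng.normal(size=(6, 2))
        doubled = np.vstack([sh, sh])
        assert rh.point_to_set(x, sh, ref) == pytest.approx(
            rh.point_to_set(x, doubled, ref), abs=1e-12)

    def test_centroid_equals_mean_squared_offsets(self):
        ref = _ref_identity()
        sh = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        # centroid at origin; direct summation oracle
        expected = np.mean([v @ v for v in sh])
        assert rh.point_to_set(np.zeros(2), sh, ref) == pytest.approx(expected)

    def test_set_to_set_double_loop_oracle(self, rng):
        A = rng.normal(size=(2, 2))
        C = A @ A.T + 0.3 * np.eye(2)
        ref = rh.HealthyReference(np.zeros((3, 2)), C, np.linalg.inv(C), False)
        S = rng.normal(size=(7, 2))
        SH = rng.normal(size=(5, 2))
        total = 0.0
        for xi in S:
            for xj in SH:
                d = xi - xj
                total += d @ np.linalg.inv(C) @ d
        assert rh.set_to_set(S, SH, ref) == pytest.approx(
            total / (7 * 5), abs=1e-12)

    def test_coincident_sets_of_one_point(self):
        ref = _ref_identity()
        pt = np.array([[0.7, -0.3]])
        assert rh.set_to_set(pt, pt, ref) == 0.0

    def test_translation_increases_distance(self, rng):
        ref = _ref_identity()
        S = rng.normal(size=(10, 2))
        SH = rng.normal(size=(10, 2))
        base = rh.set_to_set(S + SH.mean(0) - S.mean(0), SH, ref)
        shifted = rh.set_to_set(S + SH.mean(0) - S.mean(0) + [5.0, 0.0], SH, ref)
        assert shifted > base

    def test_self_distance_equals_mean_pairwise(self, rng):
        ref = _ref_identity()
        SH = rng.normal(size=(8, 2))
        pairwise = np.mean([[rh.mahalanobis_pair(a, b, ref) for b in SH]
                            for a in SH])
        assert rh.set_to_set(SH, SH, ref) == pytest.approx(pairwise, abs=1e-12)

    def test_rotation_invariance_with_isotropic_covariance(self, rng):
        ref = _ref_identity()
        S = rng.normal(size=(6, 2))
        SH = rng.normal(size=(9, 2))
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        assert rh.set_to_set(S @ R.T, SH @ R.T, ref) == pytest.approx(
            rh.set_to_set(S, SH, ref), abs=1e-10)

    def test_empty_sets_are_errors(self):
        ref = _ref_identity()
        with pytest.raises(ValueError):
            rh.point_to_set(np.zeros(2), np.zeros((0, 2)), ref)
        with pytest.raises(ValueError):
            rh.set_to_set(np.zeros((0, 2)), np.zeros((3, 2)), ref)


class TestDistanceTable:
    def test_shape_and_finiteness(self, tiny_cohort):
        sset, _ = tiny_cohort
        proc, _ = rh.preprocess_set(sset)
        dt = rh.distance_table(proc)
        assert dt.table.shape == (2, 2)
        assert np.all(np.isfinite(dt.table.to_numpy()))
        assert np.all(dt.table.to_numpy() >= 0)

    def test_deterministic_across_runs(self, tiny_cohort):
        sset, _ = tiny_cohort
        proc, _ = rh.preprocess_set(sset)
        a = rh.distance_table(proc).table.to_numpy()
        b = rh.distance_table(proc).table.to_numpy()
        assert np.array_equal(a, b)

    def test_missing_healthy_is_error(self, tiny_cohort):
        sset, _ = tiny_cohort
        wounds = sset.select(where=lambda m: m.group != "healthy")
        with pytest.raises(ValueError, match="no healthy"):
            rh.distance_table(wounds)

    def test_null_group_sits_at_healthy_self_distance(self):
        """A wound group generated from the healthy distribution scores at
        the healthy self-distance baseline."""
        ratio = rh.healing_trajectory_default()
        ch = rh.synthetic_data.ch_shift_trajectory_default()
        for day in (1, 14):
            ratio[("control", day)] = ratio[("healthy", None)]
            ch[("control", day)] = 0.0
        cfg = rh.SyntheticConfig(
            seed=31, ratio_trajectory=ratio, ch_shift_trajectory=ch,
            mouse_effect_sd=0.0,
            design=rh.CohortDesign(groups=("control", "ALA4"), days=(1, 14),
                                   mice=3, points=8, healthy_per_group=25),
        )
        sset = rh.generate_cohort(cfg)
        proc, _ = rh.preprocess_set(sset)
        p = rh.fit_pca(proc, (2800.0, 3000.0))
        sp = rh.scale_pc23(p)
        ref = rh.build_reference(sp)
        mask = np.array([m.group == "healthy" for m in sp.metas])
        self_dist = rh.set_to_set(sp.coords[mask], sp.coords[mask], ref)
        dt = rh.distance_table(proc)
        for day in ("day 1", "day 14"):
            assert dt.table.loc["control", day] == pytest.approx(
                self_dist, rel=0.4)

    def test_healing_ordering_recovered(self, tiny_cohort):
        sset, _ = tiny_cohort
        proc, _ = rh.preprocess_set(sset)
        dt = rh.distance_table(proc).table
        assert dt.loc["ALA4", "day 14"] < dt.loc["ALA4", "day 1"]
        assert dt.loc["control", "day 14"] > dt.loc["ALA4", "day 14"]
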