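"""PCA engine: SVD equivalence, missing tolerance, Q² and Hotelling flags."""
import numpy as np
import pytest

from metabotyper.pca import fit_pca, hotelling_flags, pca_grid_report, q2_cv


def _svd_reference(x, a):
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores, loadings = u[:, :a] * s[:a], vt[:a].T
    for c in range(a):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return scores, loadings


class TestFit:
    def test_rank1_explains_everything_on_pc1(self, rng):
        x = np.outer(rng.standard_normal(15), rng.standard_normal(6))
        model = fit_pca(x, 2)
        assert model.r2x[0] == pytest.approx(1.0, abs=1e-12)
        assert model.r2x[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_svd_oracle_on_complete_data(self, rng):
        x = rng.standard_normal((20, 5))
        model = fit_pca(x, 2)
        scores, loadings = _svd_reference(x, 2)
        np.testing.assert_allclose(model.scores, scores, atol=1e-8)
        np.testing.assert_allclose(model.loadings, loadings, atol=1e-8)

    def test_loadings_unit_norm_orthogonal(self, rng):
        x = rng.standard_normal((25, 6))
        model = fit_pca(x, 3)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self, rng):
        x = rng.standard_normal((25, 6))
        model = fit_pca(x, 3)
        for a in range(3):
            j = np.argmax(np.abs(model.loadings[:, a]))
            assert model.loadings[j, a] > 0

    def test_five_percent_missing_r2x_close(self, rng):
        x = rng.standard_normal((40, 8)) + 3 * np.outer(
            rng.standard_normal(40), rng.standard_normal(8)
        )
        complete = fit_pca(x, 2).r2x_cum[-1]
        xm = x.copy()
        xm[rng.random(x.shape) < 0.05] = np.nan
        assert abs(fit_pca(xm, 2).r2x_cum[-1] - complete) < 0.05

    def test_r2x_cum_monotone_and_bounded(self, rng):
        x = rng.standard_normal((30, 7))
        model = fit_pca(x, 5)
        assert np.all(np.diff(model.r2x_cum) >= -1e-12)
        assert model.r2x_cum[-1] <= 1 + 1e-12

    def test_row_permutation_invariance(self, rng):
        x = rng.standard_normal((20, 5))
        perm = rng.permutation(20)
        np.testing.assert_allclose(
            fit_pca(x, 2).r2x, fit_pca(x[perm], 2).r2x, atol=1e-10
        )

    def test_too_small_matrix_errors(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((1, 5)), 1)

    def test_empty_row_errors(self):
        x = np.ones((4, 3))
        x[2] = np.nan
        with pytest.raises(ValueError):
            fit_pca(x, 1)


class TestQ2:
    def test_rank1_noiseless_cross_validates(self, rng):
        x = np.outer(rng.standard_normal(30), rng.standard_normal(8))
        assert q2_cv(x, 1) > 0.9

    def test_pure_noise_has_no_predictive_structure(self):
        neg = 0
        for seed in range(8):
            x = np.random.default_rng(seed).standard_normal((30, 8))
            if q2_cv(x, 2) <= 0:
                neg += 1
        assert neg >= 7

    def test_q2_never_exceeds_r2x(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((25, 6)) + np.outer(
                rng.standard_normal(25), rng.standard_normal(6)
            )
            assert q2_cv(x, 2) <= fit_pca(x, 2).r2x_cum[-1] + 1e-6

    def test_q2_degrades_with_added_noise(self):
        # monotone trend over 5 noise levels, median over 10 seeds
        levels = [0.0, 0.5, 1.0, 2.0, 4.0]
        med = []
        for lv in levels:
            q2s = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                base = 3 * np.outer(rng.standard_normal(30), rng.standard_normal(8))
                q2s.append(q2_cv(base + lv * rng.standard_normal((30, 8)), 2))
            med.append(np.median(q2s))
        assert all(a >= b for a, b in zip(med, med[1:]))

    def test_bad_fold_count_errors(self, rng):
        with pytest.raises(ValueError):
            q2_cv(rng.standard_normal((10, 4)), 2, folds=1)


class TestHotelling:
    def test_origin_scores_unflagged(self):
        scores = np.zeros((10, 2))
        assert not hotelling_flags(scores).any()

    def test_extreme_point_flagged(self, rng):
        scores = rng.standard_normal((50, 2))
        scores[7] = [100.0, 100.0]
        flags = hotelling_flags(scores)
        assert flags[7]
        assert flags.sum() <= 3

    def test_false_positive_rate_near_alpha(self, rng):
        rates = []
        for _ in range(30):
            scores = rng.standard_normal((500, 2))
            rates.append(hotelling_flags(scores, alpha=0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_requires_two_components(self, rng):
        with pytest.raises(ValueError):
            hotelling_flags(rng.standard_normal((10, 3)))


class TestGridReport:
    @pytest.fixture(scope="class")
    def report(self, cohort):
        from metabotyper import aggregate_to_aglycones

        sums = aggregate_to_aglycones(cohort.table)
        return pca_grid_report(
            cohort.table.values.to_numpy(float), sums.values.to_numpy(float)
        )

    def test_24_rows_in_grid_order(self, report):
        assert len(report) == 24
        assert list(report["dataset"][:12]) == ["individual"] * 12

    def test_r2x_in_unit_interval(self, report):
        ok = report["status"] == "ok"
        assert ((report.loc[ok, "r2x_cum"] >= 0) & (report.loc[ok, "r2x_cum"] <= 1)).all()

    def test_unscaled_model_has_highest_r2x(self, report):
        # on raw-amount data the unscaled model soaks up the magnitude axis
        for ds in ("individual", "sums"):
            sub = report[(report["dataset"] == ds) & (report["transform"] == "none")]
            best = sub.loc[sub["r2x_cum"].idxmax()]
            assert best["scaling"] == "none"
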