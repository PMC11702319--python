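import numpy as np
import pandas as pd
import pytest

from fjordapcs.factors import (FactorModel, broken_stick_thresholds, fit_pca,
                               pc_independence_test, retain_components,
                               significant_loadings, varimax, varimax_rotate)


def _standardize(x):
    x = np.asarray(x, float)
    return pd.DataFrame((x - x.mean(0)) / x.std(0, ddof=1))


def _model_with_loadings(loadings: np.ndarray) -> FactorModel:
    """Minimal model stub for loading-only operations."""
    loadings = np.asarray(loadings, float)
    p, k = loadings.shape
    cols = [f"PC{i+1}" for i in range(k)]
    idx = [f"v{j}" for j in range(p)]
    dummy = pd.DataFrame(np.zeros((3, k)), columns=cols)
    return FactorModel(
        eigenvalues=np.ones(p), loadings=pd.DataFrame(loadings, idx, cols),
        scores=dummy, score_coefficients=pd.DataFrame(np.zeros((p, k)),
                                                      idx, cols),
        variance_fraction=np.full(k, 1 / k), rotated=True)


class TestFitPCA:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z = _standardize(np.column_stack([x, 2 * x + 1]))
        model = fit_pca(z)
        assert model.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)
        assert model.variance_fraction[0] == pytest.approx(1.0)

    def test_independent_columns_flat_spectrum(self):
        """For independent columns the correlation spectrum is flat; with
        p=2 the eigenvalues are 1 +/- |r| and |r| ~ 1/sqrt(n)."""
        n = 4000
        rng = np.random.default_rng(1)
        z = _standardize(rng.normal(size=(n, 2)))
        model = fit_pca(z)
        assert np.all(np.abs(model.eigenvalues - 1.0) < 3 / np.sqrt(n))

    def test_requires_standardized_input(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="standardized"):
            fit_pca(pd.DataFrame(rng.normal(5, 2, size=(20, 3))))

    def test_rank_deficient_warns(self, synthetic_study):
        from fjordapcs.geochem import standardize
        table, _ = synthetic_study
        z, _ = standardize(table.subset("fjord"))
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_pca(z)
        assert model.k <= 13  # n - 1 components at most

    def test_deterministic_reconstruction_and_signs(self, fitted_default):
        model, z = fitted_default["model"], fitted_default["z"]
        again = fit_pca(z)
        pd.testing.assert_frame_equal(model.loadings, again.loadings)
        recon = model.reconstruct()
        assert np.linalg.norm(recon - z) / np.linalg.norm(z) < 1e-8
        # score columns standardized
        assert np.allclose(model.scores.mean(), 0, atol=1e-10)
        assert np.allclose(model.scores.std(ddof=1), 1, atol=1e-8)


class TestRetention:
    def test_guttman_kaiser_counts_above_one(self, fitted_default):
        assert retain_components(fitted_default["model"]) == 3

    def test_exact_boundary_excluded(self):
        model = _model_with_loadings(np.eye(2))
        model.eigenvalues = np.array([1.0, 1.0])
        assert retain_components(model) == 0
        model.eigenvalues = np.array([3.0, 2.0, 1.1, 0.5])
        assert retain_components(model) == 3

    def test_fixed_k(self, fitted_default):
        model = fitted_default["model"]
        assert retain_components(model, "fixed_k", k=2) == 2
        with pytest.raises(ValueError, match="exceeds"):
            retain_components(model, "fixed_k", k=model.k + 1)


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        b = np.zeros((6, 2))
        b[:3, 0] = [0.9, 0.8, 0.85]
        b[3:, 1] = [0.7, 0.95, 0.75]
        rotated, rot = varimax(b)
        assert np.abs(np.abs(rot) - np.eye(2)).max() < 1e-6
        assert np.allclose(np.abs(rotated), np.abs(b), atol=1e-6)

    def test_rotation_orthogonal_and_communality_preserved(self,
                                                           fitted_default):
        model, rotated = fitted_default["model"], fitted_default["rotated"]
        rot = rotated.rotation
        assert np.abs(rot.T @ rot - np.eye(3)).max() < 1e-8
        comm_before = (model.loadings.iloc[:, :3] ** 2).sum(axis=1)
        comm_after = rotated.communalities()
        assert np.allclose(comm_before, comm_after, atol=1e-8)
        assert rotated.variance_fraction.sum() == pytest.approx(
            model.variance_fraction[:3].sum(), abs=1e-8)

    def test_reconstruction_preserved(self, fitted_default):
        model, rotated = fitted_default["model"], fitted_default["rotated"]
        before = model.scores.iloc[:, :3].to_numpy() @ \
            model.loadings.iloc[:, :3].to_numpy().T
        after = rotated.scores.to_numpy() @ rotated.loadings.to_numpy().T
        assert np.allclose(before, after, atol=1e-10)

    def test_k_below_two_unchanged(self, fitted_default):
        model = fitted_default["model"]
        out = varimax_rotate(model, 1)
        pd.testing.assert_frame_equal(out.loadings,
                                      model.loadings.iloc[:, :1])

    def test_against_statsmodels_oracle(self, fitted_default):
        """Independent cross-check of the rotation optimizer."""
        from scipy.optimize import linear_sum_assignment
        from statsmodels.multivariate.factor_rotation import rotate_factors

        b = fitted_default["model"].loadings.iloc[:, :3].to_numpy()
        ours, _ = varimax(b, normalize=False)
        theirs, _ = rotate_factors(b, "varimax")
        cost = -np.abs(ours.T @ theirs)
        rows, cols = linear_sum_assignment(cost)
        aligned = np.empty_like(ours)
        for r, c in zip(rows, cols):
            sign = np.sign(ours[:, r] @ theirs[:, c])
            aligned[:, c] = sign * ours[:, r]
        assert np.abs(aligned - theirs).max() < 1e-4


class TestBrokenStick:
    def test_closed_form(self):
        assert broken_stick_thresholds(1) == pytest.approx([1.0])
        assert broken_stick_thresholds(3) == pytest.approx(
            [0.6111, 0.2778, 0.1111], abs=5e-5)
        with pytest.raises(ValueError):
            broken_stick_thresholds(0)

    @pytest.mark.parametrize("p", [1, 2, 5, 18, 100])
    def test_normalized_and_decreasing(self, p):
        b = broken_stick_thresholds(p)
        assert b.sum() == pytest.approx(1.0)
        assert np.all(np.diff(b) < 0) or p == 1


class TestLoadingSignificance:
    def test_dominant_loading_flagged_once(self):
        model = _model_with_loadings([[0.99, 0.05, 0.02],
                                      [0.1, 0.95, 0.05]])
        sig = significant_loadings(model)
        assert sig.significant.iloc[0].tolist() == [True, False, False]
        assert sig.significant.iloc[1].tolist() == [False, True, False]

    def test_flat_communality_flags_nothing(self):
        flat = np.full((1, 3), 1 / np.sqrt(3))
        sig = significant_loadings(_model_with_loadings(flat))
        assert not sig.significant.to_numpy().any()

    def test_each_component_claims_some_parameter(self, fitted_default):
        sig = fitted_default["sig"]
        assert sig.significant.any(axis=0).all()

    def test_per_component_variant(self):
        """Across-variables variant: a component whose variance is carried
        by one variable flags exactly that variable."""
        b = np.full((6, 2), 0.05)
        b[0, 0] = 0.95
        b[1:, 1] = 0.6
        sig = significant_loadings(_model_with_loadings(b),
                                   method="per_component")
        assert sig.method == "per_component"
        col1 = sig.significant.iloc[:, 0]
        assert col1.iloc[0] and not col1.iloc[1:].any()

    def test_mixing_component_parameter_set(self, fitted_default):
        """The strongly mixing-loaded parameters (the conservative group)
        are exactly the ones flagged on PC1 in the synthetic system."""
        sig = fitted_default["sig"]
        expected = {"salinity", "AT", "CT", "dAl", "dV", "dMn", "dCo",
                    "dNi", "dPb"}
        assert set(sig.parameters_on("PC1")) == expected


class TestIndependenceTest:
    def test_duplicated_column_rejected_as_dependent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        res = pc_independence_test(np.column_stack([x, x]))
        assert (res["decision"] == "reject").all()

    def test_type_one_error_rate(self):
        """Under independent standard-normal scores the rejection rate at
        alpha=0.05 stays below 0.08 (200 replicates, n=1000)."""
        rng = np.random.default_rng(1234)
        rejections = trials = 0
        for _ in range(200):
            res = pc_independence_test(rng.standard_normal((1000, 3)))
            rejections += int((res["decision"] == "reject").sum())
            trials += len(res)
        assert rejections / trials <= 0.08

    def test_detects_depth_coupled_processes(self, fitted_default):
        """The synthetic pelagic and benthic processes are linearly
        orthogonal but both depth-driven; the discretized test correctly
        detects that nonlinear coupling while covering all pairs."""
        res = pc_independence_test(fitted_default["rotated"].scores)
        assert len(res) == 3
        assert (res["decision"] == "reject").any()

    def test_component_by_bin_construction(self, fitted_default):
        res = pc_independence_test(fitted_default["rotated"].scores,
                                   construction="component_by_bin")
        assert len(res) == 1 and res["dof"].iloc[0] > 0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pc_independence_test(np.column_stack(
                [np.ones(50), np.arange(50.0)]))
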