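import numpy as np
import pytest

import fsva
from fsva import ContractError


def _identity_model(m=6, n_sv=2):
    """A frozen model whose training matrix is the identity (U = V = D = I)."""
    X = fsva.ExpressionMatrix(np.eye(m), [f"g{i}" for i in range(m)],
                              [f"s{j}" for j in range(m)])
    U, d, V = fsva.weighted_svd(X.values, np.ones(m))
    w = fsva.FeatureWeights(np.ones(m), np.zeros(m), np.ones(m))
    fit = fsva.SurrogateFit(n_sv=n_sv, G_hat=V[:, :n_sv].T,
                            Gamma_hat=np.zeros((m, n_sv)), B_hat=np.zeros((m, 2)),
                            weights=w, svd_U=U, svd_D=d, svd_V=V, noise=None)
    return X, fit


class TestBuildProjection:
    def test_identity_training_matrix(self):
        X, fit = _identity_model()
        proj = fsva.build_projection(fit)
        np.testing.assert_allclose(proj.P, np.eye(6), atol=1e-12)
        x = np.arange(6.0)
        np.testing.assert_allclose(proj.P @ x, x, atol=1e-12)

    def test_projection_reproduces_training_singular_vectors(self, scenario1_model):
        ds, _, fit, model = scenario1_model
        P = model.projection.P
        vt = fit.svd_V.T[: P.shape[0]]
        assert np.abs(P @ ds.X_db.values - vt).max() < 1e-8

    def test_matches_dense_assembly_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 20))
        w = rng.uniform(0.1, 1.0, 50)
        U, d, V = fsva.weighted_svd(X, w)
        fw = fsva.FeatureWeights(np.ones(50), 1.0 - w, w)
        fit = fsva.SurrogateFit(n_sv=1, G_hat=V[:, :1].T, Gamma_hat=np.zeros((50, 1)),
                                B_hat=np.zeros((50, 2)), weights=fw,
                                svd_U=U, svd_D=d, svd_V=V, noise=None)
        proj = fsva.build_projection(fit)
        keep = proj.P.shape[0]
        expected = np.diag(1.0 / d[:keep]) @ U[:, :keep].T @ np.diag(w)
        np.testing.assert_allclose(proj.P, expected, atol=1e-10)

    def test_rank_too_low(self):
        X, fit = _identity_model()
        object.__setattr__(fit, "svd_D", np.array([1.0] + [0.0] * 5))
        with pytest.raises(ContractError, match="rank too low"):
            fsva.build_projection(fit)


class TestFastMode:
    def test_zero_gamma_identity_bitwise(self):
        X, fit = _identity_model()
        model = fsva.build_frozen_model(X, fit)
        out = fsva.fsva_fast(model, X)
        np.testing.assert_array_equal(out.values, X.values)

    def test_training_column_maps_to_clean_training(self, scenario1_model):
        ds, _, fit, model = scenario1_model
        cleaned_db = fsva.clean_training(ds.X_db, fit)
        out = fsva.fsva_fast(model, ds.X_db)
        assert np.abs(out.values - cleaned_db.values).max() < 1e-8

    def test_columns_processed_independently(self, scenario1_model):
        ds, _, _, model = scenario1_model
        both = fsva.fsva_fast(model, ds.X_new.subset_samples([0, 1]))
        a = fsva.fsva_fast(model, ds.X_new.subset_samples([0]))
        b = fsva.fsva_fast(model, ds.X_new.subset_samples([1]))
        np.testing.assert_array_equal(both.values,
                                      np.hstack([a.values, b.values]))

    def test_feature_mismatch(self, scenario1_model):
        *_, model = scenario1_model
        bad = fsva.ExpressionMatrix(np.ones((3, 2)), list("abc"), ["x", "y"])
        with pytest.raises(ContractError, match="feature space mismatch"):
            fsva.fsva_fast(model, bad)

    def test_feature_reordering_is_transparent(self, scenario1_model):
        ds, _, _, model = scenario1_model
        straight = fsva.fsva_fast(model, ds.X_new)
        perm = np.random.default_rng(0).permutation(ds.X_new.m)
        shuffled = fsva.ExpressionMatrix(ds.X_new.values[perm],
                                         ds.X_new.feature_ids[perm],
                                         ds.X_new.sample_ids)
        out = fsva.fsva_fast(model, shuffled)
        np.testing.assert_array_equal(out.values, straight.values)


class TestAlignSurrogates:
    @pytest.mark.parametrize("scale,expected", [(1.0, 1.0), (-1.0, -1.0), (2.0, 0.5)])
    def test_scalar_maps(self, scale, expected):
        G = np.random.default_rng(1).normal(size=(2, 10))
        c = fsva.align_surrogates(scale * G, G)
        np.testing.assert_allclose(c, expected, atol=1e-12)

    def test_degenerate_component(self):
        with pytest.raises(ContractError, match="degenerate component"):
            fsva.align_surrogates(np.zeros((1, 5)), np.ones((1, 5)))


class TestExactMode:
    def test_zero_gamma_identity(self):
        X, fit = _identity_model()
        model = fsva.build_frozen_model(X, fit)
        x = np.arange(6.0)
        np.testing.assert_array_equal(fsva.fsva_exact_one(model, x), x)

    def test_duplicate_training_column_nearly_clean(self, scenario1_model):
        ds, _, fit, model = scenario1_model
        cleaned_db = fsva.clean_training(ds.X_db, fit)
        j = 3
        out = fsva.fsva_exact_one(model, ds.X_db.values[:, j])
        ref = cleaned_db.values[:, j]
        assert np.linalg.norm(out - ref) <= 0.1 * np.linalg.norm(ref)

    def test_exact_correction_reduces_batch_deviation(self):
        ds = fsva.simulate_dataset(1, 0.6, n_db=100, n_new=40, m=1000, seed=17)
        S = fsva.build_design(ds.outcome_db.astype(str))
        fit = fsva.irwsva_fit(ds.X_db, S, n_sv=1)
        model = fsva.build_frozen_model(ds.X_db, fit)
        cleaned = fsva.fsva_exact(model, ds.X_new)
        target = ds.true_B[:, None] * ds.outcome_new + ds.noise_new
        dev_clean = np.abs(cleaned.values - target).mean()
        dev_raw = np.abs(ds.X_new.values - target).mean()
        assert dev_clean < dev_raw

    def test_single_column_matches_exact_one(self, scenario1_model):
        ds, _, _, model = scenario1_model
        one = ds.X_new.subset_samples([5])
        out = fsva.fsva_exact(model, one)
        np.testing.assert_array_equal(
            out.values[:, 0], fsva.fsva_exact_one(model, ds.X_new.values[:, 5]))

    def test_column_permutation_equivariance(self, scenario1_model):
        ds, _, _, model = scenario1_model
        sub = ds.X_new.subset_samples([0, 1, 2, 3])
        perm = [2, 0, 3, 1]
        out = fsva.fsva_exact(model, sub)
        out_perm = fsva.fsva_exact(model, sub.subset_samples(perm))
        np.testing.assert_array_equal(out_perm.values, out.values[:, perm])

    def test_fast_approximates_exact(self, scenario1_model):
        ds, _, _, model = scenario1_model
        sub = ds.X_new.subset_samples(list(range(20)))
        exact = fsva.fsva_exact(model, sub)
        fast = fsva.fsva_fast(model, sub)
        corrs = [np.corrcoef(exact.values[:, j], fast.values[:, j])[0, 1]
                 for j in range(sub.n)]
        assert np.median(corrs) >= 0.95

    def test_non_finite_sample_rejected(self, scenario1_model):
        *_, model = scenario1_model
        x = np.full(model.fit.m, np.nan)
        with pytest.raises(ContractError, match="invalid sample"):
            fsva.fsva_exact_one(model, x)

    def test_fast_only_model_has_no_exact_mode(self, scenario1_model):
        ds, _, fit, _ = scenario1_model
        fast_only = fsva.build_frozen_model(ds.X_db, fit, keep_train=False)
        with pytest.raises(ContractError, match="exact mode unavailable"):
            fsva.fsva_exact_one(fast_only, ds.X_new.values[:, 0])
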