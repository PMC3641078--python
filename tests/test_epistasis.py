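"""LASSO path, cross-validation, extrapolation diagnostic and selection."""

import itertools

import numpy as np
import pytest

from promland.codec import FeatureIndex, build_design_matrix
from promland.epistasis import (
    LambdaPathResult,
    cross_validated_r2,
    delta_r2_higher_order,
    fit_lasso_path,
    kkt_violation,
    lambda_grid,
    lambda_max,
    random_sequence_variance,
    select_model,
)
from promland.model import LandscapeModel, random_sequences
from promland.simulate import mutagenize_library, sample_landscape


def _random_binary_design(n, L, rate, seed):
    wt = "A" * L
    seqs = mutagenize_library(wt, n, per_site_rate=rate, seed=seed)
    X, idx = build_design_matrix(seqs, wt, order=2)
    return seqs, X, idx, wt


class TestLassoPath:
    def test_all_zero_at_lambda_max(self):
        _, X, idx, _ = _random_binary_design(300, 6, 0.3, seed=1)
        rng = np.random.default_rng(2)
        y = np.asarray(X[:, :5] @ rng.normal(size=5)) + rng.normal(size=300) * 0.1
        path = fit_lasso_path(X, y, idx, n_lambda=10, lambda_min_ratio=1e-2)
        assert path.nonzero[0] == 0

    def test_soft_threshold_oracle(self):
        """Single-feature LASSO equals the closed-form soft-thresholded OLS value."""
        rng = np.random.default_rng(3)
        n = 200
        x = (rng.random(n) < 0.5).astype(float)
        y = 2.0 * x + rng.normal(size=n) * 0.3
        X = x[:, None]
        idx = FeatureIndex.build(1, 1)
        # restrict to the single real column by padding the design
        Xp = np.zeros((n, 3))
        Xp[:, 0] = x
        path = fit_lasso_path(Xp, y, idx, n_lambda=8, lambda_min_ratio=1e-2, tol=1e-12)
        xc = x - x.mean()
        yc = y - y.mean()
        denom = float(xc @ xc) / n
        for k, lam in enumerate(path.lambdas):
            rho = float(xc @ yc) / n
            expect = np.sign(rho) * max(abs(rho) - lam, 0.0) / denom
            assert path.coefs[0, k] == pytest.approx(expect, abs=1e-6)

    def test_smallest_lambda_matches_ols(self):
        """On a well-conditioned overdetermined design the end of the path is OLS."""
        rng = np.random.default_rng(4)
        X = (rng.random((60, 12)) < 0.5).astype(float)
        beta = rng.normal(size=12)
        y = X @ beta + 0.05 * rng.normal(size=60)
        idx = FeatureIndex.build(4, 1)
        path = fit_lasso_path(X, y, idx, n_lambda=30, lambda_min_ratio=1e-6, tol=1e-12)
        A = np.column_stack([np.ones(60), X])
        theta, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(path.coefs[:, -1], theta[1:], atol=1e-3)
        assert path.intercepts[-1] == pytest.approx(theta[0], abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kkt_conditions_along_path(self, seed):
        _, X, idx, _ = _random_binary_design(250, 5, 0.3, seed=seed)
        rng = np.random.default_rng(seed + 10)
        y = np.asarray(X @ rng.normal(size=X.shape[1], scale=0.3)) + rng.normal(size=250) * 0.2
        path = fit_lasso_path(X, y, idx, n_lambda=12, lambda_min_ratio=1e-3, tol=1e-12)
        Xd = X.toarray()
        for k in range(path.n_lambda):
            v = kkt_violation(Xd, y, path.coefs[:, k], path.intercepts[k], path.lambdas[k])
            assert v <= 1e-6

    def test_support_monotone_in_lambda(self):
        _, X, idx, _ = _random_binary_design(400, 6, 0.3, seed=7)
        rng = np.random.default_rng(8)
        y = np.asarray(X @ rng.normal(size=X.shape[1], scale=0.4)) + rng.normal(size=400) * 0.3
        path = fit_lasso_path(X, y, idx, n_lambda=25, lambda_min_ratio=1e-3)
        drops = np.clip(-np.diff(path.nonzero.astype(int)), 0, None)
        assert drops.sum() <= 2  # rare coordinate swaps tolerated

    def test_constant_columns_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        X = np.column_stack(
            [np.ones(50), (rng.random(50) < 0.5).astype(float), np.zeros(50)]
        )
        y = X[:, 1] + rng.normal(size=50) * 0.1
        idx = FeatureIndex.build(1, 1)
        with pytest.warns(UserWarning, match="constant"):
            path = fit_lasso_path(X, y, idx, n_lambda=5, lambda_min_ratio=1e-2)
        assert (path.coefs[0] == 0).all() and (path.coefs[2] == 0).all()


class TestCrossValidation:
    def test_pure_noise_cv_near_zero(self):
        _, X, idx, _ = _random_binary_design(2000, 8, 0.25, seed=11)
        y = np.random.default_rng(12).normal(size=2000)
        lams = lambda_grid(lambda_max(X, y), 12, 1e-2)
        cv = cross_validated_r2(X, y, lams, n_folds=5, seed=13)
        assert (cv <= 0.05).all()

    def test_strong_signal_cv_close_to_insample(self):
        seqs, X, idx, wt = _random_binary_design(3000, 8, 0.25, seed=14)
        rng = np.random.default_rng(15)
        beta = rng.normal(size=24, scale=1.0)
        y = np.asarray(X[:, :24] @ beta)
        path = fit_lasso_path(X, y, idx, n_lambda=15, lambda_min_ratio=1e-3)
        cv = cross_validated_r2(X, y, path.lambdas, n_folds=5, seed=16)
        k = int(np.argmax(cv))
        assert abs(cv[k] - path.r2_in[k]) < 0.05

    def test_deterministic_given_seed(self):
        _, X, idx, _ = _random_binary_design(500, 5, 0.3, seed=17)
        y = np.random.default_rng(18).normal(size=500)
        lams = lambda_grid(lambda_max(X, y), 6, 1e-1)
        a = cross_validated_r2(X, y, lams, n_folds=4, seed=42)
        b = cross_validated_r2(X, y, lams, n_folds=4, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_too_few_records(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError):
            cross_validated_r2(X, np.ones(3), np.array([1.0]), n_folds=10)


def _path_from_model(model: LandscapeModel, index: FeatureIndex, lambdas):
    """Wrap a fixed model as a constant one-column-per-lambda path."""
    coef = np.zeros(len(index))
    for i, b in enumerate(model.beta):
        coef[i] = b
    for (a, b), v in model.J.items():
        i, mi = divmod(a, 3)
        j, mj = divmod(b, 3)
        coef[index.position(("J", i, mi, j, mj))] = v
    coefs = np.tile(coef[:, None], (1, len(lambdas)))
    return LambdaPathResult(
        lambdas=np.asarray(lambdas, dtype=float),
        coefs=coefs,
        intercepts=np.full(len(lambdas), model.alpha),
        r2_in=np.linspace(0.2, 0.9, len(lambdas)),
        fitted_variance=np.ones(len(lambdas)),
        nonzero=(coefs != 0).sum(axis=0),
        feature_index=index,
    )


class TestRandomSequenceVariance:
    def test_zero_model(self):
        idx = FeatureIndex.build(4, 2)
        path = _path_from_model(
            LandscapeModel(1.0, np.zeros(12)), idx, [1.0, 0.5]
        )
        rv = random_sequence_variance(path, "ACGT", n_random=200, seed=0)
        np.testing.assert_allclose(rv, 0.0)

    def test_additive_matches_exhaustive_enumeration(self):
        L = 4
        idx = FeatureIndex.build(L, 1)
        rng = np.random.default_rng(20)
        model = LandscapeModel(0.3, rng.normal(size=3 * L))
        wt = "ACGT"
        path = _path_from_model(model, idx, [1.0])
        rv = random_sequence_variance(path, wt, n_random=40_000, seed=21)
        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=L)]
        exact = model.predict(seqs, wt).var()
        assert rv[0] == pytest.approx(exact, rel=0.05)

    def test_minimum_sample_size(self):
        idx = FeatureIndex.build(4, 1)
        path = _path_from_model(LandscapeModel(0.0, np.zeros(12)), idx, [1.0])
        with pytest.raises(ValueError):
            random_sequence_variance(path, "ACGT", n_random=10)


class TestSelectModel:
    def _base_path(self, rv, cv=None):
        idx = FeatureIndex.build(2, 1)
        n = len(rv)
        lams = np.geomspace(1.0, 1e-3, n)
        path = _path_from_model(LandscapeModel(0.0, np.ones(6)), idx, lams)
        path.random_variance = np.asarray(rv, dtype=float)
        path.r2_cv = (
            np.asarray(cv, dtype=float) if cv is not None else np.linspace(0.1, 0.6, n)
        )
        return path

    def test_cap_never_exceeded_selects_smallest_lambda(self):
        path = self._base_path(rv=[0.5, 0.6, 0.7, 0.8])
        sel = select_model(path, variance_cap_ratio=2.0)
        assert sel.selected_index == path.n_lambda - 1

    def test_blowup_selects_more_constrained_than_cv(self):
        cv = [0.1, 0.3, 0.5, 0.65, 0.7, 0.6]
        rv = [0.5, 0.8, 1.2, 1.8, 50.0, 500.0]
        path = self._base_path(rv=rv, cv=cv)
        sel = select_model(path, variance_cap_ratio=2.0)
        assert sel.selected_index == 3
        assert sel.selected_lambda > sel.cv_optimal_lambda
        assert not sel.used_fallback

    def test_infinite_cap_returns_cv_optimum(self):
        cv = [0.1, 0.3, 0.7, 0.5]
        path = self._base_path(rv=[1.0, 10.0, 100.0, 1000.0], cv=cv)
        sel = select_model(path, variance_cap_ratio=np.inf)
        assert sel.selected_index == sel.cv_optimal_index == 2

    def test_fallback_warns(self):
        path = self._base_path(rv=[10.0, 10.0, 10.0, 10.0])
        with pytest.warns(UserWarning, match="falling back"):
            sel = select_model(path, variance_cap_ratio=1.0)
        assert sel.used_fallback and sel.selected_index == sel.cv_optimal_index

    def test_empty_path_rejected(self):
        path = self._base_path(rv=[0.5])
        path.lambdas = np.empty(0)
        path.coefs = path.coefs[:, :0]
        with pytest.raises(ValueError):
            select_model(path)


class TestPredict:
    def test_expansion_identities(self):
        wt = "AAAA"
        beta = np.zeros(12)
        beta[0] = 1.5  # site 0, A->T
        beta[3] = -0.7  # site 1, A->T
        model = LandscapeModel(2.0, beta, {(0, 3): 0.4})
        assert model.predict([wt], wt)[0] == pytest.approx(2.0)
        assert model.predict(["TAAA"], wt)[0] == pytest.approx(2.0 + 1.5)
        assert model.predict(["TTAA"], wt)[0] == pytest.approx(2.0 + 1.5 - 0.7 + 0.4)

    def test_vectorized_matches_scalar_path(self):
        rng = np.random.default_rng(30)
        truth = sample_landscape(12, epistatic_sparsity=0.08, seed=31,
                                 region_map=__import__("promland").RegionMap({"B": (0, 12)}, 12))
        seqs = random_sequences(500, 12, rng)
        fast = truth.model.predict(seqs, truth.wildtype)
        slow = np.array(
            [truth.model.predict([s], truth.wildtype)[0] for s in seqs[:50]]
        )
        np.testing.assert_allclose(fast[:50], slow, rtol=1e-12)


class TestDeltaR2HigherOrder:
    def test_subset_too_small(self):
        with pytest.raises(ValueError):
            delta_r2_higher_order(["ACG"], np.array([1.0]), "ACG", site_subset=[0, 1])

    def test_order2_report_consistent_with_direct_fit(self):
        """The order-2 leg of the comparison equals a standalone order-2 fit."""
        from promland.epistasis import fit_epistatic

        truth = sample_landscape(
            8, region_map=__import__("promland").RegionMap({"B": (0, 8)}, 8),
            epistatic_sparsity=0.1, seed=33,
        )
        seqs = mutagenize_library(truth.wildtype, 1500, per_site_rate=0.25, seed=34)
        gy = truth.model.predict(seqs, truth.wildtype)
        kwargs = dict(n_lambda=8, lambda_min_ratio=1e-2, n_folds=4, seed=1,
                      variance_cap_ratio=np.inf, n_random=200)
        rep = delta_r2_higher_order(seqs, gy, truth.wildtype, site_subset=None,
                                    orders=(2, 3), **kwargs)
        _, sel = fit_epistatic(seqs, gy, truth.wildtype, order=2, **kwargs)
        assert rep["order2"]["selected_lambda"] == pytest.approx(sel.selected_lambda)
        assert rep["order2"]["nonzero"] == int(
            (sel.model.beta != 0).sum() + len(sel.model.J)
        )
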