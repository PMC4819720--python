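import numpy as np
import pytest
import statsmodels.api as sm

from taylornet import (
    ConnectivityMatrix,
    MatrixStack,
    ModelSpec,
    SyntheticSpec,
    TaylorNetworkModel,
    ValidationError,
    build_terms,
    count_coefficients,
    fit_model_sequence,
    fit_taylor,
    gen_stack,
    plant_target,
    r_squared,
    shared_connectivity,
    spectral_check,
)
from conftest import random_target


def _triple_loop_product(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Independent brute-force oracle for the matrix product."""
    p = a.shape[0]
    out = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            for k in range(p):
                out[i, j] += a[i, k] * b[k, j]
    return out


def _cm(w, **kw):
    return ConnectivityMatrix(w, **kw)


def _rand_cm(p, rng, labels=None):
    w = rng.normal(0, 0.3, (p, p))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return _cm(np.clip(w, -1, 1), region_labels=labels or [])


class TestSharedConnectivity:
    def test_zero_matrix(self, rng):
        z = _cm(np.zeros((4, 4)))
        w = _rand_cm(4, rng)
        assert np.allclose(shared_connectivity(z, w), 0.0)

    def test_diagonal_is_column_norms(self, rng):
        w = _rand_cm(6, rng)
        prod = shared_connectivity(w, w)
        for q in range(6):
            assert prod[q, q] == pytest.approx(np.sum(w.weights[:, q] ** 2))

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            a, b = _rand_cm(5, rng), _rand_cm(5, rng)
            assert np.max(
                np.abs(shared_connectivity(a, b) - _triple_loop_product(a.weights, b.weights))
            ) < 1e-12

    def test_explicit_3x3_entry(self):
        w = np.array([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])
        cm = _cm(w)
        prod = shared_connectivity(cm, cm)
        # entry (0, 1) is the dot product of columns 0 and 1
        assert prod[0, 1] == pytest.approx(w[:, 0] @ w[:, 1])
        assert np.allclose(prod, _triple_loop_product(w, w))


class TestBuildTerms:
    @pytest.mark.parametrize(
        "variant,expected_k",
        [("linear", 6), ("nonlinear", 11), ("nonlinear_cross", 21)],
    )
    def test_design_width_for_five_bands(self, variant, expected_k, small_spec):
        spec5 = SyntheticSpec(P=15, D=5, seed=7)
        stack = gen_stack(spec5)
        terms = build_terms(stack, ModelSpec(variant, metrics=("AEC",)))
        assert terms.K == expected_k
        assert terms.E == 15 * 14 // 2

    def test_regressors_symmetric(self, small_stack):
        terms = build_terms(small_stack, ModelSpec("nonlinear_cross", metrics=("AEC",)))
        for mat in terms.matrices:
            assert np.allclose(mat, mat.T)


class TestCountCoefficients:
    def test_paper_convention_counts(self):
        assert count_coefficients(10, "paper").total == 110
        assert count_coefficients(1, "paper").total == 2
        assert count_coefficients(5, "paper").total == 30

    def test_fitted_convention_counts(self):
        assert count_coefficients(5, "fitted").total == 20
        assert count_coefficients(10, "fitted").total == 65

    def test_spec_respects_term_flags(self):
        lin = ModelSpec("linear", bands=("delta", "theta", "alpha"), metrics=("AEC",))
        assert count_coefficients(lin).total == 3
        nl = ModelSpec("nonlinear", bands=("delta", "theta", "alpha"), metrics=("AEC",))
        assert count_coefficients(nl).total == 6  # 3 linear + 3 squares


class TestFit:
    def test_exact_linear_relation(self, rng):
        labels = [f"r{i}" for i in range(10)]
        w1 = _rand_cm(10, rng, labels)
        target = _cm(2.0 * w1.weights, region_labels=labels, check_range=False)
        stack = MatrixStack([w1])
        res = fit_taylor(target, stack, ModelSpec("linear"))
        assert res.a.iloc[0] == pytest.approx(2.0, abs=1e-10)
        assert res.c == pytest.approx(0.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_planted_recovery(self, small_spec, small_stack, small_target):
        res = fit_taylor(small_target, small_stack, small_spec.fit_spec)
        a, b, c = small_spec.coefficients()
        model = TaylorNetworkModel(small_target, small_stack, small_spec.fit_spec)
        theta = np.concatenate([a, [b[m, n] for m, n in model.terms.quad_pairs], [c]])
        rel = np.max(np.abs(res.params.to_numpy() - theta)) / np.max(np.abs(theta))
        assert rel < 1e-6
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_iterative_solver_agrees_with_ols(self, small_stack, small_target, small_spec):
        ols = fit_taylor(small_target, small_stack, small_spec.fit_spec, method="ols")
        it = fit_taylor(small_target, small_stack, small_spec.fit_spec, method="iterative")
        assert np.allclose(ols.params.to_numpy(), it.params.to_numpy(), atol=1e-6)

    def test_matches_statsmodels_ols(self, small_stack, rng):
        """Independent route: statsmodels OLS on the same design."""
        target = random_target(small_stack, rng)
        spec = ModelSpec("nonlinear_cross", metrics=("AEC",))
        res = fit_taylor(target, small_stack, spec)
        model = TaylorNetworkModel(target, small_stack, spec)
        smres = sm.OLS(model.endog, model.terms.design).fit()
        assert np.allclose(res.params.to_numpy(), smres.params, atol=1e-8)
        assert res.rsquared == pytest.approx(smres.rsquared, abs=1e-10)
        assert np.allclose(res.bse.to_numpy(), smres.bse, atol=1e-8)
        ci = res.conf_int().to_numpy()
        assert np.allclose(ci, smres.conf_int(), atol=1e-8)

    def test_pure_noise_r2_near_chance_level(self, rng):
        """R^2 against unrelated regressors ~ (K-1)/(E-1) on average."""
        spec = SyntheticSpec(P=78, D=5, seed=17)
        stack = gen_stack(spec)
        mspec = ModelSpec("nonlinear_cross", metrics=("AEC",))
        r2s = []
        for _ in range(200):
            r2s.append(fit_taylor(random_target(stack, rng), stack, mspec).rsquared)
        e, k = 3003, 21
        expected = (k - 1) / (e - 1)
        # Monte-Carlo spread of the mean over 200 replicates
        assert np.mean(r2s) == pytest.approx(expected, abs=3 * np.std(r2s) / np.sqrt(200))

    def test_under_determined_rejected(self, rng):
        labels = [f"r{i}" for i in range(4)]
        stack = MatrixStack([_rand_cm(4, rng, labels) for _ in range(3)])
        target = random_target(stack, rng)
        with pytest.raises(ValidationError, match="nder-determined"):
            fit_taylor(target, stack, ModelSpec("nonlinear_cross"))

    def test_rank_deficient_warns_and_names_regressor(self, rng):
        labels = [f"r{i}" for i in range(8)]
        w = _rand_cm(8, rng, labels)
        dup = ConnectivityMatrix(
            w.weights.copy(), metric="AEC", band=None, region_labels=labels
        )
        stack = MatrixStack([w, dup])
        target = random_target(stack, rng)
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_taylor(target, stack, ModelSpec("linear"))


class TestPredict:
    def test_offset_only(self, small_stack):
        target = ConnectivityMatrix(
            0.1 * (np.ones((20, 20)) - np.eye(20)),
            metric="generic",
            region_labels=small_stack.region_labels,
            check_range=False,
        )
        res = fit_taylor(target, small_stack, ModelSpec("linear", metrics=("AEC",)))
        assert res.c == pytest.approx(0.1, abs=1e-10)
        assert np.allclose(res.a.to_numpy(), 0.0, atol=1e-10)

    def test_round_trip_on_training_stack(self, small_spec, small_stack, small_target):
        res = fit_taylor(small_target, small_stack, small_spec.fit_spec)
        vhat = res.predict(small_stack)
        assert np.max(np.abs(vhat - small_target.weights)) < 1e-8

    def test_refit_is_idempotent(self, small_spec, small_stack, small_target):
        res = fit_taylor(small_target, small_stack, small_spec.fit_spec)
        res2 = res.refit()
        assert np.allclose(res.params.to_numpy(), res2.params.to_numpy(), atol=1e-8)

    def test_summary_mentions_r2(self, small_spec, small_stack, small_target):
        res = fit_taylor(small_target, small_stack, small_spec.fit_spec)
        text = res.summary()
        assert "R^2" in text and "c" in text


class TestRSquared:
    def test_perfect_and_mean_baselines(self, rng):
        v = _rand_cm(6, rng)
        assert r_squared(v, v) == pytest.approx(1.0)
        mean_mat = np.full((6, 6), v.upper_values().mean())
        assert r_squared(v.weights, mean_mat) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        v = np.zeros((3, 3))
        v[np.triu_indices(3, 1)] = [0.2, 0.4, 0.6]
        v = v + v.T
        vhat = np.zeros((3, 3))
        vhat[np.triu_indices(3, 1)] = [0.2, 0.5, 0.5]
        vhat = vhat + vhat.T
        # SSE = 0 + .01 + .01; SST = .08
        assert r_squared(v, vhat) == pytest.approx(0.75)

    def test_constant_target_signalled(self):
        with pytest.raises(ValidationError, match="variance"):
            r_squared(np.zeros((4, 4)), np.zeros((4, 4)))


class TestSpectralCheck:
    def test_trace_and_eigen_sum_zero(self, small_stack):
        diag = spectral_check(small_stack)
        assert np.allclose(diag.trace, 0.0)
        for lam in diag.eigenvalues:
            assert abs(lam.sum()) < 1e-10

    def test_two_by_two_closed_form(self):
        w = _cm(np.array([[0.0, 0.4], [0.4, 0.0]]))
        lam = np.sort(spectral_check(MatrixStack([w])).eigenvalues[0])
        assert np.allclose(lam, [-0.4, 0.4])


class TestModelSequence:
    def _ladder(self):
        return [
            ModelSpec("single_frequency", bands=("delta",), metrics=("AEC",)),
            ModelSpec("linear", metrics=("AEC",)),
            ModelSpec("nonlinear", metrics=("AEC",)),
            ModelSpec("nonlinear_cross", metrics=("AEC",)),
        ]

    def test_noiseless_planted_ends_at_one(self, small_spec, small_stack, small_target):
        fits = fit_model_sequence(small_target, small_stack, self._ladder())
        r2 = [f.rsquared for f in fits]
        assert r2[-1] == pytest.approx(1.0, abs=1e-10)
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_single_band_target_saturates_early(self, small_stack):
        w1 = small_stack[0]
        target = ConnectivityMatrix(
            1.5 * w1.weights,
            metric="generic",
            region_labels=small_stack.region_labels,
            check_range=False,
        )
        band = w1.band.name
        specs = [
            ModelSpec("single_frequency", bands=(band,), metrics=("AEC",))
        ] + self._ladder()[1:]
        fits = fit_model_sequence(target, small_stack, specs)
        for f in fits:
            assert f.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_random_target_monotone(self, small_stack, rng):
        target = random_target(small_stack, rng)
        fits = fit_model_sequence(target, small_stack, self._ladder())
        r2 = [f.rsquared for f in fits]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))


class TestNoiseMonotonicity:
    def test_recovery_error_shrinks_with_noise(self):
        """Median coefficient error decreases as noise drops 0.1 -> 0.001."""
        medians = []
        for sd in (0.1, 0.01, 0.001):
            errs = []
            for seed in range(20):
                spec = SyntheticSpec(P=20, D=5, noise_sd=sd, seed=300 + seed)
                stack = gen_stack(spec)
                target = plant_target(stack, spec)
                model = TaylorNetworkModel(target, stack, spec.fit_spec)
                res = model.fit()
                a, b, c = spec.coefficients()
                theta = np.concatenate(
                    [a, [b[m, n] for m, n in model.terms.quad_pairs], [c]]
                )
                errs.append(
                    np.max(np.abs(res.params.to_numpy() - theta)) / np.max(np.abs(theta))
                )
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]
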