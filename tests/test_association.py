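import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gutmet.association import (bonferroni_threshold, covariate_sensitivity,
                                fit_vc, lrt_association, run_screen,
                                storey_qvalues)
from gutmet.pedigree import kinship_matrix
from gutmet.synthetic import CohortSpec, generate_pedigree


def ols_ml_loglik(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n = len(y)
    return -n / 2 * (np.log(2 * np.pi * rss / n) + 1), beta


def ols_lrt_p(y, X_null, X_full):
    """Closed-form likelihood-ratio P for nested Gaussian linear models."""
    ll0, _ = ols_ml_loglik(y, X_null)
    ll1, _ = ols_ml_loglik(y, X_full)
    return stats.chi2.sf(2 * (ll1 - ll0), df=1)


class TestFitVC:
    def test_identity_kinship_equals_ols(self, rng):
        n = 150
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ [1.0, 0.4] + rng.standard_normal(n)
        fit = fit_vc(y, X, K=np.eye(n))
        ll, beta = ols_ml_loglik(y, X)
        assert fit.loglik == pytest.approx(ll, abs=1e-8)
        assert np.allclose(fit.beta_hat, beta, atol=1e-8)

    def test_h_recovery(self):
        # mean estimated heritability fraction close to truth across seeds
        spec = CohortSpec(n_mz_pairs=150, n_dz_pairs=150, n_singletons=0,
                          seed=0)
        K = kinship_matrix(generate_pedigree(spec)).to_numpy()
        n = K.shape[0]
        d, U = np.linalg.eigh(K)
        d = np.clip(d, 0, None)
        L = U * np.sqrt(d)
        X = np.ones((n, 1))
        h_true = 0.6
        rng = np.random.default_rng(1)
        hs = []
        for _ in range(100):
            y = (np.sqrt(h_true) * L @ rng.standard_normal(n)
                 + np.sqrt(1 - h_true) * rng.standard_normal(n))
            hs.append(fit_vc(y, X, eig=(d, U)).h)
        assert abs(np.mean(hs) - h_true) < 0.05

    def test_perfect_fit_boundary(self, rng):
        n = 60
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_vc(x, X, K=np.eye(n))
        assert fit.sigma_e2 < 1e-10

    def test_rank_deficient_error(self, rng):
        n = 50
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, x])
        with pytest.raises(ValueError, match="rank"):
            fit_vc(rng.standard_normal(n), X, K=np.eye(n))

    def test_variance_components_nonnegative(self, rng):
        spec = CohortSpec(n_mz_pairs=30, n_dz_pairs=30, n_singletons=30,
                          seed=0)
        K = kinship_matrix(generate_pedigree(spec)).to_numpy()
        n = K.shape[0]
        fit = fit_vc(rng.standard_normal(n), np.ones((n, 1)), K=K)
        assert fit.sigma_g2 >= 0 and fit.sigma_e2 > 0


class TestLRT:
    def _setup(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        idx = pd.Index(ids)
        K = pd.DataFrame(np.eye(n), index=ids, columns=ids)
        y = pd.Series(rng.standard_normal(n), index=idx)
        x = pd.Series(rng.standard_normal(n), index=idx)
        cov = pd.DataFrame({"c": rng.standard_normal(n)}, index=idx)
        return y, x, cov, K

    def test_matches_ols_oracle(self):
        y, x, cov, K = self._setup()
        rec = lrt_association(y, x, cov, K, min_n=50)
        n = len(y)
        X0 = np.column_stack([np.ones(n), cov["c"]])
        X1 = np.column_stack([X0, x])
        assert rec["p"] == pytest.approx(ols_lrt_p(y.to_numpy(), X0, X1),
                                         abs=1e-6)

    def test_min_n_skip(self):
        y, x, cov, K = self._setup(n=60)
        y.iloc[:11] = np.nan  # 49 complete
        assert lrt_association(y, x, cov, K, min_n=50) is None

    def test_full_loglik_dominates_null(self):
        y, x, cov, K = self._setup(seed=3)
        rec = lrt_association(y, x, cov, K)
        assert rec["loglik_full"] >= rec["loglik_null"] - 1e-9

    def test_null_calibration_smoke(self):
        # quick null check; the full 2,000-rep calibration is in acceptance
        spec = CohortSpec(n_mz_pairs=50, n_dz_pairs=50, n_singletons=0,
                          seed=0)
        K = kinship_matrix(generate_pedigree(spec))
        ids = list(K.index)
        n = len(ids)
        L = np.linalg.cholesky(0.4 * K.to_numpy() + 0.6001 * np.eye(n))
        rng = np.random.default_rng(7)
        cache = {}
        rejections = 0
        reps = 300
        for _ in range(reps):
            y = pd.Series(L @ rng.standard_normal(n), index=ids)
            x = pd.Series(rng.standard_normal(n), index=ids)
            rec = lrt_association(y, x, None, K, min_n=50, eig_cache=cache)
            rejections += rec["p"] < 0.05
        assert 0.02 < rejections / reps < 0.09


class TestStorey:
    def test_bh_identity_when_pi0_one(self, rng):
        p = rng.random(500)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_hand_oracle(self):
        q = storey_qvalues(np.array([0.01, 0.02, 0.9]), pi0=1.0)
        assert np.allclose(q, [0.03, 0.03, 0.9])

    def test_pi0_near_one_under_null(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            p = rng.random(5000)
            q = storey_qvalues(p)
            # recover implied pi0 from the largest q
            pi0 = q[np.argmax(p)] / multipletests(p, method="fdr_bh")[1][
                np.argmax(p)]
            hits += 0.9 <= pi0 <= 1.0 + 1e-9
        assert hits >= 95

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            storey_qvalues(np.array([0.5, 1.5]))

    def test_small_m_warns_and_uses_bh(self):
        p = np.array([0.01, 0.2, 0.5])
        with pytest.warns(UserWarning):
            q = storey_qvalues(p)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_order_invariance(self, rng):
        p = rng.random(300)
        perm = rng.permutation(300)
        q = storey_qvalues(p, pi0=1.0)
        q2 = storey_qvalues(p[perm], pi0=1.0)
        assert np.allclose(q[perm], q2)

    def test_monotone_in_p(self, rng):
        p = rng.random(1000)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestScreen:
    def test_deterministic(self, small_cohort):
        from gutmet.preprocess import preprocess_features, preprocess_metabolites
        c = small_cohort
        K = kinship_matrix(c.pedigree)
        feats = preprocess_features(c.species).iloc[:, :5]
        mets = preprocess_metabolites(
            c.faecal, c.covariates["runday"], scale=True).iloc[:, :5]
        cov = c.covariates[["sex", "age"]]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_screen(mets, feats, cov, K, min_n=40)
            b = run_screen(mets, feats, cov, K, min_n=40)
        assert a.equals(b)

    def test_planted_effects_recovered(self):
        from gutmet.preprocess import preprocess_features, preprocess_metabolites
        from gutmet.synthetic import generate_cohort
        spec = CohortSpec(n_mz_pairs=50, n_dz_pairs=50, n_singletons=100,
                          n_species=10, n_pathways=4, n_faecal_mets=20,
                          n_blood_mets=4, n_planted_effects=5,
                          n_planted_trios=0, effect_size=0.8,
                          heritability=0.3, missing_rate=0.0,
                          prevalence_range=(0.6, 0.95), seed=31)
        c = generate_cohort(spec)
        K = kinship_matrix(c.pedigree)
        feats = preprocess_features(c.species)
        mets = preprocess_metabolites(c.faecal, c.covariates["runday"],
                                      scale=True)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = run_screen(mets, feats, c.covariates[["sex", "age"]], K,
                             min_n=50)
        planted = {(f, m) for f, m, _ in c.truth.planted_effects
                   if m.startswith("FMET")}
        sig = set(zip(rec.loc[rec.q <= 0.05, "feature_id"],
                      rec.loc[rec.q <= 0.05, "metabolite_id"]))
        assert len(planted & sig) >= 0.8 * len(planted)

    def test_no_pairs_error(self):
        ids = ["a", "b", "c"]
        mets = pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=ids)
        feats = pd.DataFrame({"f": [0.1, 0.2, 0.3]}, index=ids)
        K = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        with pytest.raises(ValueError, match="no testable"):
            run_screen(mets, feats, None, K, min_n=50)


class TestCovariateSensitivity:
    def _records(self):
        return pd.DataFrame({
            "feature_id": ["f1", "f1", "f2"],
            "metabolite_id": ["m1", "m2", "m1"],
            "n": [100, 100, 100],
            "beta": [0.5, -0.3, 0.2],
            "se": [0.1, 0.1, 0.1],
            "p": [1e-5, 1e-4, 0.2],
            "q": [1e-4, 1e-3, 0.3],
        })

    def test_identical_screens_full_concordance(self):
        a = self._records()
        out = covariate_sensitivity(a, a.copy())
        assert out["concordance"] == 1.0
        assert out["n_discordant"] == 0

    def test_sign_flip_reported(self):
        a = self._records()
        b = a.copy()
        b.loc[0, "beta"] = -0.5
        out = covariate_sensitivity(a, b)
        assert out["n_discordant"] == 1

    def test_noise_covariate_high_concordance(self, small_cohort):
        from gutmet.preprocess import preprocess_features, preprocess_metabolites
        import warnings
        c = small_cohort
        K = kinship_matrix(c.pedigree)
        feats = preprocess_features(c.species).iloc[:, :8]
        mets = preprocess_metabolites(c.faecal, c.covariates["runday"],
                                      scale=True).iloc[:, :8]
        cov_a = c.covariates[["sex", "age"]]
        rng = np.random.default_rng(9)
        cov_b = cov_a.assign(noise=rng.standard_normal(len(cov_a)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_screen(mets, feats, cov_a, K, min_n=40)
            b = run_screen(mets, feats, cov_b, K, min_n=40)
        out = covariate_sensitivity(a, b)
        if out["n_significant_both"]:
            assert out["concordance"] >= 0.95

    def test_pair_mismatch_error(self):
        a = self._records()
        b = a.copy()
        b.loc[0, "feature_id"] = "f9"
        with pytest.raises(ValueError):
            covariate_sensitivity(a, b)


def test_bonferroni_threshold():
    assert bonferroni_threshold(0.05, 3) == 0.017
    assert bonferroni_threshold(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
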