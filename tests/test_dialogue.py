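import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutmet import dialogue as dlg


def _assoc(rows):
    return pd.DataFrame(rows, columns=["feature_id", "metabolite_id", "n",
                                       "beta", "se", "p", "q"])


def _sig(feature, met):
    return {"feature_id": feature, "metabolite_id": met, "n": 150,
            "beta": 0.5, "se": 0.1, "p": 1e-6, "q": 1e-4}


def _tables(n=160, n_f=4, n_b=4, seed=0, feat_prev=0.9):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    fae = pd.DataFrame(rng.standard_normal((n, n_f)),
                       index=idx, columns=[f"FM{j}" for j in range(n_f)])
    blo = pd.DataFrame(rng.standard_normal((n, n_b)),
                       index=idx, columns=[f"BM{j}" for j in range(n_b)])
    feats = pd.DataFrame(
        np.where(rng.random((n, 3)) < feat_prev,
                 rng.standard_normal((n, 3)), np.nan),
        index=idx, columns=["f1", "f2", "f3"])
    return fae, blo, feats


class TestFindCoAssociations:
    def test_cartesian_count(self):
        fae, blo, feats = _tables()
        fa = _assoc([_sig("f1", "FM0"), _sig("f1", "FM1")])
        ba = _assoc([_sig("f1", "BM0"), _sig("f1", "BM1"), _sig("f1", "BM2")])
        trios = dlg.find_co_associations(fa, ba, fae, blo, feats,
                                         min_complete=0)
        assert len(trios) == 6

    def test_no_shared_feature_empty(self):
        fae, blo, feats = _tables()
        fa = _assoc([_sig("f1", "FM0")])
        ba = _assoc([_sig("f2", "BM0")])
        trios = dlg.find_co_associations(fa, ba, fae, blo, feats)
        assert trios.empty

    def test_min_complete_filter(self):
        fae, blo, feats = _tables(n=160, feat_prev=0.5)
        fa = _assoc([_sig("f1", "FM0")])
        ba = _assoc([_sig("f1", "BM0")])
        assert dlg.find_co_associations(fa, ba, fae, blo, feats,
                                        min_complete=150).empty
        got = dlg.find_co_associations(fa, ba, fae, blo, feats,
                                       min_complete=10)
        assert len(got) == 1
        # n_complete equals the hand count
        present = feats["f1"].notna() & (feats["f1"] != 0)
        assert got["n_complete"].iloc[0] == int(present.sum())


class TestLogRatio:
    def test_equal_inputs_zero(self):
        m = pd.Series([1.0, 2.0], index=["a", "b"])
        assert (dlg.log_ratio(m, m) == 0).all()

    def test_closed_form(self):
        m1 = pd.Series([np.log(4)], index=["a"])
        m2 = pd.Series([np.log(2)], index=["a"])
        assert dlg.log_ratio(m1, m2).iloc[0] == pytest.approx(np.log(2))

    def test_missing_propagates(self):
        m1 = pd.Series([1.0, 2.0], index=["a", "b"])
        m2 = pd.Series([np.nan, 1.0], index=["a", "b"])
        out = dlg.log_ratio(m1, m2)
        assert np.isnan(out["a"]) and out["b"] == 1.0


class TestPgain:
    def test_arithmetic(self):
        assert dlg.pgain(0.01, 0.05, 0.001) == pytest.approx(10.0)

    def test_no_gain_is_one(self):
        assert dlg.pgain(0.01, 0.05, 0.01) == pytest.approx(1.0)
        assert dlg.pgain(1.0, 1.0, 1.0) == 1.0

    def test_scale_free(self):
        a = dlg.pgain(0.02, 0.04, 0.002)
        b = dlg.pgain(0.002, 0.004, 0.0002)
        assert a == pytest.approx(b)

    def test_domain(self):
        with pytest.raises(ValueError):
            dlg.pgain(0.0, 0.5, 0.1)
        with pytest.raises(ValueError):
            dlg.pgain(0.5, 0.5, 1.5)


class TestLmmFamilyP:
    def test_singleton_families_equal_ols(self):
        rng = np.random.default_rng(2)
        n = 150
        idx = pd.Index([f"s{i}" for i in range(n)])
        y = pd.Series(rng.standard_normal(n), index=idx)
        x = pd.Series(rng.standard_normal(n), index=idx)
        fam = pd.Series([f"F{i}" for i in range(n)], index=idx)
        p = dlg.lmm_family_p(y, x, None, fam, min_complete=100)
        # OLS likelihood-ratio oracle
        X0 = np.ones((n, 1))
        X1 = np.column_stack([X0, x])
        def ll(X):
            b, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            rss = np.sum((y.to_numpy() - X @ b) ** 2)
            return -n / 2 * (np.log(2 * np.pi * rss / n) + 1)
        p_ols = stats.chi2.sf(2 * (ll(X1) - ll(X0)), 1)
        assert p == pytest.approx(p_ols, abs=1e-6)

    def test_planted_slope_power(self):
        rng = np.random.default_rng(3)
        n = 400
        idx = pd.Index([f"s{i}" for i in range(n)])
        fam = pd.Series([f"F{i // 2}" for i in range(n)], index=idx)
        hits = 0
        for s in range(10):
            x = pd.Series(rng.standard_normal(n), index=idx)
            y = 0.5 * x + pd.Series(rng.standard_normal(n), index=idx)
            hits += dlg.lmm_family_p(y, x, None, fam) < 0.001
        assert hits >= 9

    def test_min_complete_enforced(self):
        rng = np.random.default_rng(4)
        idx = pd.Index([f"s{i}" for i in range(50)])
        y = pd.Series(rng.standard_normal(50), index=idx)
        x = pd.Series(rng.standard_normal(50), index=idx)
        fam = pd.Series("F0", index=idx)
        with pytest.raises(ValueError, match="complete"):
            dlg.lmm_family_p(y, x, None, fam, min_complete=100)


class TestMatching:
    def _targets(self):
        return pd.DataFrame({
            "feature_id": ["f1", "f2"],
            "faecal_met_id": ["FM0", "FM1"],
            "blood_met_id": ["BM0", "BM1"],
            "n_complete": [120, 140],
            "r_observed": [0.3, -0.2],
        })

    def test_pool_copies_match_exactly(self):
        t = self._targets()
        pool = t.assign(feature_id=["g1", "g2"])
        out = dlg.match_null_pairs(t, pool, 10, np.random.default_rng(0))
        # by construction every draw matches its target's r and n exactly
        for _, row in out.iterrows():
            tgt = t.iloc[int(row["target_index"])]
            assert abs(abs(row["r_observed"]) - abs(tgt["r_observed"])) == 0
            assert row["n_complete"] == tgt["n_complete"]

    def test_empty_pool_error(self):
        with pytest.raises(ValueError):
            dlg.match_null_pairs(self._targets(), pd.DataFrame(), 5,
                                 np.random.default_rng(0))

    def test_tolerances_respected(self):
        rng = np.random.default_rng(1)
        t = self._targets()
        pool = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(200)],
            "faecal_met_id": [f"FMx{i}" for i in range(200)],
            "blood_met_id": [f"BMx{i}" for i in range(200)],
            "n_complete": rng.integers(100, 160, 200),
            "r_observed": rng.uniform(-0.5, 0.5, 200),
        })
        out = dlg.match_null_pairs(t, pool, 50, rng, tol_r=0.05, tol_n=0.10)
        for _, row in out.iterrows():
            tgt = t.iloc[int(row["target_index"])]
            assert abs(abs(row["r_observed"]) - abs(tgt["r_observed"])) <= 0.05
            assert abs(row["n_complete"] - tgt["n_complete"]) <= \
                0.10 * tgt["n_complete"]

    def test_unmatched_error_lists_targets(self):
        t = self._targets()
        pool = t.assign(feature_id=["g1", "g2"]).copy()
        pool["r_observed"] = 0.99
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="FM0"):
                dlg.match_null_pairs(t, pool, 5, np.random.default_rng(0))


class TestThreshold:
    def test_order_statistic(self):
        assert dlg.empirical_pgain_threshold(np.arange(1.0, 101.0)) == 95.0

    def test_all_equal(self):
        assert dlg.empirical_pgain_threshold(np.full(200, 3.3)) == 3.3

    def test_too_few_error(self):
        with pytest.raises(ValueError):
            dlg.empirical_pgain_threshold(np.arange(50.0))

    def test_holdout_calibration_iid(self):
        # smaller version of the acceptance check on iid draws
        rng = np.random.default_rng(0)
        nulls = np.exp(rng.standard_normal(4000))
        thr = dlg.empirical_pgain_threshold(nulls[:2000])
        rate = np.mean(nulls[2000:] >= thr)
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < 3 * se


class TestSummary:
    def _records(self):
        return pd.DataFrame({
            "feature_id": ["f1", "f1", "f2"],
            "faecal_met_id": ["FM0", "FM0", "FM1"],
            "blood_met_id": ["BM0", "BM1", "BM2"],
            "pgain": [100.0, 1.0, 50.0],
        })

    def test_none_pass(self):
        out = dlg.dialogue_summary(self._records(), 1e6, 10, 10, 5)
        assert out["frac_faecal_mets"] == 0.0
        assert out["n_passing"] == 0

    def test_all_pass(self):
        out = dlg.dialogue_summary(self._records(), 0.5, 10, 10, 5)
        assert out["n_passing"] == 3
        assert out["frac_faecal_mets"] == pytest.approx(2 / 10)
        assert out["frac_blood_mets"] == pytest.approx(3 / 10)
        assert out["frac_features"] == pytest.approx(2 / 5)


class TestPresenceCorrelation:
    def test_exchangeable_pool_p_near_half(self):
        rng = np.random.default_rng(5)
        n = 200
        idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        fae = pd.DataFrame({"FM0": rng.standard_normal(n)}, index=idx)
        blo = pd.DataFrame({"BM0": rng.standard_normal(n)}, index=idx)
        feats = pd.DataFrame(
            {"f1": np.where(rng.random(n) < 0.7,
                            rng.standard_normal(n), np.nan)}, index=idx)
        present = feats["f1"].notna() & (feats["f1"] != 0)
        r, _ = dlg.pairwise_r(fae["FM0"], blo["BM0"])
        trio = pd.DataFrame({
            "feature_id": ["f1"], "faecal_met_id": ["FM0"],
            "blood_met_id": ["BM0"], "n_complete": [int(present.sum())],
            "r_observed": [r],
        })
        pool = trio.assign(feature_id=["f1"])
        out = dlg.presence_correlation_test(
            trio, pool, feats, fae, blo, n_datasets=400, n_pairs=1,
            min_missing=30, rng=rng)
        # null pairs are copies of the observed trio: P is ~uniform on the
        # achievable grid, so far from both tails
        assert 0.1 < out["empirical_p"] <= 1.0
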