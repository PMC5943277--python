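import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amfniche import ecostats
from amfniche.ecostats import (bray_curtis, bray_curtis_matrix, commonness,
                               correlate, logistic_glmm, odds_ratio,
                               permanova, robustness, stepwise_lm,
                               yield_response)
from conftest import make_table


class TestYieldResponse:
    def test_equal_yields_zero_response(self, toy_metadata):
        meta = toy_metadata.copy()
        meta["yield_kg_ha"] = 100.0
        yr = yield_response(meta)
        assert (yr["response"] == 0).all()

    def test_hand_computed_responses(self, toy_metadata):
        yr = yield_response(toy_metadata)
        # T1 control mean 105: (120-105)/105, (130-105)/105
        assert yr.loc["T1_I0", "response"] == pytest.approx(15 / 105)
        assert yr.loc["T1_I1", "response"] == pytest.approx(25 / 105)
        # T2 control mean 200
        assert yr.loc["T2_I0", "response"] == pytest.approx(-0.10)
        assert yr.loc["T2_I1", "response"] == pytest.approx(0.10)

    def test_zero_control_mean_raises(self, toy_metadata):
        meta = toy_metadata.copy()
        meta.loc[~meta["inoculated"], "yield_kg_ha"] = 0.0
        with pytest.raises(ZeroDivisionError):
            yield_response(meta)

    def test_unmatched_inoculated_plot_raises(self, toy_metadata):
        meta = toy_metadata.copy()
        meta.loc[meta["sample_id"] == "T1_I0", "p_level"] = 50
        with pytest.raises(ValueError, match="no control"):
            yield_response(meta)


def _three_trial_meta(samples_per_trial=2):
    rows = []
    for t in ("T1", "T2", "T3"):
        for i in range(samples_per_trial):
            rows.append({"sample_id": f"{t}_c{i}", "trial": t,
                         "inoculated": False})
            rows.append({"sample_id": f"{t}_i{i}", "trial": t,
                         "inoculated": True})
    return pd.DataFrame(rows)


def _table_from_trial_means(means_by_otu, meta, inoculated_counts=None):
    """Control samples carry the stated per-trial mean counts exactly."""
    counts = {}
    for _, r in meta.iterrows():
        sid, trial = r["sample_id"], r["trial"]
        row = {}
        for otu, by_trial in means_by_otu.items():
            if r["inoculated"]:
                row[otu] = (inoculated_counts or {}).get(otu, {}).get(trial, 0)
            else:
                row[otu] = by_trial[trial]
        # filler OTU keeps totals comparable without entering the analysis
        row["FILL"] = 100000 - sum(row.values())
        counts[sid] = row
    return make_table(counts)


class TestCommonness:
    def test_even_spread_equals_n_trials(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means({"X": {"T1": 100, "T2": 100, "T3": 100}},
                                    meta)
        res = commonness(t, meta, rare_filter=0.0)
        assert res.commonness["X"] == pytest.approx(3.0, abs=1e-9)

    def test_specialist_equals_one(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means({"X": {"T1": 100, "T2": 0, "T3": 0}}, meta)
        res = commonness(t, meta, rare_filter=0.0)
        assert res.commonness["X"] == pytest.approx(1.0, abs=1e-9)

    def test_60_30_10_split(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means({"X": {"T1": 60, "T2": 30, "T3": 10}},
                                    meta)
        res = commonness(t, meta, rare_filter=0.0)
        assert res.commonness["X"] == pytest.approx(1 / 0.46, abs=1e-9)

    def test_rare_otus_excluded(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means(
            {"X": {"T1": 5000, "T2": 5000, "T3": 5000},
             "RARE": {"T1": 10, "T2": 10, "T3": 10}}, meta)
        res = commonness(t, meta, rare_filter=0.002)
        assert "RARE" in res.excluded_rare
        assert "RARE" not in res.commonness.index

    def test_inoculum_set_excluded(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means(
            {"X": {"T1": 5000, "T2": 5000, "T3": 5000},
             "INOC_01": {"T1": 5000, "T2": 5000, "T3": 5000}}, meta)
        res = commonness(t, meta, rare_filter=0.0, exclude={"INOC_01"})
        assert "INOC_01" not in res.commonness.index

    def test_uses_controls_only(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means(
            {"X": {"T1": 100, "T2": 100, "T3": 100}}, meta,
            inoculated_counts={"X": {"T1": 99999, "T2": 0, "T3": 0}})
        res = commonness(t, meta, rare_filter=0.0)
        assert res.commonness["X"] == pytest.approx(3.0, abs=1e-9)

    def test_bounded_in_one_to_n_trials(self):
        rng = np.random.default_rng(0)
        meta = _three_trial_meta()
        counts = {r["sample_id"]: {f"O{k}": int(rng.integers(0, 500))
                                   for k in range(8)}
                  for _, r in meta.iterrows()}
        res = commonness(make_table(counts), meta, rare_filter=0.0)
        assert ((res.commonness >= 1 - 1e-9)
                & (res.commonness <= 3 + 1e-9)).all()

    def test_scale_invariance(self):
        meta = _three_trial_meta()
        t1 = _table_from_trial_means({"X": {"T1": 60, "T2": 30, "T3": 10}},
                                     meta)
        t2 = _table_from_trial_means({"X": {"T1": 600, "T2": 300, "T3": 100}},
                                     meta)
        c1 = commonness(t1, meta, rare_filter=0.0).commonness["X"]
        c2 = commonness(t2, meta, rare_filter=0.0).commonness["X"]
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_single_trial_raises(self):
        meta = _three_trial_meta()
        meta = meta[meta["trial"] == "T1"]
        t = _table_from_trial_means({"X": {"T1": 100}}, meta)
        with pytest.raises(ValueError, match="trials"):
            commonness(t, meta)


class TestRobustness:
    def test_equal_means_ratio_one(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means(
            {"X": {"T1": 50, "T2": 50, "T3": 50}}, meta,
            inoculated_counts={"X": {"T1": 50, "T2": 50, "T3": 50}})
        res = robustness(t, meta, rare_filter=0.0)
        assert np.allclose(res.ratios.loc["X"], 1.0)

    def test_halved_abundance(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means(
            {"X": {"T1": 50, "T2": 50, "T3": 50}}, meta,
            inoculated_counts={"X": {"T1": 25, "T2": 50, "T3": 50}})
        res = robustness(t, meta, rare_filter=0.0)
        assert res.ratios.loc["X", "T1"] == pytest.approx(0.5)

    def test_zero_control_mean_flagged(self):
        meta = _three_trial_meta()
        t = _table_from_trial_means(
            {"X": {"T1": 0, "T2": 50, "T3": 50}}, meta,
            inoculated_counts={"X": {"T1": 10, "T2": 50, "T3": 50}})
        res = robustness(t, meta, rare_filter=0.0)
        assert math.isnan(res.ratios.loc["X", "T1"])
        assert ("X", "T1") in res.undefined

    def test_missing_treatment_raises(self):
        meta = _three_trial_meta()
        meta = meta[~((meta["trial"] == "T2") & meta["inoculated"])]
        t = _table_from_trial_means({"X": {"T1": 5, "T2": 5, "T3": 5}}, meta)
        with pytest.raises(ValueError, match="treatments"):
            robustness(t, meta, rare_filter=0.0)


class TestBrayCurtis:
    def test_identical_samples(self):
        assert bray_curtis([5, 5, 0], [5, 5, 0]) == 1.0

    def test_disjoint_samples(self):
        assert bray_curtis([5, 0], [0, 5]) == 0.0

    def test_hand_example(self):
        assert bray_curtis([6, 4], [4, 6]) == pytest.approx(0.8)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=10),
           st.data())
    def test_symmetry_and_bounds(self, x, data):
        y = data.draw(st.lists(st.integers(0, 1000), min_size=len(x),
                               max_size=len(x)))
        if sum(x) == 0 or sum(y) == 0 or sum(x) + sum(y) == 0:
            return
        s = bray_curtis(x, y)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(bray_curtis(y, x))

    def test_matches_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.diversity")
        rng = np.random.default_rng(9)
        X = rng.integers(0, 200, (6, 8))
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(6)])
        from amfniche.classify import OTUTable
        ours = bray_curtis_matrix(OTUTable(df)).to_numpy()
        theirs = skbio_distance.beta_diversity(
            "braycurtis", X, ids=df.index).data
        assert np.allclose(ours, theirs)


def _oneway_permanova_oracle(D, labels):
    """Independent one-way pseudo-F from the classic sum-of-squares
    identity: SS_total = sum d^2 / n within the whole set, SS_within from
    each group's own pairwise distances."""
    n = len(labels)
    idx = np.arange(n)
    ss_t = (D[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_w = 0.0
    for g in set(labels):
        sel = idx[np.array(labels) == g]
        sub = D[np.ix_(sel, sel)]
        ss_w += (sub[np.triu_indices(len(sel), 1)] ** 2).sum() / len(sel)
    a = len(set(labels))
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    def _toy(self, n=6, seed=3):
        rng = np.random.default_rng(seed)
        X = rng.lognormal(3, 1, (n, 5))
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
        from amfniche.classify import OTUTable
        D = bray_curtis_matrix(OTUTable(df))
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        fac = pd.DataFrame({"g": labels}, index=D.index)
        return D, fac

    def test_pseudo_f_matches_oneway_oracle(self):
        D, fac = self._toy()
        res = permanova(D, fac, terms=("g",), n_perm=99, seed=0)
        f_oracle = _oneway_permanova_oracle(D.to_numpy(), fac["g"].tolist())
        assert res.loc["g", "pseudo_F"] == pytest.approx(f_oracle)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        D, fac = self._toy()
        res = permanova(D, fac, terms=("g",), exhaustive=True)
        Dn = D.to_numpy()
        labels = fac["g"].tolist()
        f_obs = _oneway_permanova_oracle(Dn, labels)
        count = total = 0
        for perm in itertools.permutations(range(len(labels))):
            Dp = Dn[np.ix_(perm, perm)]
            if _oneway_permanova_oracle(Dp, labels) >= f_obs - 1e-12:
                count += 1
            total += 1
        assert res.loc["g", "p"] == pytest.approx(count / total)

    def test_matches_scikit_bio_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        import skbio
        D, fac = self._toy(n=10, seed=8)
        res = permanova(D, fac, terms=("g",), n_perm=99, seed=0)
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=list(D.index))
        ref = skbio_stats.permanova(dm, fac["g"].to_numpy(), permutations=99)
        assert res.loc["g", "pseudo_F"] == pytest.approx(ref["test statistic"])

    def test_deterministic_under_seed(self):
        D, fac = self._toy(n=12, seed=5)
        r1 = permanova(D, fac, terms=("g",), n_perm=199, seed=7)
        r2 = permanova(D, fac, terms=("g",), n_perm=199, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_two_factor_power_on_separated_trials(self):
        rng = np.random.default_rng(12)
        rows, meta = {}, []
        for t, shift in [("T1", 0), ("T2", 4), ("T3", 8)]:
            for i in range(4):
                inoc = i % 2 == 1
                base = np.roll(np.array([100.0, 10, 10, 10, 10, 10]), shift // 4)
                rows[f"{t}_{i}"] = base * 10 + rng.integers(0, 10, 6)
                meta.append({"sample_id": f"{t}_{i}", "trial": t,
                             "inoculated": inoc})
        df = pd.DataFrame(rows).T
        from amfniche.classify import OTUTable
        D = bray_curtis_matrix(OTUTable(df))
        fac = pd.DataFrame(meta).set_index("sample_id")
        res = permanova(D, fac, n_perm=999, seed=0)
        assert res.loc["trial", "p"] <= 0.005

    def test_single_level_factor_raises(self):
        D, fac = self._toy()
        fac["g"] = "same"
        with pytest.raises(ValueError, match="single level"):
            permanova(D, fac, terms=("g",))


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(0)
        rs = [correlate(rng.normal(size=20), rng.normal(size=20))[0]
              for _ in range(500)]
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs))

    def test_log_transform_with_zeros(self):
        x = np.array([0.0, 1.0, 10.0, 100.0])
        r, _ = correlate(x, np.log(x + 0.5), log_x=True)
        assert r == pytest.approx(1.0)

    def test_anti_monotone_negative(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, _ = correlate(x, -x ** 2)
        assert r < 0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestStepwiseLM:
    def test_noiseless_standardized_coefficient_is_one(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"x": x, "y": 3 * x + 1})
        fit = stepwise_lm(df, "y", ["x"], select=False)
        assert fit.std_coefs["x"] == pytest.approx(1.0)

    def test_strong_predictor_retained(self):
        rng = np.random.default_rng(1)
        n = 48
        df = pd.DataFrame(rng.normal(size=(n, 5)),
                          columns=["true", "n1", "n2", "n3", "n4"])
        df["y"] = 2.0 * df["true"] + rng.normal(size=n)
        fit = stepwise_lm(df, "y", ["true", "n1", "n2", "n3", "n4"])
        assert "true" in fit.terms
        assert fit.params["true"] > 0

    def test_aic_never_above_full_or_null(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(30, 4)),
                              columns=list("abcd"))
            df["y"] = rng.normal(size=30)
            fit = stepwise_lm(df, "y", list("abcd"))
            full = stepwise_lm(df, "y", list("abcd"), select=False)
            null = stepwise_lm(df, "y", [], select=False)
            assert fit.aic <= full.aic + 1e-9
            assert fit.aic <= null.aic + 1e-9

    def test_all_noise_modal_model_is_intercept_only(self):
        models = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(48, 4)),
                              columns=list("abcd"))
            df["y"] = rng.normal(size=48)
            fit = stepwise_lm(df, "y", list("abcd"))
            models.append(frozenset(fit.terms))
        counts = pd.Series(models).value_counts()
        assert counts.index[0] == frozenset()

    def test_too_few_observations_raise(self):
        df = pd.DataFrame({"a": [1.0, 2], "b": [2.0, 1], "y": [0.0, 1]})
        with pytest.raises(ValueError):
            stepwise_lm(df, "y", ["a", "b"])


def irls_binomial_glm(y, m, X, tol=1e-12, max_iter=200):
    """Independent iteratively-reweighted-least-squares logistic fit."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        W = m * p * (1 - p)
        z = eta + (y - m * p) / np.maximum(W, 1e-12)
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestLogisticGLMM:
    def _data(self, seed=3, re_sd=0.4):
        rng = np.random.default_rng(seed)
        n = 48
        blocks = np.repeat([f"B{i}" for i in range(12)], 4)
        df = pd.DataFrame({"x1": rng.normal(size=n),
                           "x2": rng.normal(size=n), "block": blocks})
        u = dict(zip(np.unique(blocks), rng.normal(0, re_sd, 12)))
        eta = 0.5 - 1.0 * df.x1 + 0.3 * df.x2 + np.array(
            [u[b] for b in blocks])
        df["succ"] = rng.binomial(500, 1 / (1 + np.exp(-eta)))
        return df

    def test_zero_variance_reduces_to_glm_oracle(self):
        df = self._data()
        fit = logistic_glmm(df, "succ", 500, ["x1", "x2"], group="block",
                            fix_re_sd=0.0)
        X = np.column_stack([np.ones(len(df)), df.x1, df.x2])
        beta = irls_binomial_glm(df.succ.to_numpy(float),
                                 np.full(len(df), 500.0), X)
        assert np.abs(fit.params.to_numpy() - beta).max() < 1e-6

    def test_recovers_coefficients_and_variance(self):
        df = self._data()
        fit = logistic_glmm(df, "succ", 500, ["x1", "x2"], group="block")
        assert fit.converged
        assert fit.params["x1"] == pytest.approx(-1.0, abs=0.15)
        assert 0.05 < fit.re_sd < 0.8
        assert (fit.odds_ratios["x1"]
                == pytest.approx(math.exp(fit.params["x1"])))

    def test_invalid_successes_raise(self):
        df = self._data()
        df.loc[0, "succ"] = 501
        with pytest.raises(ValueError):
            logistic_glmm(df, "succ", 500, ["x1"], group="block")


class TestOddsRatio:
    def test_zero_is_one(self):
        assert odds_ratio(0.0) == 1.0

    def test_ln2_is_two(self):
        assert odds_ratio(math.log(2)) == pytest.approx(2.0)

    def test_infinite_raises(self):
        with pytest.raises(ValueError):
            odds_ratio(float("inf"))
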