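"""Proportional-odds model: prediction identities, fitting, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy.special import expit

import healthimpact as hi


def _simulate_po(rng, X, beta, thresholds):
    """Sample an ordinal outcome under P(Y<=i)=logistic(Z_i - x.beta)."""
    eta = X @ beta
    cum = expit(np.asarray(thresholds)[None, :] - eta[:, None])
    u = rng.random(len(X))[:, None]
    return 1 + (u >= cum).sum(axis=1)


class TestOrdinalModelType:
    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            hi.OrdinalModel(thresholds=[0.0, 0.0, 0.0], coefficients={})

    def test_coefficients_must_match_spec(self):
        with pytest.raises(ValueError, match="match"):
            hi.OrdinalModel(
                thresholds=[-1.0, 1.0],
                coefficients={"a": 1.0},
                covariate_spec=[{"name": "b"}],
            )

    def test_json_yaml_roundtrip(self, pub_model, tmp_path):
        for name in ("m.json", "m.yaml"):
            path = tmp_path / name
            pub_model.save(path)
            back = hi.OrdinalModel.load(path)
            np.testing.assert_allclose(back.thresholds, pub_model.thresholds)
            assert back.coefficients == pub_model.coefficients
            assert back.convention_note == pub_model.convention_note


class TestPrediction:
    def test_symmetric_thresholds_give_uniform_probs(self):
        model = hi.OrdinalModel(
            thresholds=[-1.0986122886681098, 0.0, 1.0986122886681098],
            coefficients={},
        )
        probs = hi.predict_category_probs(model, {})
        np.testing.assert_allclose(probs, [0.25, 0.25, 0.25, 0.25], atol=5e-9)
        assert hi.expected_ordinal(model, {}) == pytest.approx(2.5, abs=1e-8)

    def test_published_model_hand_computation(self, pub_model):
        # healthy young woman: logistic(Z_i - x.beta) evaluated by hand
        rec = {"hii": 0, "mhi": 1.0, "age": 25, "sex": 0}
        probs = hi.predict_category_probs(pub_model, rec)
        cum = np.cumsum(probs)
        assert cum[0] == pytest.approx(0.00058, rel=5e-3)
        assert cum[1] == pytest.approx(0.0275, rel=5e-3)
        assert cum[2] == pytest.approx(0.4465, rel=5e-3)
        assert hi.expected_ordinal(pub_model, rec) == pytest.approx(3.525, abs=2e-3)

    def test_missing_covariate_named(self, pub_model):
        with pytest.raises(ValueError, match="mhi"):
            hi.predict_category_probs(pub_model, {"hii": 0, "age": 25, "sex": 0})

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(min_value=-3, max_value=3),
    )
    def test_probs_sum_to_one_and_nonnegative(self, seed, xval):
        rng = np.random.default_rng(seed)
        thresholds = np.sort(rng.normal(0, 3, size=3))
        if len(np.unique(thresholds)) < 3:
            thresholds = thresholds + np.arange(3) * 1e-6
        model = hi.OrdinalModel(
            thresholds=thresholds, coefficients={"x": float(rng.normal())}
        )
        probs = hi.predict_category_probs(model, {"x": xval})
        assert np.all(probs >= 0)
        assert abs(probs.sum() - 1.0) < 1e-12

    @given(st.integers(0, 2**31 - 1))
    def test_negative_coefficient_monotone_expected(self, seed):
        """Raising a harmful covariate weakly lowers the expected outcome."""
        rng = np.random.default_rng(seed)
        model = hi.OrdinalModel(
            thresholds=np.sort(rng.normal(0, 2, 3)) + np.arange(3) * 1e-6,
            coefficients={"x": -abs(rng.normal())},
        )
        values = [hi.expected_ordinal(model, {"x": v}) for v in (-1, 0, 1, 2)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_expected_ordinal_bounded(self, pub_model):
        for hii in (0, 5, 40):
            e = hi.expected_ordinal(
                pub_model, {"hii": hii, "mhi": 2.0, "age": 60, "sex": 1}
            )
            assert 1.0 <= e <= 4.0


class TestFitPo:
    def test_null_effect_recovery(self):
        rng = np.random.default_rng(42)
        n = 20_000
        x = rng.binomial(1, 0.3, n).astype(float)
        y = _simulate_po(rng, x[:, None], np.array([0.0]), [-1.5, 0.0, 1.5])
        df = pd.DataFrame({"y": y, "x": x})
        rep = hi.fit_po(df, "y", ["x"])
        assert abs(rep.model.coefficients["x"]) < 0.1
        assert rep.lr_p > 0.01

    def test_known_model_recovery_within_ci(self, sim_cohort_20k, pub_model,
                                            pub_weights):
        """Refitting data generated from the published model recovers every
        coefficient within its own 95% CI."""
        rep = hi.fit_hii_model(sim_cohort_20k, pub_weights)
        for name, truth in pub_model.coefficients.items():
            lo, hic = rep.ci95[name]
            assert lo <= truth <= hic, f"{name}: {truth} not in [{lo}, {hic}]"

    def test_local_optimality_against_random_perturbations(self):
        """Brute-force oracle: the fitted optimum beats 1,000 random
        perturbations of norm 0.1 in exact log-likelihood."""
        rng = np.random.default_rng(7)
        n = 200
        X = np.column_stack([rng.normal(size=n), rng.binomial(1, 0.5, n)])
        y = _simulate_po(rng, X, np.array([-0.8, 0.5]), [-1.0, 0.5, 1.5])
        df = pd.DataFrame({"y": y, "x1": X[:, 0], "x2": X[:, 1]})
        rep = hi.fit_po(df, "y", ["x1", "x2"])

        def loglik(beta, thr):
            cum = expit(np.asarray(thr)[None, :] - (X @ beta)[:, None])
            full = np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))])
            p = np.diff(full, axis=1)
            return float(np.log(p[np.arange(n), y - 1]).sum())

        beta_hat = np.array([rep.model.coefficients["x1"],
                             rep.model.coefficients["x2"]])
        thr_hat = rep.model.thresholds
        ll_hat = loglik(beta_hat, thr_hat)
        assert ll_hat == pytest.approx(rep.log_likelihood, abs=1e-6)
        for _ in range(1000):
            d = rng.normal(size=5)
            d *= 0.1 / np.linalg.norm(d)
            thr = np.sort(thr_hat + d[2:])
            assert loglik(beta_hat + d[:2], thr) <= ll_hat + 1e-9

    def test_binary_outcome_matches_logistic(self):
        """K=2 proportional-odds fit equals a plain binary logit."""
        rng = np.random.default_rng(3)
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        eta = 0.8 * x1 - 0.5 * x2
        y = 1 + (rng.random(n) < expit(-0.2 + eta)).astype(float)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        rep = hi.fit_po(df, "y", ["x1", "x2"], allow_binary=True)
        res = sm.Logit((df.y == 2).astype(float),
                       sm.add_constant(df[["x1", "x2"]])).fit(disp=0)
        assert rep.model.coefficients["x1"] == pytest.approx(
            res.params["x1"], abs=1e-6
        )
        assert rep.model.coefficients["x2"] == pytest.approx(
            res.params["x2"], abs=1e-6
        )
        assert rep.model.thresholds[0] == pytest.approx(-res.params["const"],
                                                        abs=1e-6)

    def test_binary_outcome_rejected_by_default(self):
        df = pd.DataFrame({"y": [1, 2, 1, 2] * 10, "x": [0.0, 1.0] * 20})
        with pytest.raises(ValueError, match="binary logit"):
            hi.fit_po(df, "y", ["x"])

    def test_constant_covariate_named(self):
        df = pd.DataFrame({"y": [1, 2, 3, 4] * 10, "x": 1.0})
        with pytest.raises(ValueError, match="'x'"):
            hi.fit_po(df, "y", ["x"])

    def test_bias_shrinks_with_n(self):
        """Mean absolute estimation error over 5 seeds falls with n."""
        truth = np.array([-0.7])
        biases = {}
        for n in (2000, 20_000):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                x = rng.normal(size=n)
                y = _simulate_po(rng, x[:, None], truth, [-1.5, 0.0, 1.5])
                rep = hi.fit_po(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
                errs.append(abs(rep.model.coefficients["x"] - truth[0]))
            biases[n] = np.mean(errs)
        assert biases[20_000] < biases[2000]
        assert biases[20_000] < 0.05

    def test_nagelkerke_zero_under_null_and_bounds(self):
        rng = np.random.default_rng(11)
        n = 3000
        x = rng.normal(size=n)
        y_null = _simulate_po(rng, x[:, None], np.array([0.0]), [-1.0, 0.0, 1.0])
        rep = hi.fit_po(pd.DataFrame({"y": y_null, "x": x}), "y", ["x"])
        assert 0.0 <= rep.nagelkerke_r2 <= 1.0
        assert rep.nagelkerke_r2 < 0.01  # ~0 when the covariate is noise


class TestOddsRatios:
    def test_zero_coefficient_is_or_one(self, pub_model):
        rep = hi.FitReport(
            model=hi.OrdinalModel(thresholds=[-1.0, 1.0],
                                  coefficients={"x": 0.0}),
            log_likelihood=0.0, lr_chi2=0.0, lr_df=1, lr_p=1.0,
            nagelkerke_r2=0.0, n_used=10, se={"x": 1.0},
            ci95={"x": (-1.96, 1.96)},
        )
        out = hi.odds_ratios(rep)
        assert out["x"]["or"] == pytest.approx(1.0)
        lo, hic = out["x"]["ci95"]
        assert lo < 1.0 < hic

    def test_generative_or_three_recovered(self):
        """A condition tripling the cumulative odds of a lower outcome is
        estimated with OR in [2.7, 3.3] at n=20,000."""
        rng = np.random.default_rng(8)
        n = 20_000
        x = rng.binomial(1, 0.2, n).astype(float)
        beta = np.array([-np.log(3.0)])  # harmful: OR of lower outcome = 3
        y = _simulate_po(rng, x[:, None], beta, [-2.0, -0.5, 1.0])
        rep = hi.fit_po(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        or_x = hi.odds_ratios(rep)["x"]["or"]
        assert 2.7 <= or_x <= 3.3

    def test_rare_strong_condition_has_wide_ci(self):
        """~20 cases with a strong harmful effect give a qualitatively wide
        CI (spanning several-fold), unlike common conditions."""
        rng = np.random.default_rng(21)
        n = 5000
        x = np.zeros(n)
        x[rng.choice(n, size=20, replace=False)] = 1.0
        y = _simulate_po(rng, x[:, None], np.array([-3.0]), [-3.0, -1.0, 1.5])
        rep = hi.fit_po(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
        lo, hic = hi.odds_ratios(rep)["x"]["ci95"]
        assert hic / lo > 5.0
        # a common condition with the same data scale is far tighter
        xc = rng.binomial(1, 0.2, n).astype(float)
        yc = _simulate_po(rng, xc[:, None], np.array([-1.0]), [-3.0, -1.0, 1.5])
        repc = hi.fit_po(pd.DataFrame({"y": yc, "x": xc}), "y", ["x"])
        loc_, hic_ = hi.odds_ratios(repc)["x"]["ci95"]
        assert hic_ / loc_ < 2.0


class TestPoAssumptionCheck:
    def test_under_proportional_odds(self):
        """Per-cutpoint ORs are near-constant when the data satisfy PO
        exactly in the fitted covariates (all with prevalence > 5%)."""
        rng = np.random.default_rng(13)
        n = 20_000
        X = np.column_stack(
            [rng.binomial(1, p, n).astype(float) for p in (0.07, 0.12, 0.20, 0.40)]
        )
        beta = np.array([-1.5, -0.8, -0.4, -0.2])
        y = _simulate_po(rng, X, beta, [-3.5, -1.5, 0.5])
        df = pd.DataFrame(X, columns=["c1", "c2", "c3", "c4"])
        df["srh"] = y
        chk = hi.po_assumption_check(df, "srh", ["c1", "c2", "c3", "c4"])
        for cov, ratio in chk.or_ratio.items():
            assert ratio < 1.3, f"{cov}: max/min OR ratio {ratio}"

    def test_detects_threshold_specific_effect(self):
        """A covariate with OR 2 at the first cutpoint and OR 4 at the last
        shows a max/min OR ratio above 1.5."""
        rng = np.random.default_rng(17)
        n = 20_000
        x = rng.binomial(1, 0.3, n).astype(float)
        base_cum = np.array([0.05, 0.30, 0.80])
        odds = base_cum / (1 - base_cum)
        cum0 = np.tile(base_cum, (n, 1))
        cum1 = (odds * np.array([2.0, 2.83, 4.0])) / (
            1 + odds * np.array([2.0, 2.83, 4.0])
        )
        cum = np.where(x[:, None] == 1, cum1, cum0)
        y = 1 + (rng.random(n)[:, None] >= cum).sum(axis=1)
        chk = hi.po_assumption_check(
            pd.DataFrame({"srh": y, "x": x}), "srh", ["x"]
        )
        assert chk.or_ratio["x"] > 1.5

    def test_absent_covariate_named(self, small_cohort):
        with pytest.raises(ValueError, match="ghost"):
            hi.po_assumption_check(small_cohort, "srh", ["ghost"])

    def test_sparse_cutpoint_skipped(self):
        rng = np.random.default_rng(2)
        n = 400
        x = rng.binomial(1, 0.5, n).astype(float)
        # exactly 5 subjects in the lowest category: that cutpoint is skipped
        y = np.concatenate([np.ones(5), rng.integers(2, 5, n - 5)]).astype(float)
        chk = hi.po_assumption_check(pd.DataFrame({"srh": y, "x": x}), "srh", ["x"])
        assert 1.0 in chk.skipped_thresholds
        assert set(chk.per_threshold.columns) == {"Y<=2", "Y<=3"}
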