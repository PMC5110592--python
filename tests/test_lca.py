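import numpy as np
import pandas as pd
import pytest

from aqstruct import lca
from aqstruct import synthetic_data as sd
from aqstruct._rng import substream


def _two_class_items(n=5000, seed=2):
    prof = sd.load_six_class_profiles()
    probs = np.vstack([prof["item_probs"][3], prof["item_probs"][5]])
    spec = sd.PopulationSpec(
        structure="taxonic", n=n, class_weights=(0.85, 0.15),
        class_item_probs=probs, seed=seed,
    )
    items, labels = sd.generate_taxonic_items(spec)
    return items, labels, probs


class TestFitLca:
    def test_one_class_closed_form(self):
        rng = substream(1, 0)
        items = pd.DataFrame(
            rng.integers(0, 2, size=(200, 12)).astype(float),
            columns=[f"item_{i}" for i in range(1, 13)],
        )
        fit = lca.fit_lca(items, 1)
        p = np.clip(items.mean(axis=0).to_numpy(), 1e-4, 1 - 1e-4)
        np.testing.assert_allclose(fit.item_probs[0], p, atol=1e-12)
        counts = items.sum(axis=0).to_numpy()
        n = len(items)
        expected_ll = float(np.sum(counts * np.log(p) + (n - counts) * np.log(1 - p)))
        assert fit.loglik == pytest.approx(expected_ll, abs=1e-8)

    def test_two_class_parameter_recovery(self):
        items, labels, probs = _two_class_items()
        fit = lca.fit_lca(items, 2, n_starts=5, seed=0)
        assert fit.weights[1] == pytest.approx(0.15, abs=0.02)
        assert np.sqrt(np.mean((fit.item_probs - probs) ** 2)) < 0.05

    def test_loglik_matches_percase_oracle(self):
        items, _, _ = _two_class_items(n=500)
        fit = lca.fit_lca(items, 2, n_starts=3, seed=0)
        x = items.to_numpy(float)[:60]
        oracle = 0.0
        for row in x:
            mix = 0.0
            for w, p in zip(fit.weights, fit.item_probs):
                mix += w * np.prod(np.where(row == 1, p, 1 - p))
            oracle += np.log(mix)
        assert lca.lca_loglik(items.iloc[:60], fit.weights, fit.item_probs) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_em_trace_monotone(self):
        items, _, _ = _two_class_items(n=1000)
        fit = lca.fit_lca(items, 3, n_starts=3, seed=1)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_posterior_rows_sum_to_one(self):
        items, _, _ = _two_class_items(n=800)
        fit = lca.fit_lca(items, 2, n_starts=3, seed=1)
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(fit.assignment, fit.posterior.argmax(axis=1))

    def test_label_permutation_leaves_loglik_unchanged(self):
        items, _, _ = _two_class_items(n=600)
        fit = lca.fit_lca(items, 3, n_starts=3, seed=2)
        perm = [2, 0, 1]
        ll = lca.lca_loglik(items, fit.weights[perm], fit.item_probs[perm])
        assert ll == pytest.approx(fit.loglik, abs=1e-8)

    def test_classes_ordered_by_expected_total(self):
        items, _, _ = _two_class_items(n=800)
        fit = lca.fit_lca(items, 3, n_starts=3, seed=3)
        totals = fit.item_probs.sum(axis=1)
        assert np.all(np.diff(totals) >= 0)

    def test_excess_classes_warn(self):
        items = pd.DataFrame(np.tile([[0, 1], [1, 0]], (10, 1)), columns=["item_1", "item_2"])
        with pytest.warns(RuntimeWarning, match="response patterns"):
            lca.fit_lca(items.astype(float), 3, n_starts=2, seed=0, max_iter=50)

    def test_invalid_k(self):
        items, _, _ = _two_class_items(n=100)
        with pytest.raises(ValueError, match=">= 1"):
            lca.fit_lca(items, 0)


class TestFitIndices:
    def _fake_fit(self, posterior, loglik=-100.0, n_params=5):
        k = posterior.shape[1]
        return lca.MixtureFit(
            n_classes=k, weights=np.full(k, 1 / k), item_probs=np.full((k, 3), 0.5),
            loglik=loglik, n_params=n_params, posterior=posterior,
            assignment=posterior.argmax(axis=1), converged=True, n_starts=1,
            loglik_trace=np.array([loglik]),
        )

    def test_information_criteria_arithmetic(self):
        fit = self._fake_fit(np.ones((100, 2)) / 2)
        idx = lca.fit_indices(fit, 100)
        assert idx.aic == pytest.approx(210.0)
        assert idx.bic == pytest.approx(200 + 5 * np.log(100))
        assert idx.ssabic == pytest.approx(200 + 5 * np.log(102 / 24))

    def test_entropy_degenerate_is_one(self):
        post = np.zeros((50, 3))
        post[np.arange(50), np.arange(50) % 3] = 1.0
        assert lca.fit_indices(self._fake_fit(post), 50).entropy == pytest.approx(1.0)

    def test_entropy_uniform_is_zero(self):
        post = np.full((50, 4), 0.25)
        assert lca.fit_indices(self._fake_fit(post), 50).entropy == pytest.approx(0.0)

    def test_one_class_entropy_defined(self):
        post = np.ones((30, 1))
        assert lca.fit_indices(self._fake_fit(post), 30).entropy == 1.0


class TestBlrt:
    def test_zero_reps_rejected(self):
        items, _, _ = _two_class_items(n=100)
        with pytest.raises(ValueError, match="reps"):
            lca.blrt(items, 2, reps=0)

    def test_k_below_two_rejected(self):
        items, _, _ = _two_class_items(n=100)
        with pytest.raises(ValueError, match="K >= 2"):
            lca.blrt(items, 1)

    def test_separated_classes_reach_minimum_p(self):
        """On strongly 2-class data the K=2 vs 1 BLRT attains the smallest
        attainable p-value, 1/(reps+1)."""
        items, _, _ = _two_class_items(n=1000, seed=5)
        res = lca.blrt(items, 2, reps=19, seed=0, n_starts=3)
        assert res["p_value"] == pytest.approx(1 / 20)
        assert res["statistic"] > 0


class TestBivariateResiduals:
    def test_duplicated_items_flagged_under_one_class(self):
        rng = substream(9, 0)
        base = rng.integers(0, 2, size=500).astype(float)
        items = pd.DataFrame({"item_1": base, "item_2": base, "item_3": rng.integers(0, 2, 500)})
        fit = lca.fit_lca(items, 1)
        table = lca.bivariate_residuals(fit, items)
        dup = table[(table.item_a == "item_1") & (table.item_b == "item_2")]
        assert bool(dup.flagged.iloc[0])

    def test_expected_counts_conserve_n_and_match_enumeration(self):
        items, _, _ = _two_class_items(n=400)
        fit = lca.fit_lca(items, 2, n_starts=3, seed=0)
        table = lca.bivariate_residuals(fit, items)
        esum = table[["e_11", "e_10", "e_01", "e_00"]].sum(axis=1)
        np.testing.assert_allclose(esum, 400.0, atol=1e-6)
        # brute-force enumeration over classes for one pair
        row = table.iloc[0]
        a = items.columns.get_loc(row.item_a)
        b = items.columns.get_loc(row.item_b)
        e11 = 400 * sum(
            w * fit.item_probs[k, a] * fit.item_probs[k, b]
            for k, w in enumerate(fit.weights)
        )
        assert row.e_11 == pytest.approx(e11, abs=1e-8)

    def test_calibration_under_true_model(self):
        """Data simulated from a correctly specified model flags few cells.

        Residuals use model-estimated expected counts, so they are
        conservative relative to unit normal (fitting absorbs variation);
        the point of the check is type-I control, not exact 5% coverage.
        """
        rng = substream(10, 0)
        weights = np.array([0.6, 0.4])
        probs = np.vstack([rng.uniform(0.1, 0.4, 10), rng.uniform(0.6, 0.9, 10)])
        items = lca.simulate_lca(weights, probs, 10_000, rng)
        fit = lca.fit_lca(items, 2, n_starts=3, seed=0)
        table = lca.bivariate_residuals(fit, items)
        cells = table[["res_11", "res_10", "res_01", "res_00"]].to_numpy().ravel()
        assert np.mean(np.abs(cells) > 1.96) <= 0.05


class TestClassSummaries:
    def test_single_class(self):
        items, _, _ = _two_class_items(n=300)
        fit = lca.fit_lca(items, 1)
        totals = items.sum(axis=1)
        summary = lca.class_summaries(fit, totals)
        assert summary.share.iloc[0] == 1.0
        assert summary.mean_total.iloc[0] == pytest.approx(totals.mean())

    def test_shares_match_counting_oracle(self):
        items, _, _ = _two_class_items(n=2000)
        fit = lca.fit_lca(items, 2, n_starts=3, seed=0)
        totals = items.sum(axis=1)
        summary = lca.class_summaries(fit, totals)
        for k in range(2):
            assert summary.share.iloc[k] == pytest.approx(
                np.mean(fit.assignment == k)
            )
        assert summary.share.sum() == pytest.approx(1.0)

    def test_six_class_severe_group_mean(self, six_class_items):
        """The most severe class's mean total is near its analytic expectation."""
        items, _ = six_class_items
        fit = lca.fit_lca(items, 6, n_starts=4, seed=0)
        totals = items.sum(axis=1)
        summary = lca.class_summaries(fit, totals)
        expected = sd.load_six_class_profiles()["expected_totals"].max()
        assert summary.mean_total.iloc[-1] == pytest.approx(expected, abs=1.0)


class TestCovariateRegression:
    def test_two_class_matches_binary_logit(self):
        import statsmodels.api as sm

        rng = substream(11, 0)
        n = 2000
        x = rng.integers(0, 2, n)
        logit_p = -0.5 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit_p))).astype(int)
        out = lca.class_covariate_regression(y, x, reference_class=0)
        ref = sm.Logit(y, sm.add_constant(x.astype(float))).fit(disp=False)
        row = out["table"][out["table"]["class"] == 2].iloc[0]
        assert row.log_odds == pytest.approx(ref.params[1], abs=1e-6)
        assert row.se == pytest.approx(ref.bse[1], abs=1e-6)

    def test_reference_class_log_odds_zero(self):
        rng = substream(12, 0)
        y = rng.integers(0, 3, 1500)
        x = rng.integers(0, 2, 1500)
        out = lca.class_covariate_regression(y, x, reference_class=1)
        ref_row = out["table"][out["table"]["class"] == 2].iloc[0]
        assert ref_row.log_odds == 0.0

    def test_null_covariate_has_tiny_r2(self):
        rng = substream(13, 0)
        y = rng.integers(0, 4, 10_000)
        x = rng.integers(0, 2, 10_000)
        out = lca.class_covariate_regression(y, x)
        assert out["mcfadden_r2"] < 0.005
        assert out["g2_p"] > 0.001

    def test_nonbinary_covariate_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            lca.class_covariate_regression(np.array([0, 1] * 10), np.arange(20))


def test_lmr_stub_raises():
    with pytest.raises(NotImplementedError):
        lca.lmr_test()


def test_fit_json_roundtrip():
    import json

    items, _, _ = _two_class_items(n=300)
    fit = lca.fit_lca(items, 2, n_starts=3, seed=0)
    parsed = json.loads(fit.to_json())
    np.testing.assert_allclose(parsed["weights"], fit.weights)
    assert parsed["loglik"] == fit.loglik
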