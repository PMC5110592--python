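import numpy as np
import pandas as pd
import pytest

from aqstruct import indicators as ind
from aqstruct import synthetic_data as sd
from aqstruct._rng import substream


class TestPrincipalAxisEFA:
    def test_one_factor_recovery(self):
        """Loadings estimated from probit one-factor items track the
        generating loading pattern."""
        lam = np.linspace(0.3, 0.9, 12)
        spec = sd.PopulationSpec(
            structure="dimensional", n=10_000, n_items=12,
            loadings=lam, thresholds=np.zeros(12), seed=3,
        )
        items, _ = sd.generate_dimensional_items(spec)
        sol = ind.principal_axis_efa(items, 1)
        est = sol.loadings.iloc[:, 0].to_numpy()
        assert np.corrcoef(est, lam)[0, 1] > 0.95

    def test_independent_items_have_tiny_communalities(self):
        items = pd.DataFrame(
            substream(1, 0).integers(0, 2, size=(20_000, 8)).astype(float),
            columns=[f"item_{i}" for i in range(1, 9)],
        )
        sol = ind.principal_axis_efa(items, 2)
        assert sol.communalities.max() < 0.05

    def test_varimax_is_a_fixed_point(self, three_factor_items):
        items, _ = three_factor_items
        sol = ind.principal_axis_efa(items, 3)
        lam = sol.loadings.to_numpy()
        again = ind.varimax(lam)
        assert abs(ind._varimax_criterion(again) - ind._varimax_criterion(lam)) < 1e-8

    def test_varimax_preserves_communalities_and_orthogonality(self, three_factor_items):
        items, _ = three_factor_items
        unrot = ind.principal_axis_efa(items, 3, rotation="none")
        rot = ind.principal_axis_efa(items, 3, rotation="varimax")
        np.testing.assert_allclose(
            unrot.communalities.to_numpy(), rot.communalities.to_numpy(), atol=1e-8
        )
        # rotated = unrotated @ T with T orthonormal
        t, *_ = np.linalg.lstsq(unrot.loadings.to_numpy(), rot.loadings.to_numpy(), rcond=None)
        np.testing.assert_allclose(t.T @ t, np.eye(3), atol=1e-6)

    def test_block_structure_recovered(self, three_factor_items):
        items, true_loadings = three_factor_items
        sol = ind.principal_axis_efa(items, 3)
        # each item's dominant estimated factor matches its generating block
        est_block = sol.loadings.abs().to_numpy().argmax(axis=1)
        true_block = true_loadings.argmax(axis=1)
        # factor order is arbitrary: require a consistent relabeling
        mapping = {}
        for f in range(3):
            vals, counts = np.unique(est_block[true_block == f], return_counts=True)
            mapping[f] = vals[counts.argmax()]
        assert len(set(mapping.values())) == 3
        assert (np.array([mapping[b] for b in true_block]) == est_block).mean() > 0.9

    def test_too_many_factors_rejected(self, three_factor_items):
        items, _ = three_factor_items
        with pytest.raises(ValueError, match="smaller"):
            ind.principal_axis_efa(items, items.shape[1])


class TestRetention:
    def test_pure_noise_keeps_at_most_one_factor(self):
        for seed in range(3):
            items = pd.DataFrame(
                substream(seed, 2).integers(0, 2, size=(1000, 10)).astype(float),
                columns=[f"item_{i}" for i in range(1, 11)],
            )
            out = ind.factor_retention_suite(items, max_factors=5, seed=seed)
            assert out["parallel_analysis"] <= 1
            assert out["velicer_map"] <= 1

    def test_three_strong_factors_recovered(self, three_factor_items):
        items, _ = three_factor_items
        out = ind.factor_retention_suite(items, max_factors=6, seed=0)
        assert out["parallel_analysis"] == 3
        assert out["velicer_map"] == 3
        assert out["kaiser"] >= 3
        assert out["bic"] >= 3

    def test_few_replicates_warns(self, three_factor_items):
        items, _ = three_factor_items
        with pytest.warns(RuntimeWarning, match="replicates"):
            ind.factor_retention_suite(items.iloc[:200], max_factors=3, n_parallel=5)


class TestComposites:
    def _solution(self, loadings, items_cols):
        lam = pd.DataFrame(
            loadings, index=items_cols,
            columns=[f"F{k+1}" for k in range(loadings.shape[1])],
        )
        return ind.FactorSolution(
            loadings=lam,
            communalities=(lam**2).sum(axis=1),
            variance_explained=(lam**2).sum(axis=0),
            rotation="varimax",
            n_iter=1,
        )

    def test_single_positive_factor_gives_plain_sum(self):
        cols = [f"item_{i}" for i in range(1, 5)]
        items = pd.DataFrame(
            substream(4, 0).integers(0, 2, size=(30, 4)), columns=cols
        )
        sol = self._solution(np.full((4, 1), 0.6), cols)
        comp, info = ind.build_composite_indicators(sol, items, {"ind_1": ["F1"]})
        np.testing.assert_array_equal(comp["ind_1"].to_numpy(), items.sum(axis=1).to_numpy())
        assert info["excluded_items"] == []

    def test_negative_loading_subtracts(self):
        cols = ["item_1", "item_2", "item_30"]
        items = pd.DataFrame([[0, 0, 1]], columns=cols)
        sol = self._solution(np.array([[0.5], [0.5], [-0.4]]), cols)
        comp, _ = ind.build_composite_indicators(sol, items, {"ind_1": ["F1"]})
        assert comp["ind_1"].iloc[0] == -1

    def test_matches_bruteforce_recomputation(self):
        rng = substream(6, 0)
        cols = [f"item_{i}" for i in range(1, 13)]
        items = pd.DataFrame(rng.integers(0, 2, size=(100, 12)), columns=cols)
        lam = rng.uniform(-0.8, 0.8, size=(12, 3))
        sol = self._solution(lam, cols)
        plan = {"c1": ["F1", "F3"], "c2": ["F2"]}
        comp, info = ind.build_composite_indicators(sol, items, plan, threshold=0.2)
        # independent oracle: recompute assignments and sums cell by cell
        for name, factors in plan.items():
            expected = np.zeros(100)
            for j, col in enumerate(cols):
                best = np.argmax(np.abs(lam[j]))
                if abs(lam[j, best]) > 0.2 and f"F{best+1}" in factors:
                    expected += np.sign(lam[j, best]) * items[col].to_numpy()
            np.testing.assert_array_equal(comp[name].to_numpy(), expected)

    def test_item_order_invariance(self):
        rng = substream(7, 0)
        cols = [f"item_{i}" for i in range(1, 9)]
        items = pd.DataFrame(rng.integers(0, 2, size=(50, 8)), columns=cols)
        lam = rng.uniform(0.3, 0.9, size=(8, 2))
        sol = self._solution(lam, cols)
        plan = {"c1": ["F1"], "c2": ["F2"]}
        comp1, _ = ind.build_composite_indicators(sol, items, plan)
        shuffled = list(reversed(cols))
        sol2 = self._solution(lam[::-1], shuffled)
        comp2, _ = ind.build_composite_indicators(sol2, items[shuffled], plan)
        pd.testing.assert_frame_equal(comp1, comp2)

    def test_empty_composite_rejected(self):
        cols = ["item_1", "item_2"]
        items = pd.DataFrame([[1, 0]], columns=cols)
        sol = self._solution(np.array([[0.5, 0.0], [0.5, 0.0]]), cols)
        with pytest.raises(ValueError, match="no items"):
            ind.build_composite_indicators(sol, items, {"c": ["F2"]})

    def test_packaged_item_map_subtraction(self):
        """The packaged map subtracts item 30 from indicator 2."""
        cols = [f"item_{i}" for i in range(1, 51)]
        items = pd.DataFrame(np.zeros((1, 50), dtype=int), columns=cols)
        items.loc[0, "item_30"] = 1
        comp = ind.composites_from_item_map(items)
        assert comp["ind_2"].iloc[0] == -1
        assert comp.drop(columns="ind_2").iloc[0].eq(0).all()

    def test_packaged_map_covers_43_items(self):
        imap = ind.load_indicator_item_map()
        assigned = [abs(i) for lst in imap["indicators"].values() for i in lst]
        assert len(assigned) == 43 and len(set(assigned)) == 43
        assert len(imap["excluded"]) == 7
        assert sorted(assigned + imap["excluded"]) == list(range(1, 51))


class TestSerialization:
    def test_factor_solution_csv_roundtrip(self, three_factor_items, tmp_path):
        items, _ = three_factor_items
        sol = ind.principal_axis_efa(items, 3)
        path = tmp_path / "loadings.csv"
        sol.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(
            back[["F1", "F2", "F3"]].to_numpy(), sol.loadings.to_numpy(), atol=1e-12
        )

    def test_validity_report_json(self):
        import json

        spec = sd.PopulationSpec(structure="taxonic", n=2000, seed=1)
        x, labels = sd.generate_continuous_indicators(spec)
        report = ind.indicator_validity(x, labels.astype(bool))
        parsed = json.loads(report.to_json())
        assert parsed["passed"] == report.passed
        assert set(parsed["flags"]) == set(report.flags)


class TestValidity:
    def test_identical_means_fail_separation(self):
        rng = substream(8, 0)
        x = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        member = np.arange(200) < 100
        report = ind.indicator_validity(x, member, min_n=100)
        assert np.abs(report.cohens_d).max() < 0.5
        assert not report.flags["separation"]

    def test_d_matches_hand_computed_pooled_sd(self):
        a = np.array([0.0, 1.0, -1.0, 0.5, -0.5] * 20)
        b = a + 1.5
        x = pd.DataFrame({"ind": np.concatenate([a, b])})
        member = np.arange(200) >= 100
        report = ind.indicator_validity(x, member, min_n=10)
        sp = np.sqrt((99 * a.var(ddof=1) + 99 * b.var(ddof=1)) / 198)
        assert report.cohens_d["ind"] == pytest.approx(1.5 / sp)

    def test_synthetic_targets_recovered(self):
        spec = sd.PopulationSpec(
            structure="taxonic", n=20_000, class_weights=(0.85, 0.15),
            target_d=2.0, within_class_r=0.2, seed=9,
        )
        x, labels = sd.generate_continuous_indicators(spec)
        report = ind.indicator_validity(x, labels.astype(bool))
        assert np.abs(report.cohens_d - 2.0).max() < 0.1
        assert abs(report.mean_r_taxon - 0.2) < 0.1
        assert report.passed

    def test_tiny_group_rejected(self):
        x = pd.DataFrame({"a": np.arange(10.0)})
        member = np.zeros(10, dtype=bool)
        member[0] = True
        with pytest.raises(ValueError, match="at least 2"):
            ind.indicator_validity(x, member)

    def test_flags_are_pure_threshold_functions(self):
        rng = substream(10, 0)
        spec = sd.PopulationSpec(structure="taxonic", n=2000, seed=2)
        x, labels = sd.generate_continuous_indicators(spec)
        for _ in range(20):
            dt = rng.uniform(0.5, 3.0)
            rt = rng.uniform(0.05, 0.6)
            report = ind.indicator_validity(
                x, labels.astype(bool), d_threshold=dt, r_threshold=rt
            )
            assert report.flags["separation"] == bool(np.all(np.abs(report.cohens_d) > dt))
            assert report.flags["nuisance_covariance"] == (
                report.mean_r_taxon < rt and report.mean_r_complement < rt
            )
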