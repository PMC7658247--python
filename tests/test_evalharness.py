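import itertools

import numpy as np
import pytest
import scipy.stats

from ddgstack import (
    CVScheme,
    StackSpec,
    apply_leakage_firewall,
    compare_methods,
    cv_evaluate_gpr,
    cv_evaluate_precomputed,
    detect_firewall_violations,
    make_folds,
    nested_cv_evaluate_rfr,
    pearson_r,
    predictor_correlation_matrix,
    select_features_by_importance,
    sem,
    verify_cv_hygiene,
    wilcoxon_signed_rank,
)
from ddgstack.errors import (
    DegenerateDataError,
    FirewallError,
    PairingError,
    TableValidationError,
    UndefinedCorrelationError,
)
from ddgstack.evalharness import averaged_gini_importance

from conftest import build_table


class TestMakeFolds:
    def test_balanced_partition_n8_k4(self):
        folds = make_folds(8, 4, seed=0)
        sizes = np.bincount(folds.labels, minlength=4)
        assert sizes.tolist() == [2, 2, 2, 2]
        assert sorted(np.concatenate([folds.indices(f) for f in range(4)])) == list(range(8))

    def test_balance_rule_n10_k4(self):
        sizes = np.bincount(make_folds(10, 4, seed=1).labels, minlength=4)
        assert sorted(sizes.tolist()) == [2, 2, 3, 3]

    def test_deterministic_given_seed(self):
        assert make_folds(20, 4, 7).labels.tolist() == make_folds(20, 4, 7).labels.tolist()
        assert make_folds(20, 4, 7).labels.tolist() != make_folds(20, 4, 8).labels.tolist()

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(TableValidationError):
            make_folds(3, 4, 0)


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            assert pearson_r(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-12
            )

    def test_affine_invariance_and_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 12))
        r = pearson_r(x, y)
        assert pearson_r(3.5 * x + 2, y) == pytest.approx(r, abs=1e-12)
        assert pearson_r(-x, y) == pytest.approx(-r, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        from ddgstack.errors import SchemaError

        with pytest.raises(SchemaError):
            pearson_r([1, 2, 3], [1, 2])


class TestSem:
    def test_constant_values(self):
        assert sem([3, 3, 3, 3]) == 0.0

    def test_formula_oracle(self):
        assert sem([1, 2, 3, 4, 5]) == pytest.approx(np.sqrt(0.5), abs=1e-12)
        rng = np.random.default_rng(2)
        v = rng.normal(size=30)
        assert sem(v) == pytest.approx(scipy.stats.sem(v), abs=1e-12)

    def test_homogeneity(self):
        v = [1.0, 4.0, 2.5, 0.5]
        assert sem([-3 * x for x in v]) == pytest.approx(3 * sem(v), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(TableValidationError):
            sem([1.0])


def brute_force_wilcoxon(d):
    """Exhaustive two-sided signed-rank p over all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_all_positive_n6(self):
        a = np.arange(1.0, 7.0)
        w, p = wilcoxon_signed_rank(a + [1, 2, 3, 1, 2, 3], a)
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_uniform_shift_same_p(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        _, p = wilcoxon_signed_rank(a + 2.0, a)
        assert p == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 8))
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(brute_force_wilcoxon(a - b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_handles_midranks(self, seed):
        rng = np.random.default_rng(seed + 100)
        d = rng.integers(-4, 5, size=9).astype(float)  # many tied |d|, some zeros
        if np.all(d == 0):
            d[0] = 1.0
        _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 12))
        w, p = wilcoxon_signed_rank(a, b, method="exact")
        res = scipy.stats.wilcoxon(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(res.pvalue, abs=1e-12)

    @pytest.mark.parametrize("n", [15, 20, 25])
    def test_exact_and_approx_branches_agree(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            a, b = rng.normal(size=(2, n))
            _, p_exact = wilcoxon_signed_rank(a, b, method="exact")
            _, p_approx = wilcoxon_signed_rank(a, b, method="approx")
            assert abs(p_exact - p_approx) <= 0.01

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


def perfect_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    ddg = rng.gamma(2.0, 1.2, size=n) - 0.65
    return build_table(ddg[:, None], ddg, seed=seed, predictor_names=["perfect"])


class TestCvEvaluate:
    def test_gpr_with_perfect_feature(self):
        res = cv_evaluate_gpr(
            perfect_table(), scheme=CVScheme(n_repeats=2, master_seed=0)
        )
        assert res.mean_r >= 0.999
        assert res.per_repeat_r.shape == (2,)

    def test_gpr_is_deterministic(self):
        scheme = CVScheme(n_repeats=2, master_seed=5)
        r1 = cv_evaluate_gpr(perfect_table(seed=1), scheme=scheme)
        r2 = cv_evaluate_gpr(perfect_table(seed=1), scheme=scheme)
        assert r1.per_repeat_r.tolist() == r2.per_repeat_r.tolist()

    def test_result_invariants(self):
        res = cv_evaluate_gpr(
            perfect_table(seed=2), scheme=CVScheme(n_repeats=3, master_seed=1)
        )
        assert res.mean_r == pytest.approx(res.per_repeat_r.mean())
        assert res.sem_r == pytest.approx(sem(res.per_repeat_r))

    def test_precomputed_shares_folds_with_gpr(self):
        table = perfect_table(seed=3)
        scheme = CVScheme(n_repeats=3, master_seed=9)
        a = cv_evaluate_gpr(table, scheme=scheme)
        b = cv_evaluate_precomputed(table, table.column("perfect"), "raw", scheme)
        for la, lb in zip(a.audit["fold_labels"], b.audit["fold_labels"]):
            assert la.tolist() == lb.tolist()

    def test_nested_rfr_with_perfect_feature_and_clean_audit(self):
        table = perfect_table(n=48, seed=4)
        spec = StackSpec(model_kind="rfr", rfr_tree_grid=(8, 32))
        res = nested_cv_evaluate_rfr(table, spec=spec,
                                     scheme=CVScheme(n_repeats=2, master_seed=0))
        assert res.mean_r >= 0.95
        assert verify_cv_hygiene(res)
        # every outer fold recorded a selected tree count from the grid
        for per_fold in res.audit["selected_n_trees"]:
            assert all(t in (8, 32) for t in per_fold)

    def test_nested_rfr_prefers_larger_forest_when_it_wins(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 1))
        y = X[:, 0] + 0.7 * rng.normal(size=60)
        table = build_table(X, y)
        spec = StackSpec(model_kind="rfr", rfr_tree_grid=(1, 128))
        res = nested_cv_evaluate_rfr(
            table, spec=spec, scheme=CVScheme(n_repeats=6, master_seed=0)
        )
        chosen = np.concatenate(res.audit["selected_n_trees"])
        assert (chosen == 128).mean() > 0.5


class TestFirewall:
    def make_flagged(self, n_flags, with_subs=True):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(6, 2))
        table = build_table(scores, rng.normal(size=6), firewall=("P1",))
        ids = table.record_ids
        flags = {(ids[i], "P1") for i in range(n_flags)}
        table.firewall_flags = flags
        if with_subs:
            table.firewall_substitutes = {k: 99.0 + i for i, k in enumerate(sorted(flags))}
        return table

    def test_no_flags_is_identity(self):
        table = self.make_flagged(0)
        out = apply_leakage_firewall(table)
        np.testing.assert_array_equal(out.scores, table.scores)

    def test_exactly_flagged_cells_change(self):
        table = self.make_flagged(3)
        out = apply_leakage_firewall(table)
        diff = out.scores != table.scores
        assert diff.sum() == 3
        assert set(zip(np.array(table.record_ids)[diff[:, 1]], ["P1"] * 3)) == table.firewall_flags
        for (rid, pname), val in table.firewall_substitutes.items():
            i = table.record_ids.index(rid)
            assert out.scores[i, 1] == val

    def test_missing_substitute_raises_listing_cells(self):
        table = self.make_flagged(2, with_subs=False)
        with pytest.raises(FirewallError) as err:
            apply_leakage_firewall(table)
        assert set(err.value.offending) == table.firewall_flags
        assert set(detect_firewall_violations(table)) == table.firewall_flags


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self, random_table):
        m = predictor_correlation_matrix(random_table(n=10, p=4, seed=6))
        np.testing.assert_allclose(np.diag(m.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)

    def test_identical_columns_correlate_perfectly(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=8)
        table = build_table(np.column_stack([col, col]), rng.normal(size=8))
        m = predictor_correlation_matrix(table)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_rejected(self):
        table = build_table(
            np.column_stack([np.ones(5), np.arange(5.0)]), np.arange(5.0)
        )
        with pytest.raises(UndefinedCorrelationError, match="P0"):
            predictor_correlation_matrix(table)


class TestSelectFeatures:
    IMP = {"a": 0.30, "b": 0.25, "c": 0.20, "d": 0.15, "e": 0.05, "f": 0.05}

    def test_threshold_mode(self):
        assert select_features_by_importance(self.IMP, "threshold", 0.1) == [
            "a", "b", "c", "d",
        ]

    def test_top_k_all_returns_sorted(self):
        assert select_features_by_importance(self.IMP, "top_k", 6) == [
            "a", "b", "c", "d", "e", "f",
        ]

    def test_ties_broken_by_insertion_order(self):
        out = select_features_by_importance(self.IMP, "top_k", 6)
        assert out.index("e") < out.index("f")  # equal importances, registry order

    def test_top_k_too_large_rejected(self):
        with pytest.raises(TableValidationError):
            select_features_by_importance(self.IMP, "top_k", 7)

    def test_negative_importance_rejected(self):
        with pytest.raises(TableValidationError):
            select_features_by_importance({"a": -0.1}, "top_k", 1)


class TestTrainTestEvaluate:
    def test_perfect_feature_scores_unity_on_train_as_test(self):
        from ddgstack import train_test_evaluate

        table = perfect_table(n=40, seed=0)
        assert train_test_evaluate(table, table, ["perfect"]) >= 0.999

    def test_missing_predictor_in_test_table_rejected(self):
        from ddgstack import train_test_evaluate
        from ddgstack.errors import SchemaError

        train = perfect_table(n=40, seed=0)
        rng = np.random.default_rng(1)
        test = build_table(rng.normal(size=(10, 1)), rng.normal(size=10),
                           predictor_names=["other"])
        with pytest.raises(SchemaError, match="perfect"):
            train_test_evaluate(train, test, ["perfect"])

    def test_stack_usually_beats_train_selected_single_on_independent_data(self):
        # scaled-down mirror of the independent-data benchmark protocol:
        # train n=212, test n=34 from the same generative process
        from ddgstack import (
            SIPMAB_INFORMATIVE,
            StackSpec,
            generate_feature_table,
            sipmab_like_config,
            train_test_evaluate,
        )

        wins = 0
        for i in range(10):
            train = generate_feature_table(sipmab_like_config(seed=300 + i))
            test = generate_feature_table(sipmab_like_config(seed=400 + i, n_records=34))
            r_stack = train_test_evaluate(
                train, test, list(SIPMAB_INFORMATIVE), StackSpec(model_kind="gpr", seed=i)
            )
            best = max(
                train.predictor_names,
                key=lambda nm: pearson_r(train.column(nm), train.ddg_exp),
            )
            wins += r_stack > pearson_r(test.column(best), test.ddg_exp)
        assert wins >= 6


class TestCompareMethods:
    def make_results(self, n=3, repeats=10, seed=0):
        table = perfect_table(n=40, seed=seed)
        scheme = CVScheme(n_repeats=repeats, master_seed=seed)
        rng = np.random.default_rng(seed)
        return [
            cv_evaluate_precomputed(
                table, table.ddg_exp + 0.3 * (i + 1) * rng.normal(size=40),
                f"m{i}", scheme,
            )
            for i in range(n)
        ]

    def test_row_counts(self):
        results = self.make_results(3)
        df = compare_methods(results)
        assert (df.row_type == "method").sum() == 3
        assert (df.row_type == "comparison").sum() == 3  # C(3,2)

    def test_self_comparison_reported_as_identical(self):
        res = self.make_results(1)[0]
        df = compare_methods([res, res])
        row = df[df.row_type == "comparison"].iloc[0]
        assert row.note == "identical"
        assert np.isnan(row.p_value)

    def test_unpaired_results_rejected(self):
        a = self.make_results(1, repeats=10)[0]
        b = self.make_results(1, repeats=12)[0]
        with pytest.raises(PairingError):
            compare_methods([a, b])

    def test_dominant_method_gets_tiny_p(self):
        a, b = self.make_results(2, repeats=30)
        # m0 has less noise than m1, so should win nearly every repeat
        df = compare_methods([a, b])
        row = df[df.row_type == "comparison"].iloc[0]
        assert a.mean_r > b.mean_r
        assert row.p_value < 1e-4


class TestAveragedImportance:
    def test_sums_to_one_and_preserves_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = X[:, 1] + 0.5 * rng.normal(size=60)
        table = build_table(X, y)
        imp = averaged_gini_importance(
            table, scheme=CVScheme(n_repeats=2, master_seed=0), n_trees=32
        )
        assert list(imp) == ["P0", "P1", "P2"]
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert max(imp, key=imp.get) == "P1"
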