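"""Directional gene-set tests: ranks, enrichment tests, global Q, rotations."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mirset import (
    ExpressionMatrix,
    GroupDesign,
    SetTestContext,
    ValidationError,
    available_set_tests,
    get_set_test,
    global_q_test_subset,
    rank_by_direction,
    register_set_test,
    split_set_by_direction,
    run_feature_tests,
)
from mirset.settest import (
    RotationContext,
    fisher_exact_enrichment,
    ks_one_sided,
    wilcoxon_one_sided,
)
from conftest import make_null_data


def make_ctx(rng, p=40, n_per_group=4, shift_rows=(), shift=0.0, n_rot=199, n_perm=199):
    x, design = make_null_data(rng, p=p, n_per_group=n_per_group)
    vals = x.values.copy()
    for r in shift_rows:
        vals[r, n_per_group:] += shift
    x = ExpressionMatrix(vals, x.feature_ids, x.sample_ids)
    stats_ = run_feature_tests(x, design)
    return SetTestContext(
        mrna=x, design=design, mrna_stats=stats_,
        rng=rng, n_rot=n_rot, n_perm=n_perm, tau=0.05,
    ), x, design


class TestRanks:
    def test_ranks_follow_p_values(self, rng):
        ctx, x, _ = make_ctx(rng)
        ranks = rank_by_direction(ctx.mrna_stats)
        order_up = np.argsort(ctx.mrna_stats.p_up, kind="stable")
        assert ranks.rank_up[order_up[0]] == 1
        assert sorted(ranks.rank_up) == list(range(1, x.n_features + 1))
        assert sorted(ranks.rank_down) == list(range(1, x.n_features + 1))

    def test_up_down_ranks_sum_without_ties(self, rng):
        ctx, x, _ = make_ctx(rng)
        ranks = rank_by_direction(ctx.mrna_stats)
        p = x.n_features
        np.testing.assert_allclose(ranks.rank_up + ranks.rank_down, p + 1)

    def test_tie_break_by_feature_id(self):
        from mirset.feature import FeatureStats

        ids = ["gB", "gA", "gC"]
        pv = np.array([0.2, 0.2, 0.9])
        st_ = FeatureStats(
            feature_ids=ids, diff=np.zeros(3), s_sq=np.ones(3),
            s_tilde_sq=np.ones(3), t_mod=np.zeros(3), df_total=4,
            p_two=pv, p_up=pv, p_down=1 - pv,
        )
        ranks = rank_by_direction(st_)
        # tie between gA and gB resolved alphabetically: gA first
        assert ranks.rank_up[ids.index("gA")] == 1
        assert ranks.rank_up[ids.index("gB")] == 2


class TestKs:
    def test_whole_universe_gives_one(self):
        assert ks_one_sided(np.arange(1, 11), p=10) == pytest.approx(1.0)

    def test_hand_computed_small_case(self):
        # members at ranks {1, 3} of 10: u = (0.1, 0.3);
        # D+ = max(0.5 - 0.1, 1.0 - 0.3) = 0.7
        d_plus = 0.7
        expected = math.exp(-2 * 2 * d_plus**2)
        assert ks_one_sided(np.array([1, 3]), p=10) == pytest.approx(expected)

    def test_top_ranks_give_small_p(self):
        m, p = 10, 1000
        got = ks_one_sided(np.arange(1, m + 1), p)
        assert got == pytest.approx(math.exp(-2 * m * (1 - m / p) ** 2), rel=1e-6)
        assert got < 1e-7


class TestWilcoxon:
    def test_average_ranks_give_half(self):
        # ranks {1, 6} of p=6: W = 7 = m(p+1)/2
        assert wilcoxon_one_sided(np.array([1, 6]), p=6) == pytest.approx(0.5)

    def test_hand_computed_and_enumeration_oracle(self):
        member = np.array([1, 2, 3])
        p = 10
        z = (6 - 3 * 11 / 2) / math.sqrt(3 * 7 * 11 / 12)
        assert wilcoxon_one_sided(member, p) == pytest.approx(stats.norm.cdf(z))
        # exact null: enumerate all rank triples; the normal approximation
        # must agree with the exact tail probability to ~0.02
        exact = np.mean([
            sum(c) <= 6 for c in itertools.combinations(range(1, p + 1), 3)
        ])
        assert abs(wilcoxon_one_sided(member, p) - exact) < 0.02

    def test_directional_p_sum_to_one(self, rng):
        ctx, x, _ = make_ctx(rng)
        func, _ = get_set_test("wilcoxon")
        members = frozenset(np.asarray(x.feature_ids)[[3, 7, 11, 20]])
        res = func(ctx, members, "m")
        assert res.p_set_up + res.p_set_down == pytest.approx(1.0)
        assert res.complementary

    def test_whole_universe_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            wilcoxon_one_sided(np.arange(1, 11), p=10)


class TestFisherExact:
    def test_no_de_calls_give_one(self):
        calls = np.zeros(100, dtype=bool)
        in_set = np.zeros(100, dtype=bool)
        in_set[:10] = True
        assert fisher_exact_enrichment(calls, in_set) == 1.0

    def test_hypergeometric_tail_oracle(self):
        # in-set: 3 DE of 10; out-set: 2 DE of 90
        calls = np.zeros(100, dtype=bool)
        in_set = np.zeros(100, dtype=bool)
        in_set[:10] = True
        calls[:3] = True
        calls[10:12] = True
        # enumeration over the hypergeometric support
        big_k, m, p = 5, 10, 100
        pmf = [
            math.comb(m, k) * math.comb(p - m, big_k - k) / math.comb(p, big_k)
            for k in range(0, min(m, big_k) + 1)
        ]
        expected = sum(pmf[3:])
        assert fisher_exact_enrichment(calls, in_set) == pytest.approx(expected)

    def test_perfect_separation_point_mass(self):
        calls = np.zeros(20, dtype=bool)
        in_set = np.zeros(20, dtype=bool)
        in_set[:5] = True
        calls[:5] = True
        assert fisher_exact_enrichment(calls, in_set) == pytest.approx(
            1 / math.comb(20, 5)
        )


class TestSplitByDirection:
    def test_all_up_leaves_down_empty(self, rng):
        x, design = make_null_data(rng, p=5, n_per_group=3)
        vals = x.values.copy()
        vals[:, 3:] += 10
        x = ExpressionMatrix(vals, x.feature_ids, x.sample_ids)
        up, down = split_set_by_direction(x, design, set(x.feature_ids))
        assert down == frozenset() and up == frozenset(x.feature_ids)

    def test_matches_mean_comparison_oracle(self, toy_matrix, toy_design):
        up, down = split_set_by_direction(toy_matrix, toy_design, {"gA", "gB", "gC"})
        ind = toy_design.indicator(toy_matrix.sample_ids) == 1
        for i, g in enumerate(toy_matrix.feature_ids):
            m2 = toy_matrix.values[i, ind].mean()
            m1 = toy_matrix.values[i, ~ind].mean()
            assert (g in up) == (m2 > m1)
            assert (g in down) == (m2 < m1)

    def test_exact_tie_joins_neither(self):
        vals = np.array([[1.0, 2.0, 2.0, 1.0]])
        x = ExpressionMatrix(vals, ["g"], ["s1", "s2", "s3", "s4"])
        design = GroupDesign({"s1": 1, "s2": 1, "s3": 2, "s4": 2})
        up, down = split_set_by_direction(x, design, {"g"})
        assert up == frozenset() and down == frozenset()


class TestGlobalQ:
    def test_zero_matrix_gives_p_one(self, rng):
        x = ExpressionMatrix(np.zeros((3, 8)), list("abc"), [f"s{j}" for j in range(8)])
        design = GroupDesign({f"s{j}": (1 if j < 4 else 2) for j in range(8)})
        p = global_q_test_subset(x, design, {"a", "b"}, n_perm=99, rng=rng)
        assert p == 1.0

    def test_two_gene_quadratic_form_oracle(self, rng):
        x, design = make_null_data(rng, p=2, n_per_group=3)
        y = design.indicator(x.sample_ids)
        resid = y - y.mean()
        xm = x.values.T - x.values.T.mean(axis=0)
        q_hand = float(sum((xm[:, j] @ resid) ** 2 for j in range(2)))
        from mirset.settest import global_q_statistic

        assert global_q_statistic(xm, y) == pytest.approx(q_hand)

    def test_permutation_floor(self, rng):
        x, design = make_null_data(rng, p=4, n_per_group=4)
        vals = x.values.copy()
        vals[:, 4:] += 50.0  # overwhelming group effect
        x = ExpressionMatrix(vals, x.feature_ids, x.sample_ids)
        p = global_q_test_subset(x, design, set(x.feature_ids), n_perm=99, rng=rng)
        # a permutation that reproduces the exact grouping recreates Q_obs,
        # so the smallest attainable p can be a few multiples of the floor
        assert p <= 5 / 100

    def test_empty_subset_warns_and_returns_one(self, rng):
        x, design = make_null_data(rng, p=3, n_per_group=3)
        assert global_q_test_subset(x, design, set(), n_perm=99, rng=rng) == 1.0


class TestRotationTests:
    def test_roast_floor_under_strong_shift(self, rng):
        ctx, x, _ = make_ctx(rng, shift_rows=range(8), shift=25.0, n_rot=199)
        func, _ = get_set_test("roast")
        members = frozenset(np.asarray(x.feature_ids)[:8])
        res = func(ctx, members, "m")
        assert res.p_set_up == pytest.approx(1 / 200)

    def test_romer_floor_and_complementarity(self, rng):
        # heteroscedastic noise keeps the variance prior finite; with an
        # infinite d0 the rotated scores of strongly shifted genes saturate
        # the rank extremes and the competitive test loses power by design
        x, design = make_null_data(rng, p=40, n_per_group=4)
        vals = x.values * rng.lognormal(0, 0.6, size=(40, 1))
        vals[:5, 4:] += 25.0
        x = ExpressionMatrix(vals, x.feature_ids, x.sample_ids)
        stats_ = run_feature_tests(x, design)
        ctx = SetTestContext(
            mrna=x, design=design, mrna_stats=stats_,
            rng=rng, n_rot=199, n_perm=199, tau=0.05,
        )
        func, _ = get_set_test("romer")
        members = frozenset(np.asarray(x.feature_ids)[:5])
        res = func(ctx, members, "m")
        # no exact floor: a rotation with a large contrast component carries
        # the whole shifted block back to the top ranks, so p_up stays a few
        # rotation counts above 1/(B+1)
        assert res.p_set_up <= 0.10
        assert res.p_set_down >= 0.90
        # each rotation counts on at least one side and the observed value
        # on both, so the directional p-values sum to >= 1 + 1/(B+1), with
        # equality only in the absence of ties
        assert res.p_set_up + res.p_set_down >= 1 + 1 / 200 - 1e-12

    def test_roast_null_p_uniform(self, rng):
        """Over independent null replicates roast's directional p is ~uniform."""
        pvals = []
        for _ in range(400):
            ctx, x, _ = make_ctx(rng, p=12, n_per_group=3, n_rot=99)
            func, _ = get_set_test("roast")
            members = frozenset(np.asarray(x.feature_ids)[:4])
            pvals.append(func(ctx, members, "m").p_set_up)
        # p is supported on {1/100, ..., 1}; compare against the discrete null
        grid = np.arange(1, 101) / 100
        ecdf = np.searchsorted(np.sort(pvals), grid, side="right") / len(pvals)
        assert np.max(np.abs(ecdf - grid)) < 0.08

    def test_romer_null_p_uniform_for_random_subset(self, rng):
        pvals = []
        for _ in range(300):
            ctx, x, _ = make_ctx(rng, p=30, n_per_group=3, n_rot=99)
            func, _ = get_set_test("romer")
            idx = rng.choice(30, size=6, replace=False)
            members = frozenset(np.asarray(x.feature_ids)[idx])
            pvals.append(func(ctx, members, "m").p_set_up)
        grid = np.arange(1, 101) / 100
        ecdf = np.searchsorted(np.sort(pvals), grid, side="right") / len(pvals)
        assert np.max(np.abs(ecdf - grid)) < 0.10

    def test_romer_invariant_to_global_shift(self, rng):
        """A shift common to ALL genes leaves the competitive p moderate."""
        ctx, x, _ = make_ctx(rng, p=40, shift_rows=range(40), shift=8.0, n_rot=399)
        func, _ = get_set_test("romer")
        members = frozenset(np.asarray(x.feature_ids)[:10])
        res = func(ctx, members, "m")
        assert 0.01 < res.p_set_up < 0.99

    def test_rotation_reproducible_with_fixed_seed(self):
        results = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            ctx, x, _ = make_ctx(rng, n_rot=199)
            func, _ = get_set_test("romer")
            members = frozenset(np.asarray(x.feature_ids)[:6])
            r = func(ctx, members, "m")
            results.append((r.p_set_up, r.p_set_down))
        assert results[0] == results[1]

    def test_small_set_rejected(self, rng):
        ctx, x, _ = make_ctx(rng)
        for name in ("roast", "romer"):
            func, _ = get_set_test(name)
            with pytest.raises(ValidationError):
                func(ctx, frozenset([x.feature_ids[0]]), "m")


class TestInvariancesAndRegistry:
    def test_rank_tests_depend_only_on_ranks(self, rng):
        """Perturbing p-values without changing their order leaves KS,
        Wilcoxon and Fisher-exact results unchanged."""
        ctx, x, design = make_ctx(rng)
        members = frozenset(np.asarray(x.feature_ids)[[2, 9, 17]])
        st1 = ctx.mrna_stats
        import copy

        # rank-preserving, call-preserving perturbation: scale all p slightly
        st2 = copy.deepcopy(st1)
        st2.p_up = st1.p_up * 0.999
        st2.p_down = st1.p_down * 0.999
        ctx2 = SetTestContext(
            mrna=x, design=design, mrna_stats=st2,
            rng=np.random.default_rng(0), n_rot=99, n_perm=99, tau=0.05,
        )
        for name in ("ks", "wilcoxon", "fisher_exact"):
            func, _ = get_set_test(name)
            r1, r2 = func(ctx, members, "m"), func(ctx2, members, "m")
            assert r1.p_set_up == pytest.approx(r2.p_set_up)
            assert r1.p_set_down == pytest.approx(r2.p_set_down)

    def test_invariant_to_gene_relabeling(self, rng):
        ctx, x, design = make_ctx(rng, p=20)
        members_idx = [1, 4, 9, 13]
        new_ids = [f"zz{i:03d}" for i in range(20)]  # preserves relative order
        x2 = ExpressionMatrix(x.values.copy(), new_ids, x.sample_ids)
        st2 = run_feature_tests(x2, design)
        ctx2 = SetTestContext(
            mrna=x2, design=design, mrna_stats=st2,
            rng=np.random.default_rng(0), n_rot=99, n_perm=99, tau=0.05,
        )
        for name in ("ks", "wilcoxon", "fisher_exact"):
            func, _ = get_set_test(name)
            r1 = func(ctx, frozenset(np.asarray(x.feature_ids)[members_idx]), "m")
            r2 = func(ctx2, frozenset(np.asarray(new_ids)[members_idx]), "m")
            assert r1.p_set_up == pytest.approx(r2.p_set_up)

    def test_registry_round_trip(self):
        from mirset.settest import SetTestResult

        def dummy(ctx, members, mirna_id):
            return SetTestResult(mirna_id, "dummy", 0.5, 0.5, len(members), True)

        register_set_test("dummy", dummy, complementary=True)
        try:
            func, comp = get_set_test("dummy")
            assert comp and func is dummy
            assert "dummy" in available_set_tests()
        finally:
            from mirset.settest import _REGISTRY

            _REGISTRY.pop("dummy", None)

    def test_unknown_test_rejected(self):
        with pytest.raises(ValidationError, match="unknown set test"):
            get_set_test("nope")
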