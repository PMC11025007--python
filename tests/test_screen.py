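import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paralogsl import (
    OmicsMatrix,
    ParalogPair,
    ParalogScreen,
    ScreenConfig,
    ScreenRecord,
    SyntheticConfig,
    ValidationError,
    adjust_bh,
    generate_panel,
    pearson_with_p,
    rank_and_flag,
    screen_paralog_pairs,
)


def pearson_bruteforce(x, y):
    """Independent oracle: raw-sum Pearson formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(
        (n * np.sum(x * x) - np.sum(x) ** 2) * (n * np.sum(y * y) - np.sum(y) ** 2)
    )
    return num / den


def bh_bruteforce(p):
    """Independent oracle: literal step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    raw = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPearson:
    def test_five_point_worked_example(self):
        r, p, n = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert n == 5

    def test_perfect_correlation_p_at_minimum(self):
        r, p, n = pearson_with_p([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r == 1.0
        assert p == np.finfo(float).tiny

    def test_constant_vector_is_degenerate(self):
        r, p, n = pearson_with_p([1, 2, 3, 4], [5, 5, 5, 5])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_complete_pairs_degenerate(self):
        r, p, n = pearson_with_p([1, 2, np.nan], [1, 2, 3])
        assert n == 2 and np.isnan(r)

    def test_pairwise_deletion(self):
        x = np.array([1, 2, 3, 4, np.nan, 6.0])
        y = np.array([2, 1, 4, 3, 5, np.nan])
        r, p, n = pearson_with_p(x, y)
        assert n == 4
        assert r == pytest.approx(pearson_bruteforce(x[:4], y[:4]), abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 60)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p, _ = pearson_with_p(x, y)
            assert r == pytest.approx(pearson_bruteforce(x, y), abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=53)
        y = 0.4 * x + rng.normal(size=53)
        r, p, _ = pearson_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_permutation_p_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        a = pearson_with_p(x, y, p_method="permutation", n_permutations=500, rng_seed=9)
        b = pearson_with_p(x, y, p_method="permutation", n_permutations=500, rng_seed=9)
        assert a == b
        assert 1 / 501 <= a.p <= 1.0

    def test_unknown_p_method_rejected(self):
        with pytest.raises(ValidationError):
            pearson_with_p([1, 2, 3], [1, 2, 3], p_method="bootstrap")


class TestAdjustBH:
    def test_worked_example_uniform_spacing(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_worked_example_running_minimum(self):
        q = adjust_bh([0.005, 0.04, 0.04])
        assert np.allclose(q, [0.015, 0.04, 0.04])

    def test_missing_passes_through_and_excluded_from_m(self):
        q = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        # m = 2, not 3
        assert np.allclose([q[0], q[2]], [0.02, 0.02])

    def test_out_of_range_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(ValidationError):
                adjust_bh(bad)

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=50,
        )
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_properties_against_oracle(self, ps):
        q = adjust_bh(ps)
        assert np.allclose(q, bh_bruteforce(ps), atol=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)
        # invariance under reordering (up to the same reordering)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ps))
        q_perm = adjust_bh(np.asarray(ps)[perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)


class TestRankAndFlag:
    def _rec(self, fam, r, q, status="scored"):
        return ScreenRecord(
            family_id=fam, dep_gene=fam + "B", expr_gene=fam + "A",
            n_samples=53, pearson_r=r, p_value=abs(r) / 10 if status == "scored" else np.nan,
            q_value=q, status=status,
        )

    def test_ranking_and_single_hit(self):
        recs = [self._rec("f1", 0.9, 0.001), self._rec("f2", 0.5, 0.2),
                self._rec("f3", -0.3, 0.5)]
        out = rank_and_flag(recs, q_threshold=0.05)
        assert [r.rank for r in out] == [1, 2, 3]
        assert [r.is_hit for r in out] == [True, False, False]

    def test_negative_r_never_hit_by_default(self):
        recs = [self._rec("f1", -0.9, 0.0001)]
        assert not rank_and_flag(recs)[0].is_hit
        assert rank_and_flag(recs, require_positive_r=False)[0].is_hit

    def test_degenerate_records_unranked(self):
        recs = [self._rec("f1", 0.5, 0.01), self._rec("f2", np.nan, np.nan, "degenerate")]
        out = rank_and_flag(recs)
        ranks = {r.family_id: r.rank for r in out}
        assert ranks == {"f1": 1, "f2": None}

    def test_empty_in_empty_out(self):
        assert rank_and_flag([]) == []

    def test_ranks_are_gapless_permutation(self):
        rng = np.random.default_rng(2)
        recs = [self._rec(f"f{i}", float(rng.uniform(-1, 1)), 0.5) for i in range(20)]
        out = rank_and_flag(recs)
        assert sorted(r.rank for r in out) == list(range(1, 21))
        rs = [r.pearson_r for r in sorted(out, key=lambda r: r.rank)]
        assert rs == sorted(rs, reverse=True)


def _panel_matrices(genes, samples, dep_vals, expr_vals):
    dep = OmicsMatrix("gene_effect", "Chronos",
                      pd.DataFrame(dep_vals, index=genes, columns=samples))
    expr = OmicsMatrix("expression", "log2(TPM+1)",
                       pd.DataFrame(expr_vals, index=genes, columns=samples))
    return dep, expr


class TestScreen:
    def test_implanted_pair_ranks_first(self):
        panel = generate_panel(SyntheticConfig(rng_seed=7, n_sl_families=1))
        recs = screen_paralog_pairs(panel.gene_effect, panel.expression, panel.pairs)
        fam = panel.truth.sl_families[0]
        top = recs[0]
        assert top.rank == 1
        assert (top.dep_gene, top.expr_gene) == (fam.partner_gene, fam.silenced_gene)

    def test_missing_gene_yields_flagged_record(self, panel7):
        pairs = list(panel7.pairs[:5]) + [ParalogPair("fx", "F0000A", "GHOST", 80.0)]
        recs = screen_paralog_pairs(panel7.gene_effect, panel7.expression, pairs)
        ghost = [r for r in recs if r.expr_gene == "GHOST" or r.dep_gene == "GHOST"]
        assert ghost and all(r.status == "missing_gene" for r in ghost)
        assert all(np.isnan(r.pearson_r) for r in ghost)

    def test_sample_permutation_invariance(self, panel7):
        rng = np.random.default_rng(0)
        perm = rng.permutation(panel7.gene_effect.sample_ids).tolist()
        dep_p = panel7.gene_effect.select_samples(perm)
        expr_p = panel7.expression.select_samples(perm)
        base = screen_paralog_pairs(panel7.gene_effect, panel7.expression, panel7.pairs[:20])
        permuted = screen_paralog_pairs(dep_p, expr_p, panel7.pairs[:20])
        r0 = {(r.dep_gene, r.expr_gene): r.pearson_r for r in base}
        r1 = {(r.dep_gene, r.expr_gene): r.pearson_r for r in permuted}
        for key in r0:
            assert r1[key] == pytest.approx(r0[key], abs=1e-12)

    def test_directions_switch(self, panel7):
        both = screen_paralog_pairs(panel7.gene_effect, panel7.expression, panel7.pairs[:10])
        one = screen_paralog_pairs(
            panel7.gene_effect, panel7.expression, panel7.pairs[:10],
            ScreenConfig(directions="a_dep_b_expr"),
        )
        assert len(both) == 20 and len(one) == 10
        assert all(r.dep_gene.endswith("A") for r in one)

    def test_empty_pairs_empty_records(self, panel7):
        assert screen_paralog_pairs(panel7.gene_effect, panel7.expression, []) == []

    def test_all_degenerate_errors(self):
        genes = ["fA", "fB"]
        samples = [f"s{i}" for i in range(12)]
        dep, expr = _panel_matrices(
            genes, samples,
            np.zeros((2, 12)),  # constant Chronos rows: degenerate
            np.random.default_rng(0).normal(size=(2, 12)),
        )
        with pytest.raises(ValidationError, match="no scorable"):
            screen_paralog_pairs(dep, expr, [ParalogPair("f", "fA", "fB", 80.0)])

    def test_kind_validation(self, panel7):
        with pytest.raises(ValidationError, match="gene_effect"):
            screen_paralog_pairs(panel7.expression, panel7.expression, panel7.pairs[:2])

    def test_estimator_params_roundtrip(self):
        est = ParalogScreen(q_threshold=0.1, min_samples=12)
        params = est.get_params()
        assert params["q_threshold"] == 0.1
        clone = ParalogScreen().set_params(**params)
        assert clone.get_params() == params
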