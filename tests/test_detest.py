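import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, nbinom, poisson, ttest_ind

from magtx.detest import (
    PSEUDO_MEAN,
    _exact_p_one,
    bh_adjust,
    consensus_de,
    de_pipeline,
    estimate_dispersions,
    exact_test_nb,
    glm_wald_nb,
    make_contrast,
    moderated_t_log,
)
from magtx.types import Contrast, ValidationError

C33 = Contrast(group_a=("a0", "a1", "a2"), group_b=("b0", "b1", "b2"))


def frame(rows, n=3):
    cols = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
    return pd.DataFrame(rows, columns=cols)


class TestDispersion:
    def test_poisson_like_data_gives_zero(self):
        # v = m in both groups -> phi_g = 0 everywhere, median 0, shrunk 0
        m = 100.0
        d = np.sqrt(m)  # values m-d, m, m+d have sample variance d^2 = m
        rows = [[m - d, m, m + d, m - d, m, m + d]] * 20
        df = frame(rows)
        phi = estimate_dispersions(df, C33)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_moment_formula_matches_hand_value(self):
        # mean 100, var 1100 in both groups -> phi_g = (1100-100)/100^2 = 0.1
        d = np.sqrt(1100.0)
        row = [100 - d, 100.0, 100 + d, 100 - d, 100.0, 100 + d]
        df = frame([row] * 50)  # identical genes -> median = phi_g -> no shrink shift
        phi = estimate_dispersions(df, C33)
        np.testing.assert_allclose(phi, 0.1, rtol=1e-9)

    def test_recovers_simulated_dispersion(self, make_two_group):
        rng = np.random.default_rng(77)
        df, _ = make_two_group(rng, 2000, 10, mean=500, phi=0.2)
        contrast = Contrast(group_a=tuple(f"a{i}" for i in range(10)),
                            group_b=tuple(f"b{i}" for i in range(10)))
        phi = estimate_dispersions(df, contrast)
        assert 0.15 <= float(np.median(phi)) <= 0.25

    def test_single_sample_group_rejected(self):
        df = pd.DataFrame([[1, 2, 3]], columns=["a0", "a1", "b0"])
        with pytest.raises(ValidationError):
            estimate_dispersions(
                df, Contrast(group_a=("a0", "a1"), group_b=("b0", "b1"))
            )


def brute_force_exact_p(s_a, s_b, n_a, n_b, phi):
    """Direct enumeration over every split of T = s_a + s_b."""
    T = s_a + s_b
    if T == 0:
        return 1.0
    mu = T / (n_a + n_b)

    def pmf(k, n, mean):
        if phi == 0:
            return poisson.pmf(k, mean)
        r = n / phi
        return nbinom.pmf(k, r, r / (r + mean))

    probs = np.array([pmf(k, n_a, n_a * mu) * pmf(T - k, n_b, n_b * mu)
                      for k in range(T + 1)])
    obs = probs[s_a]
    return min(1.0, probs[probs <= obs * (1 + 1e-12)].sum() / probs.sum())


class TestExactTest:
    def test_identical_group_sums_give_p_one(self):
        df = frame([[5, 6, 7, 7, 6, 5]])
        res = exact_test_nb(df, C33, pd.Series(0.1, index=df.index))
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_all_zero_gene_is_degenerate(self):
        df = frame([[0, 0, 0, 0, 0, 0]])
        res = exact_test_nb(df, C33, pd.Series(0.1, index=df.index))
        assert res["p"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.3])
    def test_matches_enumeration_oracle_small_totals(self, phi):
        rng = np.random.default_rng(123)
        disp = pd.Series([phi], index=["g"])
        for _ in range(40):
            T = int(rng.integers(1, 51))
            s_a = int(rng.integers(0, T + 1))
            row = np.zeros(6)
            row[0], row[3] = s_a, T - s_a
            df = frame([row])
            df.index = ["g"]
            p_impl = exact_test_nb(df, C33, disp)["p"].iloc[0]
            p_oracle = brute_force_exact_p(s_a, T - s_a, 3, 3, phi)
            assert abs(p_impl - p_oracle) < 1e-10

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        df = frame(rng.integers(0, 300, (30, 6)))
        disp = pd.Series(0.1, index=df.index)
        swapped = Contrast(group_a=C33.group_b, group_b=C33.group_a)
        r1 = exact_test_nb(df, C33, disp)
        r2 = exact_test_nb(df, swapped, disp)
        np.testing.assert_allclose(r1["p"], r2["p"], rtol=1e-12)
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], rtol=1e-12)

    def test_laplace_branch_agrees_with_enumeration(self):
        """Near the enumeration limit the two branches agree to a few %."""
        import magtx.detest as dt

        for frac, phi in [(0.53, 0.05), (0.6, 0.2), (0.55, 0.0)]:
            T = 9000
            s_a = T * frac
            p_enum = _exact_p_one(s_a, T - s_a, 3, 3, phi)
            old = dt.EXACT_ENUMERATION_LIMIT
            try:
                dt.EXACT_ENUMERATION_LIMIT = 0
                p_lap = _exact_p_one(s_a, T - s_a, 3, 3, phi)
            finally:
                dt.EXACT_ENUMERATION_LIMIT = old
            if p_enum < 0.9:
                assert p_lap == pytest.approx(p_enum, rel=0.1)


class TestWald:
    def test_equal_means_give_p_one(self):
        df = frame([[10, 10, 10, 10, 10, 10]])
        res = glm_wald_nb(df, C33, pd.Series(0.1, index=df.index))
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_huge_dispersion_kills_significance(self):
        df = frame([[1000, 1100, 900, 10, 12, 8]])
        p_small = glm_wald_nb(df, C33, pd.Series(0.01, index=df.index))["p"].iloc[0]
        p_huge = glm_wald_nb(df, C33, pd.Series(1e6, index=df.index))["p"].iloc[0]
        assert p_small < 0.01
        assert p_huge > 0.99

    def test_power_at_fourfold_change(self, make_two_group):
        rng = np.random.default_rng(9)
        df, n_de = make_two_group(rng, 500, 50, mean=200, phi=0.05,
                                  de_frac=1.0, log2fc=2.0)
        contrast = Contrast(group_a=tuple(f"a{i}" for i in range(50)),
                            group_b=tuple(f"b{i}" for i in range(50)))
        phi = estimate_dispersions(df, contrast)
        res = glm_wald_nb(df, contrast, phi)
        assert (res["p"] < 0.01).mean() >= 0.95

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(15)
        df = frame(rng.integers(0, 500, (40, 6)))
        disp = pd.Series(0.05, index=df.index)
        swapped = Contrast(group_a=C33.group_b, group_b=C33.group_a)
        r1 = glm_wald_nb(df, C33, disp)
        r2 = glm_wald_nb(df, swapped, disp)
        np.testing.assert_allclose(r1["p"], r2["p"], rtol=1e-12)
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], rtol=1e-12)


class TestModeratedT:
    def test_identical_groups_give_p_one(self):
        df = frame([[4, 8, 6, 4, 8, 6]] * 10)
        res = moderated_t_log(df, C33)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_d0_zero_equals_ordinary_t(self):
        rng = np.random.default_rng(3)
        df = frame(rng.integers(1, 400, (50, 6)))
        res = moderated_t_log(df, C33, d0=0.0)
        y = np.log2(df.to_numpy() + 0.5)
        t_ref = ttest_ind(y[:, :3], y[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res["p"], t_ref.pvalue, rtol=1e-9)

    def test_null_pvalues_uniform(self, make_two_group):
        rng = np.random.default_rng(44)
        df, _ = make_two_group(rng, 2000, 3, mean=300, phi=0.1)
        res = moderated_t_log(df, C33)
        ks = kstest(res["p"], "uniform").statistic
        assert ks < 0.05


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.42]), [0.42])

    def test_matches_step_up_definition_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 1000))
            # oracle: direct step-up formula with cumulative minimum
            m = len(p)
            order = np.argsort(p)
            adj = p[order] * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=50),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_permutation(self, ps, rnd):
        p = np.array(ps)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        direct = bh_adjust(p)
        permuted = bh_adjust(p[perm])
        np.testing.assert_allclose(permuted, direct[perm], rtol=1e-12)


class TestConsensus:
    @pytest.mark.parametrize(
        "padj,expected",
        [
            ((0.005, 0.5, 0.009), True),
            ((0.005, 0.5, 0.5), False),
            ((0.009, 0.009, 0.009), True),
        ],
    )
    def test_two_of_three_rule(self, padj, expected):
        table = pd.DataFrame(
            {"log2fc": [0.01], "padj_exact": [padj[0]],
             "padj_glm": [padj[1]], "padj_modt": [padj[2]]}
        )
        out = consensus_de(table, alpha=0.01, min_methods=2)
        assert bool(out["consensus"].iloc[0]) is expected

    def test_no_fold_change_restriction(self):
        # tiny fold change, three significant methods: still consensus
        table = pd.DataFrame(
            {"log2fc": [0.01], "padj_exact": [0.009],
             "padj_glm": [0.009], "padj_modt": [0.009]}
        )
        assert bool(consensus_de(table)["consensus"].iloc[0])

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError):
            consensus_de(pd.DataFrame({"padj_exact": [0.1]}))


class TestDePipeline:
    def test_consensus_subset_of_union(self, make_two_group):
        rng = np.random.default_rng(8)
        df, _ = make_two_group(rng, 400, 3, mean=200, phi=0.05,
                               de_frac=0.1, log2fc=2.0)
        from magtx.simulate import simulate_design

        sheet = simulate_design(3)
        table = de_pipeline(df, sheet, C33)
        union = (table[["padj_exact", "padj_glm", "padj_modt"]] < 0.01).any(axis=1)
        assert (table["consensus"] <= union).all()

    def test_direction_labels_follow_sign(self, make_two_group):
        rng = np.random.default_rng(10)
        df, n_de = make_two_group(rng, 300, 3, mean=300, phi=0.02,
                                  de_frac=0.2, log2fc=3.0)
        from magtx.simulate import simulate_design

        table = de_pipeline(df, simulate_design(3), C33)
        hits = table[table["consensus"]]
        assert len(hits) > 0
        assert (hits.loc[hits["log2fc"] > 0, "direction"] == "up_a").all()
        assert (hits.loc[hits["log2fc"] < 0, "direction"] == "up_b").all()

    def test_label_permutation_stays_null(self, make_two_group):
        """Mixing group labels of a null dataset yields ~no consensus calls."""
        rng = np.random.default_rng(12)
        df, _ = make_two_group(rng, 500, 3, mean=200, phi=0.05)
        from magtx.simulate import simulate_design

        sheet = simulate_design(3)
        mixed = Contrast(group_a=("a0", "b1", "a2"), group_b=("b0", "a1", "b2"))
        table = de_pipeline(df, sheet, mixed)
        assert table["consensus"].sum() <= 0.01 * len(table) * 3

    def test_padj_never_below_p(self, make_two_group):
        rng = np.random.default_rng(13)
        df, _ = make_two_group(rng, 200, 3, mean=100, phi=0.1)
        from magtx.simulate import simulate_design

        table = de_pipeline(df, simulate_design(3), C33)
        for m in ("exact", "glm", "modt"):
            assert (table[f"padj_{m}"] >= table[f"p_{m}"] - 1e-15).all()


def test_make_contrast_groups_by_phase_and_condition():
    from magtx.simulate import simulate_design

    sheet = simulate_design(3)
    c = make_contrast(sheet, "feeding")
    assert set(c.group_a) == {"LP_F_c1", "LP_F_c2", "LP_F_c3"}
    assert set(c.group_b) == {"HP_F_c1", "HP_F_c2", "HP_F_c3"}
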