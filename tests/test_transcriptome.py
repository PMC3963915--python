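import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_matrix
from cordmediate.transcriptome import (
    FLAG_NAMES,
    SchemaError,
    ScreenError,
    collapse_replicates,
    quadrant_screen,
    quantile_normalize,
    read_expression,
    reliability_filter,
    welch_t,
    write_expression,
)

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_tie_rule_assigns_mean_of_tied_reference_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        # reference = (1.5, 2.5, 5.5); ties in a at ranks 1,2 -> (1.5+2.5)/2
        assert out["a"].tolist() == [2.0, 2.0, 5.5]
        assert out["b"].tolist() == [1.5, 2.5, 5.5]

    def test_rejects_missing_values_and_single_sample(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]}))
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))

    @given(arrays(float, (17, 4), elements=finite, unique=True))
    def test_idempotent_and_sorted_columns_identical(self, X):
        out = quantile_normalize(pd.DataFrame(X))
        s = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(s - s[:, [0]], 0.0, atol=1e-12)
        again = quantile_normalize(out)
        assert np.allclose(out.to_numpy(), again.to_numpy(), atol=1e-12)

    @given(arrays(float, (11, 3), elements=finite, unique=True), st.permutations(range(3)))
    def test_permutation_equivariant_over_samples(self, X, perm):
        df = pd.DataFrame(X, columns=list("abc"))
        out = quantile_normalize(df)
        out_perm = quantile_normalize(df.iloc[:, list(perm)])
        pd.testing.assert_frame_equal(out_perm, out.iloc[:, list(perm)])


class TestCollapseReplicates:
    def test_duplicate_probes_averaged(self):
        m = make_matrix([[4.0, 8.0], [6.0, 10.0]], genes=["G1", "G1"])
        m.annotation["transcript"] = ["T1", "T1"]
        out = collapse_replicates(m)
        assert out.values.loc["T1"].tolist() == [5.0, 9.0]
        assert out.annotation.loc["T1", "n_probes"] == 2

    def test_singleton_groups_unchanged(self):
        m = make_matrix([[4.0, 8.0], [6.0, 10.0]])
        out = collapse_replicates(m)
        assert np.array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_one_unreliable_replicate_poisons_group(self):
        m = make_matrix([[4.0, 8.0], [6.0, 10.0]], genes=["G1", "G1"])
        m.annotation["transcript"] = ["T1", "T1"]
        m.flags["spot_uniform"].iloc[0, 1] = False
        out = collapse_replicates(m)
        assert out.reliable().loc["T1"].tolist() == [True, False]


class TestReliabilityFilter:
    def test_all_passing_is_identity(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        kept, report = reliability_filter(m, m.samples)
        assert list(kept) == list(m.values.index)
        assert report["n_features_kept"] == 3

    def test_single_failure_in_subset_excludes_feature(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4))
        m.flags["above_noise"].iloc[1, 2] = False
        kept, _ = reliability_filter(m, m.samples)
        assert m.values.index[1] not in kept
        kept2, _ = reliability_filter(m, [m.samples[0], m.samples[1]])
        assert m.values.index[1] in kept2  # failing sample outside subset

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        m = make_matrix(rng.normal(size=(40, 6)))
        for name in FLAG_NAMES:
            m.flags[name].iloc[:, :] = rng.random((40, 6)) > 0.05
        subset = list(m.samples[:4])
        kept, _ = reliability_filter(m, subset)
        expected = [
            f
            for f in m.values.index
            if all(
                m.flags[name].loc[f, s] for name in FLAG_NAMES for s in subset
            )
        ]
        assert list(kept) == expected

    def test_empty_subset_rejected(self):
        m = make_matrix(np.ones((2, 2)))
        with pytest.raises(ValueError):
            reliability_filter(m, [])


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        res = welch_t([5.0, 5.0, 5.0], [5.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_matches_textbook_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy import stats as sps

        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        res = welch_t(a, b)
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == pytest.approx(df_hand, abs=1e-12)
        assert res.p == pytest.approx(p_hand, abs=1e-12)
        assert res.mean_diff == pytest.approx(-1.0)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(1, 1, size=5)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)


class TestExpressionIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(8, 1, size=(20, 6)))
        m.flags["spot_uniform"].iloc[3, 2] = False
        paths = write_expression(m, tmp_path)
        again = read_expression(paths["values"], paths["flags"], paths["annotation"])
        pd.testing.assert_frame_equal(m.values, again.values)
        for name in FLAG_NAMES:
            pd.testing.assert_frame_equal(m.flags[name], again.flags[name])
        pd.testing.assert_frame_equal(m.annotation, again.annotation)

    def test_missing_flag_column_named_in_error(self, tmp_path):
        m = make_matrix(np.ones((3, 3)))
        paths = write_expression(m, tmp_path)
        flags = pd.read_csv(paths["flags"], sep="\t").drop(columns=["spot_uniform"])
        flags.to_csv(paths["flags"], sep="\t", index=False)
        with pytest.raises(SchemaError, match="spot_uniform"):
            read_expression(paths["values"], paths["flags"], paths["annotation"])

    def test_parses_fixture_dimensions(self, tmp_path):
        m = make_matrix(np.random.default_rng(0).normal(size=(100, 12)))
        paths = write_expression(m, tmp_path)
        again = read_expression(paths["values"], paths["flags"], paths["annotation"])
        assert again.values.shape == (100, 12)


def _screen_inputs(n_genes=60, seed=0, shift=0.0):
    """Null screen bed: 40 samples, disjoint contrast groups, girls only."""
    rng = np.random.default_rng(seed)
    X = rng.normal(8.0, 0.5, size=(n_genes, 40))
    X[0, :10] += shift   # high-As group
    X[0, 20:30] -= shift  # high-BW group (low-BW minus high-BW positive)
    m = make_matrix(X)
    samples = m.samples
    exposure = pd.Series("median", index=samples, dtype=object)
    exposure.iloc[:10] = "high"
    exposure.iloc[10:20] = "low"
    bw = pd.Series("mid", index=samples, dtype=object)
    bw.iloc[20:30] = "high"
    bw.iloc[30:40] = "low"
    sex = pd.Series("girl", index=samples)
    return m, exposure, bw, sex


class TestQuadrantScreen:
    def test_planted_gene_in_quadrant_one_with_both_significant(self):
        m, exposure, bw, sex = _screen_inputs(seed=1, shift=2.0)
        res = quadrant_screen(m, exposure, bw, sex, "girl")
        row = res.table.iloc[0]
        assert row["quadrant"] == 1
        assert row["p_as"] < 0.05 and row["p_bw"] < 0.05
        assert bool(row["candidate"])

    def test_sign_flip_maps_quadrant_one_to_three(self):
        m, exposure, bw, sex = _screen_inputs(seed=2, shift=1.5)
        res = quadrant_screen(m, exposure, bw, sex, "girl")
        flipped = make_matrix(-m.values.to_numpy())
        res2 = quadrant_screen(flipped, exposure, bw, sex, "girl")
        q1, q2 = res.table["quadrant"], res2.table["quadrant"]
        assert ((q1 == 1) == (q2 == 3)).all()
        assert ((q1 == 3) == (q2 == 1)).all()
        pd.testing.assert_series_equal(res.table["p_as"], res2.table["p_as"])

    def test_invariant_to_probe_and_sample_order(self):
        m, exposure, bw, sex = _screen_inputs(seed=3, shift=1.0)
        res = quadrant_screen(m, exposure, bw, sex, "girl")
        rng = np.random.default_rng(0)
        fperm = rng.permutation(m.n_features)
        sperm = rng.permutation(len(m.samples))
        from cordmediate.transcriptome import ExpressionMatrix

        shuffled = ExpressionMatrix(
            values=m.values.iloc[fperm, sperm],
            flags={k: v.iloc[fperm, sperm] for k, v in m.flags.items()},
            annotation=m.annotation.iloc[fperm],
        )
        res2 = quadrant_screen(shuffled, exposure, bw, sex, "girl")
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_unreliable_feature_excluded_from_screen(self):
        m, exposure, bw, sex = _screen_inputs(seed=4)
        m.flags["above_noise"].iloc[5, 0] = False  # sample 0 is in the As-high group
        res = quadrant_screen(m, exposure, bw, sex, "girl")
        assert m.values.index[5] not in res.table.index
        assert res.filter_report["n_features_kept"] == m.n_features - 1

    def test_empty_stratum_group_raises(self):
        m, exposure, bw, sex = _screen_inputs(seed=5)
        with pytest.raises(ScreenError):
            quadrant_screen(m, exposure, bw, sex, "boy")

    def test_candidate_requires_both_significant_but_label_either(self):
        m, exposure, bw, sex = _screen_inputs(seed=6)
        X = m.values.to_numpy().copy()
        X[1, :10] += 3.0  # strong As contrast only
        m2 = make_matrix(X)
        res = quadrant_screen(m2, exposure, bw, sex, "girl")
        row = res.table.loc[m2.values.index[1]]
        if row["p_bw"] >= 0.05:
            assert not row["candidate"]
            assert row["labelled"]

    def test_panel_restriction(self):
        m, exposure, bw, sex = _screen_inputs(seed=7)
        m.annotation.loc[m.values.index[:30], "panels"] = "oxidative_stress"
        res = quadrant_screen(m, exposure, bw, sex, "girl", panel="embryonal_growth")
        assert len(res.table) == 30
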