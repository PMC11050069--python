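import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import bh_oracle
from ploidy_consensus.containers import ExpressionDataset
from ploidy_consensus.diffexp import (
    benjamini_hochberg,
    fit_variance_prior,
    moderated_t_test,
    prepare,
    quantile_normalize,
    select_degs,
)
from ploidy_consensus.errors import ValidationError

GROUPS_2V2 = {"d1": "diploid", "d2": "diploid", "p1": "polyploid", "p2": "polyploid"}


class TestQuantileNormalize:
    def test_hand_example(self):
        out = quantile_normalize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_unchanged(self):
        m = np.array([[1.0, 1.0], [7.0, 7.0], [3.0, 3.0]])
        np.testing.assert_allclose(quantile_normalize(m), m)

    def test_single_row_becomes_row_mean(self):
        out = quantile_normalize(np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out, np.full((1, 3), 4.0))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(50, 6))
        once = quantile_normalize(m)
        np.testing.assert_allclose(quantile_normalize(once), once, atol=1e-12)

    def test_columns_share_sorted_vector(self):
        rng = np.random.default_rng(1)
        out = quantile_normalize(rng.gamma(2.0, size=(40, 5)))
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_rejects_non_finite(self):
        with pytest.raises(ValidationError):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPrepare:
    def test_zero_count_offset(self):
        matrix = pd.DataFrame(
            [[0, 0, 0, 0]], index=["GA"], columns=list(GROUPS_2V2)
        ).astype(float)
        ds = ExpressionDataset("c", matrix, GROUPS_2V2, "counts")
        out = prepare(ds)
        # log2(0 + 0.5) = -1 in every cell, preserved by normalization
        np.testing.assert_allclose(out.to_numpy(), -1.0)

    def test_logged_intensity_left_alone(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(4, 12, size=(30, 4))  # max < 30: already log scale
        matrix = pd.DataFrame(values, columns=list(GROUPS_2V2))
        ds = ExpressionDataset("c", matrix, GROUPS_2V2, "intensity")
        out = prepare(ds)
        assert out.to_numpy().max() < 30

    def test_unlogged_intensity_gets_logged(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(100, 20000, size=(30, 4))
        matrix = pd.DataFrame(values, columns=list(GROUPS_2V2))
        ds = ExpressionDataset("c", matrix, GROUPS_2V2, "intensity")
        out = prepare(ds)
        assert out.to_numpy().max() < 20  # log2 scale now

    def test_output_idempotent_under_quantile_normalize(self, tiny_dataset):
        out = prepare(tiny_dataset).to_numpy()
        np.testing.assert_allclose(quantile_normalize(out), out, atol=1e-12)


class TestModeratedT:
    def _matrix(self, dip_values, pol_values, n_extra=0, seed=0):
        rng = np.random.default_rng(seed)
        rows = [list(dip_values) + list(pol_values)]
        for _ in range(n_extra):
            rows.append(list(rng.normal(5, 1, size=len(rows[0]))))
        cols = [f"d{i}" for i in range(len(dip_values))] + [
            f"p{i}" for i in range(len(pol_values))
        ]
        groups = {c: ("diploid" if c.startswith("d") else "polyploid") for c in cols}
        genes = [f"G{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=genes, columns=cols), groups

    def test_hand_example_ordinary_t(self):
        matrix, groups = self._matrix([1, 2, 3], [4, 5, 6])
        res = moderated_t_test(matrix, groups, prior_df=0)
        assert res.loc[0, "lfc"] == pytest.approx(3.0)
        assert res.loc[0, "t"] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)

    def test_prior_df_zero_equals_pooled_t(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            values = rng.normal(size=(30, 8))
            cols = [f"d{i}" for i in range(4)] + [f"p{i}" for i in range(4)]
            groups = {c: ("diploid" if c.startswith("d") else "polyploid") for c in cols}
            matrix = pd.DataFrame(values, columns=cols)
            res = moderated_t_test(matrix, groups, prior_df=0)
            t_ref, p_ref = stats.ttest_ind(
                values[:, 4:], values[:, :4], axis=1, equal_var=True
            )
            np.testing.assert_allclose(res["t"], t_ref, atol=1e-12)
            np.testing.assert_allclose(res["p"], p_ref, atol=1e-12)

    def test_label_swap_flips_lfc_keeps_p(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(40, 8))
        cols = [f"s{i}" for i in range(8)]
        matrix = pd.DataFrame(values, columns=cols)
        groups = {c: ("diploid" if i < 4 else "polyploid") for i, c in enumerate(cols)}
        swapped = {c: ("polyploid" if g == "diploid" else "diploid")
                   for c, g in groups.items()}
        res = moderated_t_test(matrix, groups)
        res_sw = moderated_t_test(matrix, swapped)
        np.testing.assert_allclose(res["lfc"], -res_sw["lfc"], atol=1e-12)
        np.testing.assert_allclose(res["p"], res_sw["p"], atol=1e-12)

    def test_moderation_shrinks_extreme_variances(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(200, 12))
        values[0] *= 1e-3  # artificially tiny variance gene
        cols = [f"d{i}" for i in range(6)] + [f"p{i}" for i in range(6)]
        groups = {c: ("diploid" if c.startswith("d") else "polyploid") for c in cols}
        matrix = pd.DataFrame(values, columns=cols)
        plain = moderated_t_test(matrix, groups, prior_df=0)
        moderated = moderated_t_test(matrix, groups)
        assert abs(moderated.loc[0, "t"]) < abs(plain.loc[0, "t"])

    def test_zero_variance_zero_lfc_gene(self):
        matrix, groups = self._matrix([2, 2], [2, 2])
        res = moderated_t_test(matrix, groups, prior_df=0)
        assert res.loc[0, "t"] == 0.0
        assert res.loc[0, "p"] == 1.0

    def test_single_sample_group_rejected(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["d1", "d2", "p1"])
        groups = {"d1": "diploid", "d2": "diploid", "p1": "polyploid"}
        with pytest.raises(ValidationError):
            moderated_t_test(matrix, groups)


class TestVariancePrior:
    def test_equal_variances_degenerate_to_pooled(self):
        # no excess spread in log s^2 -> infinite prior df; the pooled scale
        # carries the chi-square log-bias correction exp(log(d/2)-digamma(d/2))
        from scipy.special import digamma

        d0, s0 = fit_variance_prior(np.full(50, 2.0), df=10)
        assert np.isinf(d0)
        assert s0 == pytest.approx(2.0 * np.exp(np.log(5.0) - digamma(5.0)), rel=1e-9)

    def test_recovers_prior_scale_on_simulated_variances(self):
        # s2 ~ s0^2 * chi2_df / df has the assumed scaled distribution
        rng = np.random.default_rng(11)
        df, s0_true = 10, 2.5
        s2 = s0_true * rng.chisquare(df, size=20000) / df
        d0, s0 = fit_variance_prior(s2, df=df)
        assert d0 > 50  # data follow the prior exactly: huge prior df
        assert s0 == pytest.approx(s0_true, rel=0.05)


class TestSelectDegs:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "lfc", "t", "p", "fdr", "direction"]
        )

    @pytest.mark.parametrize(
        "p,fdr,lfc,expected",
        [
            (0.04, 0.09, 1.0, "up"),
            (0.04, 0.2, 1.0, "none"),  # FDR bound fails
            (0.05, 0.09, 1.0, "none"),  # strict inequality at p = 0.05
            (0.04, 0.09, -1.0, "down"),
            (0.04, 0.09, 0.0, "none"),  # zero lfc never called
        ],
    )
    def test_threshold_rules(self, p, fdr, lfc, expected):
        res = self._results([["G1", lfc, 1.0, p, fdr, "none"]])
        up, down = select_degs(res)
        direction = "up" if "G1" in up else "down" if "G1" in down else "none"
        assert direction == expected


class TestBenjaminiHochberg:
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(
            benjamini_hochberg(np.array(p)), bh_oracle(p), atol=1e-12
        )

    def test_monotone_step_up_transform(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
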