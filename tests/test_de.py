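"""Count-level differential expression: normalization, dispersions,
NB exact test, BH correction, signed fold change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hoxmir import de
from hoxmir.de import (
    DifferentialExpression,
    add_pseudocount,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    fold_change,
    nbinom_exact_test,
    normalize,
    pca_outliers,
)


def nb_matrix(rng, mu, alpha, n_samples, n_features):
    """NB draws at common mean(s) mu; mu may be scalar or per-feature."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_features,))
    size = 1.0 / alpha
    p = size / (size + mu)
    k = np.stack(
        [rng.negative_binomial(size, p[i], n_samples) for i in range(n_features)]
    )
    return pd.DataFrame(k, columns=[f"s{j}" for j in range(n_samples)])


class TestPseudocount:
    def test_all_zero_rows_removed_before_increment(self):
        m = pd.DataFrame({"a": [0, 0, 3], "b": [0, 1, 0]},
                         index=["dead", "low", "hi"])
        out = add_pseudocount(m)
        assert list(out.index) == ["low", "hi"]
        assert out.loc["low"].tolist() == [1, 2]

    def test_zero_pseudocount_is_identity_after_removal(self):
        m = pd.DataFrame({"a": [0, 2], "b": [0, 5]})
        out = add_pseudocount(m, c=0)
        assert out.equals(m.iloc[[1]])


class TestSizeFactors:
    def test_two_feature_worked_example(self):
        # features (2,4) and (8,16): geometric means sqrt(8) and sqrt(128),
        # ratios identical per sample -> s = (1/sqrt 2, sqrt 2)
        m = pd.DataFrame([[2, 4], [8, 16]], columns=["a", "b"])
        s = estimate_size_factors(m)
        assert s.to_numpy() == pytest.approx([0.70710678, 1.41421356])

    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [3, 9, 27], "b": [3, 9, 27], "c": [3, 9, 27]})
        assert estimate_size_factors(m).to_numpy() == pytest.approx([1, 1, 1])

    def test_scaling_one_column_scales_its_factor_tenfold_relatively(self):
        # the geometric-mean reference absorbs a common 10^(1/m) factor,
        # so it is the *relative* factor of the scaled library that
        # grows tenfold while the others stay put
        rng = np.random.default_rng(0)
        m = nb_matrix(rng, np.exp(rng.normal(4, 1, 50)), 0.1, 4, 50) + 1
        s0 = estimate_size_factors(m)
        m2 = m.copy()
        m2["s0"] = m2["s0"] * 10
        s1 = estimate_size_factors(m2)
        rel0 = s0 / s0["s1"]
        rel1 = s1 / s1["s1"]
        assert rel1["s0"] == pytest.approx(10 * rel0["s0"])
        assert rel1[1:].to_numpy() == pytest.approx(rel0[1:].to_numpy())

    def test_library_scaling_leaves_normalized_ratios_unchanged(self):
        # normalized counts change only by one global constant when
        # libraries are rescaled: all between-sample structure survives
        rng = np.random.default_rng(1)
        m = nb_matrix(rng, 100, 0.1, 5, 40) + 1
        q0 = normalize(m, estimate_size_factors(m))
        m2 = m * [1, 7, 1, 1, 3]
        q1 = normalize(m2, estimate_size_factors(m2))
        ratio = (q1 / q0).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])

    def test_no_all_positive_feature_is_an_error(self):
        m = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(de.NormalizationError):
            estimate_size_factors(m)


class TestPCAOutliers:
    def test_planted_outlier_flagged_clean_samples_kept(self):
        from hoxmir import simulate

        cfg = simulate.SimulationConfig(seed=13, plant_outlier=True)
        ds = simulate.simulate_dataset(cfg, with_reads=False)
        work = add_pseudocount(ds.counts)
        sf = estimate_size_factors(work)
        flagged = pca_outliers(normalize(work, sf))
        assert flagged == ds.truth.true_outlier_samples

    def test_near_replicate_samples_none_flagged(self):
        rng = np.random.default_rng(3)
        base = np.exp(rng.normal(4, 1, 60))
        m = pd.DataFrame(
            {f"s{j}": rng.poisson(base) + 1 for j in range(8)}
        )
        assert pca_outliers(m) == []

    def test_zero_variance_features_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.poisson(50, (20, 6)) + 1.0)
        m.iloc[0] = 7.0  # constant feature
        with pytest.warns(UserWarning, match="zero-variance"):
            pca_outliers(m)

    def test_requires_three_samples(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            pca_outliers(m)


class TestDispersions:
    conditions = staticmethod(
        lambda na, nb: pd.Series(
            ["A"] * na + ["B"] * nb, index=[f"s{j}" for j in range(na + nb)]
        )
    )

    def test_poisson_data_raw_near_zero(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.normal(4.5, 0.8, 400))
        m = pd.DataFrame(
            np.stack([rng.poisson(v, 12) for v in mu]),
            columns=[f"s{j}" for j in range(12)],
        ) + 1
        sf = estimate_size_factors(m)
        disp = estimate_dispersions(m, sf, self.conditions(6, 6))
        assert np.median(disp.raw) < 0.02
        # final values are dominated by the (small) trend floor
        assert np.median(disp.final) < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(6)
        mu = np.exp(rng.normal(5, 1, 500))
        m = nb_matrix(rng, mu, 0.2, 24, 500) + 1
        sf = estimate_size_factors(m)
        disp = estimate_dispersions(m, sf, self.conditions(12, 12))
        assert 0.1 <= np.median(disp.final) <= 0.4

    def test_constant_feature_has_zero_raw_dispersion(self):
        m = pd.DataFrame({f"s{j}": [5, 10] for j in range(6)})
        sf = pd.Series(1.0, index=m.columns)
        disp = estimate_dispersions(m, sf, self.conditions(3, 3))
        assert disp.raw.iloc[0] == 0.0

    def test_requires_replication(self):
        m = pd.DataFrame({"s0": [5], "s1": [9]})
        sf = pd.Series(1.0, index=m.columns)
        cond = pd.Series(["A", "B"], index=m.columns)
        with pytest.raises(ValueError):
            estimate_dispersions(m, sf, cond)


class TestExactTest:
    def run(self, m, na, nb, alpha=0.1):
        cond = pd.Series(["A"] * na + ["B"] * nb, index=m.columns)
        sf = estimate_size_factors(m)
        disp = estimate_dispersions(m, sf, cond)
        return nbinom_exact_test(m, sf, disp, cond)

    def test_identical_balanced_counts_give_p_one(self):
        m = pd.DataFrame([[50] * 8, [200] * 8],
                         columns=[f"s{j}" for j in range(8)])
        res = self.run(m, 4, 4)
        assert res["pvalue"].to_numpy() == pytest.approx([1.0, 1.0])
        assert res["fold_change"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        m = nb_matrix(rng, np.exp(rng.normal(4, 1, 30)), 0.1, 10, 30) + 1
        cond = pd.Series(["A"] * 5 + ["B"] * 5, index=m.columns)
        sf = estimate_size_factors(m)
        disp = estimate_dispersions(m, sf, cond)
        ab = nbinom_exact_test(m, sf, disp, cond, "A", "B")
        ba = nbinom_exact_test(m, sf, disp, cond, "B", "A")
        assert np.allclose(ab["pvalue"], ba["pvalue"])
        assert np.allclose(ab["fold_change"], -ba["fold_change"])
        # |FC| = 1 boundary: exactly equal means invert to themselves
        assert (ab["fold_change"].abs() >= 1).all()

    def test_large_planted_effect_detected(self):
        rng = np.random.default_rng(8)
        m = nb_matrix(rng, 200, 0.05, 21, 50) + 1
        m.iloc[0, 9:] = (m.iloc[0, 9:] * 28).astype(int)  # case columns
        res = self.run(m, 9, 12, alpha=0.05)
        assert res["qvalue"].iloc[0] < 1e-6
        assert res["fold_change"].iloc[0] > 15


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )
        # a non-degenerate hand evaluation: p=(.01,.04,.03,.8), m=4
        # sorted: .01*4/1=.04, .03*4/2=.06, .04*4/3=.0533.., .8*4/4=.8
        # step-up minima: .04, .0533.., .0533.., .8
        assert bh_adjust([0.01, 0.04, 0.03, 0.8]).tolist() == pytest.approx(
            [0.04, 0.16 / 3, 0.16 / 3, 0.8]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_restricted_denominator_scales_q(self):
        # subset of 3 p-values corrected as part of a family of 55
        q = bh_adjust([0.001, 0.01, 0.02], m=55)
        assert q == pytest.approx([0.055, 0.275, 0.3666667])

    def test_m_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariants(self, ps):
        q = bh_adjust(ps)
        p = np.asarray(ps)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()
        # order invariance
        assert np.allclose(np.sort(q), np.sort(bh_adjust(ps[::-1])))

    def test_all_equal_p_pass_through(self):
        q = bh_adjust([0.2] * 5)
        assert q.tolist() == pytest.approx([0.2] * 5)


class TestFoldChange:
    @pytest.mark.parametrize(
        "control, case, expected",
        [
            (915.81, 26020.05, 28.41),
            (49.44, 102.01, 2.06),
            (22.91, 140.82, 6.15),
            (784.95, 1762.88, 2.25),
            (113.74, 51.99, -2.19),
            (55.91, 22.80, -2.45),
        ],
    )
    def test_published_group_means(self, control, case, expected):
        assert round(fold_change(control, case), 2) == expected

    def test_equal_means_give_one(self):
        assert fold_change(3.7, 3.7) == 1.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 5.0)


class TestModelObject:
    def test_fit_removes_outlier_and_recovers_planted_features(self):
        from hoxmir import simulate

        cfg = simulate.SimulationConfig(seed=5, plant_outlier=True)
        ds = simulate.simulate_dataset(cfg, with_reads=False)
        res = DifferentialExpression(
            ds.counts, ds.truth.conditions, order=("control", "case")
        ).fit()
        assert res.outliers == ds.truth.true_outlier_samples
        sig = set(res.significant(0.05).index)
        assert {"miR-10b-like", "miR-196a-like", "miR-615-like"} <= sig
        assert "miR-10b-like" in res.summary()

    def test_conditions_must_match_columns(self):
        m = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ValueError):
            DifferentialExpression(m, pd.Series(["x"], index=["zzz"]))
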