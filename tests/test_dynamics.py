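"""Pooled-reference M-values, significance machinery, proteome filter
cascade and overview summaries."""

import numpy as np
import pandas as pd
import pytest

from prokdyn.core import ExpressionMatrix
from prokdyn.dynamics import (ModificationRecord, benjamini_hochberg, compute_m_values,
                              filter_dynamic, fraction_reconciliation,
                              proteome_filter_cascade, ptm_summary,
                              significance_overview, size_factor_normalize,
                              summarize_significance, test_significance)

test_significance.__test__ = False  # library function, not a test case


def make_matrix(values: np.ndarray, layer="transcript_counts", times=None, n_rep=3, **kw):
    n_feat = values.shape[0]
    n_time = values.shape[1] // n_rep
    times = times or [float(t) for t in range(n_time)]
    cols = pd.MultiIndex.from_product([times, range(1, n_rep + 1)],
                                      names=["time", "replicate"])
    df = pd.DataFrame(values, index=[f"f{i}" for i in range(n_feat)], columns=cols)
    return ExpressionMatrix(df, layer, **kw)


def bh_oracle(p):
    """Brute-force BH step-up: sort, scale by m/rank, enforce monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        mat = make_matrix(np.tile([[10.0], [20.0], [5.0]], (1, 6)), n_rep=3)
        _, factors = size_factor_normalize(mat)
        np.testing.assert_allclose(factors, 1.0)

    def test_scaled_sample_detected_and_equalized(self):
        col = np.abs(np.random.default_rng(0).lognormal(3, 1, size=50)) + 1
        vals = np.tile(col[:, None], (1, 6))
        vals[:, 2] *= 2.0
        mat = make_matrix(vals, n_rep=3)
        normed, factors = size_factor_normalize(mat)
        assert factors.iloc[2] / factors.iloc[0] == pytest.approx(2.0)
        # after normalization the doubled sample matches the others
        np.testing.assert_allclose(normed.values.iloc[:, 2], normed.values.iloc[:, 0],
                                   rtol=1e-9)

    def test_geometric_mean_of_factors_is_one(self, rng):
        vals = rng.negative_binomial(10, 0.3, size=(80, 21)).astype(float) + 1
        _, factors = size_factor_normalize(make_matrix(vals, times=list(range(7))))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)

    def test_matches_median_of_ratios_oracle(self, rng):
        vals = rng.negative_binomial(10, 0.3, size=(60, 6)).astype(float) + 1
        _, factors = size_factor_normalize(make_matrix(vals))
        log_ref = np.log(vals).mean(axis=1)
        oracle = np.exp(np.median(np.log(vals) - log_ref[:, None], axis=0))
        oracle /= np.exp(np.mean(np.log(oracle)))
        np.testing.assert_allclose(factors, oracle, rtol=1e-12)

    def test_all_zero_sample_rejected(self):
        vals = np.ones((5, 6))
        vals[:, 3] = 0.0
        with pytest.raises(ValueError):
            size_factor_normalize(make_matrix(vals))


class TestMValues:
    def test_constant_feature_is_zero(self):
        mat = make_matrix(np.full((1, 9), 7.0), times=[0.0, 1.0, 2.0])
        m = compute_m_values(mat)
        np.testing.assert_allclose(m["M"], 0.0)

    def test_two_point_toy(self):
        mat = make_matrix(np.repeat([[2.0, 8.0]], 3, axis=1).reshape(1, 6))
        m = compute_m_values(mat).sort_values("time")
        np.testing.assert_allclose(m["M"], [np.log2(0.4), np.log2(1.6)])

    def test_pooled_reference_identity(self, rng):
        vals = rng.lognormal(3, 1, size=(40, 21))
        m = compute_m_values(make_matrix(vals, times=list(range(7))))
        back = m.assign(fc=2.0 ** m["M"]).groupby("feature")["fc"].mean()
        np.testing.assert_allclose(back, 1.0, rtol=1e-12)

    def test_zero_reference_flagged(self):
        vals = np.zeros((1, 6))
        m = compute_m_values(make_matrix(vals))
        assert m["flagged"].all()
        assert m["M"].isna().all()

    def test_log_scale_matrix_uses_difference_contrast(self, rng):
        z = rng.normal(size=(20, 21))
        mat = make_matrix(z, layer="protein_lfq", times=list(range(7)), normalized=True)
        m = compute_m_values(mat)
        means = m.groupby("feature")["M"].mean()
        np.testing.assert_allclose(means, 0.0, atol=1e-12)


class TestSignificance:
    def test_bh_paper_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04, 0.5]))
        np.testing.assert_allclose(adj, [0.05, 0.05, 0.05, 0.05, 0.5])

    @pytest.mark.parametrize("seed", range(20))
    def test_bh_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 11)))
        np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p), rtol=1e-12)

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg(np.array([0.037])), [0.037])

    def test_bh_monotone_and_above_raw(self, rng):
        p = rng.uniform(size=50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_identical_values_never_significant(self):
        mat = make_matrix(np.full((4, 21), 100.0), times=list(range(7)))
        rec = test_significance(mat)
        assert not rec["significant"].any()

    def test_shifted_feature_detected(self, rng):
        vals = rng.normal(100, 1, size=(30, 21)).clip(min=1)
        vals[0, :3] += 500  # one feature spikes at the first time point
        rec = test_significance(make_matrix(vals, times=list(range(7))))
        hit = rec[(rec["feature"] == "f0") & (rec["time"] == 0)]
        assert hit["significant"].all()

    def test_too_few_replicates_gives_missing_p(self):
        vals = np.full((2, 21), 50.0)
        vals[:, 1:3] = np.nan  # time 0 keeps a single replicate
        mat = make_matrix(vals, layer="protein_lfq", times=list(range(7)), normalized=True)
        rec = test_significance(mat, log_transform=False)
        t0 = rec[rec["time"] == 0]
        assert t0["p"].isna().all()
        assert not t0["significant"].any()


class TestFilterDynamic:
    def _records(self, p_adj_by_feature):
        rows = []
        for feat, padjs in p_adj_by_feature.items():
            for t, pa in enumerate(padjs):
                rows.append({"feature": feat, "time": t, "p_adj": pa,
                             "significant": pa < 0.05})
        return pd.DataFrame(rows)

    def test_single_significant_time_point_retains(self):
        rec = self._records({"a": [0.5, 0.01, 0.9], "b": [0.5, 0.6, 0.9]})
        assert list(filter_dynamic(rec)) == ["a"]

    def test_exact_boundary_is_ruled_out(self):
        rec = self._records({"edge": [0.05, 0.05, 0.05]})
        assert len(filter_dynamic(rec)) == 0

    def test_null_features_mostly_ruled_out(self):
        rng = np.random.default_rng(11)
        vals = rng.lognormal(5, 0.2, size=(300, 21))  # flat archetype, pure noise
        rec = test_significance(make_matrix(vals, times=list(range(7))))
        retained = filter_dynamic(rec)
        assert len(retained) / 300 <= 0.05  # >= 95% ruled out


class TestProteomeCascade:
    def _lfq(self, vals, upc):
        meta = pd.DataFrame({"unique_peptide_count": upc},
                            index=[f"f{i}" for i in range(vals.shape[0])])
        return make_matrix(vals, layer="protein_lfq", times=list(range(7)), meta=meta)

    def test_single_peptide_protein_removed(self, rng):
        vals = rng.lognormal(16, 1, size=(3, 21))
        filtered, report = proteome_filter_cascade(self._lfq(vals, [1, 2, 5]))
        assert "f0" not in filtered.features
        assert report["removed_few_peptides"] == 1

    def test_incomplete_replicate_cell_blanked_others_kept(self, rng):
        vals = rng.lognormal(16, 1, size=(1, 21))
        vals[0, 12] = np.nan  # time 4, one replicate missing
        filtered, report = proteome_filter_cascade(self._lfq(vals, [3]))
        z = filtered.values
        assert z.xs(4.0, axis=1, level="time").isna().all(axis=None)
        for t in [0.0, 1.0, 2.0, 3.0, 5.0, 6.0]:
            assert z.xs(t, axis=1, level="time").notna().all(axis=None)
        assert report["cells_blanked"] == 1
        assert report["n_at_least_6_of_7"] == 1

    def test_z_normalization_moments(self, rng):
        vals = rng.lognormal(16, 1, size=(10, 21))
        filtered, _ = proteome_filter_cascade(self._lfq(vals, [5] * 10))
        z = filtered.values.to_numpy()
        np.testing.assert_allclose(np.nanmean(z, axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.nanstd(z, axis=1), 1.0, rtol=1e-9)

    def test_rules_order_independent(self, rng):
        vals = rng.lognormal(16, 1, size=(6, 21))
        vals[2, ::3] = np.nan
        upc = [1, 3, 4, 2, 1, 5]
        a, _ = proteome_filter_cascade(self._lfq(vals, upc))
        # apply rule 2 manually first, then rule 1: same retained set
        mat = self._lfq(vals, upc)
        blanked = mat.values.copy()
        for t in mat.times:
            cols = [c for c in blanked.columns if c[0] == t]
            bad = blanked[cols].notna().sum(axis=1) < 3
            blanked.loc[bad[bad].index, cols] = np.nan
        b, _ = proteome_filter_cascade(
            ExpressionMatrix(blanked, "protein_lfq", mat.meta))
        assert list(a.features) == list(b.features)
        assert a.values.notna().equals(b.values.notna())


class TestFractionReconciliation:
    def test_rules(self):
        loc = pd.Series({"a": "extracellular", "b": "cytosolic", "c": "membrane"})
        assign, counts = fraction_reconciliation({"a", "b", "c"}, {"a", "b"}, loc)
        assert assign["a"] == "extracellular"   # both fractions + signal peptide
        assert assign["b"] == "both"            # both fractions, cytosolic
        assert assign["c"] == "cellular"        # cellular only
        assert counts["both_reassigned_extracellular"] == 1

    def test_unknown_label_warns_and_defaults(self):
        loc = pd.Series({"x": "mystery"})
        with pytest.warns(UserWarning):
            assign, counts = fraction_reconciliation({"x"}, {"x"}, loc)
        assert assign["x"] == "both"
        assert counts["unknown_labels"] == 1


class TestSummaries:
    @pytest.mark.parametrize("n,den,expected", [
        (1421, 8364, 17.0), (1246, 8364, 14.9), (2491, 8364, 29.8),
        (2531, 8364, 30.3), (699, 878, 79.6), (408, 1029, 39.7),
        (1789, 4757, 37.6), (0, 10, 0.0), (4143, 4228, 98.0),
    ])
    def test_percentage_rounding(self, n, den, expected):
        assert summarize_significance(n, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            summarize_significance(1, 0)

    def test_overview_counts_signed_directions(self):
        rec = pd.DataFrame({
            "feature": ["a", "b", "c", "a", "b", "c"],
            "time": [0, 0, 0, 1, 1, 1],
            "M": [1.0, -1.0, 0.5, 0.2, 0.1, -0.3],
            "significant": [True, True, False, False, False, True],
        })
        ov = significance_overview(rec, denominator=10)
        t0 = ov[ov["time"] == 0].iloc[0]
        assert (t0["n_up"], t0["n_down"]) == (1, 1)
        assert t0["pct_up"] == 10.0
        t1 = ov[ov["time"] == 1].iloc[0]
        assert (t1["n_up"], t1["n_down"]) == (0, 1)


class TestPTMSummary:
    def _acb_records(self):
        return [
            ModificationRecord("AcbZ", "pyro-Glu", ["T1", "T3", "T4", "T6"]),
            ModificationRecord("AcbQ", "N-terminal acetylation", ["T3"]),
            ModificationRecord("AcbQ", "pyro-Glu", ["T5"]),
            ModificationRecord("AcbD", "pyro-Glu", ["T2", "T5", "T7"]),
            ModificationRecord("AcbQ", "oxidation", ["T1"], residue="M12"),
        ]

    def test_acbq_rows_match_study_table(self):
        table = ptm_summary(self._acb_records())
        acbq = table[table["protein"] == "AcbQ"].set_index("modification")
        assert acbq.loc["Acetylation", "time_points"] == "T3"
        assert acbq.loc["Gln → pyro-Glu", "time_points"] == "T5"
        assert "Oxidation" not in acbq.index

    def test_empty_records(self):
        assert ptm_summary([]).empty

    def test_oxidation_only_gives_empty_table(self):
        recs = [ModificationRecord("P1", "oxidation", ["T1"])]
        assert ptm_summary(recs).empty
        assert len(ptm_summary(recs, exclude_oxidation=False)) == 1

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            ModificationRecord("P1", "glycosylation", ["T1"])
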