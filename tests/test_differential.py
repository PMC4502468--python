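"""Fold change, one-way ANOVA, DE selection, and Z-scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rootarray as ra
from rootarray.differential import (FoldChangeANOVA, ZScoreTransformer,
                                    anova_pvalues, fold_changes, select_de,
                                    stage_means, zscores)


def _em(values, design):
    return ra.ExpressionMatrix(pd.DataFrame(values), design)


def test_stage_means_simple_and_loop_oracle(small_em):
    sm = stage_means(small_em)
    for stage in small_em.stage_order:
        cols = small_em.stage_columns(stage)
        for probe in small_em.probe_ids:
            expected = sum(small_em.values.at[probe, c] for c in cols) / len(cols)
            assert sm.at[probe, stage] == pytest.approx(expected)


def test_stage_means_replicate_pair(small_design):
    em = _em({"10D_r1": [4.0], "10D_r2": [6.0],
              "15D_r1": [1.0], "15D_r2": [1.0]}, small_design)
    assert stage_means(em).at[em.probe_ids[0], "10"] == 5.0


def test_fold_change_boundary_inclusive():
    sm = pd.DataFrame({"10": [5.0, 5.0, 5.0], "30": [5.0, 6.0, 4.0]},
                      index=["eq", "up2", "down2"])
    fc = fold_changes(sm, "10")
    assert list(fc.columns) == ["30"]
    assert fc.at["eq", "30"] == 0.0                      # FC exactly 1
    assert 2 ** fc.at["up2", "30"] == pytest.approx(2.0)  # at the threshold
    assert 2 ** fc.at["down2", "30"] == pytest.approx(0.5)
    pv = pd.DataFrame({"F": [1, 1, 1], "p": [1e-6] * 3}, index=sm.index)
    de = select_de(fc, pv, fc_threshold=2.0, alpha=0.05)
    assert list(de.table["de"]) == [False, True, True]   # both directions


def test_fold_change_unknown_reference():
    sm = pd.DataFrame({"10": [5.0]})
    with pytest.raises(ValueError, match="reference"):
        fold_changes(sm, "99")


def test_anova_degenerate_conventions(small_design):
    em = _em(
        {"10D_r1": [5.0, 5.0], "10D_r2": [5.0, 5.0],
         "15D_r1": [5.0, 9.0], "15D_r2": [5.0, 9.0]},
        small_design,
    )
    res = anova_pvalues(em)
    assert res["F"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0
    assert np.isinf(res["F"].iloc[1]) and res["p"].iloc[1] == 0.0


def test_anova_two_groups_equals_t_test(small_design):
    """With two stages, F = t² and the p-values coincide."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(rng.normal(8, 1, (50, 4)), columns=small_design.index)
    em = _em(values, small_design)
    res = anova_pvalues(em)
    t, p = stats.ttest_ind(values.iloc[:, :2], values.iloc[:, 2:], axis=1)
    np.testing.assert_allclose(res["F"], t**2, rtol=1e-10)
    np.testing.assert_allclose(res["p"], p, rtol=1e-10)


def test_anova_matches_scipy_f_oneway(scaled_counts):
    """Independent oracle: scipy.stats.f_oneway on simulated data."""
    cfg = ra.SimulationConfig(class_counts=scaled_counts, seed=3)
    em, _ = ra.simulate(cfg)
    sub = em.subset(em.probe_ids[:200])
    res = anova_pvalues(sub)
    groups = [sub.values[sub.stage_columns(s)].to_numpy() for s in sub.stage_order]
    F, p = stats.f_oneway(*groups, axis=1)
    np.testing.assert_allclose(res["F"], F, rtol=1e-8)
    np.testing.assert_allclose(res["p"], p, rtol=1e-8)


def test_anova_null_pvalues_uniform():
    """10,000 null genes: ANOVA p-values pass a KS uniformity test."""
    rng = np.random.default_rng(12)
    design = pd.DataFrame(
        {"stage": np.repeat([str(s) for s in (10, 15, 20, 30, 60, 90, 120)], 2),
         "replicate": [1, 2] * 7},
        index=[f"{s}D_r{r}" for s in (10, 15, 20, 30, 60, 90, 120)
               for r in (1, 2)],
    )
    em = _em(pd.DataFrame(rng.normal(9, 1, (10_000, 14)),
                          columns=design.index), design)
    res = anova_pvalues(em)
    assert stats.kstest(res["p"], "uniform").pvalue > 0.01


def test_select_de_gates():
    fc = pd.DataFrame({"30": [np.log2(1.9), 2.0]}, index=["small_fc", "big_fc"])
    pv = pd.DataFrame({"F": [10.0, 1.0], "p": [0.001, 0.2]}, index=fc.index)
    de = select_de(fc, pv)
    assert not de.table.at["small_fc", "de"]   # FC gate
    assert not de.table.at["big_fc", "de"]     # p gate
    with pytest.raises(ValueError):
        select_de(fc, pv, fc_threshold=-1)


def test_select_de_bh_adjustment_is_more_conservative():
    rng = np.random.default_rng(5)
    fc = pd.DataFrame({"30": np.full(100, 2.0)})
    pv = pd.DataFrame({"F": np.ones(100), "p": rng.uniform(0, 0.2, 100)})
    raw = select_de(fc, pv, adjust="none")
    bh = select_de(fc, pv, adjust="bh")
    assert bh.de_count <= raw.de_count
    np.testing.assert_allclose(
        bh.table["p_adj"],
        stats.false_discovery_control(pv["p"].to_numpy(), method="bh"),
    )


def test_de_selection_shift_invariant(scaled_counts):
    """Adding a constant to the whole log2 matrix changes nothing."""
    cfg = ra.SimulationConfig(class_counts=scaled_counts, seed=4)
    em, _ = ra.simulate(cfg)
    shifted = ra.ExpressionMatrix(em.values + 3.7, em.design)
    a = FoldChangeANOVA().fit(em)
    b = FoldChangeANOVA().fit(shifted)
    pd.testing.assert_series_equal(a.de_mask_, b.de_mask_)
    np.testing.assert_allclose(a.log2fc_, b.log2fc_, atol=1e-9)


@pytest.mark.parametrize("seed", [0, 1])
def test_power_and_false_positive_rate(seed):
    """Planted DE with |log2FC| >= 1.5 at replicate_sd 0.1 is recovered at
    >= 99% sensitivity; flat genes stay under alpha + 2% false positives."""
    cfg = ra.SimulationConfig(
        class_counts={"constitutive": 2000, "de_cluster_I": 500,
                      "de_cluster_V": 500},
        replicate_sd=0.1, de_fold_range=(2.83, 4.0),  # log2 in [1.5, 2]
        seed=seed,
    )
    em, truth = ra.simulate(cfg)
    sel = FoldChangeANOVA(alpha=0.05).fit(em)
    de = sel.de_mask_
    planted = truth["planted_class"].str.startswith("de_cluster")
    sensitivity = de[planted.to_numpy()].mean()
    fpr = de[(~planted).to_numpy()].mean()
    assert sensitivity >= 0.99
    assert fpr <= 0.05 + 0.02


class TestZScores:
    def test_global_convention_identities(self, small_em):
        z, mu, sigma = zscores(small_em.values)
        arr = z.to_numpy()
        assert arr.mean() == pytest.approx(0.0, abs=1e-12)
        assert arr.std(ddof=0) == pytest.approx(1.0)
        x = small_em.values.iloc[0, 0]
        assert z.iloc[0, 0] == pytest.approx((x - mu) / sigma)
        assert z.attrs["zscore_convention"] == "global"

    def test_value_at_global_mean_maps_to_zero(self):
        values = pd.DataFrame([[4.0, 6.0], [5.0, 9.0]])
        z, mu, _ = zscores(values)
        values.iloc[0, 0] = mu
        z2, mu2, sigma2 = zscores(values)
        assert z2.iloc[0, 0] == pytest.approx((mu - mu2) / sigma2)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            zscores(pd.DataFrame(np.full((3, 4), 2.0)))

    def test_sample_means_convention_recorded(self, small_em):
        z, mu, sigma = zscores(small_em.values, convention="sample_means")
        col_means = small_em.values.to_numpy().mean(axis=0)
        assert mu == pytest.approx(col_means.mean())
        assert sigma == pytest.approx(col_means.std(ddof=0))
        assert z.attrs["zscore_convention"] == "sample_means"
        with pytest.raises(ValueError):
            zscores(small_em.values, convention="bogus")

    def test_transformer_estimator(self, small_em):
        tr = ZScoreTransformer().fit(small_em.values)
        z = tr.transform(small_em.values)
        assert z.to_numpy().mean() == pytest.approx(0.0, abs=1e-12)
        assert tr.get_params() == {"convention": "global"}
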