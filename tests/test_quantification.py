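import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import qpcrlmm as q
from qpcrlmm.mixed_model import ContrastResult
from qpcrlmm.quantification import (
    adjust_pvalues,
    contrast_weights,
    correlation_matrix,
    effective_tests,
    run_all_contrasts,
    to_fold_change,
)

from conftest import small_qpcr_config


# ---------------------------------------------------------------------------
# fold-change back-transform
# ---------------------------------------------------------------------------

def test_null_contrast_gives_unit_fc_with_log_symmetric_ci():
    c = ContrastResult(name="g:effect", diff=0.0, se=0.3, df=20.0, t_stat=0.0, p_nominal=1.0)
    f = to_fold_change(c)
    assert f.fc == pytest.approx(1.0)
    assert f.ci_low * f.ci_high == pytest.approx(1.0, rel=1e-12)


def test_fold_change_against_t_quantile_oracle():
    # t(10, 0.975) = 2.2281388519862735 from a published quantile table
    c = ContrastResult(name="g:e", diff=-1.0, se=0.5, df=10.0, t_stat=-2.0, p_nominal=0.07)
    f = to_fold_change(c)
    assert f.fc == pytest.approx(2.0, rel=1e-12)
    assert f.ci_high == pytest.approx(2 ** (1 + 2.2281388519862735 * 0.5), rel=1e-9)
    assert f.ci_low == pytest.approx(2 ** (1 - 2.2281388519862735 * 0.5), rel=1e-9)
    assert f.se_fc == pytest.approx(2 ** -0.5, rel=1e-12)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(diff=st.floats(-4, 4), se=st.floats(0.01, 2.0), df=st.floats(2, 200))
def test_back_transform_consistency_properties(diff, se, df):
    from scipy import stats
    c = ContrastResult(name="g:e", diff=diff, se=se, df=df,
                       t_stat=diff / se, p_nominal=0.5)
    f = to_fold_change(c)
    assert f.ci_low <= f.fc <= f.ci_high
    assert np.sqrt(f.ci_low * f.ci_high) == pytest.approx(f.fc, rel=1e-9)
    tq = stats.t.ppf(0.975, df)
    assert np.log2(f.ci_high / f.ci_low) == pytest.approx(2 * tq * se, rel=1e-9)
    # direction convention: fc > 1 iff diff < 0 (higher expression, first class)
    if diff < -1e-9:
        assert f.fc > 1
    elif diff > 1e-9:
        assert f.fc < 1


def test_invalid_contrast_rejected_by_back_transform():
    bad = ContrastResult(name="g:e", diff=0.0, se=0.0, df=10.0, t_stat=0.0, p_nominal=1.0)
    with pytest.raises(ValueError):
        to_fold_change(bad)


# ---------------------------------------------------------------------------
# effective number of tests and BH adjustment
# ---------------------------------------------------------------------------

def test_effective_tests_identity_and_rank_one():
    assert effective_tests(np.eye(13)) == pytest.approx(13.0)
    assert effective_tests(np.ones((6, 6))) == pytest.approx(1.0)


def test_effective_tests_two_by_two_closed_form():
    corr = np.array([[1.0, 0.5], [0.5, 1.0]])
    # eigenvalues {1.5, 0.5}: Var = 0.5, m_eff = 1 + 1 * (1 - 0.5/2) = 1.75
    assert effective_tests(corr) == pytest.approx(1.75)


def test_effective_tests_rejects_asymmetric():
    with pytest.raises(ValueError):
        effective_tests(np.array([[1.0, 0.4], [0.2, 1.0]]))


def test_bh_with_meff_hand_computation():
    out = adjust_pvalues([0.01, 0.02, 0.03], m_eff=3.0)
    np.testing.assert_allclose(out, [0.03, 0.03, 0.03])


def test_single_p_with_unit_meff_unchanged():
    np.testing.assert_allclose(adjust_pvalues([0.2], m_eff=1.0), [0.2])


def test_adjust_rejects_invalid_p():
    with pytest.raises(ValueError):
        adjust_pvalues([0.1, 1.2], m_eff=2.0)
    with pytest.raises(ValueError):
        adjust_pvalues([-0.1], m_eff=2.0)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
       st.floats(1.0, 12.0))
def test_adjustment_properties(p, m_eff):
    p = np.array(p)
    adj = adjust_pvalues(p, m_eff)
    assert np.all(adj >= p - 1e-15)           # adjusted never undercuts nominal
    assert np.all(adj <= 1.0 + 1e-15)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in nominal rank
    # sandwich: Bonferroni-with-m_eff >= BH-with-m_eff >= nominal
    bonf = np.minimum(np.maximum(p * m_eff, p), 1.0)
    assert np.all(bonf >= adj - 1e-12)


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def test_correlation_matrix_symmetric_unit_diagonal(small_sim):
    sim, tdf = small_sim
    corr = correlation_matrix(tdf, ["LEP", "ACACA"], ["ACTB", "PPIA"])
    arr = corr.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 1.0)


def test_coregulated_genes_correlate_and_independent_do_not():
    rng = np.random.default_rng(8)
    n = 96
    rows = []
    shared = rng.normal(0, 0.5, n)
    indep = rng.normal(0, 0.5, n)
    loading = rng.normal(0, 0.3, n)
    for i in range(n):
        for gene, val in (("co1", shared[i]), ("co2", shared[i] * 1.3 + 0.4),
                          ("solo", indep[i]), ("REF", 0.0)):
            rows.append(dict(gene=gene, animal=f"a{i}", breed="Iberian", diet="HO",
                             status="fed", plate="p", box="b", replicate=1,
                             y=20 + val + loading[i]))
    tdf = pd.DataFrame(rows)
    corr = correlation_matrix(tdf, ["co1", "co2", "solo"], ["REF"])
    assert corr.loc["co1", "co2"] == pytest.approx(1.0, abs=0.02)
    assert abs(corr.loc["co1", "solo"]) < 0.15


def test_constant_gene_gets_zero_correlations():
    rng = np.random.default_rng(9)
    rows = []
    for i in range(10):
        for gene in ("flat", "varies", "REF"):
            val = 0.0 if gene in ("flat", "REF") else rng.normal()
            rows.append(dict(gene=gene, animal=f"a{i}", breed="Iberian", diet="HO",
                             status="fed", plate="p", box="b", replicate=1, y=20 + val))
    tdf = pd.DataFrame(rows)
    with pytest.warns(UserWarning, match="constant"):
        corr = correlation_matrix(tdf, ["flat", "varies"], ["REF"])
    assert corr.loc["flat", "varies"] == 0.0
    assert corr.loc["flat", "flat"] == 1.0


# ---------------------------------------------------------------------------
# contrasts over the joint fit
# ---------------------------------------------------------------------------

def test_breed_contrast_weights_reproduce_design(small_fit):
    design = q.treatment_design()
    w = contrast_weights(small_fit, design, "LEP", "breed")
    for label, weight in zip(small_fit.fixed_labels, w):
        gene, breed, _, _ = label
        if gene != "LEP":
            assert weight == 0.0
        else:
            assert weight == (0.25 if breed == "Iberian" else -0.25)
    assert w.sum() == pytest.approx(0.0, abs=1e-15)


def test_normalized_weights_subtract_reference_mean(small_fit):
    design = q.treatment_design()
    w = contrast_weights(small_fit, design, "LEP", "status",
                         references=("ACTB", "PPIA"), normalize=True)
    for label, weight in zip(small_fit.fixed_labels, w):
        gene, _, _, status = label
        sign = 0.25 if status == "fed" else -0.25
        if gene == "LEP":
            assert weight == pytest.approx(sign)
        elif gene in ("ACTB", "PPIA"):
            assert weight == pytest.approx(-sign / 2)
        else:
            assert weight == 0.0


def test_empty_reference_set_with_normalization_rejected(small_fit):
    design = q.treatment_design()
    with pytest.raises(ValueError, match="reference"):
        run_all_contrasts(small_fit, design, ["LEP"], [], normalize=True)


def test_overlapping_targets_and_references_rejected(small_fit):
    design = q.treatment_design()
    with pytest.raises(ValueError, match="disjoint"):
        run_all_contrasts(small_fit, design, ["LEP", "ACTB"], ["ACTB"], normalize=True)


def test_flat_reference_makes_normalization_innocuous():
    # references simulated with identical cell means: normalized and
    # unnormalized estimates agree on average over replicates
    diffs = []
    for rep in range(25):
        cfg = small_qpcr_config(seed=5000 + rep,
                                effects={"LEP": {"breed": -1.0}})
        sim = q.simulate_qpcr(cfg)
        tdf = q.transform_all(sim.wells, sim.efficiencies)
        fit = q.fit_reml(tdf)
        design = q.treatment_design()
        w_norm = contrast_weights(fit, design, "LEP", "breed", ("ACTB", "PPIA"), True)
        w_raw = contrast_weights(fit, design, "LEP", "breed")
        diffs.append(float(w_norm @ fit.beta) - float(w_raw @ fit.beta))
    mc_se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
    assert abs(np.mean(diffs)) <= 3 * mc_se + 1e-3


def test_direction_convention_on_study_table(study_fit):
    _, table = study_fit
    for _, row in table.iterrows():
        assert (row.fold_change > 1) == (row.diff_log2 < 0) or row.diff_log2 == 0


def test_analyze_table_schema_and_meff_range(study_fit):
    _, table = study_fit
    expected = {"gene", "effect", "fold_change", "ci_low", "ci_high",
                "p_value", "adjusted_p_value", "diff_log2", "se", "df"}
    assert expected <= set(table.columns)
    assert len(table) == 13 * 6
    assert 1.0 <= table.attrs["m_eff"] <= 13.0
    assert (table["adjusted_p_value"] >= table["p_value"] - 1e-12).all()
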