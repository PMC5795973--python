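import numpy as np
import pandas as pd
import pytest

import qpcrlmm as q
from qpcrlmm.mixed_model import (
    ContrastResult,
    ConvergenceError,
    MixedModel,
    RankDeficientError,
    cell_difference,
    qpcr_spec,
)

from conftest import (
    brute_force_reml_max,
    dense_gls_beta,
    dense_indicators,
    dense_reml_loglik,
    small_qpcr_config,
)


def tiny_tdf(seed=0, n_animals=4, replicates=2, genes=("A", "B"),
             n_plates=1, n_boxes=1,
             vc=(0.05, 0.02, 0.08, 0.06, 0.03)):
    """Hand-rolled generative draw: 2 cells (fed/fasting), one breed and diet."""
    rng = np.random.default_rng(seed)
    sp, sb, sa, sd, se = np.sqrt(vc)
    animals = [f"a{i}" for i in range(n_animals)]
    plates = {a: f"p{i % n_plates}" for i, a in enumerate(animals)}
    boxes = {a: f"b{i % n_boxes}" for i, a in enumerate(animals)}
    P = {(g, p): rng.normal(0, sp) for g in genes for p in set(plates.values())}
    B = {(g, b): rng.normal(0, sb) for g in genes for b in set(boxes.values())}
    A = {(g, a): rng.normal(0, sa) for g in genes for a in animals}
    D = {(a, s): rng.normal(0, sd) for a in animals for s in ("fed", "fasting")}
    mu = {(g, s): 20.0 + i + (0.5 if s == "fed" else 0.0)
          for i, g in enumerate(genes) for s in ("fed", "fasting")}
    rows = []
    for a in animals:
        for s in ("fed", "fasting"):
            for g in genes:
                for r in range(replicates):
                    y = (mu[(g, s)] + P[(g, plates[a])] + B[(g, boxes[a])]
                         + A[(g, a)] + D[(a, s)] + rng.normal(0, se))
                    rows.append((g, a, "Iberian", "HO", s, plates[a], boxes[a], r + 1, y))
    return pd.DataFrame(rows, columns=["gene", "animal", "breed", "diet", "status",
                                       "plate", "box", "replicate", "y"])


def test_noise_free_balanced_fit_interpolates_cell_means():
    tdf = tiny_tdf(seed=1, vc=(0, 0, 0, 0, 0))
    fit = q.fit_reml(tdf)
    for label, beta in zip(fit.fixed_labels, fit.beta):
        gene, _, _, status = label
        expected = tdf[(tdf.gene == gene) & (tdf.status == status)]["y"].iloc[0]
        assert beta == pytest.approx(expected, abs=1e-8)
    assert all(v == pytest.approx(0.0, abs=1e-8) for v in fit.vc.values())


def test_tiny_instance_matches_brute_force_oracle():
    tdf = tiny_tdf(seed=3)
    spec = qpcr_spec(tdf)
    fit = q.fit_reml(tdf, spec=spec)
    y = tdf["y"].to_numpy()
    Zs = dense_indicators(spec)
    oracle = brute_force_reml_max(y, spec.X, Zs)
    assert fit.reml_loglik == pytest.approx(oracle, abs=1e-6)
    # beta solves the GLS (mixed-model) equations at the fitted components
    vc_vec = np.array([fit.vc[n] for n in spec.random_effects] + [fit.sigma2_e])
    np.testing.assert_allclose(fit.beta, dense_gls_beta(y, spec.X, Zs, vc_vec), atol=1e-7)


def test_reml_loglik_agrees_with_dense_formula():
    tdf = tiny_tdf(seed=5)
    spec = qpcr_spec(tdf)
    model = MixedModel(tdf["y"].to_numpy(), spec)
    vc = np.array([0.02, 0.01, 0.05, 0.03, 0.04])
    dense = dense_reml_loglik(tdf["y"].to_numpy(), spec.X, dense_indicators(spec), vc)
    assert model.reml_loglik(vc) == pytest.approx(dense, abs=1e-8)
    # dict form addresses components by grouping name
    as_dict = dict(zip(spec.random_effects, vc[:-1])) | {"residual": vc[-1]}
    assert model.reml_loglik(as_dict) == pytest.approx(dense, abs=1e-8)


def test_reml_loglik_ols_limit():
    # all component variances 0 reduces to the OLS residual restricted likelihood
    tdf = tiny_tdf(seed=7)
    spec = qpcr_spec(tdf)
    model = MixedModel(tdf["y"].to_numpy(), spec)
    y, X = tdf["y"].to_numpy(), spec.X
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    s2 = 0.013
    # log|V| = n log s2; log|X'V^-1 X| = log|X'X| - p log s2
    _, ldxx = np.linalg.slogdet(X.T @ X)
    expected = -0.5 * ((n - p) * np.log(2 * np.pi) + (n - p) * np.log(s2)
                       + ldxx + r @ r / s2)
    got = model.reml_loglik(np.array([0, 0, 0, 0, s2]))
    assert got == pytest.approx(expected, abs=1e-8)


def test_reml_loglik_scale_identity():
    # scaling all variances by c shifts the likelihood by a closed-form term
    tdf = tiny_tdf(seed=9)
    spec = qpcr_spec(tdf)
    model = MixedModel(tdf["y"].to_numpy(), spec)
    vc = np.array([0.02, 0.01, 0.05, 0.03, 0.04])
    y, X, Zs = tdf["y"].to_numpy(), spec.X, dense_indicators(spec)
    n, p = X.shape
    V = vc[-1] * np.eye(n)
    for Z, s2 in zip(Zs, vc[:-1]):
        V += s2 * Z @ Z.T
    Vi = np.linalg.inv(V)
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    quad = float(y @ P @ y)
    c = 2.0
    expected_shift = -0.5 * ((n - p) * np.log(c) + quad * (1 / c - 1))
    assert (model.reml_loglik(c * vc) - model.reml_loglik(vc)
            == pytest.approx(expected_shift, abs=1e-8))


def test_local_optimality_no_better_grid_neighbor():
    tdf = tiny_tdf(seed=11)
    spec = qpcr_spec(tdf)
    model = MixedModel(tdf["y"].to_numpy(), spec)
    fit = q.fit_reml(tdf, spec=spec)
    base = np.array([max(fit.vc[n], 1e-10) for n in spec.random_effects] + [fit.sigma2_e])
    best = model.reml_loglik(np.array([fit.vc[n] for n in spec.random_effects]
                                      + [fit.sigma2_e]))
    for i in range(len(base)):
        for f in (0.8, 1.2):
            cand = base.copy()
            cand[i] *= f
            assert model.reml_loglik(cand) <= best + 1e-7


def test_equivariance_under_per_gene_shift():
    tdf = tiny_tdf(seed=13, genes=("A", "B", "C"), n_plates=2, n_boxes=2)
    shifted = tdf.copy()
    shifted.loc[shifted.gene == "B", "y"] += 5.0
    spec1, spec2 = qpcr_spec(tdf), qpcr_spec(shifted)
    m1 = MixedModel(tdf["y"].to_numpy(), spec1)
    m2 = MixedModel(shifted["y"].to_numpy(), spec2)
    # sharp invariance: the restricted likelihood surface is unchanged by a
    # per-gene shift, at any candidate variance components
    for vc in (np.array([0.02, 0.01, 0.05, 0.03, 0.04]),
               np.array([0.0, 0.0, 0.1, 0.0, 0.02])):
        assert m2.reml_loglik(vc) == pytest.approx(m1.reml_loglik(vc), abs=1e-8)
    fit1, fit2 = m1.fit(), m2.fit()
    for name in fit1.vc:
        assert fit2.vc[name] == pytest.approx(fit1.vc[name], rel=0.02, abs=1e-4)
    for label, b1 in zip(fit1.fixed_labels, fit1.beta):
        b2 = fit2.beta[fit2.index_of(label)]
        expected = b1 + (5.0 if label[0] == "B" else 0.0)
        assert b2 == pytest.approx(expected, abs=1e-4)
    # a within-gene status contrast in an unshifted gene is untouched
    c1 = cell_difference(fit1, ("A", "Iberian", "HO", "fed"), ("A", "Iberian", "HO", "fasting"))
    c2 = cell_difference(fit2, ("A", "Iberian", "HO", "fed"), ("A", "Iberian", "HO", "fasting"))
    assert c2.diff == pytest.approx(c1.diff, abs=1e-4)
    assert c2.se == pytest.approx(c1.se, rel=1e-2)


def test_cross_check_against_statsmodels_single_grouping():
    import statsmodels.api as sm
    from qpcrlmm.mixed_model import MixedModelSpec

    rng = np.random.default_rng(21)
    n_groups, per = 12, 5
    groups = np.repeat([f"g{i}" for i in range(n_groups)], per)
    x = rng.normal(size=n_groups * per)
    u = rng.normal(0, 0.7, n_groups)
    y = 1.0 + 0.5 * x + u[np.repeat(np.arange(n_groups), per)] + rng.normal(0, 0.4, len(x))
    X = np.column_stack([np.ones_like(x), x])
    spec = MixedModelSpec(X=X, fixed_labels=["intercept", "slope"],
                          random_effects={"group": groups})
    fit = MixedModel(y, spec).fit()
    sm_fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    np.testing.assert_allclose(fit.beta, sm_fit.fe_params, rtol=1e-4)
    assert fit.vc["group"] == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3)
    assert fit.sigma2_e == pytest.approx(float(sm_fit.scale), rel=1e-3)


def test_variance_component_recovery_simulation():
    # moderate-scale recovery: estimates unbiased within 3 Monte-Carlo SEs
    truth = dict(q.synthetic_data.DEFAULT_VARIANCE_COMPONENTS)
    estimates = {k: [] for k in truth}
    reps = 40
    for rep in range(reps):
        cfg = small_qpcr_config(seed=1000 + rep, genes=("LEP", "ACACA", "SCD"),
                                n_iberian=12, n_duroc=10, n_boxes=8, n_litters=8,
                                diet_counts={("Iberian", "HO"): 6, ("Iberian", "CH"): 6,
                                             ("Duroc", "HO"): 5, ("Duroc", "CH"): 5})
        sim = q.simulate_qpcr(cfg)
        tdf = q.transform_all(sim.wells, sim.efficiencies)
        fit = q.fit_reml(tdf)
        for name in ("plate", "box", "animal", "sample"):
            estimates[name].append(fit.vc[name])
        estimates["residual"].append(fit.sigma2_e)
    for name, vals in estimates.items():
        mean, mc_se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(mean - truth[name]) <= 3 * mc_se + 1e-4, (name, mean, truth[name])


def test_contrast_error_contracts(small_fit):
    p = len(small_fit.fixed_labels)
    with pytest.raises(ValueError, match="zero"):
        small_fit.contrast(np.zeros(p))
    bad = np.zeros(p)
    bad[0] = 1.0  # does not sum to zero
    with pytest.raises(ValueError, match="sum"):
        small_fit.contrast(bad)
    with pytest.raises(ValueError, match="length"):
        small_fit.contrast(np.zeros(p + 1))


def test_cell_difference_of_cell_with_itself(small_fit):
    label = small_fit.fixed_labels[0]
    c = cell_difference(small_fit, label, label)
    assert c.diff == 0.0 and c.p_nominal == 1.0


def test_contrast_t_and_p_consistency(small_fit):
    labels = small_fit.fixed_labels
    c = cell_difference(small_fit, labels[0], labels[1])
    assert c.t_stat == pytest.approx(c.diff / c.se)
    assert 0.0 <= c.p_nominal <= 1.0 and c.se > 0 and c.df >= 1


def test_rank_deficiency_names_empty_cells():
    tdf = tiny_tdf(seed=2)
    spec = qpcr_spec(tdf)
    X = np.hstack([spec.X, np.zeros((spec.X.shape[0], 1))])
    from qpcrlmm.mixed_model import MixedModelSpec
    bad = MixedModelSpec(X=X, fixed_labels=spec.fixed_labels + [("ghost", "cell")],
                         random_effects=spec.random_effects)
    with pytest.raises(RankDeficientError, match="ghost"):
        MixedModel(tdf["y"].to_numpy(), bad)


def test_nonconvergence_raises_with_last_iterate():
    tdf = tiny_tdf(seed=4)
    model = MixedModel(tdf["y"].to_numpy(), qpcr_spec(tdf))
    with pytest.raises(ConvergenceError) as err:
        model.fit(maxiter=0, polish=False)
    assert err.value.last_iterate is not None


def test_satterthwaite_df_spread_is_contrast_specific(study_fit):
    fit, table = study_fit
    dfs = table["df"].to_numpy()
    assert np.all(np.isfinite(dfs)) and np.all(dfs >= 2)
    # fractional, contrast-specific df spanning a wide range
    assert dfs.max() / dfs.min() > 5
    assert any(abs(d - round(d)) > 1e-6 for d in dfs)


def test_fit_summary_serializable(small_fit):
    import json
    blob = json.dumps(small_fit.to_dict())
    assert "variance_components" in blob
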