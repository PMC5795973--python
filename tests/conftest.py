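"""Shared fixtures and independent oracles for the test suite.

The dense-matrix REML oracle here deliberately bypasses all of the package's
level-space linear algebra: it builds the full n x n marginal covariance and
evaluates the textbook restricted-likelihood formula, so agreement with the
package is a genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import qpcrlmm as q


def dense_indicators(spec) -> list[np.ndarray]:
    """Dense indicator matrix per random grouping of a MixedModelSpec."""
    Zs = []
    for labels in spec.random_effects.values():
        codes, uniques = pd.factorize(np.asarray(labels), sort=True)
        Z = np.zeros((len(codes), len(uniques)))
        Z[np.arange(len(codes)), codes] = 1.0
        Zs.append(Z)
    return Zs


def dense_reml_loglik(y, X, Zs, vc) -> float:
    """Textbook restricted log-likelihood from the explicit n x n covariance."""
    y = np.asarray(y, float)
    n, p = X.shape
    V = vc[-1] * np.eye(n)
    for Z, s2 in zip(Zs, vc[:-1]):
        V += s2 * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld = np.linalg.slogdet(V)
    _, ld2 = np.linalg.slogdet(XtViX)
    return float(-0.5 * ((n - p) * np.log(2 * np.pi) + ld + ld2 + r @ Vi @ r))


def dense_gls_beta(y, X, Zs, vc) -> np.ndarray:
    """Generalized-least-squares fixed effects at given variance components."""
    n = X.shape[0]
    V = vc[-1] * np.eye(n)
    for Z, s2 in zip(Zs, vc[:-1]):
        V += s2 * Z @ Z.T
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


def brute_force_reml_max(y, X, Zs) -> float:
    """Grid + Nelder-Mead polish of the dense restricted likelihood.

    Searches log-variances of every component (and the residual) over a
    coarse grid anchored at the OLS residual variance, then polishes from the
    best grid point.  Independent of the package's optimizer and algebra.
    """
    y = np.asarray(y, float)
    K = len(Zs)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    v0 = max(float(np.var(y - X @ beta0, ddof=X.shape[1])), 1e-8)
    comp_grid = np.log(v0 * np.array([1e-6, 1e-3, 0.05, 0.3, 1.0]))
    resid_grid = np.log(v0 * np.array([0.01, 0.1, 0.5, 1.0]))

    def neg(logvc):
        return -dense_reml_loglik(y, X, Zs, np.exp(logvc))

    best_val, best_x = np.inf, None
    for combo in itertools.product(comp_grid, repeat=K):
        for lr in resid_grid:
            x = np.array(list(combo) + [lr])
            v = neg(x)
            if v < best_val:
                best_val, best_x = v, x
    res = minimize(neg, best_x, method="Nelder-Mead",
                   options=dict(maxiter=8000, maxfev=8000, xatol=1e-9, fatol=1e-13))
    res2 = minimize(neg, res.x, method="Nelder-Mead",
                    options=dict(maxiter=4000, maxfev=4000, xatol=1e-10, fatol=1e-14))
    return float(-min(res.fun, res2.fun))


def small_qpcr_config(seed=0, genes=("LEP", "ACACA"), refs=("ACTB", "PPIA"),
                      effects=None, **overrides) -> q.QpcrSimConfig:
    """A reduced two-breed design for fast simulation-based tests."""
    base = dict(
        n_iberian=8, n_duroc=6,
        diet_counts={("Iberian", "HO"): 4, ("Iberian", "CH"): 4,
                     ("Duroc", "HO"): 3, ("Duroc", "CH"): 3},
        target_genes=tuple(genes), reference_genes=tuple(refs),
        effects=effects or {}, n_boxes=4, n_litters=4, seed=seed,
    )
    base.update(overrides)
    return q.QpcrSimConfig(**base)


@pytest.fixture(scope="session")
def study_sim():
    """One full-size simulated study (15 genes, 49 animals, triplicates)."""
    sim = q.simulate_qpcr(q.QpcrSimConfig(seed=1234))
    tdf = q.transform_all(sim.wells, sim.efficiencies)
    return sim, tdf


@pytest.fixture(scope="session")
def study_fit(study_sim):
    """Joint fit and full contrast table on the study-scale simulation."""
    sim, tdf = study_sim
    fit = q.fit_reml(tdf)
    table = q.analyze(tdf, list(q.study.TARGET_GENES),
                      list(q.study.REFERENCE_GENES), fit=fit)
    return fit, table


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by fast tests."""
    sim = q.simulate_qpcr(small_qpcr_config(seed=42))
    tdf = q.transform_all(sim.wells, sim.efficiencies)
    return sim, tdf


@pytest.fixture(scope="session")
def small_fit(small_sim):
    _, tdf = small_sim
    return q.fit_reml(tdf)


@pytest.fixture(scope="session")
def small_fa_table():
    profiles = q.simulate_fa(q.FaSimConfig(seed=77))
    return q.fa_table(profiles, responses=["C16:0", "C18:0", "C18:1n-9",
                                           "C18:2n-6", "SFA", "MUFA"])
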