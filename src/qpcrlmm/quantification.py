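"""Fold-change estimation: contrasts, normalization, CIs and multiplicity.

For each target gene and each named effect (breed, status, diet and their
two-way interactions) a zero-sum contrast over the gene's treatment-cell
means is tested.  With reference-gene normalization on, the contrast applied
to the target is its own cell contrast *minus the mean of the same contrast
over the reference genes*, so the standard error reflects the combined
weight vector; with normalization off, the sample-shared random effect alone
absorbs loading differences.

Estimates live on the -log2 expression scale, so the back-transforms are
FC = 2^-diff, SE(FC) = 2^-SE, and the asymmetric 95 % interval
[2^-(diff + t * SE), 2^-(diff - t * SE)] with t the 97.5 % Student quantile at
the contrast's denominator df.  FC > 1 means higher expression in the
first-named class (Iberian, fed, HO).

Multiple testing uses Benjamini-Hochberg step-up with the number of tests
replaced by the effective number of tests m_eff from the eigenvalue
dispersion of the inter-gene correlation matrix (Cheverud-Nyholt):
m_eff = 1 + (M - 1) (1 - Var(lambda) / M), Var with denominator M - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TreatmentDesign, treatment_design
from .mixed_model import ContrastResult, ModelFit
from .reference_stability import collapse_wells

__all__ = [
    "FoldChangeResult",
    "MultiplicityAdjustment",
    "contrast_weights",
    "run_all_contrasts",
    "to_fold_change",
    "effective_tests",
    "adjust_pvalues",
    "correlation_matrix",
    "analyze",
    "EFFECT_NAMES",
]

EFFECT_NAMES = ("breed", "status", "diet", "breedxstatus", "breedxdiet", "dietxstatus")

# map public effect names to the design's contrast keys
_DESIGN_KEYS = {
    "breed": "breed", "status": "status", "diet": "diet",
    "breedxstatus": "breedxstatus", "breedxdiet": "breedxdiet",
    "dietxstatus": "dietxstatus",
}


@dataclass
class FoldChangeResult:
    """Back-transformed contrast: fold change with asymmetric 95 % CI.

    ``direction`` records which class is the numerator (the first-named
    class of the effect's factor).
    """

    gene: str
    effect: str
    fc: float
    se_fc: float
    ci_low: float
    ci_high: float
    direction: str = "first-named class in numerator"


@dataclass
class MultiplicityAdjustment:
    m: int
    m_eff: float
    eigenvalues: np.ndarray
    adjusted: np.ndarray


def contrast_weights(fit: ModelFit, design: TreatmentDesign, gene: str, effect: str,
                     references=(), normalize: bool = False) -> np.ndarray:
    """Weight vector over the fit's fixed cells for one gene x effect contrast."""
    key = _DESIGN_KEYS[effect]
    cw = design.contrasts[key]
    w = np.zeros(len(fit.fixed_labels))
    for ci, cell in enumerate(design.cells):
        w[fit.index_of((gene, *cell))] = cw[ci]
    if normalize:
        if not references:
            raise ValueError("normalization requested but the reference set is empty")
        for ref in references:
            for ci, cell in enumerate(design.cells):
                w[fit.index_of((ref, *cell))] -= cw[ci] / len(references)
    return w


def run_all_contrasts(fit: ModelFit, design: TreatmentDesign, targets, references,
                      normalize: bool = True,
                      effects=EFFECT_NAMES) -> list[ContrastResult]:
    """One ContrastResult per target gene and named effect."""
    targets = list(targets)
    references = list(references)
    if set(targets) & set(references):
        raise ValueError("target and reference gene sets must be disjoint")
    results = []
    for gene in targets:
        for effect in effects:
            w = contrast_weights(fit, design, gene, effect, references, normalize)
            c = fit.contrast(w, name=f"{gene}:{effect}")
            results.append(c)
    return results


def to_fold_change(c: ContrastResult, gene: str | None = None,
                   effect: str | None = None) -> FoldChangeResult:
    """Back-transform a contrast to a fold change with its asymmetric CI."""
    if not (c.se > 0):
        raise ValueError("contrast must carry a positive standard error")
    if not (c.df > 0):
        raise ValueError("contrast must carry positive degrees of freedom")
    tq = float(stats.t.ppf(0.975, c.df))
    if gene is None or effect is None:
        parts = c.name.split(":")
        gene = gene or (parts[0] if len(parts) == 2 else c.name)
        effect = effect or (parts[1] if len(parts) == 2 else "")
    return FoldChangeResult(
        gene=gene, effect=effect,
        fc=2.0 ** (-c.diff),
        se_fc=2.0 ** (-c.se),
        ci_low=2.0 ** (-(c.diff + tq * c.se)),
        ci_high=2.0 ** (-(c.diff - tq * c.se)),
    )


def effective_tests(corr: np.ndarray) -> float:
    """Effective number of tests from eigenvalue dispersion of a correlation.

    m_eff = 1 + (M - 1) (1 - Var(lambda)/M) with Var using denominator M - 1,
    clipped to [1, M].  Identity correlation gives M; a rank-one (all-ones)
    correlation gives 1.
    """
    corr = np.asarray(corr, float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    m = corr.shape[0]
    if m == 1:
        return 1.0
    lam = np.linalg.eigvalsh(corr)
    var_lam = float(np.var(lam, ddof=1))
    m_eff = 1.0 + (m - 1) * (1.0 - var_lam / m)
    return float(np.clip(m_eff, 1.0, m))


def adjust_pvalues(p, m_eff: float) -> np.ndarray:
    """BH step-up with the test count replaced by m_eff.

    Sort ascending, q_(i) = m_eff * p_(i) / i, enforce monotonicity from the
    largest rank down, clip at 1, return in the original order.
    """
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m_eff < 1:
        raise ValueError("m_eff must be at least 1")
    n = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, n + 1)
    q = m_eff * p[order] / ranks
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = np.maximum(q, p[order])  # an adjusted p never undercuts nominal
    return out


def correlation_matrix(tdf: pd.DataFrame, targets, references) -> pd.DataFrame:
    """Inter-gene Pearson correlation of reference-normalized sample means.

    Wells are collapsed to per-sample gene means, each sample's mean over the
    reference genes is subtracted, and target genes are correlated across
    samples.  A gene constant across samples gets zero correlations.
    """
    targets = list(targets)
    mat = collapse_wells(tdf)
    if mat.shape[0] < 3:
        raise ValueError("correlation needs at least 3 samples")
    ref_mean = mat[list(references)].mean(axis=1)
    norm = mat[targets].sub(ref_mean, axis=0)
    sds = norm.std(ddof=1)
    constant = [g for g in targets if sds[g] == 0 or not np.isfinite(sds[g])]
    if constant:
        warnings.warn(f"genes constant across samples: {constant}; correlations set to 0",
                      stacklevel=2)
    corr = norm.corr().fillna(0.0)
    for g in constant:
        corr.loc[g, :] = 0.0
        corr.loc[:, g] = 0.0
    np.fill_diagonal(corr.values, 1.0)
    return corr


def analyze(tdf: pd.DataFrame, targets, references, normalize: bool = True,
            fit: ModelFit | None = None, design: TreatmentDesign | None = None,
            adjust_per_effect: bool = True, **fit_kwargs) -> pd.DataFrame:
    """Full expression analysis on transformed observations.

    Fits the joint mixed model (unless a fit is supplied), runs all effect
    contrasts with reference normalization, back-transforms to fold changes
    with asymmetric CIs, and BH-adjusts p-values with the effective number of
    tests, by default within each effect family.  Returns a tidy results
    table with one row per gene x effect.
    """
    from .mixed_model import fit_reml

    design = design or treatment_design()
    if fit is None:
        fit = fit_reml(tdf, **fit_kwargs)
    results = run_all_contrasts(fit, design, targets, references, normalize=normalize)
    corr = correlation_matrix(tdf, targets, references)
    m_eff = effective_tests(corr.to_numpy())
    rows = []
    for c in results:
        gene, effect = c.name.split(":")
        f = to_fold_change(c, gene, effect)
        rows.append(dict(gene=gene, effect=effect, fold_change=f.fc,
                         ci_low=f.ci_low, ci_high=f.ci_high,
                         p_value=c.p_nominal, adjusted_p_value=np.nan,
                         diff_log2=c.diff, se=c.se, df=c.df))
    table = pd.DataFrame(rows)
    if adjust_per_effect:
        for effect in table["effect"].unique():
            mask = table["effect"] == effect
            table.loc[mask, "adjusted_p_value"] = adjust_pvalues(
                table.loc[mask, "p_value"].to_numpy(), m_eff)
    else:
        table["adjusted_p_value"] = adjust_pvalues(table["p_value"].to_numpy(), m_eff)
    table.attrs["m_eff"] = m_eff
    return table
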