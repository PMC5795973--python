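"""Reference-gene stability ranking (geNorm and NormFinder style).

Both measures operate on a per-sample expression matrix on the log2 scale
(technical replicates collapsed to one value per gene per sample — stability
concerns biological samples, not well noise).

geNorm's M value for gene j is the average, over every other candidate k, of
the standard deviation across samples of the pairwise log-ratio y_j - y_k;
perfectly co-regulated pairs contribute an SD of zero.  Ranking proceeds by
iteratively excluding the gene with the largest M and recomputing on the
remainder until two genes are left.

The NormFinder-style measure first removes sample loading by centering each
sample at its across-gene mean, then combines, per gene, the squared
between-group deviation with the sampling variance of the group mean:
mean over groups of sqrt(d_gj^2 + s2_gj / n_j).  With a single group it
reduces to the standard deviation of the gene's centered values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StabilityReport",
    "collapse_wells",
    "genorm_m",
    "genorm_rank",
    "normfinder_stability",
    "select_references",
    "compute_stability",
]


@dataclass
class StabilityReport:
    """Per-gene stability measures, ranks and the selected reference set."""

    genorm_m: pd.Series
    genorm_exclusion_order: list[str]
    normfinder: pd.Series
    selected: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        m_rank = self.genorm_m.rank(method="first").astype(int)
        nf_rank = self.normfinder.rank(method="first").astype(int)
        return pd.DataFrame({
            "gene": self.genorm_m.index,
            "genorm_m": self.genorm_m.values,
            "genorm_rank": m_rank.values,
            "normfinder_stability": self.normfinder.reindex(self.genorm_m.index).values,
            "normfinder_rank": nf_rank.reindex(self.genorm_m.index).values,
            "selected": [g in self.selected for g in self.genorm_m.index],
        }).reset_index(drop=True)


def collapse_wells(tdf: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Average wells to one y per (sample, gene): samples x genes matrix."""
    df = tdf if genes is None else tdf[tdf["gene"].isin(genes)]
    mat = df.pivot_table(index=["animal", "status"], columns="gene", values="y",
                         aggfunc="mean")
    mat.columns.name = None
    return mat


def _as_matrix(y_matrix: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(y_matrix, pd.DataFrame):
        y_matrix = pd.DataFrame(y_matrix)
    return y_matrix


def genorm_m(y_matrix: pd.DataFrame) -> pd.Series:
    """geNorm M value per gene (columns) from a samples x genes matrix."""
    y = _as_matrix(y_matrix)
    genes = list(y.columns)
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs at least 3 candidate genes")
    if y.shape[0] < 2:
        raise ValueError("geNorm needs at least 2 samples")
    vals = y.to_numpy(float)
    m = {}
    for j, gj in enumerate(genes):
        sds = [np.std(vals[:, j] - vals[:, k], ddof=1)
               for k in range(len(genes)) if k != j]
        m[gj] = float(np.mean(sds))
    return pd.Series(m).loc[genes]


def genorm_rank(y_matrix: pd.DataFrame) -> tuple[list[str], dict[str, float]]:
    """Iterative geNorm exclusion order (least stable first) and stepwise M.

    At each step the gene with the largest M on the remaining set is removed
    (ties broken by lexicographic gene identifier) until two genes remain.
    Returns the exclusion order over *all* candidates — the final surviving
    pair is appended in lexicographic order — and each gene's M at the step
    it was excluded.
    """
    y = _as_matrix(y_matrix).copy()
    order: list[str] = []
    stepwise: dict[str, float] = {}
    while y.shape[1] > 2:
        m = genorm_m(y)
        worst = sorted(m.index[m == m.max()])[0]
        order.append(worst)
        stepwise[worst] = float(m[worst])
        y = y.drop(columns=[worst])
    survivors = sorted(y.columns)
    pair_m = _pair_sd(y)
    for g in survivors:
        order.append(g)
        stepwise[g] = pair_m
    return order, stepwise


def _pair_sd(y: pd.DataFrame) -> float:
    vals = y.to_numpy(float)
    return float(np.std(vals[:, 0] - vals[:, 1], ddof=1))


def normfinder_stability(y_matrix: pd.DataFrame, groups) -> pd.Series:
    """NormFinder-style stability value per gene.

    ``groups`` maps each sample (row) to a group label (array-like aligned
    with the rows, or a mapping from row label to group).  Every group needs
    at least 2 samples.
    """
    y = _as_matrix(y_matrix)
    if y.shape[1] < 2:
        raise ValueError("NormFinder needs at least 2 genes")
    if isinstance(groups, dict):
        glabels = np.array([groups[i] for i in y.index])
    else:
        glabels = np.asarray(groups)
        if glabels.shape[0] != y.shape[0]:
            raise ValueError("groups length does not match the number of samples")
    vals = y.to_numpy(float)
    centered = vals - vals.mean(axis=1, keepdims=True)  # remove sample loading
    overall = centered.mean(axis=0)
    uniq = pd.unique(glabels)
    counts = {g: int(np.sum(glabels == g)) for g in uniq}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if len(uniq) == 1:
        rho = np.std(centered, axis=0, ddof=1)
        return pd.Series(rho, index=y.columns)
    rho = np.zeros(y.shape[1])
    for g in uniq:
        sub = centered[glabels == g]
        n_j = sub.shape[0]
        d = sub.mean(axis=0) - overall
        s2 = sub.var(axis=0, ddof=1)
        rho += np.sqrt(d ** 2 + s2 / n_j)
    rho /= len(uniq)
    return pd.Series(rho, index=y.columns)


def select_references(report: StabilityReport, n: int) -> tuple[str, ...]:
    """The n genes with the best (lowest) mean of geNorm and NormFinder ranks.

    Ties are broken by gene identifier.
    """
    genes = list(report.genorm_m.index)
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > len(genes):
        raise ValueError(f"cannot select {n} references from {len(genes)} candidates")
    m_rank = report.genorm_m.rank(method="average")
    nf_rank = report.normfinder.reindex(genes).rank(method="average")
    combined = (m_rank + nf_rank) / 2.0
    ordered = sorted(genes, key=lambda g: (combined[g], g))
    return tuple(sorted(ordered[:n]))


def compute_stability(y_matrix: pd.DataFrame, groups, n_select: int = 2) -> StabilityReport:
    """Run both stability measures and select the reference set."""
    m = genorm_m(y_matrix)
    order, _ = genorm_rank(y_matrix)
    nf = normfinder_stability(y_matrix, groups)
    report = StabilityReport(genorm_m=m, genorm_exclusion_order=order, normfinder=nf)
    report.selected = select_references(report, n_select)
    return report
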