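"""REML estimation of variance-component mixed models with contrast inference.

The model is

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k I),  e ~ N(0, sigma2_e I)

with crossed, independent, homoscedastic random groupings (one variance per
grouping).  For the joint qPCR analysis the fixed part is the gene x
treatment-cell mean structure and the groupings are plate-within-gene,
box-within-gene, animal-within-gene and biopsy sample (shared across genes);
the fatty-acid models reuse the same engine with breed x diet cells and
litter/box groupings.

Estimation profiles both the fixed effects and the residual variance out of
the restricted likelihood and optimizes the variance *ratios*
gamma_k = sigma2_k / sigma2_e by bounded quasi-Newton with an analytic
gradient (Nelder-Mead polish as fallback).  All linear algebra runs through
the level-space matrix M0 = I + S Z'Z S (S = diag(sqrt(gamma)) expanded to
levels), so the per-iteration cost is one Cholesky of a q x q matrix, with q
the total number of random-effect levels; ratios driven below 1e-8 are pinned
to exactly zero.  Denominator degrees of freedom for contrasts use the
Satterthwaite approximation from the observed information of the variance
parameters (containment df available as an alternative).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats

__all__ = [
    "ConvergenceError",
    "RankDeficientError",
    "MixedModelSpec",
    "MixedModel",
    "ModelFit",
    "ContrastResult",
    "qpcr_spec",
    "fit_reml",
    "reml_loglik",
    "cell_difference",
]

_PIN_TOL = 1e-8          # gamma below this is treated as exactly zero
_MAX_GAMMA = 1e6


class ConvergenceError(RuntimeError):
    """REML optimization failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class RankDeficientError(ValueError):
    """The fixed-effect design is rank deficient; names the offending cells."""


@dataclass
class MixedModelSpec:
    """Design for one fit: fixed-effect matrix plus random groupings.

    ``random_effects`` maps grouping name to a per-observation array of level
    labels; every observation belongs to exactly one level of each grouping.
    """

    X: np.ndarray
    fixed_labels: list
    random_effects: dict[str, np.ndarray]


@dataclass
class ContrastResult:
    """A linear contrast of fixed effects with its t-based inference."""

    name: str
    diff: float
    se: float
    df: float
    t_stat: float
    p_nominal: float
    p_adjusted: float | None = None


@dataclass
class ModelFit:
    """REML estimates: fixed effects, variance components and covariances."""

    beta: np.ndarray
    fixed_labels: list
    vc: dict[str, float]          # per-grouping variances, squared log2 units
    sigma2_e: float
    cov_beta: np.ndarray
    reml_loglik: float
    n_obs: int
    n_params: int
    converged: bool
    n_iter: int
    df_method: str = "satterthwaite"
    _model: "MixedModel | None" = field(default=None, repr=False)

    def index_of(self, label) -> int:
        return self.fixed_labels.index(label)

    def contrast(self, weights: np.ndarray, name: str = "contrast") -> ContrastResult:
        """Estimate ``weights . beta`` with SE, approximate df and p-value."""
        if self._model is None:
            raise RuntimeError("fit is detached from its model; cannot compute contrasts")
        return self._model.estimate_contrast(self, weights, name)

    def to_dict(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "beta": {str(l): float(b) for l, b in zip(self.fixed_labels, self.beta)},
            "variance_components": {k: float(v) for k, v in self.vc.items()},
            "sigma2_e": float(self.sigma2_e),
            "reml_loglik": float(self.reml_loglik),
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "df_method": self.df_method,
        }


def _encode(labels: np.ndarray) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(labels, sort=True)
    return codes.astype(np.int64), len(uniques)


class MixedModel:
    """Precomputed cross-products and REML machinery for one design."""

    def __init__(self, y: np.ndarray, spec: MixedModelSpec):
        y = np.asarray(y, float)
        X = np.asarray(spec.X, float)
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("y and X have incompatible shapes")
        self._check_rank(X, spec.fixed_labels)
        self.y, self.X, self.n, self.p = y, X, n, p
        self.spec = spec
        self.names = list(spec.random_effects)
        self.K = len(self.names)

        codes, sizes = [], []
        for name in self.names:
            c, m = _encode(np.asarray(spec.random_effects[name]))
            codes.append(c)
            sizes.append(m)
        self.block_sizes = sizes
        self.q = int(sum(sizes))
        offsets = np.cumsum([0] + sizes)
        self.block_slices = [slice(offsets[k], offsets[k + 1]) for k in range(self.K)]

        if self.q:
            rows = np.tile(np.arange(n), self.K)
            cols = np.concatenate([codes[k] + offsets[k] for k in range(self.K)])
            Z = sp.csr_matrix(
                (np.ones(n * self.K), (rows, cols)), shape=(n, self.q)
            )
            self.Z = Z
            self.A = np.asarray((Z.T @ Z).todense())
            self.B = X.T @ Z  # p x q, dense
            self.Zty = Z.T @ y
        else:
            self.Z = None
            self.A = np.zeros((0, 0))
            self.B = np.zeros((p, 0))
            self.Zty = np.zeros(0)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    @staticmethod
    def _check_rank(X: np.ndarray, labels) -> None:
        norms = np.linalg.norm(X, axis=0)
        empty = [labels[i] for i in np.nonzero(norms == 0)[0]]
        if empty:
            raise RankDeficientError(f"fixed-effect cells with no observations: {empty}")
        s = np.linalg.svd(X, compute_uv=False)
        if s[-1] < s[0] * 1e-10:
            _, _, v = np.linalg.svd(X)
            involved = [labels[i] for i in np.nonzero(np.abs(v[-1]) > 0.3)[0]]
            raise RankDeficientError(f"collinear fixed-effect cells: {involved}")

    # -- core linear algebra --------------------------------------------------

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        """Per-level sqrt(gamma) vector from per-grouping ratios."""
        s = np.empty(self.q)
        for k, sl in enumerate(self.block_slices):
            s[sl] = math.sqrt(max(gamma[k], 0.0))
        return s

    def _core(self, gamma: np.ndarray, need_grad: bool = False) -> dict:
        """Profiled REML pieces at variance ratios ``gamma``.

        Returns log|V0|, log|X'V0^-1 X|, beta, the residual quadratic form
        y'P0 y, and (optionally) the analytic gradient ingredients.
        """
        X, p, n = self.X, self.p, self.n
        if self.q:
            s = self._expand(np.maximum(gamma, 0.0))
            M0 = self.A * s[:, None] * s[None, :]
            M0[np.diag_indices_from(M0)] += 1.0
            L = sla.cholesky(M0, lower=True, check_finite=False)
            logdetV0 = 2.0 * float(np.sum(np.log(np.diag(L))))
            G = sla.solve_triangular(L, s[:, None] * self.B.T, lower=True, check_finite=False)
            chat = sla.solve_triangular(L, s * self.Zty, lower=True, check_finite=False)
            C0 = self.XtX - G.T @ G
            Xv_y = self.Xty - G.T @ chat
            ytVy = self.yty - float(chat @ chat)
        else:
            s = np.zeros(0)
            L = None
            logdetV0 = 0.0
            G = np.zeros((0, p))
            chat = np.zeros(0)
            C0 = self.XtX.copy()
            Xv_y = self.Xty.copy()
            ytVy = self.yty
        LC = sla.cholesky(C0, lower=True, check_finite=False)
        logdetC0 = 2.0 * float(np.sum(np.log(np.diag(LC))))
        beta = sla.cho_solve((LC, True), Xv_y, check_finite=False)
        quad = max(ytVy - float(Xv_y @ beta), 1e-300)
        out = dict(logdetV0=logdetV0, logdetC0=logdetC0, beta=beta, quad=quad,
                   C0=C0, LC=LC, s=s, L=L, G=G, chat=chat)
        if need_grad and self.q:
            F = sla.solve_triangular(L, s[:, None] * self.A, lower=True, check_finite=False)
            XvZ = self.B - G.T @ F                       # X' V0^-1 Z
            ZvZ_y = self.Zty - F.T @ chat                # Z' V0^-1 y
            Zpy = ZvZ_y - XvZ.T @ beta                   # Z' P0 y
            H = sla.solve_triangular(LC, XvZ, lower=True, check_finite=False)
            out.update(F=F, H=H, Zpy=Zpy)
        return out

    def profiled_neg2(self, gamma: np.ndarray, grad: bool = False):
        """-2 restricted log-likelihood profiled over beta and sigma2_e."""
        c = self._core(gamma, need_grad=grad)
        n, p = self.n, self.p
        sigma2 = c["quad"] / (n - p)
        val = ((n - p) * (math.log(2 * math.pi) + 1.0)
               + (n - p) * math.log(sigma2) + c["logdetV0"] + c["logdetC0"])
        if not grad:
            return val
        g = np.zeros(self.K)
        for k, sl in enumerate(self.block_slices):
            tr_ZvZ = float(np.trace(self.A[sl, sl])) - float(np.sum(c["F"][:, sl] ** 2))
            tr_corr = float(np.sum(c["H"][:, sl] ** 2))
            u = c["Zpy"][sl]
            g[k] = (tr_ZvZ - tr_corr) - float(u @ u) / sigma2
        return val, g

    # -- likelihood on the variance scale (oracle hook) -----------------------

    def reml_loglik(self, vc: np.ndarray | dict) -> float:
        """Exact restricted log-likelihood at given variance components.

        ``vc`` holds one variance per grouping (in grouping order, or as a
        mapping by name) followed by / plus the residual variance under the
        key ``"residual"``.  Exposed so tests can grid-search independently of
        the optimizer.
        """
        if isinstance(vc, dict):
            arr = np.array([vc[name] for name in self.names] + [vc["residual"]], float)
        else:
            arr = np.asarray(vc, float)
            if arr.shape[0] != self.K + 1:
                raise ValueError(f"expected {self.K + 1} variances (components + residual)")
        if np.any(arr < 0):
            raise ValueError("variance components must be non-negative")
        sigma2 = arr[-1]
        if sigma2 <= 0:
            raise np.linalg.LinAlgError("singular marginal covariance: residual variance 0")
        gamma = arr[:-1] / sigma2
        c = self._core(gamma)
        n, p = self.n, self.p
        neg2 = ((n - p) * math.log(2 * math.pi) + (n - p) * math.log(sigma2)
                + c["logdetV0"] + c["logdetC0"] + c["quad"] / sigma2)
        return -0.5 * neg2

    # -- fitting ---------------------------------------------------------------

    def fit(self, n_starts: int = 2, maxiter: int = 500, polish: bool | None = None,
            df_method: str = "satterthwaite") -> ModelFit:
        """Maximize the restricted likelihood and assemble a :class:`ModelFit`.

        Variance ratios are optimized by L-BFGS-B with the analytic gradient
        from ``n_starts`` starting points; components whose ratio collapses
        below 1e-8 are pinned to zero.  A Nelder-Mead polish runs whenever the
        quasi-Newton path ends without a clean convergence signal (or always,
        on small problems, where its cost is negligible).
        """
        if self.K == 0:
            return self._assemble(np.zeros(0), converged=True, n_iter=0, df_method=df_method)
        # perfect interpolation (all noise sources zero): OLS solves it exactly
        ols = self._core(np.zeros(self.K))
        scale = max(self.yty / max(self.n, 1), 1.0)
        if ols["quad"] / (self.n - self.p) < 1e-14 * scale:
            return self._assemble(np.zeros(self.K), converged=True, n_iter=0,
                                  df_method=df_method)
        starts = [np.full(self.K, 0.5), np.full(self.K, 0.05), np.full(self.K, 2.0)]
        starts = starts[:max(1, n_starts)]
        best = None
        nit = 0
        for i, x0 in enumerate(starts):
            try:
                res = optimize.minimize(
                    lambda g: self.profiled_neg2(g, grad=True), x0,
                    jac=True, method="L-BFGS-B",
                    bounds=[(0.0, _MAX_GAMMA)] * self.K,
                    options=dict(maxiter=maxiter, ftol=1e-10, gtol=1e-6),
                )
            except np.linalg.LinAlgError:
                continue
            nit += res.nit
            if best is None or res.fun < best.fun:
                best = res
            # remaining starts are restarts: only taken if this one failed
            if i == 0 and res.success:
                break
        if best is None:
            raise ConvergenceError("all REML starts failed with singular systems")
        if polish is None:
            polish = (not best.success) or self.n <= 200
        x, fval = best.x.copy(), float(best.fun)
        if polish:
            nm = optimize.minimize(
                lambda g: self.profiled_neg2(np.maximum(g, 0.0)), x,
                method="Nelder-Mead",
                options=dict(maxiter=200 * self.K, xatol=1e-9, fatol=1e-11),
            )
            nit += nm.nit
            if nm.fun < fval:
                x, fval = np.maximum(nm.x, 0.0), float(nm.fun)
        # projected-gradient convergence check at the solution
        _, g = self.profiled_neg2(x, grad=True)
        pg = np.where((x <= _PIN_TOL) & (g > 0), 0.0, g)
        converged = bool(best.success or np.max(np.abs(pg)) < 1e-4 * max(1.0, abs(fval)))
        if not converged and nit >= maxiter:
            raise ConvergenceError(
                f"REML did not converge within {maxiter} iterations", last_iterate=x)
        x[x < _PIN_TOL] = 0.0
        return self._assemble(x, converged=converged, n_iter=nit, df_method=df_method)

    def _assemble(self, gamma: np.ndarray, converged: bool, n_iter: int,
                  df_method: str) -> ModelFit:
        c = self._core(gamma)
        n, p = self.n, self.p
        sigma2 = max(c["quad"] / (n - p), 1e-30)
        cov_beta = sigma2 * sla.cho_solve((c["LC"], True), np.eye(p), check_finite=False)
        cov_beta = 0.5 * (cov_beta + cov_beta.T)
        ll = -0.5 * ((n - p) * (math.log(2 * math.pi) + 1.0)
                     + (n - p) * math.log(sigma2) + c["logdetV0"] + c["logdetC0"])
        vc = {name: float(gamma[k] * sigma2) for k, name in enumerate(self.names)}
        fit = ModelFit(
            beta=c["beta"], fixed_labels=list(self.spec.fixed_labels), vc=vc,
            sigma2_e=float(sigma2), cov_beta=cov_beta, reml_loglik=float(ll),
            n_obs=n, n_params=p, converged=converged, n_iter=n_iter,
            df_method=df_method, _model=self,
        )
        self._satt_cache: dict | None = None
        return fit

    # -- contrast inference ----------------------------------------------------

    def _cov_beta_at(self, theta: np.ndarray) -> np.ndarray:
        """cov(beta) at variance parameters theta = (sigma2_k..., sigma2_e)."""
        sigma2 = theta[-1]
        gamma = np.maximum(theta[:-1], 0.0) / sigma2
        c = self._core(gamma)
        return sigma2 * sla.cho_solve((c["LC"], True), np.eye(self.p), check_finite=False)

    def _satterthwaite_machinery(self, fit: ModelFit) -> dict:
        """Observed information of the variance parameters and dC/dtheta."""
        if getattr(self, "_satt_cache", None) is not None:
            return self._satt_cache
        theta = np.array([fit.vc[nm] for nm in self.names] + [fit.sigma2_e])
        free = [i for i in range(len(theta)) if theta[i] > 0]
        d = len(free)
        h = np.array([1e-4 * max(theta[i], 1e-6) for i in free])

        def ll(th):
            return self.reml_loglik(np.maximum(th, 1e-12))

        # Hessian of the restricted log-likelihood by central differences
        H = np.zeros((d, d))
        f0 = ll(theta)
        for a in range(d):
            ta, tb = theta.copy(), theta.copy()
            ta[free[a]] += h[a]
            tb[free[a]] -= h[a]
            H[a, a] = (ll(ta) - 2 * f0 + ll(tb)) / h[a] ** 2
        for a in range(d):
            for b in range(a + 1, d):
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[free[a]] += h[a]; tpp[free[b]] += h[b]
                tpm[free[a]] += h[a]; tpm[free[b]] -= h[b]
                tmp[free[a]] -= h[a]; tmp[free[b]] += h[b]
                tmm[free[a]] -= h[a]; tmm[free[b]] -= h[b]
                H[a, b] = H[b, a] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h[a] * h[b])
        try:
            vcov_theta = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            vcov_theta = np.linalg.pinv(-H)
        # derivative of cov(beta) w.r.t. each free variance parameter
        dC = []
        for a in range(d):
            tp, tm = theta.copy(), theta.copy()
            tp[free[a]] += h[a]
            tm[free[a]] = max(tm[free[a]] - h[a], 1e-12)
            dC.append((self._cov_beta_at(tp) - self._cov_beta_at(tm)) / (tp[free[a]] - tm[free[a]]))
        self._satt_cache = dict(free=free, vcov_theta=vcov_theta, dC=dC)
        return self._satt_cache

    def estimate_contrast(self, fit: ModelFit, weights: np.ndarray,
                          name: str = "contrast") -> ContrastResult:
        """t-test of a zero-sum contrast of the fixed effects.

        The denominator df comes from the Satterthwaite approximation
        2 g^2 / Var(g) with g = w' cov(beta) w, using the observed information
        of the variance parameters; boundary (zero) components are held fixed.
        """
        w = np.asarray(weights, float)
        if w.shape[0] != self.p:
            raise ValueError("contrast length does not match the number of fixed effects")
        if np.all(w == 0):
            raise ValueError("contrast weights are all zero")
        if abs(w.sum()) > 1e-8 * max(1.0, np.abs(w).max()):
            raise ValueError("contrast weights must sum to zero")
        diff = float(w @ fit.beta)
        g = float(w @ fit.cov_beta @ w)
        se = math.sqrt(max(g, 0.0))
        if fit.df_method == "containment":
            df = float(max(self.n - self.p - self.q, 1))
        else:
            m = self._satterthwaite_machinery(fit)
            grad = np.array([float(w @ dC @ w) for dC in m["dC"]])
            denom = float(grad @ m["vcov_theta"] @ grad)
            df = 2.0 * g * g / denom if denom > 0 else float(self.n - self.p)
            df = float(np.clip(df, 1.0, self.n - self.p))
        t = diff / se if se > 0 else 0.0
        p = 2.0 * float(stats.t.sf(abs(t), df)) if se > 0 else 1.0
        return ContrastResult(name=name, diff=diff, se=se, df=df, t_stat=t, p_nominal=p)


# ---------------------------------------------------------------------------
# qPCR joint-model design and functional wrappers
# ---------------------------------------------------------------------------

def qpcr_spec(tdf: pd.DataFrame) -> MixedModelSpec:
    """Build the joint gene-expression design from transformed observations.

    Fixed effects: one mean per (gene, breed, diet, status) cell.  Random
    groupings: plate-within-gene, box-within-gene, animal-within-gene and the
    biopsy sample (animal x status), shared across genes.
    """
    cell = list(zip(tdf["gene"], tdf["breed"], tdf["diet"], tdf["status"]))
    codes, uniques = pd.factorize(pd.Series(cell), sort=True)
    p = len(uniques)
    X = np.zeros((len(tdf), p))
    X[np.arange(len(tdf)), codes] = 1.0
    gene = tdf["gene"].astype(str)
    random_effects = {
        "plate": (gene + "|" + tdf["plate"].astype(str)).to_numpy(),
        "box": (gene + "|" + tdf["box"].astype(str)).to_numpy(),
        "animal": (gene + "|" + tdf["animal"].astype(str)).to_numpy(),
        "sample": (tdf["animal"].astype(str) + "|" + tdf["status"].astype(str)).to_numpy(),
    }
    return MixedModelSpec(X=X, fixed_labels=list(uniques), random_effects=random_effects)


def fit_reml(tdf: pd.DataFrame, spec: MixedModelSpec | None = None, **kwargs) -> ModelFit:
    """Fit the joint mixed model to transformed observations (``y`` column)."""
    if spec is None:
        spec = qpcr_spec(tdf)
    model = MixedModel(tdf["y"].to_numpy(float), spec)
    return model.fit(**kwargs)


def reml_loglik(tdf: pd.DataFrame, spec: MixedModelSpec, vc) -> float:
    """Restricted log-likelihood at candidate variance components (oracle hook)."""
    model = MixedModel(tdf["y"].to_numpy(float), spec)
    return model.reml_loglik(vc)


def cell_difference(fit: ModelFit, label_a, label_b, name: str = "difference") -> ContrastResult:
    """Difference between two fixed-effect cells; a == b gives diff 0, p 1."""
    if label_a == label_b:
        return ContrastResult(name=name, diff=0.0, se=0.0, df=float("nan"),
                              t_stat=0.0, p_nominal=1.0)
    w = np.zeros(len(fit.fixed_labels))
    w[fit.index_of(label_a)] = 1.0
    w[fit.index_of(label_b)] = -1.0
    return fit.contrast(w, name=name)
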