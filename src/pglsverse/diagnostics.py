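"""Collinearity and explanatory-power diagnostics.

Variance inflation factors under both the raw (OLS) and phylogenetically
whitened (PGLS) designs, the predictor correlation matrix, partial R^2
per term, and an exact conjugate Bayesian posterior over the slopes at
fixed lambda.  The posterior slope-correlation matrix is the operational
version of "do the slope estimates trade off against each other" — the
signature of weakly identifiable, collinear predictors: under a flat
prior the posterior covariance of the slopes is proportional to
(X' V^-1 X)^-1, so two predictors with sample correlation r show slope
correlation close to -r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .pgls import PGLSError, PGLSFit, fit_gls
from .treeops import VCVMatrix, lambda_transform

__all__ = [
    "DiagnosticsReport",
    "vif",
    "vif_pgls",
    "partial_r2",
    "posterior_sample",
    "posterior_correlation",
]

VIF_FLAG_THRESHOLD = 10.0  # conventional "worrying" level; reported, never enforced


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X, [f"x{j}" for j in range(X.shape[1])]


def vif(X) -> pd.Series:
    """Variance inflation factor per predictor: VIF_j = 1 / (1 - R^2_j)
    from regressing predictor j on the others (with intercept).

    Exact collinearity yields an infinite VIF, reported as ``inf``
    together with an error message naming the aliased columns.
    """
    M, names = _as_matrix(X)
    n, k = M.shape
    if k < 2:
        raise PGLSError("VIF needs at least 2 predictors")
    out = {}
    aliased = []
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        yj = M[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = float(np.sum((yj - yj.mean()) ** 2))
        rss = float(resid @ resid)
        if tss <= 0:
            raise PGLSError(f"predictor {names[j]!r} is constant")
        r2 = 1.0 - rss / tss
        if r2 >= 1.0 - 1e-12:
            out[names[j]] = np.inf
            aliased.append(names[j])
        else:
            out[names[j]] = 1.0 / (1.0 - r2)
    s = pd.Series(out, name="vif")
    if aliased:
        s.attrs["aliased"] = aliased
    return s


def vif_pgls(X, V: VCVMatrix, lam: float = 1.0) -> pd.Series:
    """VIF in the phylogenetically whitened design: with V(lambda) = L L',
    ordinary VIF applied to L^-1 X.  Reduces to :func:`vif` exactly when
    V is the identity (or the tree is a star)."""
    M, names = _as_matrix(X)
    Vl = lambda_transform(V, lam)
    L = linalg.cholesky(Vl.values, lower=True)
    Xw = linalg.solve_triangular(L, M, lower=True)
    return vif(pd.DataFrame(Xw, columns=names))


def correlation_matrix(X) -> pd.DataFrame:
    """Pearson correlation matrix of the predictors."""
    M, names = _as_matrix(X)
    return pd.DataFrame(np.corrcoef(M, rowvar=False), index=names, columns=names)


def partial_r2(fit: PGLSFit, term: str) -> float:
    """Partial R^2 of one term: (RSS_reduced - RSS_full) / RSS_reduced,
    computed in the whitened space at the full model's lambda.

    Requires the fit to retain its design; recomputed from the fit's
    stored data via refitting without the term.
    """
    if term not in fit.terms:
        raise PGLSError(f"term {term!r} not in model ({fit.terms})")
    if term == fit.terms[0]:
        raise PGLSError("partial R^2 of the intercept is not defined here")
    X_full = getattr(fit, "_X", None)
    y = getattr(fit, "_y", None)
    Vl = getattr(fit, "_Vl", None)
    if X_full is None or y is None or Vl is None:
        raise PGLSError(
            "fit does not carry its design; refit with keep_design (see "
            "pglsverse.diagnostics.attach_design)"
        )
    j = fit.terms.index(term)
    full = fit_gls(y, X_full, Vl)
    reduced = fit_gls(y, np.delete(X_full, j, axis=1), Vl)
    rss_f, rss_r = full.rss_whitened, reduced.rss_whitened
    if rss_r <= 0:
        return 0.0
    return float(max(0.0, (rss_r - rss_f) / rss_r))


def attach_design(fit: PGLSFit, y, X, V_lambda: VCVMatrix) -> PGLSFit:
    """Attach the aligned design to a fit so partial R^2 can refit
    reduced models at the same lambda."""
    fit._y = np.asarray(y, dtype=float)        # type: ignore[attr-defined]
    fit._X = np.asarray(X, dtype=float)        # type: ignore[attr-defined]
    fit._Vl = V_lambda                          # type: ignore[attr-defined]
    return fit


def posterior_sample(
    y, X, V: VCVMatrix, lam: float, n_draws: int = 10_000, seed: int = 0,
) -> np.ndarray:
    """Exact draws of the regression coefficients from the conjugate
    Normal-Inverse-Gamma posterior under a flat prior on (b, log sigma2),
    on the whitened model at fixed lambda.

    sigma2 | y ~ Inv-Gamma((n-p)/2, RSS_w/2);  b | sigma2, y ~
    N(b_hat, sigma2 (X' V^-1 X)^-1).  No Markov chain is involved, so
    there is no mixing to worry about; draws are reproducible by seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise PGLSError("need n > p for a proper posterior")
    Vl = lambda_transform(V, lam)
    L = linalg.cholesky(Vl.values, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    Q, R = linalg.qr(Xw, mode="economic")
    beta_hat = linalg.solve_triangular(R, Q.T @ yw)
    resid = yw - Xw @ beta_hat
    rss = float(resid @ resid)
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv_chol_t = Rinv  # (X'V^-1X)^-1 = Rinv Rinv'

    rng = np.random.default_rng(seed)
    # sigma2 ~ Inv-Gamma(a, b): draw g ~ Gamma(a, 1/b), sigma2 = 1/g
    a = (n - p) / 2.0
    g = rng.gamma(shape=a, scale=2.0 / rss, size=n_draws)
    sigma2 = 1.0 / g
    Z = rng.standard_normal((n_draws, p))
    draws = beta_hat[None, :] + np.sqrt(sigma2)[:, None] * (Z @ xtx_inv_chol_t.T)
    return draws


def posterior_correlation(draws: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of posterior draws (columns = parameters)."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[1] < 2:
        raise PGLSError("need draws for at least 2 parameters")
    return np.corrcoef(draws, rowvar=False)


@dataclass
class DiagnosticsReport:
    """Bundle of collinearity diagnostics for one design."""

    vif_ols: pd.Series
    vif_pgls: pd.Series
    correlation: pd.DataFrame
    posterior_corr: pd.DataFrame
    n_draws: int
    seed: int

    @property
    def flagged(self) -> list[str]:
        """Predictors whose VIF exceeds the conventional threshold of 10
        (informational only)."""
        mask = (self.vif_ols > VIF_FLAG_THRESHOLD) | (
            self.vif_pgls > VIF_FLAG_THRESHOLD
        )
        return list(self.vif_ols.index[mask])


def diagnose(
    data: pd.DataFrame,
    predictors: list[str],
    V: VCVMatrix,
    outcome: str,
    lam: float = 1.0,
    n_draws: int = 10_000,
    seed: int = 0,
) -> DiagnosticsReport:
    """Full diagnostics for one outcome/design: both VIF flavors, the
    predictor correlation matrix, and posterior slope correlations from
    the conjugate sampler at fixed lambda."""
    taxa = [t for t in V.taxa if t in set(data.index)]
    sub = data.loc[taxa, [outcome, *predictors]].dropna()
    Vs = V.reorder(list(sub.index))
    Xp = sub[predictors]
    y = sub[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), Xp.to_numpy(dtype=float)])
    draws = posterior_sample(y, X, Vs, lam, n_draws=n_draws, seed=seed)
    slope_corr = posterior_correlation(draws[:, 1:])
    return DiagnosticsReport(
        vif_ols=vif(Xp),
        vif_pgls=vif_pgls(Xp, Vs, lam),
        correlation=correlation_matrix(Xp),
        posterior_corr=pd.DataFrame(slope_corr, index=predictors, columns=predictors),
        n_draws=n_draws,
        seed=seed,
    )
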