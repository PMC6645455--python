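"""Single-model PGLS fitting.

The model is y = X b + e with e ~ N(0, sigma2 * V(lambda)), where V is the
Brownian-motion covariance implied by the phylogeny and lambda in [0, 1]
scales its off-diagonal.  Estimation is generalized least squares via
Cholesky whitening: with V = L L', the whitened problem (L^-1 y, L^-1 X)
is ordinary least squares.  lambda is estimated by profiling the ML
log-likelihood over [0, 1]; when the profile is degenerate (flat, as on a
star tree, or numerically ill-behaved) lambda falls back to 1 and the fit
is flagged, mirroring common practice when the optimizer fails near the
boundary.

Conventions
-----------
* The likelihood (and hence AIC) uses the ML residual variance RSS_w / n.
* Standard errors, t/p-values and prediction intervals use the unbiased
  variance RSS_w / (n - p), so that at lambda = 0 with a constant-diagonal
  V the fit reproduces ordinary least squares output exactly.
* AIC counts the regression terms, sigma2, and lambda only when lambda
  was actually estimated (a fallback-fixed lambda is not a free parameter).
* R^2 is the squared Pearson correlation between fitted and observed
  values — a crude but reportable summary, not a likelihood pseudo-R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .treeops import Phylogeny, VCVMatrix, lambda_transform, normalize_label

__all__ = [
    "ModelSpec",
    "GLSResult",
    "PGLSFit",
    "Prediction",
    "PGLSError",
    "fit_gls",
    "profile_loglik",
    "estimate_lambda",
    "fit_pgls",
    "aic",
    "r_squared",
    "predict",
]

logger = logging.getLogger(__name__)

INTERCEPT = "(Intercept)"


class PGLSError(ValueError):
    """Raised for invalid PGLS inputs (singular V, rank-deficient X, ...)."""


@dataclass(frozen=True)
class ModelSpec:
    """One outcome plus its predictor set.

    ``mandatory`` predictors (e.g. body mass) appear in every model of a
    multiverse; ``focal`` predictors are the subset under study.  An
    intercept is always included.
    """

    outcome: str
    focal: tuple[str, ...] = ()
    mandatory: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "focal", tuple(self.focal))
        object.__setattr__(self, "mandatory", tuple(self.mandatory))
        overlap = set(self.focal) & set(self.mandatory)
        if overlap:
            raise PGLSError(f"focal and mandatory overlap: {sorted(overlap)}")
        if self.outcome in set(self.focal) | set(self.mandatory):
            raise PGLSError(f"outcome {self.outcome!r} used as predictor")
        for group in (self.focal, self.mandatory):
            if len(set(group)) != len(group):
                raise PGLSError(f"duplicate predictor names in {group}")

    @property
    def predictors(self) -> tuple[str, ...]:
        return self.mandatory + self.focal

    @property
    def terms(self) -> tuple[str, ...]:
        return (INTERCEPT,) + self.predictors

    def label(self) -> str:
        return f"{self.outcome} ~ {' + '.join(self.predictors) or '1'}"


class GLSResult(NamedTuple):
    beta: np.ndarray
    se: np.ndarray
    sigma2: float          # ML residual variance RSS_w / n
    loglik: float
    cov_beta: np.ndarray   # unbiased, RSS_w/(n-p) * (X'V^-1 X)^-1
    rss_whitened: float
    fitted: np.ndarray


class Prediction(NamedTuple):
    point: float
    interval_low: float
    interval_high: float
    level: float


@dataclass
class PGLSFit:
    """A fitted PGLS model with the statistics reported in comparative
    analyses: per-term b, se, t, p plus lambda, AIC, R^2 and N."""

    spec: ModelSpec
    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lam: float
    lambda_fixed: bool
    sigma2: float
    loglik: float
    aic: float
    r2: float
    n: int
    df_resid: int
    taxa: tuple[str, ...]
    fitted: np.ndarray
    cov_beta: np.ndarray = field(repr=False)
    mean_tip_variance: float = field(repr=False, default=1.0)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def p_value(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def to_records(self, model_id: str = "") -> list[dict]:
        """Flatten to one record per term for the reporting layer."""
        rows = []
        for i, term in enumerate(self.terms):
            rows.append({
                "model_id": model_id,
                "outcome": self.spec.outcome,
                "focal_set": "+".join(self.spec.focal),
                "term": term,
                "b": float(self.beta[i]),
                "se": float(self.se[i]),
                "t": float(self.t_values[i]),
                "p": float(self.p_values[i]),
                "lambda": self.lam,
                "lambda_fixed": self.lambda_fixed,
                "aic": self.aic,
                "r2": self.r2,
                "n": self.n,
            })
        return rows


# ----------------------------------------------------------------------
def _check_design_rank(X: np.ndarray, names: Sequence[str]) -> None:
    n, p = X.shape
    if n < p:
        raise PGLSError(f"more terms ({p}) than observations ({n})")
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < p:
        aliased = sorted(names[j] for j in piv[rank:])
        raise PGLSError(f"design matrix is rank-deficient; aliased columns: {aliased}")


def _cholesky_or_blame(V: VCVMatrix) -> np.ndarray:
    try:
        return linalg.cholesky(V.values, lower=True)
    except linalg.LinAlgError as exc:
        A = V.values
        d = np.sqrt(np.clip(np.diag(A), 1e-300, None))
        C = A / np.outer(d, d)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        pair = (V.taxa[i], V.taxa[j])
        raise PGLSError(
            f"phylogenetic covariance matrix is singular; most nearly "
            f"redundant taxa pair: {pair}"
        ) from exc


def fit_gls(
    y: np.ndarray,
    X: np.ndarray,
    V: VCVMatrix | np.ndarray,
    term_names: Sequence[str] | None = None,
) -> GLSResult:
    """Generalized least squares via Cholesky whitening.

    b = (X' V^-1 X)^-1 X' V^-1 y, computed as OLS on (L^-1 y, L^-1 X)
    with V = L L' — no explicit matrix inverse is ever formed.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape[0] != n:
        raise PGLSError(f"y has {y.shape[0]} rows but X has {n}")
    if not isinstance(V, VCVMatrix):
        V = VCVMatrix([f"t{i}" for i in range(n)], np.asarray(V, dtype=float))
    if V.values.shape[0] != n:
        raise PGLSError(f"V has {V.values.shape[0]} taxa but X has {n} rows")
    names = list(term_names) if term_names is not None else [f"x{j}" for j in range(p)]

    L = _cholesky_or_blame(V)
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    _check_design_rank(Xw, names)

    Q, R = linalg.qr(Xw, mode="economic")
    beta = linalg.solve_triangular(R, Q.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)

    sigma2_ml = rss / n
    df_resid = n - p
    sigma2_unbiased = rss / df_resid if df_resid > 0 else np.nan
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv = Rinv @ Rinv.T
    cov_beta = sigma2_unbiased * xtx_inv
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))

    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml <= 0:
        loglik = np.inf  # perfect fit; likelihood unbounded
    else:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + n + logdet_V)
    return GLSResult(beta, se, sigma2_ml, loglik, cov_beta, rss, X @ beta)


# ----------------------------------------------------------------------
class LambdaProfiler:
    """Fast profile log-likelihood over lambda.

    V(lambda) = lambda*V + (1-lambda)*D with D = diag(V), so after
    symmetric scaling by D^-1/2 every V(lambda) shares the eigenvectors of
    D^-1/2 V D^-1/2.  One eigendecomposition makes each lambda evaluation a
    weighted least squares on precomputed rotated data — O(n p^2) instead
    of a fresh O(n^3) Cholesky.  The final fit at the chosen lambda still
    goes through :func:`fit_gls`; tests pin the two routes together.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, V: VCVMatrix):
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.diag(V.values).copy()
        if np.any(d <= 0):
            raise PGLSError("V has non-positive diagonal entries")
        s = 1.0 / np.sqrt(d)
        Vt = V.values * np.outer(s, s)
        np.fill_diagonal(Vt, 1.0)
        evals, Q = linalg.eigh(Vt)
        self.n = y.shape[0]
        self.evals = evals
        self.yr = Q.T @ (s * y)
        self.Xr = Q.T @ (X * s[:, None])
        self.logdet_D = float(np.sum(np.log(d)))

    def loglik(self, lam: float) -> float:
        w = lam * self.evals + (1.0 - lam)
        if np.any(w <= 1e-12):
            return -np.inf
        sw = 1.0 / np.sqrt(w)
        Xw = self.Xr * sw[:, None]
        yw = self.yr * sw
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < Xw.shape[1]:
            return -np.inf
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        n = self.n
        if rss <= 0:
            return np.inf
        logdet = float(np.sum(np.log(w))) + self.logdet_D
        return -0.5 * (n * np.log(2 * np.pi * rss / n) + n + logdet)


def profile_loglik(y, X, V: VCVMatrix, lam: float) -> float:
    """Log-likelihood of the GLS fit at a given lambda (definitionally
    equal to ``fit_gls(y, X, lambda_transform(V, lam)).loglik``)."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return fit_gls(y, X, lambda_transform(V, lam)).loglik


_GRID = np.linspace(0.0, 1.0, 101)


def estimate_lambda(y, X, V: VCVMatrix, policy: str = "estimate") -> tuple[float, bool]:
    """Estimate Pagel's lambda by bounded ML on [0, 1].

    policy = "estimate": maximize the profile likelihood over a 101-point
    grid refined by bounded scalar optimization.  A flat profile (lambda
    unidentifiable, e.g. a star phylogeny) or any numerical failure falls
    back to (1.0, fixed=True) with a logged warning — the error path IS
    the fallback, by design.  policy = "fixed:<v>" returns (v, True).
    """
    if policy.startswith("fixed"):
        _, _, val = policy.partition(":")
        lam = float(val) if val else 1.0
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"fixed lambda must be in [0, 1], got {lam}")
        return lam, True
    if policy != "estimate":
        raise ValueError(f"unknown lambda policy: {policy!r}")

    try:
        prof = LambdaProfiler(y, X, V)
        vals = np.array([prof.loglik(l) for l in _GRID])
    except (PGLSError, linalg.LinAlgError) as exc:
        logger.warning("lambda profile failed (%s); fixing lambda = 1", exc)
        return 1.0, True
    finite = np.isfinite(vals)
    if not finite.any():
        logger.warning("lambda profile non-finite everywhere; fixing lambda = 1")
        return 1.0, True
    if np.isposinf(vals).any():
        # perfect fit at some lambda: take the first attaining grid point
        return float(_GRID[int(np.argmax(np.isposinf(vals)))]), False
    if vals[finite].max() - vals[finite].min() < 1e-8:
        logger.warning("lambda profile flat (unidentifiable); fixing lambda = 1")
        return 1.0, True

    g = int(np.nanargmax(np.where(finite, vals, -np.inf)))
    lo = _GRID[max(g - 1, 0)]
    hi = _GRID[min(g + 1, len(_GRID) - 1)]
    try:
        res = optimize.minimize_scalar(
            lambda l: -prof.loglik(l), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8},
        )
        if res.success and np.isfinite(res.fun) and -res.fun >= vals[g]:
            return float(np.clip(res.x, 0.0, 1.0)), False
    except Exception as exc:  # pragma: no cover - defensive
        logger.warning("lambda optimizer failed (%s); fixing lambda = 1", exc)
        return 1.0, True
    return float(_GRID[g]), False


# ----------------------------------------------------------------------
def aic(loglik: float, n_terms: int, lambda_estimated: bool) -> float:
    """AIC = -2 loglik + 2k with k = regression terms + 1 (sigma2) + 1
    (lambda, only when it was estimated rather than fixed)."""
    k = n_terms + 1 + (1 if lambda_estimated else 0)
    return -2.0 * loglik + 2.0 * k


def r_squared(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson correlation between fitted and observed values."""
    fitted = np.asarray(fitted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if fitted.std() == 0.0:
        raise PGLSError(
            "R^2 undefined: fitted values have zero variance "
            "(intercept-only model?)"
        )
    r = np.corrcoef(fitted, observed)[0, 1]
    return float(r * r)


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble (y, X, taxa) from a species-indexed trait frame."""
    cols = [spec.outcome, *spec.predictors]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise PGLSError(f"variables missing from data: {missing}")
    sub = data[cols].dropna()
    y = sub[spec.outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in spec.predictors]
    )
    return y, X, [normalize_label(s) for s in sub.index]


def fit_pgls(
    data: pd.DataFrame,
    spec: ModelSpec,
    tree: Phylogeny,
    policy: str = "estimate",
) -> PGLSFit:
    """Fit one PGLS model: align complete cases with the tree, estimate
    lambda, fit by whitened GLS, and fill every reported statistic.

    ``data`` is indexed by species; row order is irrelevant — everything
    is aligned to the tree's taxa.
    """
    y, X, taxa = build_design(data, spec)
    tip_set = set(tree.tips)
    keep = [i for i, t in enumerate(taxa) if t in tip_set]
    if not keep:
        raise PGLSError("no species shared between data (complete cases) and tree")
    y, X = y[keep], X[np.asarray(keep)]
    taxa = [taxa[i] for i in keep]

    n, p = X.shape
    if n <= p + 1:
        raise PGLSError(
            f"insufficient species for model size: n={n}, terms={p}"
        )
    sub = tree.prune(taxa) if set(taxa) != tip_set else tree
    V = sub.vcv().reorder(taxa)

    lam, fixed = estimate_lambda(y, X, V, policy=policy)
    Vl = lambda_transform(V, lam)
    res = fit_gls(y, X, Vl, term_names=spec.terms)

    df_resid = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = res.beta / res.se
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), df_resid)
    model_aic = aic(res.loglik, n_terms=p, lambda_estimated=not fixed)
    r2 = r_squared(res.fitted, y) if p > 1 else np.nan

    fit = PGLSFit(
        spec=spec,
        terms=spec.terms,
        beta=res.beta,
        se=res.se,
        t_values=t_vals,
        p_values=p_vals,
        lam=lam,
        lambda_fixed=fixed,
        sigma2=res.sigma2,
        loglik=res.loglik,
        aic=model_aic,
        r2=r2,
        n=n,
        df_resid=df_resid,
        taxa=tuple(taxa),
        fitted=res.fitted,
        cov_beta=res.cov_beta,
        mean_tip_variance=float(np.mean(np.diag(Vl.values))),
    )
    # retain the aligned design so diagnostics (partial R^2) can refit
    # reduced models at the same lambda without re-deriving the alignment
    fit._y, fit._X, fit._Vl = y, X, Vl  # type: ignore[attr-defined]
    return fit


def predict(fit: PGLSFit, new_row: Mapping[str, float], level: float = 0.95) -> Prediction:
    """Predict the response for a new observation, with a prediction
    interval.

    The interval ignores any phylogenetic covariance between the new
    observation and the modeled species (its phylogenetic position is
    unknown); the residual variance term uses the mean tip variance of the
    lambda-transformed V.  Predictions are on the fitted (e.g. log) scale;
    exponentiating the bounds afterwards yields asymmetric intervals.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    missing = [t for t in fit.spec.predictors if t not in new_row]
    if missing:
        raise PGLSError(f"new_row missing predictors: {missing}")
    x0 = np.array([1.0] + [float(new_row[t]) for t in fit.spec.predictors])
    point = float(x0 @ fit.beta)
    sigma2_resid = fit.sigma2 * fit.n / fit.df_resid  # unbiased scale
    var = sigma2_resid * fit.mean_tip_variance + float(x0 @ fit.cov_beta @ x0)
    tcrit = stats.t.ppf((1.0 + level) / 2.0, fit.df_resid)
    half = tcrit * np.sqrt(var)
    return Prediction(point, point - half, point + half, level)
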