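"""Exhaustive predictor-subset ("multiverse") PGLS analysis.

For one outcome and k candidate predictors, fit all 2^k - 1 non-empty
predictor subsets (each with the mandatory covariate included), select
among them by AIC, and summarize how each predictor's p-value moves as
the concomitant predictors change.  With k = 6 this is the 63-models-per-
outcome design, each candidate appearing in 32 of them.

All models share one species set — the complete cases over the outcome,
the mandatory covariate and ALL candidates, intersected with the tree —
so AIC values are comparable and every table reports a single N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pgls import ModelSpec, PGLSError, PGLSFit, fit_pgls
from .treeops import Phylogeny

__all__ = [
    "MultiverseResult",
    "enumerate_models",
    "run_multiverse",
    "best_by_aic",
    "significance_counts",
    "p_extremes",
    "stability_table",
]


def enumerate_models(
    outcome: str,
    candidates: tuple[str, ...] | list[str],
    mandatory: tuple[str, ...] | list[str] = (),
) -> list[ModelSpec]:
    """All non-empty focal subsets of ``candidates``, ordered by subset
    size then lexicographically in the given candidate order, each with
    the mandatory terms prepended."""
    candidates = tuple(candidates)
    mandatory = tuple(mandatory)
    if not candidates:
        raise PGLSError("candidates must be nonempty")
    if len(set(candidates)) != len(candidates):
        raise PGLSError("duplicate candidate names")
    if set(candidates) & set(mandatory):
        raise PGLSError("candidates and mandatory overlap")
    specs = []
    for size in range(1, len(candidates) + 1):
        for idx in combinations(range(len(candidates)), size):
            focal = tuple(candidates[i] for i in idx)
            specs.append(ModelSpec(outcome=outcome, focal=focal, mandatory=mandatory))
    return specs


@dataclass
class MultiverseResult:
    """All subset-model fits for one outcome, plus failure records."""

    outcome: str
    candidates: tuple[str, ...]
    mandatory: tuple[str, ...]
    alpha: float
    specs: list[ModelSpec]
    fits: dict[int, PGLSFit] = field(default_factory=dict)     # index -> fit
    failures: dict[int, str] = field(default_factory=dict)     # index -> message
    species: tuple[str, ...] = ()

    @property
    def n_models(self) -> int:
        return len(self.specs)

    def fits_frame(self) -> pd.DataFrame:
        """Flat table: one row per (model, term)."""
        rows = []
        for i, spec in enumerate(self.specs):
            if i in self.fits:
                rows.extend(self.fits[i].to_records(model_id=f"m{i:03d}"))
            else:
                rows.append({
                    "model_id": f"m{i:03d}", "outcome": self.outcome,
                    "focal_set": "+".join(spec.focal), "term": "<failed>",
                    "b": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                    "lambda": np.nan, "lambda_fixed": False,
                    "aic": np.nan, "r2": np.nan, "n": 0,
                })
        return pd.DataFrame(rows)

    def models_with(self, predictor: str) -> list[int]:
        return [i for i, s in enumerate(self.specs) if predictor in s.focal]


def run_multiverse(
    data: pd.DataFrame,
    tree: Phylogeny,
    outcome: str,
    candidates,
    mandatory=(),
    policy: str = "estimate",
    alpha: float = 0.05,
) -> MultiverseResult:
    """Fit every predictor-subset model on one shared species set.

    A single model's failure (e.g. a rank-deficient design) is recorded
    and does not abort the run; a lambda fallback inside one model is a
    logged warning, not a failure.
    """
    specs = enumerate_models(outcome, candidates, mandatory)
    all_vars = [outcome, *mandatory, *candidates]
    missing = [v for v in all_vars if v not in data.columns]
    if missing:
        raise PGLSError(f"variables missing from data: {missing}")
    complete = data[all_vars].dropna()
    shared = [s for s in complete.index if s in set(tree.tips)]
    if not shared:
        raise PGLSError("no complete-case species present in the tree")
    complete = complete.loc[shared]
    subtree = tree.prune(shared)

    result = MultiverseResult(
        outcome=outcome,
        candidates=tuple(candidates),
        mandatory=tuple(mandatory),
        alpha=alpha,
        specs=specs,
        species=tuple(shared),
    )
    for i, spec in enumerate(specs):
        try:
            result.fits[i] = fit_pgls(complete, spec, subtree, policy=policy)
        except PGLSError as exc:
            result.failures[i] = str(exc)
    return result


def best_by_aic(result: MultiverseResult) -> PGLSFit:
    """The fit with minimal AIC; ties broken by fewer focal predictors,
    then enumeration order."""
    if not result.fits:
        raise PGLSError("all models failed; no AIC ranking possible")
    best_i = min(
        result.fits,
        key=lambda i: (result.fits[i].aic, len(result.specs[i].focal), i),
    )
    return result.fits[best_i]


def _per_predictor(result: MultiverseResult):
    """Yield (predictor, [(index, fit)]) over successful fits containing it."""
    for pred in result.candidates:
        entries = [
            (i, result.fits[i])
            for i in result.models_with(pred)
            if i in result.fits
        ]
        yield pred, entries


def stability_table(result: MultiverseResult, alpha: float | None = None) -> pd.DataFrame:
    """Per-candidate stability summary: membership counts, non-significance
    counts at ``alpha`` (strict p > alpha), and the min/max p-value with
    the concomitant focal predictors of the attaining models.

    Concomitant listings exclude the focal predictor itself and the
    mandatory covariate (which is in every model and carries no
    specification information).
    """
    alpha = result.alpha if alpha is None else alpha
    rows = []
    for pred, entries in _per_predictor(result):
        if not entries:
            rows.append({"predictor": pred, "n_models": 0})
            continue
        ps = np.array([fit.p_value(pred) for _, fit in entries])
        imin, imax = int(np.argmin(ps)), int(np.argmax(ps))

        def concomitants(entry_idx: int) -> tuple[str, ...]:
            spec = entries[entry_idx][1].spec
            return tuple(f for f in spec.focal if f != pred)

        rows.append({
            "predictor": pred,
            "n_models": len(entries),
            "n_nonsignificant": int(np.sum(ps > alpha)),
            "min_p": float(ps[imin]),
            "min_p_concomitants": concomitants(imin),
            "max_p": float(ps[imax]),
            "max_p_concomitants": concomitants(imax),
        })
    return pd.DataFrame(rows).set_index("predictor")


def significance_counts(result: MultiverseResult, alpha: float = 0.05) -> pd.DataFrame:
    """Counts of models in which each candidate is non-significant
    (strictly p > alpha; p = alpha counts as significant)."""
    tab = stability_table(result, alpha=alpha)
    return tab[["n_models", "n_nonsignificant"]]


def p_extremes(result: MultiverseResult) -> pd.DataFrame:
    """Min and max p-value per candidate with the concomitant focal
    predictors of the attaining models (ties resolved by enumeration
    order, since argmin/argmax take the first attaining model)."""
    tab = stability_table(result)
    return tab[["min_p", "min_p_concomitants", "max_p", "max_p_concomitants"]]
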