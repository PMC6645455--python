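"""Rendering of fit and stability results as CSV-ready frames and
markdown tables.

CSV output always carries full precision; the "<0.000" style of printed
regression tables is applied only in markdown rendering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .multiverse import MultiverseResult, stability_table
from .pgls import INTERCEPT, PGLSFit

__all__ = [
    "fit_frame",
    "fit_markdown",
    "stability_frames",
    "stability_markdown",
]


def _fmt_p(p: float, decimals: int = 3) -> str:
    if not np.isfinite(p):
        return "NA"
    if round(p, decimals) == 0:
        return "<0." + "0" * decimals
    return f"{p:.{decimals}f}"


def fit_frame(fit: PGLSFit, model_id: str = "") -> pd.DataFrame:
    """One row per term: b, se, t, p plus the model summary columns."""
    return pd.DataFrame(fit.to_records(model_id=model_id))


def fit_markdown(fit: PGLSFit, decimals: int = 3) -> str:
    """Markdown term table in the style of printed PGLS result tables:
    intercept shown, full model summary (R^2, lambda, N) as a footer."""
    lines = ["| Predictor | b | se | t | p |", "| --- | --- | --- | --- | --- |"]
    for i, term in enumerate(fit.terms):
        name = "Intercept" if term == INTERCEPT else term
        lines.append(
            f"| {name} | {fit.beta[i]:.{decimals}f} | {fit.se[i]:.{decimals}f} "
            f"| {fit.t_values[i]:.{decimals}f} | {_fmt_p(fit.p_values[i], decimals)} |"
        )
    lam = f"{fit.lam:.3g}" + (" (fixed)" if fit.lambda_fixed else "")
    r2 = "NA" if not np.isfinite(fit.r2) else f"{fit.r2:.3f}"
    lines.append("")
    lines.append(
        f"R² = {r2}, λ = {lam}, AIC = {fit.aic:.2f}, N = {fit.n}"
    )
    return "\n".join(lines)


def stability_frames(result: MultiverseResult) -> dict[str, pd.DataFrame]:
    """CSV-ready frames: the flat fits table, non-significance counts, and
    p-value extremes with concomitant sets serialized as '+'-joined."""
    tab = stability_table(result)
    counts = tab[["n_models", "n_nonsignificant"]].copy()
    extremes = tab[["min_p", "min_p_concomitants", "max_p", "max_p_concomitants"]].copy()
    for col in ("min_p_concomitants", "max_p_concomitants"):
        extremes[col] = extremes[col].map(
            lambda s: "+".join(s) if isinstance(s, tuple) else ""
        )
    return {
        "fits": result.fits_frame(),
        "counts": counts,
        "extremes": extremes,
    }


def stability_markdown(result: MultiverseResult, decimals: int = 3) -> str:
    """Markdown rendering of the counts and extremes tables."""
    tab = stability_table(result)
    out = [
        f"Non-significant models per predictor (p > {result.alpha:g}), "
        f"outcome = {result.outcome}, N = {len(result.species)}",
        "",
        "| Predictor | Non-significant |",
        "| --- | --- |",
    ]
    for pred, row in tab.iterrows():
        out.append(f"| {pred} | {int(row['n_nonsignificant'])}/{int(row['n_models'])} |")
    out += [
        "",
        "P-value range per predictor across concomitant sets",
        "",
        "| Focal predictor | Min p | Concomitants | Max p | Concomitants |",
        "| --- | --- | --- | --- | --- |",
    ]
    for pred, row in tab.iterrows():
        cmin = ", ".join(row["min_p_concomitants"]) or "No concomitant predictors"
        cmax = ", ".join(row["max_p_concomitants"]) or "No concomitant predictors"
        out.append(
            f"| {pred} | {_fmt_p(row['min_p'], decimals)} | {cmin} "
            f"| {_fmt_p(row['max_p'], decimals)} | {cmax} |"
        )
    return "\n".join(out)
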