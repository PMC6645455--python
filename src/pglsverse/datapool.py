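"""Trait-table handling: pooling multiple literature sources by weighted
averaging, the standard comparative-analysis variable transforms (natural
log for sizes/counts, arcsine-square-root for dietary proportions),
derived variables, and complete-case extraction against a phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .treeops import Phylogeny, normalize_label

__all__ = [
    "TraitTable",
    "DataError",
    "pool_weighted",
    "apply_transforms",
    "derive_lifespan",
    "complete_cases",
]


class DataError(ValueError):
    """Raised for invalid trait-table inputs."""


@dataclass
class TraitTable:
    """Species-by-variable table with per-column transform state.

    ``data`` is indexed by normalized species labels (one row per
    species).  ``transforms`` records what has been applied to each
    column ("raw", "log", "arcsine_sqrt") so a double transform can be
    rejected.  ``units`` and ``provenance`` are optional metadata carried
    through pooling.
    """

    data: pd.DataFrame
    transforms: dict[str, str] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = [normalize_label(s) for s in df.index]
        if df.index.duplicated().any():
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise DataError(f"duplicate species rows after normalization: {dupes}")
        self.data = df
        for col in df.columns:
            self.transforms.setdefault(col, "raw")

    @classmethod
    def from_csv(cls, path, species_column: str = "species", **kwargs) -> "TraitTable":
        df = pd.read_csv(path, **kwargs)
        if species_column not in df.columns:
            raise DataError(f"no {species_column!r} column in {path}")
        return cls(df.set_index(species_column))

    def to_csv(self, path, species_column: str = "species") -> None:
        self.data.rename_axis(species_column).to_csv(path)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "TraitTable":
        return TraitTable(
            self.data.copy(), dict(self.transforms), dict(self.units),
            dict(self.provenance),
        )


def _coerce(table) -> TraitTable:
    if isinstance(table, TraitTable):
        return table
    if isinstance(table, pd.DataFrame):
        return TraitTable(table)
    raise DataError(f"expected TraitTable or DataFrame, got {type(table)!r}")


def pool_weighted(sources: list, weights=None) -> TraitTable:
    """Pool several trait tables into one by per-cell weighted averaging.

    For each (species, variable) cell the pooled value is
    sum(w_i x_i) / sum(w_i) over the sources that report it; a cell no
    source reports stays missing.  ``weights`` may be None (equal
    weights), one nonnegative scalar per source, or one DataFrame per
    source giving per-cell weights.  Unit metadata must agree across
    sources; pooled provenance records the contributing sources per cell.
    """
    tables = [_coerce(s) for s in sources]
    if not tables:
        raise DataError("no sources to pool")
    if weights is None:
        weights = [1.0] * len(tables)
    if len(weights) != len(tables):
        raise DataError("one weight (scalar or frame) per source required")

    units: dict[str, str] = {}
    transforms: dict[str, str] = {}
    for t in tables:
        for var, u in t.units.items():
            if var in units and units[var] != u:
                raise DataError(
                    f"unit mismatch for {var!r}: {units[var]!r} vs {u!r}"
                )
            units[var] = u
        for var, st in t.transforms.items():
            if var in transforms and transforms[var] != st:
                raise DataError(
                    f"transform-state mismatch for {var!r}: "
                    f"{transforms[var]!r} vs {st!r}"
                )
            transforms[var] = st

    all_species = sorted(set().union(*(t.species for t in tables)))
    all_vars: list[str] = []
    for t in tables:
        for v in t.variables:
            if v not in all_vars:
                all_vars.append(v)

    num = pd.DataFrame(0.0, index=all_species, columns=all_vars)
    den = pd.DataFrame(0.0, index=all_species, columns=all_vars)
    contributors = pd.DataFrame("", index=all_species, columns=all_vars)

    for k, (t, w) in enumerate(zip(tables, weights)):
        vals = t.data.reindex(index=all_species, columns=all_vars)
        if np.isscalar(w):
            if w < 0:
                raise DataError(f"negative weight for source {k}")
            W = pd.DataFrame(float(w), index=all_species, columns=all_vars)
        else:
            W = pd.DataFrame(w).reindex(index=all_species, columns=all_vars)
            W.index = [normalize_label(s) for s in W.index]
            W = W.reindex(index=all_species, columns=all_vars)
            if (W < 0).any().any():
                raise DataError(f"negative weights for source {k}")
        mask = vals.notna() & W.notna() & (W > 0)
        num += (vals * W).where(mask, 0.0)
        den += W.where(mask, 0.0)
        tag = t.provenance.get("source_id", f"source{k}")
        contributors = contributors.where(~mask, contributors + f"{tag};")

    with np.errstate(invalid="ignore"):
        pooled = num / den.where(den > 0)
    return TraitTable(
        pooled, transforms=transforms, units=units,
        provenance={"contributors": contributors},
    )


_TRANSFORM_FUNCS = {"log", "arcsine_sqrt", "arcsine_sqrt_percent"}


def apply_transforms(table, rules: Mapping[str, str]) -> TraitTable:
    """Apply variable transforms, tracking state to guard against double
    application.

    ``rules`` maps variable name to one of:

    * ``"log"`` — natural log; requires strictly positive values.
    * ``"arcsine_sqrt"`` — asin(sqrt(p)) for proportions already in [0, 1].
    * ``"arcsine_sqrt_percent"`` — divides by 100 first (for percent
      columns, e.g. percent fruit in diet), then asin(sqrt(.)).
    """
    t = _coerce(table).copy()
    for var, rule in rules.items():
        if rule not in _TRANSFORM_FUNCS:
            raise DataError(f"unknown transform {rule!r} for {var!r}")
        if var not in t.data.columns:
            raise DataError(f"variable {var!r} not in table")
        if t.transforms.get(var, "raw") != "raw":
            raise DataError(
                f"{var!r} already transformed ({t.transforms[var]}); "
                "refusing to transform twice"
            )
        x = t.data[var].astype(float)
        present = x.notna()
        if rule == "log":
            bad = t.data.index[present & (x <= 0)]
            if len(bad):
                raise DataError(
                    f"log transform of {var!r} needs positive values; "
                    f"offending species: {sorted(bad)}"
                )
            t.data[var] = np.log(x)
            t.transforms[var] = "log"
        else:
            p = x / 100.0 if rule == "arcsine_sqrt_percent" else x
            bad = t.data.index[present & ((p < 0) | (p > 1))]
            if len(bad):
                raise DataError(
                    f"arcsine-sqrt transform of {var!r} needs proportions in "
                    f"[0, 1] (percents in [0, 100]); offending species: "
                    f"{sorted(bad)}"
                )
            t.data[var] = np.arcsin(np.sqrt(p))
            t.transforms[var] = "arcsine_sqrt"
    return t


def derive_lifespan(max_age, sexual_maturity):
    """Life span as the period between sexual maturity and the maximum
    recorded age at death (in years, pre-transform).

    Accepts scalars or aligned array-likes; any element with
    max_age <= sexual_maturity raises (a negative or zero lifespan flags
    a data problem rather than being propagated).
    """
    ma = np.asarray(max_age, dtype=float)
    sm = np.asarray(sexual_maturity, dtype=float)
    if ma.shape != sm.shape:
        raise DataError("max_age and sexual_maturity must align")
    with np.errstate(invalid="ignore"):
        bad = (ma <= sm) | (sm <= 0)
    bad = bad & ~(np.isnan(ma) | np.isnan(sm))
    if np.any(bad):
        idx = np.nonzero(np.atleast_1d(bad))[0].tolist()
        raise DataError(
            f"max_age must exceed sexual_maturity > 0; bad positions: {idx}"
        )
    out = ma - sm
    out = np.where(np.isnan(ma) | np.isnan(sm), np.nan, out)
    if np.ndim(max_age) == 0 and np.ndim(sexual_maturity) == 0:
        return float(out)
    if isinstance(max_age, pd.Series):
        return pd.Series(out, index=max_age.index, name="lifespan")
    return out


class CompleteCases(NamedTuple):
    table: TraitTable
    tree: Phylogeny
    dropped: list[tuple[str, str]]  # (species, reason)


def complete_cases(table, tree: Phylogeny, variables: Iterable[str]) -> CompleteCases:
    """Rows with no missing value on ``variables`` and present in the
    tree; the tree is pruned to match.  Dropped species are reported with
    the reason (missing variable(s) or absence from the phylogeny)."""
    t = _coerce(table)
    variables = list(variables)
    missing_vars = [v for v in variables if v not in t.data.columns]
    if missing_vars:
        raise DataError(f"variables not in table: {missing_vars}")
    tips = set(tree.tips)
    dropped: list[tuple[str, str]] = []
    keep: list[str] = []
    for sp in t.species:
        row = t.data.loc[sp, variables]
        miss = [v for v in variables if pd.isna(row[v])]
        if miss:
            dropped.append((sp, "missing: " + ",".join(miss)))
        elif sp not in tips:
            dropped.append((sp, "not in tree"))
        else:
            keep.append(sp)
    if not keep:
        raise DataError("no species with complete data present in the tree")
    sub = TraitTable(
        t.data.loc[keep, variables].copy(),
        {v: t.transforms.get(v, "raw") for v in variables},
        {v: u for v, u in t.units.items() if v in variables},
        dict(t.provenance),
    )
    return CompleteCases(sub, tree.prune(keep), dropped)
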