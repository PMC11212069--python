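"""Trial trait tables: schema, validation, readers/writers and summaries.

The canonical in-memory container for replicate-level observations is a
tidy :class:`pandas.DataFrame` with columns ``ecotype``, ``water_regime``
(``"WS"`` water-sufficient / ``"WD"`` water-deficit), ``block`` (integer
replicate >= 1), ``trait`` (canonical registry name) and ``value``.
Summaries (mean ± SEM per ecotype × regime × trait) and the ecotype × trait
mean matrix that feeds the multivariate stages are derived from it here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .traits import resolve_trait, validate_value

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["ecotype", "water_regime", "block", "trait", "value"]
REGIMES = ("WS", "WD")
KEY = ["ecotype", "water_regime", "block", "trait"]


class TraitDataError(ValueError):
    """Fatal problem with an input trait table."""


@dataclass(frozen=True)
class RowError:
    """A rejected input row, with its 1-based line number in the file."""

    line: int
    message: str
    token: str | None = None


class ReadResult(NamedTuple):
    observations: pd.DataFrame
    errors: list[RowError]


@dataclass(frozen=True)
class ExperimentDesign:
    """Split-plot layout: water regime on whole plots, ecotype on sub-plots."""

    n_blocks: int
    ecotypes: tuple[str, ...]
    regimes: tuple[str, ...] = REGIMES

    @property
    def n_ecotypes(self) -> int:
        return len(self.ecotypes)


@dataclass
class EcotypeTraitMatrix:
    """Dense ecotype × trait matrix of means for one water regime."""

    data: pd.DataFrame  # index: ecotypes, columns: traits
    water_regime: str
    dropped_ecotypes: list[str] = field(default_factory=list)
    dropped_traits: list[str] = field(default_factory=list)

    @property
    def ecotypes(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise TraitDataError("duplicate ecotype or trait labels in matrix")
        if self.data.isna().any().any():
            raise TraitDataError("matrix has missing cells after construction")


def validate_observations(
    obs: pd.DataFrame, *, allow_custom_traits: bool = False
) -> pd.DataFrame:
    """Validate schema, trait vocabulary, domains and key uniqueness.

    Returns a normalized copy (canonical trait names, int blocks).
    Raises :class:`TraitDataError` on fatal problems.
    """
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise TraitDataError(f"missing required column(s): {', '.join(missing)}")
    out = obs[OBS_COLUMNS].copy()
    out["trait"] = [
        resolve_trait(t, allow_custom=allow_custom_traits) for t in out["trait"]
    ]
    bad_regime = set(out["water_regime"]) - set(REGIMES)
    if bad_regime:
        raise TraitDataError(f"unknown water_regime value(s): {sorted(bad_regime)}")
    out["block"] = out["block"].astype(int)
    if (out["block"] < 1).any():
        raise TraitDataError("block numbers must be >= 1")
    out["value"] = out["value"].astype(float)
    problems = [
        f"row {i}: {msg}"
        for i, (t, v) in enumerate(zip(out["trait"], out["value"]))
        if (msg := validate_value(t, v)) is not None
    ]
    if problems:
        raise TraitDataError("domain violations:\n" + "\n".join(problems))
    dup = out.duplicated(subset=KEY)
    if dup.any():
        keys = out.loc[dup, KEY].to_records(index=False).tolist()
        raise TraitDataError(f"duplicate (ecotype, regime, block, trait) keys: {keys[:5]}")
    return out


def read_trait_table(
    path,
    *,
    wide: bool = False,
    allow_custom_traits: bool = False,
) -> ReadResult:
    """Read a long (default) or wide CSV of trait observations.

    Long format has columns ``ecotype, water_regime, block, trait, value``;
    wide format has ``ecotype, water_regime, block`` plus one column per
    trait.  Rows with non-numeric values are rejected individually and
    reported with their line number and the offending token; structural
    problems (missing columns, duplicate keys) raise
    :class:`TraitDataError`.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    errors: list[RowError] = []

    if wide:
        id_cols = ["ecotype", "water_regime", "block"]
        missing = [c for c in id_cols if c not in raw.columns]
        if missing:
            raise TraitDataError(f"missing required column(s): {', '.join(missing)}")
        trait_cols = [c for c in raw.columns if c not in id_cols]
        raw = raw.melt(id_vars=id_cols, value_vars=trait_cols,
                       var_name="trait", value_name="value")
    else:
        missing = [c for c in OBS_COLUMNS if c not in raw.columns]
        if missing:
            raise TraitDataError(f"missing required column(s): {', '.join(missing)}")

    values = pd.to_numeric(raw["value"], errors="coerce")
    bad = values.isna() & raw["value"].notna()
    for idx in raw.index[bad]:
        errors.append(
            RowError(line=int(idx) + 2,  # header is line 1
                     message="non-numeric value",
                     token=str(raw.loc[idx, "value"]))
        )
    keep = ~bad & raw["value"].notna()
    obs = raw.loc[keep].copy()
    obs["value"] = values[keep]
    if obs.empty:
        logger.warning("no valid observations read from %s", path)
        empty = pd.DataFrame(columns=OBS_COLUMNS)
        return ReadResult(empty, errors)
    obs = validate_observations(obs, allow_custom_traits=allow_custom_traits)
    if errors:
        logger.warning("rejected %d malformed row(s) in %s", len(errors), path)
    return ReadResult(obs.reset_index(drop=True), errors)


def write_trait_table(obs: pd.DataFrame, path) -> None:
    """Write observations as a long UTF-8 CSV ('.' decimal separator)."""
    obs[OBS_COLUMNS].to_csv(path, index=False)


def summarize(obs: pd.DataFrame) -> pd.DataFrame:
    """Per (ecotype, water_regime, trait): mean, SEM and replicate count.

    SEM is the sample standard deviation over blocks divided by sqrt(n);
    cells with a single replicate get SEM 0 (with a warning).
    """
    if obs.empty:
        return pd.DataFrame(columns=["ecotype", "water_regime", "trait",
                                     "mean", "sem", "n"])
    g = obs.groupby(["ecotype", "water_regime", "trait"], sort=False)["value"]
    out = g.agg(mean="mean", sem=lambda v: 0.0 if len(v) < 2 else v.std(ddof=1) / np.sqrt(len(v)),
                n="size").reset_index()
    out["sem"] = out["sem"].fillna(0.0)
    if (out["n"] == 1).any():
        warnings.warn("some cells have a single replicate; SEM set to 0",
                      stacklevel=2)
    return out


def to_matrix(
    summaries: pd.DataFrame,
    water_regime: str,
    traits: Sequence[str] | None = None,
) -> EcotypeTraitMatrix:
    """Pivot summaries into a dense ecotype × trait matrix of means.

    Ecotypes (rows) with any missing requested trait and traits (columns)
    missing for every ecotype are dropped with a warning — never imputed.
    Row order follows first appearance in the input.
    """
    sub = summaries[summaries["water_regime"] == water_regime]
    if sub.empty:
        raise TraitDataError(f"no summaries for water_regime {water_regime!r}")
    if traits is not None:
        absent = [t for t in traits if t not in set(sub["trait"])]
        if absent:
            raise TraitDataError(
                f"requested trait(s) absent for all ecotypes: {absent}")
        sub = sub[sub["trait"].isin(traits)]
    eco_order = list(dict.fromkeys(sub["ecotype"]))
    wide = sub.pivot(index="ecotype", columns="trait", values="mean")
    wide = wide.reindex(index=eco_order)
    if traits is not None:
        wide = wide[list(traits)]
    dropped_traits = [c for c in wide.columns if wide[c].isna().all()]
    if dropped_traits:
        warnings.warn(f"dropping trait(s) with no data: {dropped_traits}",
                      stacklevel=2)
        wide = wide.drop(columns=dropped_traits)
    dropped_ecos = [e for e in wide.index[wide.isna().any(axis=1)]]
    if dropped_ecos:
        warnings.warn(
            f"dropping ecotype(s) with incomplete traits: {dropped_ecos}",
            stacklevel=2)
        wide = wide.drop(index=dropped_ecos)
    wide.index.name = "ecotype"
    wide.columns.name = "trait"
    return EcotypeTraitMatrix(
        data=wide, water_regime=water_regime,
        dropped_ecotypes=dropped_ecos, dropped_traits=dropped_traits,
    )


def check_balanced(obs: pd.DataFrame, trait: str) -> ExperimentDesign:
    """Verify every (block, regime, ecotype) cell is observed exactly once.

    Returns the inferred design; raises with the missing cells listed
    otherwise.
    """
    sub = obs[obs["trait"] == trait]
    if sub.empty:
        raise TraitDataError(f"no observations for trait {trait!r}")
    blocks = sorted(sub["block"].unique())
    ecos = list(dict.fromkeys(sub["ecotype"]))
    expected = {(b, r, e) for b in blocks for r in REGIMES for e in ecos}
    got = set(zip(sub["block"], sub["water_regime"], sub["ecotype"]))
    missing = expected - got
    extra = len(sub) - len(got)
    if missing or extra:
        msg = []
        if missing:
            msg.append(f"missing cells: {sorted(missing)[:10]}"
                       + (" ..." if len(missing) > 10 else ""))
        if extra:
            msg.append(f"{extra} duplicated cell(s)")
        raise TraitDataError(f"unbalanced design for {trait}: " + "; ".join(msg))
    return ExperimentDesign(n_blocks=len(blocks), ecotypes=tuple(ecos))
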