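"""Leaf physiology and stress-response derived quantities.

Relative water content (RWC) expresses leaf hydration as the position of
the fresh weight between full dryness and full turgor:

    RWC = (FWT - DW) / (TW - DW) x 100

where FWT is the fresh weight at sampling, TW the turgid weight after
rehydration, and DW the oven-dry weight.  Stress responses are signed
percent changes of the water-deficit mean relative to the well-watered
mean: negative values are reductions, positive values increases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RWCSample:
    """One leaf's fresh (FWT), turgid (TW) and dry (DW) weights in grams."""

    FWT: float
    TW: float
    DW: float


def relative_water_content(sample: RWCSample) -> float:
    """RWC percentage in [0, 100] from a (FWT, TW, DW) weight triple.

    Raises ``ValueError`` if TW <= DW (degenerate denominator) or if FWT
    falls outside [DW, TW] (measurement inconsistency).
    """
    if not (sample.DW > 0):
        raise ValueError(f"dry weight must be positive, got {sample.DW}")
    if sample.TW <= sample.DW:
        raise ValueError(
            f"turgid weight ({sample.TW}) must exceed dry weight ({sample.DW})")
    if not (sample.DW <= sample.FWT <= sample.TW):
        raise ValueError(
            f"fresh weight {sample.FWT} outside [DW={sample.DW}, TW={sample.TW}]: "
            "measurement inconsistency")
    return (sample.FWT - sample.DW) / (sample.TW - sample.DW) * 100.0


def stress_response(mean_ws: float, mean_wd: float) -> dict:
    """Signed percent change of the WD mean relative to the WS mean.

    Returns a dict with ``pct_change`` (NaN when the WS mean is zero) and
    ``direction`` in {"decrease", "increase", "unchanged", "undefined"}.
    """
    if mean_ws == 0 or not math.isfinite(mean_ws):
        return {"pct_change": float("nan"), "direction": "undefined"}
    pct = (mean_wd - mean_ws) / mean_ws * 100.0
    direction = "unchanged" if pct == 0 else ("decrease" if pct < 0 else "increase")
    return {"pct_change": pct, "direction": direction}


def response_table(
    summaries_ws: pd.DataFrame,
    summaries_wd: pd.DataFrame,
    *,
    grand_means: pd.DataFrame | None = None,
    sort_by_magnitude: bool = False,
) -> pd.DataFrame:
    """Per ecotype × trait stress responses, plus an ``ALL`` grand-mean row.

    ``summaries_ws``/``summaries_wd`` need columns ``ecotype, trait, mean``.
    Ecotype × trait cells present in only one regime are skipped.  The
    ``ALL`` row per trait uses ``grand_means`` (columns ``trait,
    water_regime, grand_mean``) when supplied — e.g. a table's printed
    grand-mean footer — and the arithmetic mean over the matched ecotype
    means otherwise.
    """
    ws = summaries_ws.set_index(["ecotype", "trait"])["mean"]
    wd = summaries_wd.set_index(["ecotype", "trait"])["mean"]
    common = ws.index.intersection(wd.index)
    skipped = ws.index.symmetric_difference(wd.index)
    if len(skipped):
        import logging
        logging.getLogger(__name__).warning(
            "skipping %d ecotype x trait cell(s) present in one regime only",
            len(skipped))
    rows = []
    for eco, trait in common:
        r = stress_response(ws.loc[(eco, trait)], wd.loc[(eco, trait)])
        rows.append({"ecotype": eco, "trait": trait,
                     "mean_WS": ws.loc[(eco, trait)], "mean_WD": wd.loc[(eco, trait)],
                     **r})
    matched = pd.DataFrame(rows)
    traits = list(dict.fromkeys(matched["trait"])) if not matched.empty else []
    all_rows = []
    for trait in traits:
        if grand_means is not None:
            gm = grand_means.set_index(["trait", "water_regime"])["grand_mean"]
            try:
                g_ws, g_wd = gm.loc[(trait, "WS")], gm.loc[(trait, "WD")]
            except KeyError:
                sub = matched[matched["trait"] == trait]
                g_ws, g_wd = sub["mean_WS"].mean(), sub["mean_WD"].mean()
        else:
            sub = matched[matched["trait"] == trait]
            g_ws, g_wd = sub["mean_WS"].mean(), sub["mean_WD"].mean()
        r = stress_response(g_ws, g_wd)
        all_rows.append({"ecotype": "ALL", "trait": trait,
                         "mean_WS": g_ws, "mean_WD": g_wd, **r})
    out = pd.concat([matched, pd.DataFrame(all_rows)], ignore_index=True)
    if sort_by_magnitude and not out.empty:
        out = out.reindex(
            out["pct_change"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return out


def round_for_report(pct: float, decimals: int = 1) -> float:
    """Round a percent change for reporting (round-half-even)."""
    return float(np.round(pct, decimals))
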