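"""Yield-based drought-tolerance selection indices.

Given each ecotype's biomass yield under water deficit (Ys) and under
sufficient water (Yp), and the cohort means Ȳs and Ȳp, the seven classic
selection indices are:

    MP  = (Ys + Yp) / 2            mean productivity
    GMP = sqrt(Ys * Yp)            geometric mean productivity
    TOL = Yp - Ys                  tolerance (absolute yield loss)
    YSI = Ys / Yp                  yield stability index
    YI  = Ys / Ȳs                  yield index
    SSI = (1 - Ys/Yp) / (1 - Ȳs/Ȳp)   stress susceptibility index
    STI = (Ys * Yp) / Ȳp²          stress tolerance index

High MP/GMP/YI/STI (and high yields) mark genotypes productive under both
regimes; low SSI and low TOL mark genotypes losing little yield under
stress.  The ranking direction of each index is encoded in
:data:`INDEX_DIRECTIONS` so that "top-k most tolerant" queries cannot
silently invert an index.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

INDEX_COLUMNS = ["MP", "GMP", "TOL", "YSI", "YI", "SSI", "STI"]

#: Sort direction selecting the most drought-tolerant genotypes first.
INDEX_DIRECTIONS: dict[str, str] = {
    "MP": "descending", "GMP": "descending", "YI": "descending",
    "STI": "descending", "YSI": "descending",
    "SSI": "ascending", "TOL": "ascending",
    "Ys": "descending", "Yp": "descending",
}


def compute_indices(pairs: pd.DataFrame) -> pd.DataFrame:
    """All seven indices for a cohort of (ecotype, Ys, Yp) rows.

    Requires >= 2 ecotypes and every Yp > 0.  When the cohort means are
    equal (no average stress effect) SSI is undefined for the whole cohort
    and returned as NaN with a warning.  Ys > Yp is allowed (negative TOL,
    YSI > 1) but flagged.
    """
    df = pairs[["ecotype", "Ys", "Yp"]].copy()
    if len(df) < 2:
        raise ValueError("need >= 2 ecotypes to compute cohort indices")
    if df["ecotype"].duplicated().any():
        raise ValueError("duplicate ecotype identifiers")
    if (df["Yp"] <= 0).any() or (df["Ys"] < 0).any():
        raise ValueError("yields must satisfy Ys >= 0 and Yp > 0")
    ys, yp = df["Ys"].to_numpy(float), df["Yp"].to_numpy(float)
    ybar_s, ybar_p = ys.mean(), yp.mean()

    df["MP"] = (ys + yp) / 2
    df["GMP"] = np.sqrt(ys * yp)
    df["TOL"] = yp - ys
    df["YSI"] = ys / yp
    df["YI"] = ys / ybar_s
    if ybar_s == ybar_p:
        warnings.warn("cohort mean yields equal under both regimes; "
                      "SSI undefined", stacklevel=2)
        df["SSI"] = np.nan
    else:
        df["SSI"] = (1 - ys / yp) / (1 - ybar_s / ybar_p)
    df["STI"] = (ys * yp) / ybar_p**2
    if (ys > yp).any():
        flagged = df.loc[ys > yp, "ecotype"].tolist()
        warnings.warn(f"Ys > Yp (negative TOL) for: {flagged}", stacklevel=2)
    df.attrs["Ybar_s"] = float(ybar_s)
    df.attrs["Ybar_p"] = float(ybar_p)
    return df


def rank_by_index(table: pd.DataFrame, index: str, k: int | None = None) -> list[str]:
    """Ecotypes ordered most-tolerant-first by one index.

    Descending for productivity-type indices (MP, GMP, YI, STI, YSI, Ys,
    Yp), ascending for loss-type indices (SSI, TOL).  Ties break stably by
    ecotype identifier order in the table.  ``k`` truncates the list.
    """
    if index not in INDEX_DIRECTIONS:
        raise KeyError(f"unknown index {index!r}; valid: {sorted(INDEX_DIRECTIONS)}")
    if index not in table.columns:
        raise KeyError(f"index {index!r} not present in table")
    if k is not None and k > len(table):
        raise ValueError(f"k={k} exceeds cohort size {len(table)}")
    asc = INDEX_DIRECTIONS[index] == "ascending"
    ordered = table.sort_values(index, ascending=asc, kind="mergesort")
    ecos = ordered["ecotype"].tolist()
    return ecos[:k] if k is not None else ecos


def index_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among yields and indices across the cohort.

    Returns ``(r, p)`` DataFrames over {Ys, Yp, MP, GMP, TOL, YSI, YI,
    SSI, STI}; zero-variance columns give NaN rows/columns (flagged).
    """
    cols = ["Ys", "Yp"] + INDEX_COLUMNS
    data = table[cols]
    if len(data) < 3:
        raise ValueError("need >= 3 ecotypes for correlation p-values")
    n = len(data)
    zero_var = [c for c in cols if data[c].std(ddof=1) == 0]
    if zero_var:
        warnings.warn(f"zero-variance column(s): {zero_var}; correlations "
                      "undefined for them", stacklevel=2)
    r = data.corr(method="pearson")
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1 - rv**2, 1e-300, None))
        pm = 2 * stats.t.sf(np.abs(t), n - 2)
    pm[np.abs(rv) >= 1.0] = 0.0
    pm[np.isnan(rv)] = np.nan
    np.fill_diagonal(pm, 0.0)
    p = pd.DataFrame(pm, index=r.index, columns=r.columns)
    return r, p
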