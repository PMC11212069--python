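"""Split-plot ANOVA with LSD mean separation and CV%.

The trial layout is a randomized complete block in split-plot arrangement:
water regime is randomized to whole plots within each block, ecotypes to
sub-plots within each whole plot.  The analysis therefore carries two
error strata — the whole-plot error (block × regime interaction, error a)
tests the regime effect, while the sub-plot residual (error b) tests the
ecotype effect and the regime × ecotype interaction:

    y_ijk = mu + block_i + regime_j + (block x regime)_ij  [error a]
               + ecotype_k + (regime x ecotype)_jk + e_ijk [error b]

All formulas assume a balanced design, which is checked up front.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trait_data import TraitDataError, check_balanced

SOURCES = ["block", "regime", "error_a", "ecotype",
           "regime:ecotype", "error_b", "total"]


def _cell_cube(sub: pd.DataFrame) -> tuple[np.ndarray, list, list, list]:
    """Arrange one trait's observations as a (block, regime, ecotype) cube."""
    blocks = sorted(sub["block"].unique())
    regimes = ["WS", "WD"] if set(sub["water_regime"]) == {"WS", "WD"} \
        else sorted(sub["water_regime"].unique())
    ecos = list(dict.fromkeys(sub["ecotype"]))
    cube = (
        sub.set_index(["block", "water_regime", "ecotype"])["value"]
        .unstack(["water_regime", "ecotype"])
        .reindex(index=blocks)
    )
    arr = np.empty((len(blocks), len(regimes), len(ecos)))
    for j, r in enumerate(regimes):
        arr[:, j, :] = cube[r].reindex(columns=ecos).to_numpy()
    return arr, blocks, regimes, ecos


def splitplot_anova(obs: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Split-plot ANOVA table for one trait.

    Returns a DataFrame indexed by source (block, regime, error_a, ecotype,
    regime:ecotype, error_b, total) with columns df, SS, MS, F, p.  The
    regime F uses the whole-plot error; ecotype and interaction use the
    sub-plot error.  F and p are NaN for zero-variance data (flagged with
    a warning) or zero error degrees of freedom.
    """
    check_balanced(obs, trait)
    sub = obs[obs["trait"] == trait]
    y, blocks, regimes, ecos = _cell_cube(sub)
    r, a, b = y.shape
    if r < 2:
        raise TraitDataError("split-plot ANOVA needs >= 2 blocks")
    gm = y.mean()
    m_block = y.mean(axis=(1, 2))
    m_reg = y.mean(axis=(0, 2))
    m_eco = y.mean(axis=(0, 1))
    m_br = y.mean(axis=2)          # block x regime
    m_re = y.mean(axis=0)          # regime x ecotype

    ss_total = ((y - gm) ** 2).sum()
    ss_block = a * b * ((m_block - gm) ** 2).sum()
    ss_reg = r * b * ((m_reg - gm) ** 2).sum()
    ss_err_a = b * ((m_br - m_block[:, None] - m_reg[None, :] + gm) ** 2).sum()
    ss_eco = r * a * ((m_eco - gm) ** 2).sum()
    ss_re = r * ((m_re - m_reg[:, None] - m_eco[None, :] + gm) ** 2).sum()
    ss_err_b = ss_total - (ss_block + ss_reg + ss_err_a + ss_eco + ss_re)
    ss_err_b = max(ss_err_b, 0.0)

    df = {
        "block": r - 1,
        "regime": a - 1,
        "error_a": (r - 1) * (a - 1),
        "ecotype": b - 1,
        "regime:ecotype": (a - 1) * (b - 1),
        "error_b": a * (r - 1) * (b - 1),
        "total": r * a * b - 1,
    }
    ss = {
        "block": ss_block, "regime": ss_reg, "error_a": ss_err_a,
        "ecotype": ss_eco, "regime:ecotype": ss_re, "error_b": ss_err_b,
        "total": ss_total,
    }
    ms = {s: (ss[s] / df[s] if df[s] > 0 else np.nan)
          for s in SOURCES if s != "total"}

    def ftest(num: str, den: str) -> tuple[float, float]:
        if df[den] == 0 or not np.isfinite(ms[den]) or ms[den] <= 0:
            return np.nan, np.nan
        F = ms[num] / ms[den]
        return F, stats.f.sf(F, df[num], df[den])

    F: dict[str, float] = {s: np.nan for s in SOURCES}
    p: dict[str, float] = {s: np.nan for s in SOURCES}
    if ss_total == 0:
        warnings.warn(f"{trait}: zero total variance; F tests undefined",
                      stacklevel=2)
    else:
        F["regime"], p["regime"] = ftest("regime", "error_a")
        F["ecotype"], p["ecotype"] = ftest("ecotype", "error_b")
        F["regime:ecotype"], p["regime:ecotype"] = ftest("regime:ecotype", "error_b")
        if np.isnan(F["regime"]) or np.isnan(F["ecotype"]):
            warnings.warn(f"{trait}: an error stratum has zero df or zero MS; "
                          "some F tests omitted", stacklevel=2)

    table = pd.DataFrame({
        "df": [df[s] for s in SOURCES],
        "SS": [ss[s] for s in SOURCES],
        "MS": [ms.get(s, np.nan) for s in SOURCES],
        "F": [F[s] for s in SOURCES],
        "p": [p[s] for s in SOURCES],
    }, index=pd.Index(SOURCES, name="source"))
    return table


def _rcbd_error(obs: pd.DataFrame, trait: str, water_regime: str):
    """Residual MS, df, replicate count and means of the within-regime RCBD."""
    sub = obs[(obs["trait"] == trait) & (obs["water_regime"] == water_regime)]
    if sub.empty:
        raise TraitDataError(f"no data for {trait} under {water_regime}")
    wide = sub.pivot(index="block", columns="ecotype", values="value")
    if wide.isna().any().any():
        raise TraitDataError(f"unbalanced data for {trait}/{water_regime}")
    y = wide.to_numpy()
    r, g = y.shape
    gm = y.mean()
    ss_total = ((y - gm) ** 2).sum()
    ss_block = g * ((y.mean(axis=1) - gm) ** 2).sum()
    ss_eco = r * ((y.mean(axis=0) - gm) ** 2).sum()
    ss_err = max(ss_total - ss_block - ss_eco, 0.0)
    df_err = (r - 1) * (g - 1)
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    means = wide.mean(axis=0)
    return ms_err, df_err, r, means, gm


@dataclass
class LsdResult:
    trait: str
    water_regime: str
    lsd_value: float
    groups: pd.Series          # ecotype -> letter code(s), e.g. "a", "ab"
    means: pd.Series           # ecotype -> mean, descending


def lsd_letters(means: pd.Series, lsd: float) -> pd.Series:
    """Assign compact letter codes: means differing by more than ``lsd``
    share no letter; means within ``lsd`` share at least one.

    Standard sweep over means sorted descending: each maximal run of means
    whose extremes differ by at most ``lsd`` gets one letter; runs
    contained in another are dropped.
    """
    s = means.sort_values(ascending=False, kind="mergesort")
    vals = s.to_numpy()
    n = len(s)
    runs: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and vals[i] - vals[j + 1] <= lsd:
            j += 1
        runs.append((i, j))
    maximal = [run for run in runs
               if not any(o[0] <= run[0] and run[1] <= o[1] and o != run
                          for o in runs)]
    maximal = sorted(set(maximal))
    alphabet = string.ascii_lowercase
    letters = {eco: "" for eco in s.index}
    for li, (i, j) in enumerate(maximal):
        letter = alphabet[li % 26] * (1 + li // 26)
        for k in range(i, j + 1):
            letters[s.index[k]] += letter
    return pd.Series(letters).reindex(means.index)


def lsd_separation(
    obs: pd.DataFrame, trait: str, water_regime: str, alpha: float = 0.05
) -> LsdResult:
    """LSD mean separation of ecotypes within one water regime.

    ``lsd = t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n)`` from the
    within-regime randomized-complete-block ANOVA, with n the number of
    blocks.  Letters are assigned by the descending-mean sweep.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    ms_err, df_err, n, means, _ = _rcbd_error(obs, trait, water_regime)
    if df_err < 1 or not np.isfinite(ms_err):
        raise TraitDataError("error stratum has no degrees of freedom")
    lsd = stats.t.ppf(1 - alpha / 2, df_err) * np.sqrt(2 * ms_err / n)
    groups = lsd_letters(means, lsd)
    return LsdResult(trait=trait, water_regime=water_regime,
                     lsd_value=float(lsd),
                     groups=groups,
                     means=means.sort_values(ascending=False))


def cv_percent(obs: pd.DataFrame, trait: str, water_regime: str) -> float:
    """Coefficient of variation: sqrt(residual MS) / grand mean x 100.

    Residual MS from the within-regime RCBD.  NaN (flagged) when the
    grand mean is zero.
    """
    ms_err, _, _, _, gm = _rcbd_error(obs, trait, water_regime)
    if gm == 0:
        warnings.warn(f"{trait}/{water_regime}: grand mean 0, CV undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.sqrt(ms_err) / gm * 100.0)
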