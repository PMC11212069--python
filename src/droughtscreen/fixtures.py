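"""Packaged reference tables from the screening trial of 35 Urochloa ecotypes.

``table1`` (morphology: PH, NT, NL, RL) and ``table2`` (physiology: RWC,
Phi2, PhiNPQ, SPAD, Fv/Fm) hold per-ecotype means ± SEM under the WS and
WD regimes, transcribed verbatim from the published tables.  ``grand_rows``
holds the printed grand-mean / CV% / LSD footer rows.  ``table4`` holds the
published PC1–PC4 scores, mean ranking value and numerical rank per
ecotype under WD, and ``cluster_sizes`` the published five-cluster sizes.
Known print defects in the source tables (a run-together numeric, two
implausible SEMs) are resolved conservatively and documented in
``fixture_notes.json``; see :func:`fixture_notes`.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

_FIXTURES = {"table1", "table2", "table4", "grand_rows", "cluster_sizes"}


def _path(name: str):
    return resources.files("droughtscreen") / "fixtures" / name


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table by name.

    Valid names: ``table1``, ``table2`` (long: ecotype, trait,
    water_regime, mean, sem), ``grand_rows`` (trait, water_regime,
    grand_mean, sem, cv_pct, lsd_05), ``table4`` (ecotype, PC1..PC4,
    ranking_value, numerical_rank), ``cluster_sizes`` (cluster, size).
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; valid: {sorted(_FIXTURES)}")
    with resources.as_file(_path(f"{name}.csv")) as p:
        return pd.read_csv(p)


def fixture_notes() -> dict:
    """Transcription notes, including resolved print defects."""
    with resources.as_file(_path("fixture_notes.json")) as p:
        return json.loads(p.read_text())


def ecotype_means(regime: str | None = None) -> pd.DataFrame:
    """Combined table1+table2 per-ecotype means, optionally one regime."""
    df = pd.concat([load_fixture("table1"), load_fixture("table2")],
                   ignore_index=True)
    if regime is not None:
        df = df[df["water_regime"] == regime].reset_index(drop=True)
    return df
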