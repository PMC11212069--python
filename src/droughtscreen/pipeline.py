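"""End-to-end analysis pipeline: one input trial table in, a report bundle out.

The bundle mirrors the screening workflow: trait summaries, split-plot
ANOVA per trait, stress-response percentages, drought-tolerance indices
(when yield data are present), per-regime trait correlations and PCA, the
contribution-weighted ranking of ecotypes under water deficit, and
hierarchical cluster assignments with profiles.  A manifest JSON records
the configuration, package version, seed and SHA-256 of every output so
a bundle is verifiable and re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .indices import compute_indices, index_correlations
from .multivariate import (
    cluster_profile,
    correlation_matrix,
    dendrogram_newick,
    hierarchical_cluster,
    pca,
    ranking_values,
)
from .physiology import response_table
from .splitplot import cv_percent, lsd_separation, splitplot_anova
from .trait_data import REGIMES, read_trait_table, summarize, to_matrix

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input: str | Path                  # long CSV of observations
    out_dir: str | Path
    yields: str | Path | None = None   # optional CSV: ecotype, Ys, Yp
    alpha: float = 0.05
    n_components: int = 4
    cluster_k: int = 5
    linkage: str = "ward"
    seed: int = 0
    allow_custom_traits: bool = False

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.cluster_k < 1:
            raise ValueError("cluster_k must be >= 1")
        if not Path(self.input).exists():
            raise FileNotFoundError(f"input not found: {self.input}")
        if self.yields is not None and not Path(self.yields).exists():
            raise FileNotFoundError(f"yields table not found: {self.yields}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns the manifest dict.  Any stage failure raises
    :class:`StageError` naming the stage; outputs written so far are
    listed as partial in the manifest on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in dataclasses.asdict(config).items()},
        "complete": False,
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "file": path.name, "sha256": _sha256(path)}

    def flush() -> None:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    stage = "read"
    try:
        obs, errors = read_trait_table(
            config.input, allow_custom_traits=config.allow_custom_traits)
        if errors:
            logger.warning("input had %d rejected row(s)", len(errors))
        traits = list(dict.fromkeys(obs["trait"]))

        stage = "summaries"
        summaries = summarize(obs)
        _write(summaries, out / "summaries.csv", index=False)
        record(stage, out / "summaries.csv")

        stage = "anova"
        anova_frames, lsd_rows = [], []
        for trait in traits:
            tab = splitplot_anova(obs, trait).reset_index()
            tab.insert(0, "trait", trait)
            anova_frames.append(tab)
            for regime in REGIMES:
                res = lsd_separation(obs, trait, regime, alpha=config.alpha)
                cv = cv_percent(obs, trait, regime)
                for eco, grp in res.groups.items():
                    lsd_rows.append({
                        "trait": trait, "water_regime": regime, "ecotype": eco,
                        "mean": res.means[eco], "letters": grp,
                        "lsd_value": res.lsd_value, "cv_pct": cv})
        _write(pd.concat(anova_frames, ignore_index=True),
               out / "anova.csv", index=False)
        record("anova", out / "anova.csv")
        _write(pd.DataFrame(lsd_rows), out / "lsd_groups.csv", index=False)
        record("lsd_groups", out / "lsd_groups.csv")

        stage = "responses"
        ws = summaries[summaries["water_regime"] == "WS"]
        wd = summaries[summaries["water_regime"] == "WD"]
        responses = response_table(ws, wd)
        _write(responses, out / "responses.csv", index=False)
        record(stage, out / "responses.csv")

        stage = "indices"
        if config.yields is not None:
            pairs = pd.read_csv(config.yields)
        elif "DMY" in traits:
            m = obs[obs["trait"] == "DMY"].pivot_table(
                index="ecotype", columns="water_regime",
                values="value", aggfunc="mean", sort=False)
            pairs = (m.rename(columns={"WD": "Ys", "WS": "Yp"})
                     .reset_index()[["ecotype", "Ys", "Yp"]])
        else:
            pairs = None
        if pairs is not None:
            dti = compute_indices(pairs)
            _write(dti, out / "dti.csv", index=False)
            record("dti", out / "dti.csv")
            r, p = index_correlations(dti)
            _write(r, out / "dti_correlations_r.csv")
            record("dti_correlations_r", out / "dti_correlations_r.csv")
            _write(p, out / "dti_correlations_p.csv")
            record("dti_correlations_p", out / "dti_correlations_p.csv")

        stage = "multivariate"
        ranking = None
        for regime in REGIMES:
            matrix = to_matrix(summaries, regime)
            corr = correlation_matrix(matrix)
            _write(corr.r, out / f"correlation_{regime}_r.csv")
            record(f"correlation_{regime}_r", out / f"correlation_{regime}_r.csv")
            _write(corr.p, out / f"correlation_{regime}_p.csv")
            record(f"correlation_{regime}_p", out / f"correlation_{regime}_p.csv")
            res = pca(matrix)
            _write(res.scores, out / f"pca_scores_{regime}.csv")
            record(f"pca_scores_{regime}", out / f"pca_scores_{regime}.csv")
            _write(res.loadings, out / f"pca_loadings_{regime}.csv")
            record(f"pca_loadings_{regime}", out / f"pca_loadings_{regime}.csv")
            _write(res.contributions.to_frame(),
                   out / f"pca_contributions_{regime}.csv")
            record(f"pca_contributions_{regime}",
                   out / f"pca_contributions_{regime}.csv")
            if regime == "WD":
                n_comp = min(config.n_components, res.scores.shape[1])
                ranking = ranking_values(res, n_components=n_comp)
                _write(ranking, out / "ranking.csv")
                record("ranking", out / "ranking.csv")

        stage = "cluster"
        matrix_wd = to_matrix(summaries, "WD")
        if config.cluster_k > len(matrix_wd.ecotypes):
            raise ValueError(
                f"cluster_k={config.cluster_k} exceeds number of "
                f"ecotypes ({len(matrix_wd.ecotypes)})")
        clus = hierarchical_cluster(matrix_wd, linkage=config.linkage,
                                    k=config.cluster_k)
        _write(clus.assignments.to_frame(), out / "clusters.csv")
        record("clusters", out / "clusters.csv")
        _write(cluster_profile(clus, matrix_wd), out / "cluster_profile.csv")
        record("cluster_profile", out / "cluster_profile.csv")
        (out / "dendrogram.nwk").write_text(dendrogram_newick(clus) + "\n")
        record("dendrogram", out / "dendrogram.nwk")

        manifest["complete"] = True
        flush()
        return manifest
    except Exception as exc:  # noqa: BLE001 - rethrown with stage context
        flush()
        raise StageError(stage, exc) from exc
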