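"""Correlation, PCA with contribution-weighted genotype ranking, and
hierarchical clustering of ecotype × trait matrices.

The ranking value condenses a genotype's position in trait space into one
number: with component m explaining c_m percent of total variance and
s_gm the genotype's score on component m,

    ranking_value_g = sum_{m=1..M} c_m(%) * s_gm        (default M = 4)

Genotypes are then dense-ranked by descending ranking value, so rank 1 is
the genotype whose variance-weighted multivariate profile is strongest —
under water deficit, the most drought-tolerant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA as _SkPCA

from .trait_data import EcotypeTraitMatrix

LINKAGES = ("ward", "average", "complete")


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def __post_init__(self) -> None:
        assert (self.r.index == self.r.columns).all()


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def correlation_matrix(matrix: EcotypeTraitMatrix) -> CorrelationMatrix:
    """Pairwise Pearson correlations among traits across ecotypes.

    p-values from the t approximation t = r sqrt((n-2)/(1-r^2)),
    two-sided.  Zero-variance traits yield NaN rows/columns.
    """
    data = matrix.data
    n = len(data)
    if n < 3:
        raise ValueError("need >= 3 ecotypes")
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
    stars = p.map(_stars)
    return CorrelationMatrix(r=r, p=p, stars=stars)


@dataclass
class PCAResult:
    """Scores (ecotype × component), loadings (trait × component),
    percent-variance contributions per component and per-trait
    contributions (%) within each component."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    contributions: pd.Series             # % of total variance, sums to 100
    variable_contributions: pd.DataFrame  # % per trait within component
    eigenvalues: np.ndarray = field(repr=False, default=None)


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores with sample (ddof=1) standard deviation."""
    sd = data.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s) under standardization: {zero}")
    return (data - data.mean()) / sd


def pca(matrix: EcotypeTraitMatrix, standardize_cols: bool = True) -> PCAResult:
    """Principal component analysis of the ecotype × trait matrix.

    Columns are z-scored by default (traits live on wildly different
    scales).  Deterministic sign convention: within each component the
    loading of largest magnitude is made positive.  Contribution of
    component m is 100 λ_m / Σλ.
    """
    data = matrix.data
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 ecotypes and 2 traits")
    X = standardize(data) if standardize_cols else data - data.mean()
    n_comp = min(X.shape)
    sk = _SkPCA(n_components=n_comp, svd_solver="full")
    scores = sk.fit_transform(X.to_numpy())
    loadings = sk.components_.T                     # traits x components
    # sign convention: dominant loading positive
    for m in range(n_comp):
        i = np.argmax(np.abs(loadings[:, m]))
        if loadings[i, m] < 0:
            loadings[:, m] *= -1
            scores[:, m] *= -1
    eig = sk.explained_variance_
    contrib = 100.0 * eig / eig.sum()
    comp_names = [f"PC{m + 1}" for m in range(n_comp)]
    var_contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0, keepdims=True)
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=data.columns, columns=comp_names),
        contributions=pd.Series(contrib, index=comp_names, name="contribution_pct"),
        variable_contributions=pd.DataFrame(
            var_contrib, index=data.columns, columns=comp_names),
        eigenvalues=eig,
    )


def ranking_values(
    pca_result: PCAResult, n_components: int = 4
) -> pd.DataFrame:
    """Contribution-weighted ranking table from a PCA of the trait matrix.

    ranking_value = Σ_m contribution_m(%) × score_m over the first
    ``n_components`` components; ``numerical_rank`` is the dense rank of
    the ranking value in descending order, ties broken by ecotype
    identifier.
    """
    avail = pca_result.scores.shape[1]
    if n_components > avail:
        raise ValueError(f"n_components={n_components} exceeds available {avail}")
    comps = [f"PC{m + 1}" for m in range(n_components)]
    s = pca_result.scores[comps]
    w = pca_result.contributions[comps]
    rv = s.mul(w, axis=1).sum(axis=1)
    out = s.copy()
    out["ranking_value"] = rv
    order = sorted(out.index, key=lambda e: (-out.loc[e, "ranking_value"], str(e)))
    out = out.loc[order]
    out["numerical_rank"] = out["ranking_value"].rank(
        method="dense", ascending=False).astype(int)
    out.index.name = "ecotype"
    return out


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray           # scipy (n-1) x 4 merge tree
    assignments: pd.Series               # ecotype -> 1..k
    method: str
    k: int
    ecotypes: list[str]


def hierarchical_cluster(
    matrix: EcotypeTraitMatrix, linkage: str = "ward", k: int = 5
) -> ClusterResult:
    """Agglomerative clustering of ecotypes on Euclidean distances of
    standardized trait profiles, cut at ``k`` clusters."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    data = matrix.data
    if data.index.duplicated().any():
        raise ValueError("duplicate ecotype labels")
    if not (2 <= k <= len(data)) and k != 1:
        raise ValueError(f"k={k} outside [1, {len(data)}]")
    Z = hierarchy.linkage(pdist(standardize(data).to_numpy(), metric="euclidean"),
                          method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        linkage_matrix=Z,
        assignments=pd.Series(labels, index=data.index, name="cluster"),
        method=linkage, k=k, ecotypes=list(data.index),
    )


def cluster_profile(
    result: ClusterResult, matrix: EcotypeTraitMatrix
) -> pd.DataFrame:
    """Per-cluster size, percent of cohort and mean ± SEM of each trait on
    the original (unstandardized) scale."""
    data = matrix.data.loc[result.ecotypes]
    rows = []
    total = len(data)
    for c, members in result.assignments.groupby(result.assignments):
        sub = data.loc[members.index]
        n = len(sub)
        row: dict = {"cluster": c, "size": n, "pct_of_cohort": 100.0 * n / total}
        for trait in data.columns:
            row[f"{trait}_mean"] = sub[trait].mean()
            row[f"{trait}_sem"] = (
                0.0 if n < 2 else sub[trait].std(ddof=1) / np.sqrt(n))
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def cluster_shares(sizes: list[int] | np.ndarray) -> np.ndarray:
    """Percent of cohort per cluster from raw cluster sizes."""
    sizes = np.asarray(sizes, dtype=float)
    return 100.0 * sizes / sizes.sum()


def dendrogram_newick(result: ClusterResult) -> str:
    """Bracketed (newick) export of the merge tree with heights."""
    Z = result.linkage_matrix
    names = result.ecotypes
    n = len(names)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: names[i] for i in range(n)}
    for idx, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node_id = n + idx
        la = h - heights[a]
        lb = h - heights[b]
        nodes[node_id] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[node_id] = h
        del nodes[a], nodes[b]
    (root,) = nodes.values()
    return root + ";"
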