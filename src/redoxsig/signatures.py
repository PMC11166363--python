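"""Oxidation signature clustering and phenotype correlation scoring.

Significant, fully-observed sites are grouped by hierarchical clustering
into a fixed number of signatures; each signature's centroid (per-sample
mean of member rows) is scored by Pearson correlation against its own
phenotype and cross-correlated against the other phenotypes, and the
centroids are re-tested as combined features through the same moderated
regression used for single sites.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .associate import DEFAULT_COVARIATES, adjust_bh, eb_moderate, fit_site_models
from .errors import ConfigError
from .quantify import SiteQuantMatrix

logger = logging.getLogger(__name__)

DEFAULT_K = 6
CROSS_R_FLAG = 0.3
NEGATIVE_R_FLAG = -0.30
POSITIVE_R_NOTE = 0.45


@dataclass
class SignatureCluster:
    """One phenotype-associated oxidation signature."""

    phenotype: str
    index: int
    members: list
    centroid: pd.Series
    r: float
    r_p: float
    model_adj_p: float = np.nan
    cross_r: dict = field(default_factory=dict)
    cross_flags: dict = field(default_factory=dict)


def cluster_sites(
    submatrix: pd.DataFrame,
    k: int = DEFAULT_K,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[pd.Series, list]:
    """Agglomerative clustering of site rows; cut into exactly ``k`` groups.

    Rows must be fully observed over the supplied columns.  Returns the
    cluster assignment (1..k, relabeled in dendrogram-leaf order so labels
    are deterministic) and the dendrogram leaf order as a list of site_ids.
    Fewer than ``k`` rows lowers ``k`` with a warning.
    """
    n = len(submatrix)
    if n == 0:
        return pd.Series(dtype=int), []
    if submatrix.isna().any().any():
        raise ConfigError("cluster_sites requires fully observed rows")
    if n < k:
        logger.warning("only %d rows; lowering k from %d", n, k)
        k = n
    if n == 1:
        return pd.Series([1], index=submatrix.index), list(submatrix.index)
    Z = linkage(submatrix.to_numpy(), method=method, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    leaf_ix = leaves_list(Z)
    leaf_order = [submatrix.index[i] for i in leaf_ix]
    # relabel clusters by first appearance along the dendrogram leaves
    relabel: dict[int, int] = {}
    for i in leaf_ix:
        c = raw[i]
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    labels = pd.Series([relabel[c] for c in raw], index=submatrix.index)
    return labels, leaf_order


def compute_centroids(submatrix: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Per-cluster centroid: arithmetic mean over member rows at each sample.

    Returns a cluster x sample DataFrame.
    """
    missing = [s for s in submatrix.index if s not in assignments.index]
    if missing:
        raise ConfigError(f"assignments do not cover rows: {missing[:5]}")
    return submatrix.groupby(assignments.reindex(submatrix.index)).mean()


def correlate_centroid(centroid: pd.Series, phenotype: pd.Series) -> tuple[float, float]:
    """Pearson r and two-sided p between a centroid and a phenotype over
    samples observed in both; NA when fewer than 3 pairs or zero variance."""
    joined = pd.concat([centroid, phenotype], axis=1, join="inner").dropna()
    if len(joined) < 3:
        return np.nan, np.nan
    x, y = joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cross_correlate(
    centroids: pd.DataFrame,
    phenotypes: pd.DataFrame,
    r_flag: float = CROSS_R_FLAG,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate every cluster centroid against every phenotype.

    Returns (r matrix, flag matrix): flags record |r| > ``r_flag``
    ("strong"), r < -0.30 with p < 0.05 ("negative"), and r > 0.45 with
    p < 0.05 ("strong_positive"); empty string otherwise.
    """
    r_mat = pd.DataFrame(index=centroids.index, columns=phenotypes.columns, dtype=float)
    flags = pd.DataFrame("", index=centroids.index, columns=phenotypes.columns)
    for c in centroids.index:
        for ph in phenotypes.columns:
            r, p = correlate_centroid(centroids.loc[c], phenotypes[ph])
            r_mat.loc[c, ph] = r
            f = []
            if np.isfinite(r):
                if abs(r) > r_flag:
                    f.append("strong")
                if r < NEGATIVE_R_FLAG and p < 0.05:
                    f.append("negative")
                if r > POSITIVE_R_NOTE and p < 0.05:
                    f.append("strong_positive")
            flags.loc[c, ph] = "|".join(f)
    return r_mat, flags


def cluster_model_test(
    centroids: pd.DataFrame,
    cohort: pd.DataFrame,
    phenotype: str,
    covariates=DEFAULT_COVARIATES,
) -> pd.Series:
    """Adjusted p per cluster from the moderated regression applied to the
    centroids as a small feature matrix.

    With a single cluster the unadjusted p is returned (noted in the log).
    """
    mat = SiteQuantMatrix(centroids.copy().set_axis(
        [f"cluster{c}" for c in centroids.index]), stage="centered")
    fits = fit_site_models(mat, cohort, phenotype, covariates, min_resid_df=3)
    _, results = eb_moderate(fits)
    if len(centroids) < 2:
        logger.info("single cluster: unadjusted p reported")
        adj = results.set_index("site_id")["p"]
    else:
        adj = results.set_index("site_id")["adj_p"]
    out = pd.Series(np.nan, index=centroids.index, dtype=float)
    for c in centroids.index:
        key = f"cluster{c}"
        if key in adj.index:
            out[c] = adj[key]
    return out


@dataclass
class HeatmapExport:
    """Heatmap-ready table: columns are samples sorted ascending by the
    phenotype (ties by sample_id); the first row is the phenotype z-row
    (median-centered, SD-scaled); site rows follow grouped by cluster in
    dendrogram order, with star annotations where adjusted p < 0.05."""

    phenotype: str
    column_order: list
    z_row: pd.Series
    data: pd.DataFrame  # site rows, ordered
    clusters: pd.Series  # per site
    stars: pd.Series  # per site, bool

    def to_frame(self) -> pd.DataFrame:
        top = self.z_row.to_frame().T
        top.index = [f"{self.phenotype}_zscore"]
        body = self.data.copy()
        body.index = [
            f"{s}{'*' if self.stars.get(s, False) else ''}" for s in body.index
        ]
        return pd.concat([top, body])


def export_heatmap(
    submatrix: pd.DataFrame,
    assignments: pd.Series,
    leaf_order: list,
    phenotype_values: pd.Series,
    stars: pd.Series,
    phenotype_name: str,
) -> HeatmapExport:
    """Assemble the heatmap export for one phenotype.

    Columns are restricted to samples with the phenotype observed and sorted
    ascending (ties broken by sample_id); the z-row is (y - median(y))/SD(y);
    rows are grouped by cluster, within-cluster in dendrogram order.
    """
    ph = phenotype_values.dropna()
    ph = ph[[c for c in ph.index if c in submatrix.columns]]
    order = sorted(ph.index, key=lambda s: (ph[s], s))
    y = ph[order]
    sd = float(y.std(ddof=1))
    z_row = (y - float(y.median())) / sd if sd > 0 else y * 0.0

    # group rows by cluster while preserving dendrogram order within cluster
    by_cluster: dict[int, list] = {}
    for s in leaf_order:
        if s in assignments.index:
            by_cluster.setdefault(int(assignments[s]), []).append(s)
    ordered = [s for c in sorted(by_cluster) for s in by_cluster[c]]

    data = submatrix.loc[ordered, order]
    return HeatmapExport(
        phenotype=phenotype_name,
        column_order=order,
        z_row=z_row,
        data=data,
        clusters=assignments.loc[ordered],
        stars=stars.reindex(ordered).fillna(False).astype(bool),
    )


def build_signatures(
    submatrix: pd.DataFrame,
    cohort: pd.DataFrame,
    phenotype: str,
    phenotypes: pd.DataFrame,
    k: int = DEFAULT_K,
    covariates=DEFAULT_COVARIATES,
    metric: str = "euclidean",
    method: str = "complete",
) -> tuple[list, pd.Series, list]:
    """Full signature analysis for one phenotype's heatmap-eligible sites.

    Restricts the submatrix columns to samples with the phenotype observed,
    clusters, computes centroids, correlations, cross-correlations and the
    cluster-level moderated test.  Returns (clusters, assignments,
    leaf_order).
    """
    cohort_ix = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    with_ph = [c for c in submatrix.columns
               if c in cohort_ix.index and np.isfinite(cohort_ix.loc[c, phenotype])]
    sub = submatrix[with_ph]
    assignments, leaf_order = cluster_sites(sub, k=k, metric=metric, method=method)
    if assignments.empty:
        return [], assignments, leaf_order
    centroids = compute_centroids(sub, assignments)
    adj_p = cluster_model_test(centroids, cohort, phenotype, covariates)
    r_mat, flags = cross_correlate(centroids, phenotypes.loc[with_ph])
    clusters = []
    for c in centroids.index:
        r, p = correlate_centroid(centroids.loc[c], phenotypes.loc[with_ph, phenotype])
        clusters.append(SignatureCluster(
            phenotype=phenotype,
            index=int(c),
            members=assignments.index[assignments == c].tolist(),
            centroid=centroids.loc[c],
            r=r,
            r_p=p,
            model_adj_p=float(adj_p[c]),
            cross_r=r_mat.loc[c].to_dict(),
            cross_flags=flags.loc[c].to_dict(),
        ))
    return clusters, assignments, leaf_order
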