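"""Batch-effect adjustment, completeness filtering and median centering.

The batch adjustment is a parametric empirical-Bayes location/scale model:
per feature the data are standardized against the grand mean and pooled
variance, per-batch location and scale are estimated, shrunk toward
batch-level priors (normal prior for location, inverse-gamma for the
squared scale; hyperparameters by method of moments across features), the
conditional posterior updates iterated to convergence, and the adjusted
values back-transformed.  Missing entries are excluded from every estimate
and stay missing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError
from .quantify import SiteQuantMatrix, protein_of

logger = logging.getLogger(__name__)

CONVERGENCE_TOL = 1e-4
MAX_ITERATIONS = 100


@dataclass
class BatchParams:
    """Shrunk per-batch location/scale estimates and their hyperpriors.

    ``gamma_star`` and ``delta2_star`` are feature x batch DataFrames of the
    post-shrinkage location and squared-scale estimates; ``hyper`` maps each
    batch to its prior parameters (gamma_bar, tau2 for the normal location
    prior; a, b for the inverse-gamma scale prior); ``iterations`` and
    ``converged`` record the posterior iteration per batch.
    ``unadjusted_features`` lists features seen in fewer than two batches,
    which are passed through untouched.
    """

    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    hyper: dict
    iterations: dict
    converged: dict
    unadjusted_features: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "hyperparameters": self.hyper,
            "iterations": self.iterations,
            "converged": self.converged,
            "n_unadjusted_features": len(self.unadjusted_features),
            "convergence_tol": CONVERGENCE_TOL,
            "max_iterations": MAX_ITERATIONS,
        }


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(Z, g_hat, d_hat, g_bar, t2, a, b, n_obs):
    """Iterate the conditional posterior updates for one batch.

    Z: feature x sample standardized values for this batch (NaN = missing);
    returns (gamma_star, delta2_star, iterations, converged).
    """
    g_old, d_old = g_hat.copy(), d_hat.copy()
    it = 0
    converged = False
    while it < MAX_ITERATIONS:
        it += 1
        g_new = _postmean(g_hat, g_bar, n_obs, d_old, t2)
        sum2 = np.nansum((Z - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(sum2, n_obs, a, b)
        change = max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old)))
        g_old, d_old = g_new, d_new
        if change < CONVERGENCE_TOL:
            converged = True
            break
    return g_old, d_old, it, converged


def eb_batch_adjust(
    matrix: SiteQuantMatrix,
    batch_labels: pd.Series,
    allow_single_batch: bool = False,
) -> tuple[SiteQuantMatrix, BatchParams]:
    """Remove per-batch location and scale effects, feature-wise, with
    empirical-Bayes shrinkage across features.

    ``batch_labels`` maps each sample column to its batch.  Requires at
    least two batches with at least two samples each; a single batch is
    refused unless ``allow_single_batch`` (then the data pass through
    unchanged).  A feature observed in fewer than two batches is left
    unadjusted and flagged.
    """
    X = matrix.data
    labels = pd.Series(batch_labels).reindex(X.columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise SchemaError(f"no batch label for samples: {missing}")
    batches = sorted(labels.unique())
    counts = labels.value_counts()
    small = [b for b in batches if counts[b] < 2]
    if small:
        raise ConfigError(f"batches with fewer than 2 samples: {small}")
    if len(batches) < 2:
        if not allow_single_batch:
            raise ConfigError(
                "only one batch present; pass allow_single_batch=True for identity"
            )
        logger.info("single batch: adjustment is the identity")
        empty = pd.DataFrame(index=X.index, columns=batches, dtype=float)
        params = BatchParams(empty, empty, {}, {}, {}, [])
        return SiteQuantMatrix(X.copy(), stage="batch_corrected"), params

    vals = X.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    n_feat = vals.shape[0]
    batch_cols = {b: np.flatnonzero((labels == b).to_numpy()) for b in batches}

    # per-feature per-batch observed counts and means
    n_ib = np.zeros((n_feat, len(batches)))
    mean_ib = np.full((n_feat, len(batches)), np.nan)
    for k, b in enumerate(batches):
        sub = vals[:, batch_cols[b]]
        fin = np.isfinite(sub)
        nk = fin.sum(axis=1)
        n_ib[:, k] = nk
        s = np.where(fin, sub, 0.0).sum(axis=1)
        mean_ib[:, k] = np.where(nk > 0, s / np.maximum(nk, 1), np.nan)

    batches_seen = (n_ib >= 1).sum(axis=1)
    adjustable = batches_seen >= 2
    unadjusted = X.index[~adjustable].tolist()
    if unadjusted:
        logger.warning("%d features observed in <2 batches left unadjusted", len(unadjusted))

    # grand mean = overall observed mean; pooled variance = mean squared
    # residual around the batch means (observed cells only)
    with np.errstate(invalid="ignore"):
        alpha = np.nansum(n_ib * np.nan_to_num(mean_ib), axis=1) / np.maximum(n_ib.sum(axis=1), 1)
    fitted = np.zeros_like(vals)
    for k, b in enumerate(batches):
        fitted[:, batch_cols[b]] = np.nan_to_num(mean_ib[:, k])[:, None]
    resid = np.where(obs, vals - fitted, 0.0)
    n_obs_total = obs.sum(axis=1)
    pooled_var = (resid**2).sum(axis=1) / np.maximum(n_obs_total, 1)
    pooled_var = np.maximum(pooled_var, 1e-12)
    sigma = np.sqrt(pooled_var)

    Z = (vals - alpha[:, None]) / sigma[:, None]

    gamma_star = pd.DataFrame(0.0, index=X.index, columns=batches)
    delta2_star = pd.DataFrame(1.0, index=X.index, columns=batches)
    hyper: dict = {}
    iterations: dict = {}
    converged: dict = {}

    for k, b in enumerate(batches):
        Zb = Z[:, batch_cols[b]]
        nb = n_ib[:, k]
        ok = adjustable & (nb >= 2)  # need within-batch variance
        if ok.sum() < 2:
            logger.warning("batch %s: too few estimable features; skipped", b)
            continue
        Zb_ok = Zb[ok]
        g_hat = np.nanmean(Zb_ok, axis=1)
        d_hat = np.nanvar(Zb_ok, axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)

        g_bar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1))
        M = float(np.mean(d_hat))
        V = float(np.var(d_hat, ddof=1))
        V = max(V, 1e-12)
        a = (2.0 * V + M**2) / V
        bprior = (M * V + M**3) / V
        hyper[str(b)] = {"gamma_bar": g_bar, "tau2": t2, "a": a, "b": bprior}

        g_star, d_star, it, conv = _it_sol(Zb_ok, g_hat, d_hat, g_bar, t2, a, bprior, nb[ok])
        gamma_star.loc[ok, b] = g_star
        delta2_star.loc[ok, b] = d_star
        iterations[str(b)] = it
        converged[str(b)] = bool(conv)
        if not conv:
            logger.warning("batch %s: EB iteration hit cap (%d)", b, MAX_ITERATIONS)

    # back-transform: remove shrunk location, divide by shrunk scale
    Zadj = Z.copy()
    for k, b in enumerate(batches):
        cols = batch_cols[b]
        g = gamma_star[b].to_numpy()
        d = np.sqrt(delta2_star[b].to_numpy())
        Zadj[:, cols] = (Z[:, cols] - g[:, None]) / d[:, None]
    out = Zadj * sigma[:, None] + alpha[:, None]
    out[~obs] = np.nan
    # untouched features pass through
    if unadjusted:
        mask = ~adjustable
        out[mask] = vals[mask]

    params = BatchParams(gamma_star, delta2_star, hyper, iterations, converged, unadjusted)
    adjusted = pd.DataFrame(out, index=X.index, columns=X.columns)
    return SiteQuantMatrix(adjusted, stage="batch_corrected"), params


def sequential_batch_correct(
    matrix: SiteQuantMatrix,
    plex_labels: pd.Series,
    site_labels: pd.Series,
    allow_single_batch: bool = False,
) -> tuple[SiteQuantMatrix, dict]:
    """Adjust for multiplex batch, then biopsy collection site, in sequence.

    The plex-first order is the documented default and is recorded in the
    returned params dict.  A constant collection-site label skips the second
    pass with a logged notice.
    """
    adjusted, plex_params = eb_batch_adjust(matrix, plex_labels, allow_single_batch)
    site_labels = pd.Series(site_labels).reindex(matrix.data.columns)
    if site_labels.nunique() < 2:
        logger.info("collection-site labels constant; second batch pass skipped")
        return adjusted, {"order": ["plex"], "plex": plex_params, "collection_site": None}
    adjusted, site_params = eb_batch_adjust(adjusted, site_labels, allow_single_batch)
    return adjusted, {
        "order": ["plex", "collection_site"],
        "plex": plex_params,
        "collection_site": site_params,
    }


def filter_completeness(matrix: SiteQuantMatrix, tau: float = 0.75) -> SiteQuantMatrix:
    """Retain sites observed in at least ``tau`` of all sample columns
    (inclusive threshold)."""
    if not 0.0 <= tau <= 1.0:
        raise ConfigError("completeness threshold tau must be in [0, 1]")
    keep = matrix.completeness() >= tau
    return SiteQuantMatrix(matrix.data.loc[keep].copy(), stage=matrix.stage)


def median_center_rows(matrix: SiteQuantMatrix) -> SiteQuantMatrix:
    """Subtract each site's observed median; missing entries untouched."""
    med = matrix.data.median(axis=1, skipna=True)
    centered = matrix.data.sub(med, axis=0)
    return SiteQuantMatrix(centered, stage="centered")


def filter_target_proteins(matrix: SiteQuantMatrix, protein_list) -> SiteQuantMatrix:
    """Retain sites whose protein entry name is in ``protein_list``
    (case-sensitive exact match)."""
    proteins = set(protein_list)
    if not proteins:
        raise ConfigError("target protein list must be nonempty")
    keep = [protein_of(s) in proteins for s in matrix.data.index]
    out = matrix.data.loc[keep].copy()
    if out.empty:
        logger.warning("target-protein filter matched no sites")
    return SiteQuantMatrix(out, stage=matrix.stage)
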