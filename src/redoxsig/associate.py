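"""Per-site covariate-adjusted association with empirical-Bayes moderation.

Each Cys site's (centered log2) oxidation is regressed on one phenotype
plus sex, age and weight.  Residual variances are shrunk toward a common
prior fitted by method of moments on log s-squared (the scaled-F model:
s^2 ~ s0^2 F(d, d0)), yielding moderated t-statistics with d0 + d degrees
of freedom — the standard route to usable power at n = 56.  P-values are
Benjamini-Hochberg adjusted within each phenotype's family.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError
from .quantify import SiteQuantMatrix

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "weight")
P_THRESHOLD = 0.05
ADJ_P_THRESHOLD = 0.05


@dataclass
class SiteFit:
    """OLS summary for one site against one phenotype.

    ``beta`` is the phenotype coefficient (log2 oxidation per phenotype
    unit), ``v`` the unitless design quantity [(X'X)^-1] at the phenotype
    position (so SE = s * sqrt(v)), ``s2`` the residual variance and ``d``
    the residual degrees of freedom.
    """

    site_id: str
    phenotype: str
    n: int
    beta: float
    v: float
    s2: float
    d: int


@dataclass
class EBPrior:
    """Fitted variance prior: s^2 ~ s0^2 * F(d, d0); d0 may be +inf."""

    d0: float
    s02: float

    def posterior_s2(self, s2: np.ndarray, d: np.ndarray) -> np.ndarray:
        if math.isinf(self.d0):
            return np.full_like(np.asarray(s2, dtype=float), self.s02)
        if self.d0 == 0:
            return np.asarray(s2, dtype=float)
        return (self.d0 * self.s02 + d * s2) / (self.d0 + d)


def fit_site_models(
    matrix: SiteQuantMatrix,
    cohort: pd.DataFrame,
    phenotype: str,
    covariates=DEFAULT_COVARIATES,
    min_resid_df: int = 3,
) -> list[SiteFit]:
    """Ordinary least squares of each site on [1, phenotype, covariates].

    Samples missing the phenotype or any covariate are excluded; per site,
    only samples with an observed oxidation value enter.  Sites with
    residual df below ``min_resid_df`` or a rank-deficient design are
    skipped with a logged count.
    """
    if phenotype not in cohort.columns:
        raise SchemaError(f"phenotype column {phenotype!r} not in cohort")
    for c in covariates:
        if c not in cohort.columns:
            raise SchemaError(f"covariate column {c!r} not in cohort")

    cohort = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    cols = [c for c in matrix.data.columns if c in cohort.index]
    if not cols:
        raise SchemaError("no matrix columns resolvable to cohort rows")
    X_all = cohort.loc[cols, [phenotype, *covariates]].to_numpy(dtype=float)
    model_ok = np.isfinite(X_all).all(axis=1)

    Y = matrix.data[cols].to_numpy(dtype=float)
    obs = np.isfinite(Y) & model_ok[None, :]
    p = 2 + len(covariates)  # intercept + phenotype + covariates

    fits: list[SiteFit] = []
    n_skipped = 0
    # group sites by identical sample-availability pattern so the design
    # factorization is computed once per pattern
    patterns: dict[bytes, list[int]] = {}
    for i in range(Y.shape[0]):
        patterns.setdefault(obs[i].tobytes(), []).append(i)

    site_ids = matrix.data.index.to_numpy()
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n = int(mask.sum())
        if n - p < min_resid_df:
            n_skipped += len(rows)
            continue
        X = np.column_stack([np.ones(n), X_all[mask]])
        xtx = X.T @ X
        rank = np.linalg.matrix_rank(xtx)
        if rank < p:
            n_skipped += len(rows)
            continue
        xtx_inv = np.linalg.inv(xtx)
        H = xtx_inv @ X.T  # p x n
        v = float(xtx_inv[1, 1])
        d = n - p
        Yg = Y[rows][:, mask]  # len(rows) x n
        B = Yg @ H.T  # coefficients, len(rows) x p
        resid = Yg - B @ X.T
        rss = (resid**2).sum(axis=1)
        for j, i in enumerate(rows):
            fits.append(SiteFit(
                site_id=str(site_ids[i]), phenotype=phenotype, n=n,
                beta=float(B[j, 1]), v=v, s2=float(rss[j] / d), d=d,
            ))
    if n_skipped:
        logger.info("fit_site_models(%s): skipped %d sites (df < %d or rank-deficient)",
                    phenotype, n_skipped, min_resid_df)
    order = {s: i for i, s in enumerate(site_ids)}
    fits.sort(key=lambda f: order[f.site_id])
    return fits


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, d: np.ndarray) -> EBPrior:
    """Method-of-moments fit of the scaled-F variance model on log s^2.

    With s^2 = s0^2 (chi2_d/d)/(chi2_d0/d0), the residuals
    e = log s^2 - digamma(d/2) + log(d/2) have mean
    log s0^2 - digamma(d0/2) + log(d0/2) and variance
    trigamma(d/2) + trigamma(d0/2); d0 is recovered by inverting the
    trigamma function on the excess variance of e.  When the empirical
    variance does not exceed the sampling variance, d0 = +inf and
    s0^2 = exp(mean(e)).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (d > 0)
    s2, d = s2[ok], d[ok]
    fin = np.isfinite(d)
    half_d = np.where(fin, d / 2.0, 1.0)
    dig = np.where(fin, special.digamma(half_d) - np.log(half_d), 0.0)
    tri = np.where(fin, special.polygamma(1, half_d), 0.0)
    e = np.log(s2) - dig
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(np.mean(tri))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(e_mean)
    return EBPrior(d0=d0, s02=s02)


def eb_moderate(
    fits: list[SiteFit],
    prior: EBPrior | None = None,
    p_threshold: float = P_THRESHOLD,
    adj_p_threshold: float = ADJ_P_THRESHOLD,
) -> tuple[EBPrior, pd.DataFrame]:
    """Moderated t-statistics and BH-adjusted p-values for a set of fits.

    The prior is fitted from the fits unless supplied (supplying d0 = 0
    reproduces the ordinary t-test; d0 = +inf pools completely).  Fewer
    than 10 positive residual variances triggers the unmoderated fallback
    with a warning.  Sites whose posterior variance is zero get NA p-values
    with a reason.
    """
    if not fits:
        return EBPrior(0.0, 1.0), pd.DataFrame(
            columns=["site_id", "phenotype", "n", "beta", "t", "p", "adj_p",
                     "significant", "star", "reason"])
    s2 = np.array([f.s2 for f in fits])
    d = np.array([f.d for f in fits], dtype=float)
    if prior is None:
        if int((s2 > 0).sum()) >= 10:
            prior = fit_f_dist(s2, d)
        else:
            logger.warning("fewer than 10 positive residual variances; "
                           "falling back to unmoderated t")
            prior = EBPrior(d0=0.0, s02=float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0)

    s2_post = prior.posterior_s2(s2, d)
    beta = np.array([f.beta for f in fits])
    v = np.array([f.v for f in fits])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(s2_post * v)
    df_total = d + (0.0 if math.isinf(prior.d0) else prior.d0)
    if math.isinf(prior.d0):
        df_total = np.full_like(d, np.inf)
    p = np.where(
        np.isfinite(t),
        2.0 * np.where(np.isinf(df_total), stats.norm.sf(np.abs(t)),
                       stats.t.sf(np.abs(t), np.maximum(df_total, 1.0))),
        np.nan,
    )
    reason = np.where(np.isfinite(t), "", "zero posterior variance")
    adj_p = adjust_bh(p)
    out = pd.DataFrame({
        "site_id": [f.site_id for f in fits],
        "phenotype": [f.phenotype for f in fits],
        "n": [f.n for f in fits],
        "beta": beta,
        "t": t,
        "p": p,
        "adj_p": adj_p,
        "significant": p < p_threshold,
        "star": adj_p < adj_p_threshold,
        "reason": reason,
    })
    return prior, out


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1, with NA
    passthrough (NAs are excluded from the family)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        _, adj, _, _ = multipletests(p[ok], method="fdr_bh")
        out[ok] = adj
    return out


def select_significant(
    results: pd.DataFrame,
    matrix: SiteQuantMatrix,
    cohort: pd.DataFrame,
    phenotype: str,
    p_threshold: float = P_THRESHOLD,
) -> tuple[list, list]:
    """Significant sites (p below threshold) and the heatmap-eligible subset
    that is additionally 100% complete across samples with the phenotype."""
    sig = results.loc[results["p"] < p_threshold, "site_id"].tolist()
    cohort_ix = cohort.set_index("participant_id") if "participant_id" in cohort.columns else cohort
    with_ph = [c for c in matrix.data.columns
               if c in cohort_ix.index and np.isfinite(cohort_ix.loc[c, phenotype])]
    complete = matrix.data[with_ph].notna().all(axis=1)
    eligible = [s for s in sig if s in complete.index and bool(complete[s])]
    return sig, eligible
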