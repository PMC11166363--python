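"""Replicate-level calibration studies run on the synthetic generator.

These drive the package's own statistical QC: empirical type-I error of the
per-site moderated association test on null cohorts, and recovery of
planted oxidation signatures under the default study conditions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .associate import eb_moderate, fit_site_models, select_significant
from .normalize import (
    filter_completeness,
    median_center_rows,
    sequential_batch_correct,
)
from .quantify import ROLE_PARTICIPANT, abundance_correct, assemble_matrix
from .signatures import (
    cluster_model_test,
    cluster_sites,
    compute_centroids,
    correlate_centroid,
)
from .synthetic import PHENOTYPES, SimConfig, simulate_study


def preprocess(study, tau: float = 0.75):
    """Standard chain: assemble, abundance-correct, batch-correct,
    completeness-filter, median-center."""
    matrix = assemble_matrix(study.tables, study.designs)
    sample_of = {
        (d.plex_id, ch): sid for d in study.designs
        for ch, (sid, role) in d.channels.items() if role == ROLE_PARTICIPANT
    }
    gm = {
        sample_of[(p, ch)]: med
        for p, meds in study.global_medians.items()
        for ch, med in meds.items() if (p, ch) in sample_of
    }
    matrix, _ = abundance_correct(matrix, gm)
    cohort = study.cohort.set_index("participant_id")
    plex = pd.Series({
        sid: d.plex_id for d in study.designs
        for ch, (sid, role) in d.channels.items() if role == ROLE_PARTICIPANT
    })
    site = cohort["biopsy_site"].reindex(matrix.data.columns)
    matrix, _ = sequential_batch_correct(matrix, plex, site)
    matrix = filter_completeness(matrix, tau)
    return median_center_rows(matrix)


def null_type_one_error(
    seeds,
    phenotype: str = "vo2_peak",
    n_sites: int = 2000,
    p_threshold: float = 0.05,
) -> tuple[float, list[float]]:
    """Empirical per-site type-I error on null cohorts.

    Each replicate simulates a 56-participant study with ``n_sites``
    background sites and no planted effects (default noise and batch
    parameters), runs the full preprocessing and the moderated association
    against one phenotype, and records the fraction of sites below the
    per-site significance threshold.  Returns (mean fraction, per-replicate
    fractions).
    """
    fracs = []
    for seed in seeds:
        cfg = SimConfig(seed=int(seed), planted_clusters=[], target_proteins={},
                        n_background_proteins=n_sites // 5,
                        background_sites_per_protein=5)
        study = simulate_study(cfg)
        matrix = preprocess(study)
        fits = fit_site_models(matrix, study.cohort, phenotype)
        _, results = eb_moderate(fits)
        fracs.append(float((results["p"] < p_threshold).mean()))
    return float(np.mean(fracs)), fracs


def signature_recovery_replicate(seed: int, k: int = 6) -> dict:
    """One replicate of the planted-signature recovery study.

    Runs the default study conditions (three negative planted clusters, one
    positive ACTN3-like cluster, 2,000 background sites) end to end and
    reports: planted-site sensitivity at p < 0.05, and for each planted
    cluster whether the best-Jaccard-matched recovered cluster has the
    planted correlation sign and a cluster-level adjusted p < 0.05.
    """
    cfg = SimConfig(seed=seed)
    study = simulate_study(cfg)
    matrix = preprocess(study)
    cohort_ix = study.cohort.set_index("participant_id")
    planted = study.truth[study.truth["cluster"] != ""]

    hits = total = 0
    sign_ok: dict[str, bool] = {}
    cluster_p_ok: dict[str, bool] = {}
    for label, grp in planted.groupby("cluster"):
        phenotype = next(ph for ph in PHENOTYPES if (grp[f"b_{ph}"] != 0).any())
        planted_sign = float(np.sign(grp[f"b_{phenotype}"].iloc[0]))
        fits = fit_site_models(matrix, study.cohort, phenotype)
        _, results = eb_moderate(fits)
        sig_ids = set(results.loc[results["p"] < 0.05, "site_id"])
        hits += sum(s in sig_ids for s in grp.index)
        total += len(grp)

        _, eligible = select_significant(results, matrix, study.cohort, phenotype)
        with_ph = [c for c in matrix.data.columns
                   if np.isfinite(cohort_ix.loc[c, phenotype])]
        sub = matrix.data.loc[eligible, with_ph]
        if len(sub) < 2:
            sign_ok[label] = cluster_p_ok[label] = False
            continue
        labels, _ = cluster_sites(sub, k=k)
        planted_set = set(grp.index)
        best, best_j = None, -1.0
        for c in labels.unique():
            members = set(labels.index[labels == c])
            j = len(members & planted_set) / len(members | planted_set)
            if j > best_j:
                best, best_j = c, j
        centroids = compute_centroids(sub, labels)
        r, _ = correlate_centroid(centroids.loc[best],
                                  cohort_ix.loc[with_ph, phenotype])
        sign_ok[label] = bool(np.isfinite(r) and np.sign(r) == planted_sign)
        adj_p = cluster_model_test(centroids, study.cohort, phenotype)
        cluster_p_ok[label] = bool(adj_p[best] < 0.05)

    return {
        "sensitivity": hits / total if total else float("nan"),
        "sign_ok": sign_ok,
        "cluster_p_ok": cluster_p_ok,
        "success": (total > 0 and hits / total >= 0.8
                    and all(sign_ok.values()) and all(cluster_p_ok.values())),
    }
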