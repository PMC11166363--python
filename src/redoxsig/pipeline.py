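"""Pipeline orchestration: simulate -> quantify -> normalize -> associate
-> signatures, driven by one config, with seeded determinism and a
machine-readable run summary."""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import eb_moderate, fit_site_models, select_significant
from .errors import ConfigError
from .normalize import (
    filter_completeness,
    filter_target_proteins,
    median_center_rows,
    sequential_batch_correct,
)
from .quantify import (
    SiteQuantMatrix,
    ROLE_PARTICIPANT,
    abundance_correct,
    assemble_matrix,
    estimate_occupancy,
)
from .signatures import build_signatures, export_heatmap
from .synthetic import PHENOTYPES, SimConfig, read_study, simulate_study, write_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Top-level run configuration with the study's default thresholds."""

    outdir: str = "results"
    seed: int = 0
    input_dir: str | None = None  # read an existing study instead of simulating
    simulate: SimConfig = field(default_factory=SimConfig)
    completeness_tau: float = 0.75
    p_threshold: float = 0.05
    adj_p_threshold: float = 0.05
    k_clusters: int = 6
    cross_r_flag: float = 0.3
    covariates: tuple = ("sex", "age", "weight")
    phenotypes: tuple = PHENOTYPES
    target_protein_file: str | None = None
    apply_target_filter: bool = True
    batch_order: tuple = ("plex", "collection_site")
    allow_single_batch: bool = False

    def validate(self) -> None:
        if not 0 <= self.completeness_tau <= 1:
            raise ConfigError("completeness_tau must be in [0, 1]")
        for name in ("p_threshold", "adj_p_threshold"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if self.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")
        if not self.phenotypes:
            raise ConfigError("phenotype list must be nonempty")
        if self.target_protein_file is not None and not Path(self.target_protein_file).exists():
            raise ConfigError(f"target_protein_file not found: {self.target_protein_file}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if sim_raw:
            cfg.simulate = SimConfig(**sim_raw)
        return cfg


def _target_proteins(config: RunConfig) -> list[str]:
    if config.target_protein_file:
        lines = Path(config.target_protein_file).read_text().splitlines()
        return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    return sorted(config.simulate.target_proteins)


def _write_matrix(matrix: SiteQuantMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#stage={matrix.stage}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="site_id", float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write every stage output under ``config.outdir``.

    Returns the run summary (also written to ``summary.json``).  Outputs are
    pure functions of config + seed; wall-clock timings go to a separate
    ``timings.json`` so the analytical outputs are byte-reproducible.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_file = logging.FileHandler(outdir / "run.log", mode="w")
    log_file.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("redoxsig").addHandler(log_file)
    timings: dict[str, float] = {}
    summary: dict = {"version": __version__, "seed": config.seed,
                     "thresholds": {
                         "completeness_tau": config.completeness_tau,
                         "p": config.p_threshold,
                         "adj_p": config.adj_p_threshold,
                         "k": config.k_clusters,
                         "cross_r": config.cross_r_flag,
                     },
                     "batch_order": list(config.batch_order),
                     "counts": {}}
    try:
        t0 = time.perf_counter()
        # ---- simulate / load -------------------------------------------------
        if config.input_dir:
            study = read_study(config.input_dir)
        else:
            study = simulate_study(config.simulate, seed=config.seed)
            write_study(study, outdir / "study")
        timings["simulate"] = time.perf_counter() - t0

        # ---- quantify --------------------------------------------------------
        t0 = time.perf_counter()
        matrix = assemble_matrix(study.tables, study.designs)
        sample_of_channel = {}
        for design in study.designs:
            for ch, (sid, role) in design.channels.items():
                if role == ROLE_PARTICIPANT:
                    sample_of_channel[(design.plex_id, ch)] = sid
        gm = {
            sample_of_channel[(p, ch)]: med
            for p, meds in study.global_medians.items()
            for ch, med in meds.items()
            if (p, ch) in sample_of_channel
        }
        matrix, factors = abundance_correct(matrix, gm)
        occupancy = estimate_occupancy(study.tables, study.designs)
        with open(outdir / "occupancy.tsv", "w") as fh:
            fh.write("#occupancy_estimator=ratio_of_means_stand_in\n")
            occupancy.to_csv(fh, sep="\t", index_label="site_id", float_format="%.4f")
        _write_matrix(matrix, outdir / "site_matrix.tsv")
        summary["counts"]["sites_assembled"] = matrix.n_sites
        summary["counts"]["samples"] = matrix.n_samples
        timings["quantify"] = time.perf_counter() - t0

        # ---- normalize -------------------------------------------------------
        t0 = time.perf_counter()
        cohort = study.cohort.set_index("participant_id")
        plex_of_sample = pd.Series({
            sid: design.plex_id
            for design in study.designs
            for ch, (sid, role) in design.channels.items() if role == ROLE_PARTICIPANT
        })
        site_of_sample = cohort["biopsy_site"].reindex(matrix.data.columns)
        if list(config.batch_order) == ["collection_site", "plex"]:
            first, second = site_of_sample, plex_of_sample
        else:
            first, second = plex_of_sample, site_of_sample
        matrix, batch_params = sequential_batch_correct(
            matrix, first, second, allow_single_batch=config.allow_single_batch)
        bp = {k: (v.to_dict() if v is not None and not isinstance(v, list) else v)
              for k, v in batch_params.items() if k != "order"}
        with open(outdir / "batch_params.json", "w") as fh:
            json.dump({"order": batch_params["order"], **bp}, fh, indent=2, default=str)
        matrix = filter_completeness(matrix, config.completeness_tau)
        summary["counts"]["sites_post_completeness"] = matrix.n_sites
        if config.apply_target_filter:
            matrix = filter_target_proteins(matrix, _target_proteins(config))
        summary["counts"]["target_sites"] = matrix.n_sites
        matrix = median_center_rows(matrix)
        _write_matrix(matrix, outdir / "site_matrix_normalized.tsv")
        timings["normalize"] = time.perf_counter() - t0

        # ---- associate + signatures -----------------------------------------
        phenos = cohort[list(config.phenotypes)]
        summary["counts"]["significant"] = {}
        summary["counts"]["clusters"] = {}
        for ph in config.phenotypes:
            t0 = time.perf_counter()
            fits = fit_site_models(matrix, study.cohort, ph, config.covariates)
            prior, results = eb_moderate(
                fits, p_threshold=config.p_threshold,
                adj_p_threshold=config.adj_p_threshold)
            results.to_csv(outdir / f"associations_{ph}.tsv", sep="\t", index=False,
                           float_format="%.6g")
            with open(outdir / f"eb_prior_{ph}.json", "w") as fh:
                json.dump({"d0": prior.d0, "s02": prior.s02}, fh, indent=2)
            sig, eligible = select_significant(
                results, matrix, study.cohort, ph, config.p_threshold)
            summary["counts"]["significant"][ph] = len(sig)
            timings[f"associate_{ph}"] = time.perf_counter() - t0

            t0 = time.perf_counter()
            stars = results.set_index("site_id")["star"]
            sub = matrix.data.loc[eligible]
            clusters, assignments, leaf_order = build_signatures(
                sub, study.cohort, ph, phenos, k=config.k_clusters,
                covariates=config.covariates)
            summary["counts"]["clusters"][ph] = len(clusters)
            if clusters:
                rank = {s: i for i, s in enumerate(leaf_order)}
                pd.DataFrame({
                    "site_id": assignments.index,
                    "cluster": assignments.values,
                    "dendrogram_rank": [rank[s] for s in assignments.index],
                }).to_csv(outdir / f"clusters_{ph}.tsv", sep="\t", index=False)
                rows = []
                for cl in clusters:
                    row = {"phenotype": ph, "cluster": cl.index,
                           "n_sites": len(cl.members),
                           "n": int(cl.centroid.notna().sum()),
                           "r": cl.r, "p": cl.r_p, "adj_p_model": cl.model_adj_p}
                    for other, r in cl.cross_r.items():
                        row[f"r_{other}"] = r
                        row[f"flags_{other}"] = cl.cross_flags[other]
                    rows.append(row)
                pd.DataFrame(rows).to_csv(
                    outdir / f"centroid_correlations_{ph}.tsv", sep="\t",
                    index=False, float_format="%.6g")
                ph_values = cohort[ph]
                export = export_heatmap(sub, assignments, leaf_order, ph_values,
                                        stars, ph)
                with open(outdir / f"heatmap_{ph}.tsv", "w") as fh:
                    fh.write("#column_order=" + ",".join(export.column_order) + "\n")
                    export.to_frame().to_csv(fh, sep="\t", index_label="row",
                                             float_format="%.6g")
            timings[f"signatures_{ph}"] = time.perf_counter() - t0

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(outdir / "timings.json", "w") as fh:
            json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=2)
        return summary
    except Exception as exc:
        logger.error("pipeline aborted: %s (counts so far: %s)", exc, summary["counts"])
        raise
    finally:
        logging.getLogger("redoxsig").removeHandler(log_file)
        log_file.close()
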