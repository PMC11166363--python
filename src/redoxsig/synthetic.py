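"""Synthetic TMT18 redox-proteomics study generator.

Emulates a 56-participant aging-muscle cohort measured in 4 TMT18 plexes
(14 participant channels each, plus two pooled total-thiol reference
channels and two channels excluded from oxidation quantification), with
logit-normal Cys-site oxidation occupancy, planted phenotype-linked site
clusters, plex- and collection-site batch effects, channel loading, and
MCAR+MNAR missingness.  Every downstream stage of the pipeline is testable
against the ground truth this module records.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError
from .quantify import (
    DEFAULT_ROLES,
    ROLE_PARTICIPANT,
    ROLE_TOTAL_THIOL,
    ROLE_UNUSED,
    TMT18_CHANNELS,
    PlexDesign,
)

PHENOTYPES = ("vo2_peak", "walking_speed", "leg_strength", "leg_power")

#: Cohort marginal targets: mean, SD per variable.
DEFAULT_COHORT_PARAMS = {
    "age": (77.6, 5.1),
    "weight": (79.0, 18.8),
    "vo2_peak": (1588.0, 498.1),
    "walking_speed": (1.0, 0.2),
    "leg_strength": (179.3, 67.2),
    "leg_power": (347.1, 185.8),
}

#: Standardized loadings of each phenotype on (sex, age, weight); the
#: residual variance is 1 - sum of squares, so marginal SDs hit their target.
#: Signs follow physiology: men and heavier bodies have higher absolute VO2
#: and strength/power; age degrades everything; weight slows walking.
#: Magnitudes reflect the range restriction of a volunteer cohort of mobile
#: 70+ adults, where covariate-outcome correlations are attenuated relative
#: to the general population.
_PHENOTYPE_LOADINGS = {
    "vo2_peak": {"sex": 0.25, "age": -0.15, "weight": 0.20},
    "walking_speed": {"sex": 0.15, "age": -0.25, "weight": -0.15},
    "leg_strength": {"sex": 0.28, "age": -0.15, "weight": 0.18},
    "leg_power": {"sex": 0.28, "age": -0.20, "weight": 0.15},
}

#: 22 sarcomeric / contractile proteins (UniProt entry-name style) with
#: simulated Cys-site counts.
DEFAULT_TARGET_PROTEINS = {
    "NEBU": 25, "OBSCN": 18, "TITIN": 20, "MYOM1": 8, "MYOM2": 10,
    "ACTN2": 8, "ACTN3": 8, "ACTS": 6, "MYH7": 10, "TPM2": 5,
    "TNNI2": 4, "MYH1": 8, "MYH2": 8, "TNNT3": 4, "TNNC2": 3,
    "TPM1": 5, "TPM3": 4, "MYL1": 4, "MYBPC1": 7, "DES": 5,
    "FLNC": 8, "MYOZ1": 3,
}


@dataclass
class PlantedCluster:
    """One planted signature: ``n_sites`` on ``protein`` whose logit occupancy
    correlates with ``phenotype`` at population correlation ``rho``."""

    label: str
    protein: str
    n_sites: int
    phenotype: str
    rho: float

    def validate(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ConfigError(f"planted_clusters[{self.label}].rho must be in (-1, 1)")
        if self.phenotype not in PHENOTYPES:
            raise ConfigError(
                f"planted_clusters[{self.label}].phenotype {self.phenotype!r} unknown"
            )
        if self.n_sites < 1:
            raise ConfigError(f"planted_clusters[{self.label}].n_sites must be >= 1")


def default_planted_clusters() -> list[PlantedCluster]:
    """The default preset: three negative signatures and one positive
    ACTN3-like signature on leg power (8 sites, rho = +0.5)."""
    return [
        PlantedCluster("nebu_vo2", "NEBU", 5, "vo2_peak", -0.5),
        PlantedCluster("myom2_speed", "MYOM2", 8, "walking_speed", -0.5),
        PlantedCluster("actn2_strength", "ACTN2", 7, "leg_strength", -0.5),
        PlantedCluster("actn3_power", "ACTN3", 8, "leg_power", +0.5),
    ]


@dataclass
class SimConfig:
    """Study-generator configuration; defaults emulate the cohort marginals
    and plex design of the emulated study."""

    n_participants: int = 56
    n_plexes: int = 4
    participant_channels_per_plex: int = 14
    cohort_params: dict = field(default_factory=lambda: dict(DEFAULT_COHORT_PARAMS))
    n_background_proteins: int = 400
    background_sites_per_protein: int = 5
    target_proteins: dict = field(default_factory=lambda: dict(DEFAULT_TARGET_PROTEINS))
    planted_clusters: list = field(default_factory=default_planted_clusters)
    baseline_occupancy_logit_mean: float = -2.0
    baseline_occupancy_logit_sd: float = 1.0
    occupancy_noise_sd: float = 0.8  # logit units
    abundance_log2_mean: float = 18.0
    abundance_log2_sd: float = 2.0
    # sarcomeric/contractile proteins are among the most abundant in muscle;
    # their sites sit well above the detection-driven dropout tail
    target_abundance_bonus_log2: float = 3.0
    channel_loading_sd: float = 0.25  # log2 units
    plex_batch_location_sd: float = 0.5  # log2 units
    plex_batch_scale_range: tuple = (0.8, 1.25)
    collection_site_batch_sd: float = 0.3  # log2 units
    n_collection_sites: int = 2
    noise_sd: float = 0.25  # log2 units, multiplicative measurement noise
    missing_rate_mcar: float = 0.01
    mnar_slope: float = 0.5
    phenotype_missing_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.n_participants != self.n_plexes * self.participant_channels_per_plex \
                and self.n_participants != 0:
            raise ConfigError(
                "n_participants must equal n_plexes * participant_channels_per_plex "
                f"({self.n_plexes} * {self.participant_channels_per_plex})"
            )
        for name in ("baseline_occupancy_logit_sd", "occupancy_noise_sd",
                     "channel_loading_sd", "plex_batch_location_sd",
                     "collection_site_batch_sd", "noise_sd", "abundance_log2_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate_mcar < 1.0:
            raise ConfigError("missing_rate_mcar must be in [0, 1)")
        if self.mnar_slope < 0:
            raise ConfigError("mnar_slope must be >= 0")
        if not 0.0 <= self.phenotype_missing_rate < 1.0:
            raise ConfigError("phenotype_missing_rate must be in [0, 1)")
        lo, hi = self.plex_batch_scale_range
        if not 0 < lo <= hi:
            raise ConfigError("plex_batch_scale_range must satisfy 0 < lo <= hi")
        for var, ms in self.cohort_params.items():
            if len(ms) != 2 or ms[1] < 0:
                raise ConfigError(f"cohort_params[{var}] must be (mean, sd) with sd >= 0")
        for pc in self.planted_clusters:
            pc.validate()
            avail = self.target_proteins.get(pc.protein, 0)
            if pc.n_sites > avail:
                raise ConfigError(
                    f"planted_clusters[{pc.label}]: {pc.n_sites} sites requested but "
                    f"protein {pc.protein} has {avail}"
                )


@dataclass
class RawStudy:
    """Simulated study bundle: per-plex linear reporter tables, per-plex
    global channel medians, the plex designs, the (masked) cohort table and
    the ground-truth site table."""

    tables: dict  # plex_id -> DataFrame (site x channel, linear scale)
    global_medians: dict  # plex_id -> {channel: linear median}
    designs: list  # list[PlexDesign]
    cohort: pd.DataFrame
    truth: pd.DataFrame
    theta: pd.DataFrame | None = None  # simulated occupancy, site x participant


def _truncnorm_params(target_mean: float, target_sd: float, lower: float) -> tuple[float, float]:
    """Latent (mu, sigma) so that N(mu, sigma) truncated at ``lower`` has the
    requested mean and SD."""
    if target_sd == 0:
        return target_mean, 0.0

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a = (lower - mu) / sigma
        lam = stats.norm.pdf(a) / stats.norm.sf(a)
        mean = mu + sigma * lam
        var = sigma**2 * (1 + a * lam - lam**2)
        return [mean - target_mean, math.sqrt(max(var, 1e-12)) - target_sd]

    sol = optimize.root(moments, [target_mean, math.log(target_sd)], method="hybr")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def simulate_cohort(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate the participant table.

    Sexes are balanced to within one; age is truncated-normal with lower
    bound 70 and truncated moments matching the configured (mean, SD);
    each phenotype is a linear function of sex, age and weight plus noise,
    calibrated so its marginal mean and SD hit the configured targets.
    Phenotype values are masked missing-completely-at-random at
    ``phenotype_missing_rate``; the unmasked values are retained in
    ``df.attrs["complete_phenotypes"]`` for downstream simulation.
    """
    config.validate()
    n = config.n_participants
    cols = ["participant_id", "sex", "age", "weight", "biopsy_site", *PHENOTYPES]
    if n == 0:
        df = pd.DataFrame(columns=cols)
        df.attrs["complete_phenotypes"] = {ph: () for ph in PHENOTYPES}
        return df

    ids = [f"P{i + 1:03d}" for i in range(n)]
    sex = np.array([1] * (n // 2) + [0] * (n - n // 2))
    rng.shuffle(sex)

    age_mean, age_sd = config.cohort_params["age"]
    mu, sigma = _truncnorm_params(age_mean, age_sd, lower=70.0)
    if sigma == 0:
        age = np.full(n, mu)
    else:
        a = (70.0 - mu) / sigma
        age = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)

    wt_mean, wt_sd = config.cohort_params["weight"]
    weight = rng.normal(wt_mean, wt_sd, size=n)
    weight = np.maximum(weight, 0.01 * wt_mean)  # strict positivity

    # biopsy collection site assigned by plex blocks (plexes split evenly
    # across sites), partially confounding site with plex.
    per_plex = config.participant_channels_per_plex
    plex_of = np.arange(n) // per_plex
    half = config.n_plexes / config.n_collection_sites
    site = np.array([f"site_{chr(65 + int(p // half))}" for p in plex_of])

    z_sex = (sex - 0.5) / 0.5
    z_age = (age - age_mean) / age_sd if age_sd else np.zeros(n)
    z_wt = (weight - wt_mean) / wt_sd if wt_sd else np.zeros(n)

    pheno = {}
    for ph in PHENOTYPES:
        mean, sd = config.cohort_params[ph]
        load = _PHENOTYPE_LOADINGS[ph]
        r2 = sum(v**2 for v in load.values())
        latent = (load["sex"] * z_sex + load["age"] * z_age + load["weight"] * z_wt
                  + math.sqrt(1 - r2) * rng.standard_normal(n))
        y = mean + sd * latent
        pheno[ph] = np.maximum(y, 0.01 * mean)

    df = pd.DataFrame({
        "participant_id": ids, "sex": sex, "age": age, "weight": weight,
        "biopsy_site": site, **pheno,
    })
    # unmasked values kept for downstream simulation (tissue oxidation
    # depends on the participant's true phenotype, measured or not);
    # stored as plain tuples because pandas attrs must be ==-comparable
    complete = {ph: tuple(float(v) for v in df[ph]) for ph in PHENOTYPES}
    if config.phenotype_missing_rate > 0:
        for ph in PHENOTYPES:
            mask = rng.random(n) < config.phenotype_missing_rate
            df.loc[mask, ph] = np.nan
    df.attrs["complete_phenotypes"] = complete
    return df


def effect_size_for_rho(rho: float, occupancy_noise_sd: float) -> float:
    """Logit-scale slope b so that corr(logit occupancy, z-scored phenotype)
    equals rho when the residual logit SD is ``occupancy_noise_sd``:
    b = rho * sigma_u / sqrt(1 - rho^2)."""
    return rho * occupancy_noise_sd / math.sqrt(1.0 - rho**2)


def plant_signatures(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Build the ground-truth site table.

    One row per simulated Cys site: baseline logit occupancy mu_i, the
    per-phenotype logit effect b_i (zero except for planted-cluster members)
    and the cluster label.  Background sites are all null.
    """
    config.validate()
    rows = []

    def add_protein(protein: str, n_sites: int) -> list[int]:
        # Cys positions: sorted draw without replacement from a plausible span
        span = max(40, 12 * n_sites)
        pos = np.sort(rng.choice(np.arange(10, 10 + span), size=n_sites, replace=False))
        for p in pos:
            rows.append({"protein": protein, "position": int(p)})
        return [len(rows) - n_sites + i for i in range(n_sites)]

    target_rows: dict[str, list[int]] = {}
    for protein, n_sites in config.target_proteins.items():
        target_rows[protein] = add_protein(protein, n_sites)
    for b in range(config.n_background_proteins):
        add_protein(f"BG{b + 1:04d}", config.background_sites_per_protein)

    truth = pd.DataFrame(rows)
    truth["site_id"] = truth["protein"] + "_C" + truth["position"].astype(str)
    truth = truth.set_index("site_id")
    truth["mu"] = rng.normal(
        config.baseline_occupancy_logit_mean,
        config.baseline_occupancy_logit_sd,
        size=len(truth),
    )
    for ph in PHENOTYPES:
        truth[f"b_{ph}"] = 0.0
    truth["cluster"] = ""

    for pc in config.planted_clusters:
        idx = target_rows[pc.protein][: pc.n_sites]
        site_ids = truth.index[idx]
        b = effect_size_for_rho(pc.rho, config.occupancy_noise_sd)
        truth.loc[site_ids, f"b_{pc.phenotype}"] = b
        truth.loc[site_ids, "cluster"] = pc.label
    return truth


def build_designs(config: SimConfig, cohort: pd.DataFrame) -> list[PlexDesign]:
    """Assign participants to plexes/channels in id order, block by block."""
    designs = []
    ids = cohort["participant_id"].tolist()
    per = config.participant_channels_per_plex
    for p in range(config.n_plexes):
        plex_id = f"plex{p + 1}"
        block = ids[p * per: (p + 1) * per]
        channels: dict[str, tuple[str, str]] = {}
        part_i = 0
        for ch in TMT18_CHANNELS:
            role = DEFAULT_ROLES[ch]
            if role == ROLE_PARTICIPANT:
                if part_i < len(block):
                    channels[ch] = (block[part_i], ROLE_PARTICIPANT)
                    part_i += 1
            elif role == ROLE_TOTAL_THIOL:
                channels[ch] = (f"{plex_id}_pool_{ch}", ROLE_TOTAL_THIOL)
            else:
                channels[ch] = (f"{plex_id}_na_{ch}", ROLE_UNUSED)
        designs.append(PlexDesign(plex_id, channels))
    return designs


def simulate_reporter_data(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> RawStudy:
    """Simulate per-plex linear reporter-ion tables and global channel medians.

    Occupancy theta_ij = logistic(mu_i + sum_ph b_i,ph * z(y_j,ph) + u_ij);
    oxidized intensity = abundance_i x theta_ij x loading_c x plex batch x
    collection-site batch x multiplicative log-normal noise.  Total-thiol
    channels carry the same factors without the occupancy term (the pooled
    sample measures the full thiol pool).  Global channel medians reflect
    loading and batch only.  Missingness: MCAR at ``missing_rate_mcar`` plus
    an intensity-dependent MNAR term scaled by ``mnar_slope``.
    """
    config.validate()
    n = len(cohort)
    if n != config.n_participants:
        raise ConfigError("cohort size does not fit the plex design")
    designs = build_designs(config, cohort)

    complete = cohort.attrs.get("complete_phenotypes") or {
        ph: cohort[ph].to_numpy() for ph in PHENOTYPES
    }
    z = {}
    for ph in PHENOTYPES:
        mean, sd = config.cohort_params[ph]
        vals = np.asarray(complete[ph], dtype=float)
        zv = ((vals - mean) / sd) if sd else np.zeros(n)
        z[ph] = np.nan_to_num(zv)  # unknowable phenotype contributes no effect

    sites = truth.index.to_numpy()
    n_sites = len(sites)
    mu = truth["mu"].to_numpy()
    # linear predictor on the logit scale, site x participant
    eta = np.tile(mu[:, None], (1, n))
    for ph in PHENOTYPES:
        b = truth[f"b_{ph}"].to_numpy()
        eta = eta + b[:, None] * z[ph][None, :]
    eta = eta + rng.normal(0.0, config.occupancy_noise_sd, size=(n_sites, n))
    theta = 1.0 / (1.0 + np.exp(-eta))  # in (0, 1)

    log2_abundance = rng.normal(
        config.abundance_log2_mean, config.abundance_log2_sd, size=n_sites
    )
    is_target = truth["protein"].isin(config.target_proteins).to_numpy()
    log2_abundance = log2_abundance + config.target_abundance_bonus_log2 * is_target

    site_of_participant = cohort["biopsy_site"].to_numpy()
    uniq_sites = sorted(set(site_of_participant)) if n else []
    site_shift = {s: rng.normal(0.0, config.collection_site_batch_sd) for s in uniq_sites}

    tables: dict[str, pd.DataFrame] = {}
    global_medians: dict[str, dict[str, float]] = {}
    per = config.participant_channels_per_plex
    for p, design in enumerate(designs):
        plex_loc = rng.normal(0.0, config.plex_batch_location_sd)
        lo, hi = config.plex_batch_scale_range
        plex_scale = rng.uniform(lo, hi)
        # collection site of this plex's block (block assignment is uniform)
        block = slice(p * per, (p + 1) * per)
        block_site = site_of_participant[block][0] if n else None
        batch_log2 = plex_loc + (site_shift[block_site] if block_site else 0.0)

        loading = {ch: rng.normal(0.0, config.channel_loading_sd) for ch in design.channels}
        cols = {}
        part_channels = design.participant_channels()
        part_items = [(ch, sid) for ch, sid in part_channels.items()]
        theta_block = theta[:, block]
        for j, (ch, _sid) in enumerate(part_items):
            eps = rng.normal(0.0, config.noise_sd * plex_scale, size=n_sites)
            log2_int = (log2_abundance + np.log2(theta_block[:, j])
                        + loading[ch] + batch_log2 + eps)
            cols[ch] = np.exp2(log2_int)
        for ch in design.total_thiol_channels():
            eps = rng.normal(0.0, config.noise_sd * plex_scale, size=n_sites)
            cols[ch] = np.exp2(log2_abundance + loading[ch] + batch_log2 + eps)
        for ch, (_sid, role) in design.channels.items():
            if role == ROLE_UNUSED:
                eps = rng.normal(0.0, config.noise_sd * plex_scale, size=n_sites)
                mean_theta = theta_block.mean(axis=1) if n else np.full(n_sites, 0.5)
                cols[ch] = np.exp2(log2_abundance + np.log2(mean_theta)
                                   + loading[ch] + batch_log2 + eps)

        table = pd.DataFrame(cols, index=sites)
        table = table[[c for c in TMT18_CHANNELS if c in table.columns]]

        # missingness on the enriched (redox) measurements: per-cell MCAR
        # plus intensity-dependent site x plex dropout (a peptide not
        # identified in a plex is missing in all of that plex's channels)
        if config.missing_rate_mcar > 0 or config.mnar_slope > 0:
            vals = table.to_numpy()
            miss = rng.random(vals.shape) < config.missing_rate_mcar
            if config.mnar_slope > 0:
                site_mean = np.log2(vals).mean(axis=1)
                c5 = np.quantile(site_mean, 0.05)
                p_drop = config.mnar_slope / (1.0 + np.exp(-(c5 - site_mean)))
                miss |= (rng.random(len(site_mean)) < p_drop)[:, None]
            vals[miss] = np.nan
            table = pd.DataFrame(vals, index=table.index, columns=table.columns)

        tables[design.plex_id] = table
        global_medians[design.plex_id] = {
            ch: float(np.exp2(config.abundance_log2_mean + loading[ch] + batch_log2))
            for ch in design.channels
        }

    return RawStudy(
        tables=tables,
        global_medians=global_medians,
        designs=designs,
        cohort=cohort,
        truth=truth,
        theta=pd.DataFrame(theta, index=sites, columns=cohort["participant_id"]),
    )


def simulate_study(config: SimConfig, seed: Optional[int] = None) -> RawStudy:
    """Convenience wrapper: cohort + truth + reporter data from one seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort = simulate_cohort(config, rng)
    truth = plant_signatures(config, rng)
    return simulate_reporter_data(cohort, truth, config, rng)


def write_study(study: RawStudy, outdir: str | Path) -> None:
    """Write the study as plain-text tables.

    Per-plex crosstab TSVs (column 1 ``site_id``, then ``<plex>_<channel>``
    columns), ``samples.csv`` metadata, ``global_medians.tsv`` and
    ``truth.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for plex_id, table in study.tables.items():
        out = table.copy()
        out.columns = [f"{plex_id}_{c}" for c in out.columns]
        out.to_csv(outdir / f"{plex_id}.tsv", sep="\t", index_label="site_id",
                   float_format="%.6g")

    rows = []
    cohort = study.cohort.set_index("participant_id") if len(study.cohort) else study.cohort
    for design in study.designs:
        for ch, (sample_id, role) in design.channels.items():
            row = {"plex": design.plex_id, "channel": ch,
                   "sample_id": sample_id, "role": role}
            if role == ROLE_PARTICIPANT and sample_id in cohort.index:
                info = cohort.loc[sample_id]
                row.update({
                    "sex": info["sex"], "age": info["age"], "weight": info["weight"],
                    "biopsy_site": info["biopsy_site"],
                    **{ph: info[ph] for ph in PHENOTYPES},
                })
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "samples.csv", index=False, float_format="%.6g")

    gm_rows = [
        {"plex": plex_id, "channel": ch, "median": med}
        for plex_id, meds in study.global_medians.items()
        for ch, med in meds.items()
    ]
    pd.DataFrame(gm_rows).to_csv(outdir / "global_medians.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.6g")


def read_study(indir: str | Path) -> RawStudy:
    """Read back a study written by :func:`write_study`."""
    indir = Path(indir)
    samples = pd.read_csv(indir / "samples.csv")
    designs = []
    tables = {}
    for plex_id, grp in samples.groupby("plex", sort=True):
        channels = {
            r["channel"]: (r["sample_id"], r["role"]) for _, r in grp.iterrows()
        }
        designs.append(PlexDesign(plex_id, channels))
        tables[plex_id] = pd.read_csv(indir / f"{plex_id}.tsv", sep="\t",
                                      index_col="site_id")
    gm = pd.read_csv(indir / "global_medians.tsv", sep="\t")
    global_medians = {
        plex_id: dict(zip(grp["channel"], grp["median"]))
        for plex_id, grp in gm.groupby("plex", sort=True)
    }
    part = samples[samples["role"] == ROLE_PARTICIPANT].copy()
    cohort_cols = ["sample_id", "sex", "age", "weight", "biopsy_site", *PHENOTYPES]
    cohort = part[cohort_cols].rename(columns={"sample_id": "participant_id"})
    cohort = cohort.reset_index(drop=True)
    truth_path = indir / "truth.tsv"
    truth = pd.read_csv(truth_path, sep="\t", index_col="site_id") if truth_path.exists() else None
    return RawStudy(tables=tables, global_medians=global_medians, designs=designs,
                    cohort=cohort, truth=truth)
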