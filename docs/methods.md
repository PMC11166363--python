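# Methods

This note documents the statistical model behind `redoxsig`, the
synthetic-study generator that stands in for cohort data, the defaults
and why they were chosen, and the numerical decisions that a maintainer
would otherwise have to reverse-engineer.

## 1. Measurement model and preprocessing

### Site quantification

Input is a site-level crosstab per plex: rows are Cys sites keyed as
`<protein entry name>_C<1-based residue position>` (peptides spanning
several Cys residues keep a composite key with positions joined by `;`
and are treated as single sites — no splitting, no double counting),
columns are TMT18 reporter channels in linear scale. Channel roles per
plex: 14 participant channels (126–133N), two channels excluded from
oxidation quantification (133C, 134N), and two pooled total-thiol
reference channels (134C, 135N). Assembly takes the union of sites over
plexes, maps participant channels to sample ids, drops excluded
channels, routes total-thiol channels to occupancy estimation only, and
records nonpositive intensities as missing before the log2 transform.
A helper sums peptide-level rows to sites in linear scale for inputs one
level below the site-centric table.

### Abundance correction

Enriched (redox) intensities confound oxidation with protein abundance
and channel loading. The per-channel medians of the unenriched global
experiment, m_c (log2), carry that shared component. The correction is

    x′_ic = x_ic − t_c,   t_c = m_c − mean_c(m_c),

i.e. the global medians are rescaled so their average matches the
average redox column median and then subtracted, preserving the overall
redox scale (the correction terms sum to zero over channels). A channel
whose loading doubles in both the redox and global measurements cancels
out of every between-sample contrast; the only non-invariant piece is
the scale anchor mean_c(m_c), a per-matrix constant (1/n of the change)
that row median-centering removes exactly. All downstream statistics
are invariant to this constant.

### Occupancy

Per plex, occupancy% = 100 × mean(linear oxidized intensity over
participant channels) / mean(linear intensity over the two total-thiol
channels), clipped to [0, 100]; the study value averages the plexes
where both quantities are observed. This ratio-of-means estimator is a
documented stand-in for the original enrichment workflow's occupancy
calculation (whose exact form lives in prior work and is not restated
here); outputs carry an `#occupancy_estimator=ratio_of_means_stand_in`
metadata line. A total-thiol value that is zero or missing in both
reference channels makes that plex's occupancy missing rather than
raising an error. With measurement noise and loading switched off, the
estimator returns the mean simulated occupancy exactly — this identity
is a regression test.

### Batch adjustment

Batch effects are removed with a parametric empirical-Bayes
location/scale model. Per feature i: estimate the grand mean α_i (mean
over observed entries) and pooled variance σ̂²_i (mean squared residual
around the per-batch means); standardize to Z. Per batch b: estimate
location γ̂_ib (batch mean of Z) and scale δ̂²_ib (batch variance,
n−1 denominator); shrink toward batch-level priors — normal for γ
(mean/variance = moments of γ̂ across features), inverse-gamma for δ²
(shape/scale from the moments of δ̂² across features) — by iterating the
conditional posterior updates until the maximum absolute change falls
below 1e-4 (cap 100 iterations, both recorded). Adjusted values are
(Z − γ*)/δ* back-transformed by σ̂_i and α_i. Missing entries are
excluded from every estimate and stay missing.

Rules at the edges: a batch with fewer than two samples is an error; a
single batch is refused unless explicitly allowed (then the adjustment
is the identity); a feature observed in fewer than two batches passes
through unadjusted and is flagged; a feature unobserved (or observed
once) in some batch gets the identity for that batch only. The
standardization is intercept-only — no covariates enter the batch
design — because balanced plex assignment keeps phenotype–batch
confounding negligible in the simulated designs this package targets.

The two known batch factors — multiplex and biopsy collection site —
are corrected sequentially, plex first, site second; the order is a
configurable, recorded choice. Sequential one-factor passes were chosen
over a multi-factor fit for testability (each pass has a closed
simulation oracle); a constant site label skips the second pass with a
logged notice.

### Filtering and centering

Sites observed in at least 75 % of all sample columns are retained
(inclusive threshold: under a 4-plex/56-sample design, a site missing
exactly one plex sits at 42/56 = 75 % and is kept). Completeness is
computed over all participant columns regardless of phenotype
availability, since the filter precedes any phenotype-specific step.
The target-protein filter keeps sites on a configurable list of 22
sarcomeric/contractile proteins (case-sensitive entry-name match).
Finally each row is centered on its observed median. No imputation is
performed anywhere.

## 2. Association model

Per site and phenotype, ordinary least squares of (centered log2)
oxidation on [1, phenotype, sex, age, weight] over the samples where the
site value, the phenotype and all covariates are observed. Samples
missing the phenotype are excluded; sites with residual df < 3 (default,
configurable) or a rank-deficient design are skipped with a logged
count. The fit records β̂ (phenotype coefficient), the unitless design
quantity v = [(XᵀX)⁻¹]₁₁, s² and d.

Residual variances are pooled across sites under the scaled-F model
s² ~ s₀²·F(d, d₀). The prior (d₀, s₀²) is fitted by method of moments on
log s²: with e = log s² − ψ(d/2) + log(d/2), the excess of var(e) over
the mean sampling variance ψ′(d/2) equals ψ′(d₀/2), inverted by Newton
iteration on the trigamma function; d₀ = +∞ (complete pooling) when the
excess is nonpositive. The moderated statistic is
t̃ = β̂ / (s̃·√v) with s̃² = (d₀s₀² + ds²)/(d₀ + d), referred to a
Student t with d₀ + d df (normal when d₀ = ∞). Setting d₀ = 0
reproduces the ordinary t-test; both limits are unit-tested. Fewer than
10 positive residual variances triggers an unmoderated fallback with a
warning. P-values are two-sided; Benjamini–Hochberg adjustment (NA
passthrough, capped at 1) is applied within each phenotype's family —
by default the matrix as passed to the fit, i.e. post target-filter in
the standard pipeline, configurable by simply passing a different
matrix.

Sites with p < 0.05 form the significant set; the heatmap-eligible
subset additionally requires 100 % completeness across the samples that
have the phenotype.

## 3. Signatures

Heatmap-eligible significant sites are clustered on their row vectors
(restricted to phenotype-observed samples) by agglomerative clustering,
Euclidean distance, complete linkage, tree cut into exactly k = 6
groups (fewer rows lower k with a warning). Distance and linkage are
configurable (correlation + average offered); the defaults are recorded
in run metadata — the choice is genuinely open since clustering of this
kind is rarely reported with its metric. Cluster labels are relabeled
in dendrogram-leaf order, making assignments deterministic and
row-order-invariant up to relabeling; scipy's linkage provides the
documented lowest-index merge on tied heights.

Cluster centroids are per-sample means of member rows. Each centroid is
scored by Pearson r against its own raw (non-z-scored) phenotype with
the two-sided p from t = r√((n−2)/(1−r²)); fewer than 3 pairs or zero
variance yield NA. Cross-correlations against all four phenotypes carry
flags: |r| > 0.3 ("strong"), r < −0.30 with p < 0.05 ("negative"), and
r > 0.45 with p < 0.05 ("strong_positive" — reported as a flag only,
never used for selection). Centroids are also re-tested as combined
features through the same OLS + moderation + BH chain; with fewer than
two clusters the unadjusted p is reported with a log note.

Heatmap exports order columns by ascending phenotype (ties broken by
sample id), prepend a phenotype z-row computed as (y − median(y))/SD(y)
— the median-centered, SD-scaled reading of a "median-centered z-score",
the only one that yields unit-scale values — group rows by cluster in
dendrogram order, and star sites with adjusted p < 0.05.

## 4. Synthetic study generator

The generator emulates the study design end to end so that the pipeline
can be validated against known truth.

**Cohort.** 56 participants (4 plexes × 14 channels), sexes balanced
28/28 with randomized channel placement. Age is truncated-normal with
lower bound 70 whose *truncated* mean and SD match the targets
(77.6 ± 5.1 y) — the latent parameters are solved by moment matching,
not naively set, since truncation at 70 would otherwise bias the mean
upward by ~0.7 y. Weight is normal (79.0 ± 18.8 kg). Each phenotype —
VO₂ peak 1588.0 ± 498.1 mL/min, walking speed 1.0 ± 0.2 m/s, leg
strength (1RM) 179.3 ± 67.2 kg, peak leg power 347.1 ± 185.8 W — is a
linear function of standardized sex/age/weight plus noise, scaled so the
marginal mean and SD hit the targets. Covariate loadings are modest
(R² ≈ 0.11–0.14): a volunteer cohort of mobile 70+ adults is
range-restricted in both covariates and outcomes, which attenuates
covariate–outcome correlations relative to the general population. All
values are floored at 1 % of the target mean for strict positivity
(binding with probability ~1e-5; calibration is pre-floor). Phenotypes
are masked MCAR at 5 % per phenotype to exercise the exclusion rule;
the unmasked values still drive the simulated biology.

**Truth.** Sites live on 22 named sarcomeric proteins (181 sites total,
near the 173 targeted in the motivating design) plus background proteins
(default 400 × 5 sites = 2,000 null sites). Target-protein sites get a
+3 log2 abundance offset — sarcomeric proteins are among the most
abundant in muscle, which keeps their sites out of the detection-driven
dropout tail. Baseline logit occupancy is N(−2.0, 1.0²) (median
occupancy ≈ 12 %, a sizable minority above 20 %). Planted clusters set a
logit-scale slope b = ρσ_u/√(1−ρ²) against the z-scored target
phenotype, so the population correlation between a planted site's logit
occupancy and its phenotype is exactly ρ. The default preset plants
three negative signatures (NEBU×5 on VO₂ peak, MYOM2×8 on walking
speed, ACTN2×7 on leg strength, ρ = −0.5) and one positive ACTN3-like
signature (8 sites on leg power, ρ = +0.5).

**Measurements.** Occupancy θ_ij = logistic(μ_i + Σ b·z_j + u_ij) with
u ~ N(0, 0.8²) logit units — reversible thiol oxidation is dynamic, so
substantial between-individual biological spread is realistic, and it
keeps the fixed 0.25-log2 measurement noise from dominating the
biological signal. Oxidized intensity = abundance × θ × channel loading
(log2 SD 0.25) × plex batch (location log2 SD 0.5; scale factor
0.8–1.25 multiplying the noise SD) × collection-site batch (log2 SD
0.3) × multiplicative log-normal noise (log2 SD 0.25). Total-thiol
channels carry the same factors without θ (the pooled sample measures
the full thiol pool). The excluded channels are emitted with plausible
intensities and role `unused` so that ingestion must prove it drops
them. Global channel medians reflect loading × batch only. Collection
site is assigned by plex blocks (plexes 1–2 vs 3–4), partially
confounding site with plex as in a two-clinic study — deliberately
stressing the sequential correction.

**Missingness.** Per-cell MCAR (default 1 %) plus intensity-dependent
site×plex dropout: a site's whole 18-channel row in a plex goes missing
with probability `mnar_slope · logistic(c₅ − mean log2 intensity)`
(c₅ = the plex's 5th-percentile site level; default slope 0.5). The
plex-level mechanism mirrors real TMT data, where a peptide not
identified in a plex is missing in all of that plex's channels — this
is what makes 100 %-complete sites common and one-plex-missing sites
sit exactly at the 75 % completeness boundary. Setting the slope to 0
reduces exactly to per-cell MCAR (binomial completeness, unit-tested).

**What the generator does not emulate.** Spectrum-level effects
(isotope-impurity crosstalk, interference), peptide chemistry, protein
abundance differences between participants (abundance is site-level
constant, so abundance–phenotype confounding is absent), non-normal
phenotype tails, and structured (non-block) clinic assignment. Passing
tests therefore demonstrate the pipeline's statistical behavior under a
faithful but idealized generative model — calibration and recovery on
real data additionally depend on effects outside this model.

## 5. Calibration studies and problem sizes

`redoxsig.calibration` packages two replicate-level studies used by the
test suite and the acceptance script:

- **Null type-I error** — 20 replicate null cohorts (2,000 sites, 56
  samples, no planted effects, default nuisance parameters), full
  preprocessing, moderated association against one phenotype; the mean
  fraction of sites with p < 0.05 estimates the per-site type-I error
  (target 0.05; each replicate runs in ~0.1 s, so the study is cheap
  enough to run routinely).
- **Signature recovery** — 20 replicates of the default planted preset
  among 2,000 background sites; per replicate: planted-site sensitivity
  at p < 0.05, the sign of the best-Jaccard-matched recovered cluster's
  centroid correlation, and its cluster-level adjusted p. Jaccard
  matching against truth is a test-only device, never part of the
  analysis. Under these conditions per-site power is ~0.92–0.94 (the
  covariate adjustment costs √(1−R²), measurement noise ~3 %, and the
  realized per-cohort correlation fluctuates with SD ≈ 0.11 at n = 56),
  so per-replicate sensitivity hovers near the 0.8 threshold by
  construction; mean sensitivity across replicates is ~0.92.

## 6. Determinism and outputs

A single seeded NumPy generator drives every stochastic step; no global
random state is touched. Identical config + seed reproduce every
analytical output byte-for-byte. Wall-clock stage timings, which cannot
be reproducible, are written to a separate `timings.json` excluded from
that contract; `summary.json`, the stage TSVs and all JSON parameter
dumps are fully deterministic. Logs go to stderr and `run.log` without
timestamps. All thresholds (completeness 0.75, p 0.05, adjusted p 0.05,
k 6, cross-correlation flag 0.3) live in the run configuration; nothing
is hard-coded.

## 7. Known limitations

- The occupancy estimator is a stand-in (see §1); absolute occupancy
  values should be read as relative indices, not stoichiometries.
- The BH family choice (all retained sites vs target-protein sites) is
  configurable but defaults to the matrix as passed; family size
  changes adjusted p-values, not raw ones.
- The batch model assumes feature-wise Gaussian location/scale effects;
  heavy-tailed batch artifacts would call for the nonparametric prior
  variant, which is not implemented.
- With fewer than two clusters or fewer than three paired observations,
  signature statistics degrade gracefully to NAs/unadjusted values with
  log notes rather than errors — callers should check the flags.
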