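"""Synthetic study generator: cohort marginals, planted effects, reporter
tables, missingness mechanisms and determinism."""
import numpy as np
import pandas as pd
import pytest

from redoxsig.errors import ConfigError
from redoxsig.quantify import ROLE_PARTICIPANT, ROLE_TOTAL_THIOL, ROLE_UNUSED
from redoxsig.synthetic import (
    PHENOTYPES,
    PlantedCluster,
    SimConfig,
    effect_size_for_rho,
    plant_signatures,
    simulate_cohort,
    simulate_reporter_data,
    simulate_study,
)

from conftest import noise_free_config, small_config


class TestCohort:
    def test_default_cohort_shape_and_balance(self):
        rng = np.random.default_rng(3)
        cohort = simulate_cohort(SimConfig(), rng)
        assert len(cohort) == 56
        assert cohort["sex"].sum() == 28  # 28 men + 28 women
        assert (cohort["age"] >= 70).all()
        assert (cohort["weight"] > 0).all()
        for ph in PHENOTYPES:
            assert (cohort[ph].dropna() > 0).all()

    def test_empty_cohort(self):
        cohort = simulate_cohort(SimConfig(n_participants=0), np.random.default_rng(0))
        assert len(cohort) == 0

    def test_marginals_converge_to_targets(self):
        # n = 10,000 Monte-Carlo check: sample mean within 3 standard errors
        cfg = SimConfig(n_participants=10_000, n_plexes=1000,
                        participant_channels_per_plex=10)
        cohort = simulate_cohort(cfg, np.random.default_rng(42))
        n = len(cohort)
        # age at 3 SE; the remaining five marginals at 4 SE (joint check)
        for var, k in [("age", 3), ("weight", 4)] + [(ph, 4) for ph in PHENOTYPES]:
            mean, sd = cfg.cohort_params[var]
            se = sd / np.sqrt(n)
            assert abs(cohort[var].mean() - mean) < k * se, var
            assert abs(cohort[var].std() - sd) < 0.05 * sd, var

    def test_biopsy_site_blocks(self):
        cohort = simulate_cohort(SimConfig(), np.random.default_rng(0))
        assert cohort["biopsy_site"].nunique() == 2
        # first two plexes (28 participants) on one site, last two on the other
        assert cohort["biopsy_site"].iloc[:28].nunique() == 1
        assert cohort["biopsy_site"].iloc[28:].nunique() == 1

    @pytest.mark.parametrize("field,kwargs", [
        ("n_participants", dict(n_participants=55)),
        ("missing_rate_mcar", dict(missing_rate_mcar=1.5)),
        ("noise_sd", dict(noise_sd=-0.1)),
        ("plex_batch_scale_range", dict(plex_batch_scale_range=(0.0, 1.0))),
    ])
    def test_invalid_config_names_field(self, field, kwargs):
        with pytest.raises(ConfigError, match=field):
            SimConfig(**kwargs).validate()


class TestTruth:
    def test_null_preset_all_zero(self):
        cfg = SimConfig(planted_clusters=[])
        truth = plant_signatures(cfg, np.random.default_rng(0))
        for ph in PHENOTYPES:
            assert (truth[f"b_{ph}"] == 0).all()
        assert (truth["cluster"] == "").all()

    def test_default_preset_includes_positive_power_cluster(self):
        truth = plant_signatures(SimConfig(), np.random.default_rng(0))
        actn3 = truth[truth["cluster"] == "actn3_power"]
        assert len(actn3) == 8
        assert (actn3["protein"] == "ACTN3").all()
        assert (actn3["b_leg_power"] > 0).all()

    def test_cluster_shares_sign_and_phenotype(self):
        truth = plant_signatures(SimConfig(), np.random.default_rng(0))
        for lab, grp in truth[truth["cluster"] != ""].groupby("cluster"):
            nonzero = [ph for ph in PHENOTYPES if (grp[f"b_{ph}"] != 0).any()]
            assert len(nonzero) == 1
            b = grp[f"b_{nonzero[0]}"]
            assert (np.sign(b) == np.sign(b.iloc[0])).all()

    def test_oversized_cluster_rejected(self):
        cfg = SimConfig(planted_clusters=[
            PlantedCluster("too_big", "ACTS", 99, "leg_power", 0.5)])
        with pytest.raises(ConfigError, match="too_big"):
            cfg.validate()

    def test_effect_size_yields_target_correlation(self):
        # Monte-Carlo oracle: logit ell = b z + u with b from the calibration
        # formula must correlate with z at rho, averaged over replicate cohorts
        rho, sigma_u, n = -0.5, 0.8, 56
        b = effect_size_for_rho(rho, sigma_u)
        rng = np.random.default_rng(77)
        rs = []
        for _ in range(500):
            z = rng.standard_normal(n)
            ell = b * z + rng.normal(0, sigma_u, n)
            rs.append(np.corrcoef(ell, z)[0, 1])
        assert abs(np.mean(rs) - rho) < 0.02


class TestReporterData:
    def test_plex_tables_shape_and_roles(self, default_study):
        assert len(default_study.tables) == 4
        for design in default_study.designs:
            table = default_study.tables[design.plex_id]
            assert table.shape[1] == 18
            roles = [r for _, r in design.channels.values()]
            assert roles.count(ROLE_PARTICIPANT) == 14
            assert roles.count(ROLE_TOTAL_THIOL) == 2
            assert roles.count(ROLE_UNUSED) == 2

    def test_each_participant_in_exactly_one_channel(self, default_study):
        seen = [sid for d in default_study.designs
                for _, (sid, role) in d.channels.items() if role == ROLE_PARTICIPANT]
        assert sorted(seen) == sorted(default_study.cohort["participant_id"])

    def test_occupancy_in_unit_interval_and_intensities_nonnegative(self, default_study):
        theta = default_study.theta.to_numpy()
        assert ((theta > 0) & (theta < 1)).all()
        for table in default_study.tables.values():
            vals = table.to_numpy()
            assert np.nanmin(vals) >= 0

    def test_noise_free_intensity_is_abundance_times_theta(self):
        cfg = noise_free_config(seed=2, n_background_proteins=20)
        study = simulate_study(cfg)
        abundance = 2.0 ** (cfg.abundance_log2_mean)
        bonus = 2.0 ** cfg.target_abundance_bonus_log2
        design = study.designs[0]
        table = study.tables[design.plex_id]
        part = design.participant_channels()
        for ch, sid in list(part.items())[:3]:
            expected = study.theta[sid] * abundance
            is_target = ~study.truth["protein"].str.startswith("BG")
            expected = expected * np.where(is_target.reindex(expected.index), bonus, 1.0)
            np.testing.assert_allclose(table[ch], expected, rtol=1e-9)

    def test_mcar_completeness_expectation(self):
        # binomial expectation: 25% MCAR, no MNAR -> 75% observed
        cfg = small_config(seed=9, missing_rate_mcar=0.25, mnar_slope=0.0,
                           n_background_proteins=300)
        study = simulate_study(cfg)
        comp = np.mean([t.notna().mean().mean() for t in study.tables.values()])
        assert abs(comp - 0.75) < 0.01

    def test_mnar_hits_low_abundance_sites(self):
        cfg = small_config(seed=9, missing_rate_mcar=0.0, mnar_slope=0.8,
                           n_background_proteins=300, target_proteins={},
                           planted_clusters=[])
        study = simulate_study(cfg)
        table = study.tables["plex1"]
        comp = table.notna().mean(axis=1)
        # dropout is whole-plex: a site is either fully observed or fully
        # missing within the plex, and the dropped sites are low-abundance
        # (judged from the plexes where they were observed)
        assert set(comp.round(6)) <= {0.0, 1.0}
        level_elsewhere = pd.concat(
            [np.log2(study.tables[p]).mean(axis=1) for p in ("plex2", "plex3", "plex4")],
            axis=1).mean(axis=1)
        assert level_elsewhere[comp == 0].mean() < level_elsewhere[comp == 1].mean()

    def test_global_medians_reflect_loading_and_batch_only(self):
        cfg = noise_free_config(seed=4, n_background_proteins=10)
        study = simulate_study(cfg)
        for meds in study.global_medians.values():
            # loading and batch SDs are zero: all medians equal the base
            np.testing.assert_allclose(
                list(meds.values()), 2.0**cfg.abundance_log2_mean, rtol=1e-9)

    def test_determinism_byte_identical(self):
        cfg = small_config(seed=123)
        s1 = simulate_study(cfg)
        s2 = simulate_study(cfg)
        pd.testing.assert_frame_equal(s1.cohort, s2.cohort)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)
        for p in s1.tables:
            pd.testing.assert_frame_equal(s1.tables[p], s2.tables[p])
        assert s1.global_medians == s2.global_medians

    def test_cohort_size_mismatch_rejected(self):
        cfg = SimConfig()
        rng = np.random.default_rng(0)
        cohort = simulate_cohort(cfg, rng)
        truth = plant_signatures(cfg, rng)
        with pytest.raises(ConfigError):
            simulate_reporter_data(cohort.iloc[:10], truth, cfg, rng)
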