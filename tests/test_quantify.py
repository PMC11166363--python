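"""Matrix assembly, abundance correction and occupancy estimation."""
import numpy as np
import pandas as pd
import pytest

from redoxsig.errors import DesignError, SchemaError
from redoxsig.quantify import (
    PlexDesign,
    SiteQuantMatrix,
    abundance_correct,
    assemble_matrix,
    estimate_occupancy,
    sum_peptides_to_sites,
)
from redoxsig.synthetic import simulate_study

from conftest import noise_free_config, sample_global_medians


def tiny_design(plex_id, samples, tt=("134C", "135N"), unused=("133C",)):
    channels = {}
    chans = ["126", "127N", "127C", "128N"][: len(samples)]
    for ch, s in zip(chans, samples):
        channels[ch] = (s, "participant")
    for ch in tt:
        channels[ch] = (f"{plex_id}_pool_{ch}", "total_thiol")
    for ch in unused:
        channels[ch] = (f"{plex_id}_na_{ch}", "unused")
    return PlexDesign(plex_id, channels)


class TestAssemble:
    def test_full_design_yields_56_columns(self, default_study):
        matrix = assemble_matrix(default_study.tables, default_study.designs)
        assert matrix.n_samples == 56
        assert matrix.stage == "raw"
        # total-thiol and unused channels never become columns
        assert not any("pool" in c or "_na_" in c for c in matrix.data.columns)

    def test_union_semantics_site_in_one_plex(self):
        d1 = tiny_design("p1", ["s1", "s2"])
        d2 = tiny_design("p2", ["s3", "s4"])
        t1 = pd.DataFrame({"126": [4.0, 2.0], "127N": [8.0, 2.0],
                           "134C": [1, 1], "135N": [1, 1], "133C": [1, 1]},
                          index=["siteA", "siteB"])
        t2 = pd.DataFrame({"126": [16.0], "127N": [32.0],
                           "134C": [1], "135N": [1], "133C": [1]},
                          index=["siteA"])
        m = assemble_matrix({"p1": t1, "p2": t2}, [d1, d2])
        assert m.data.loc["siteB", ["s3", "s4"]].isna().all()
        assert m.data.loc["siteA", "s3"] == 4.0  # log2(16)

    def test_zero_intensity_becomes_missing(self):
        d1 = tiny_design("p1", ["s1", "s2"])
        t1 = pd.DataFrame({"126": [0.0, 2.0], "127N": [8.0, 2.0],
                           "134C": [1, 1], "135N": [1, 1], "133C": [1, 1]},
                          index=["siteA", "siteB"])
        m = assemble_matrix({"p1": t1}, [d1])
        assert np.isnan(m.data.loc["siteA", "s1"])
        assert m.data.loc["siteA", "s2"] == 3.0
        assert m.data.loc["siteB", "s1"] == 1.0

    def test_unknown_channel_raises(self):
        d1 = tiny_design("p1", ["s1"])
        t1 = pd.DataFrame({"126": [1.0], "999X": [1.0]}, index=["siteA"])
        with pytest.raises(SchemaError, match="999X"):
            assemble_matrix({"p1": t1}, [d1])

    def test_duplicate_sample_across_plexes_raises(self):
        d1 = tiny_design("p1", ["s1"])
        d2 = tiny_design("p2", ["s1"])
        t = pd.DataFrame({"126": [1.0]}, index=["siteA"])
        with pytest.raises(DesignError, match="s1"):
            assemble_matrix({"p1": t, "p2": t.copy()}, [d1, d2])

    def test_plex_order_invariance(self, default_study):
        m1 = assemble_matrix(default_study.tables, default_study.designs)
        rev_tables = dict(reversed(list(default_study.tables.items())))
        m2 = assemble_matrix(rev_tables, list(reversed(default_study.designs)))
        pd.testing.assert_frame_equal(
            m1.data, m2.data[m1.data.columns], check_like=False)

    def test_peptide_rollup_sums_linear(self):
        peps = pd.DataFrame({
            "site_id": ["A_C1", "A_C1", "B_C2"],
            "126": [1.0, 2.0, 5.0],
            "127N": [np.nan, np.nan, 1.0],
        })
        out = sum_peptides_to_sites(peps)
        assert out.loc["A_C1", "126"] == 3.0
        assert np.isnan(out.loc["A_C1", "127N"])  # no observed peptide


class TestAbundanceCorrect:
    def test_hand_toy_three_columns(self):
        # global log2 medians (10, 11, 10) -> t = (-1/3, +2/3, -1/3)
        data = pd.DataFrame([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]],
                            columns=["a", "b", "c"], index=["s1_C1", "s2_C1"])
        m = SiteQuantMatrix(data)
        gm = {"a": 2.0**10, "b": 2.0**11, "c": 2.0**10}
        corrected, factors = abundance_correct(m, gm)
        np.testing.assert_allclose(factors.correction.to_numpy(),
                                   [-1 / 3, 2 / 3, -1 / 3])
        np.testing.assert_allclose(corrected.data["b"], data["b"] - 2 / 3)
        np.testing.assert_allclose(corrected.data["a"], data["a"] + 1 / 3)
        # overall redox scale preserved
        assert abs(corrected.data.median(axis=0).mean()
                   - data.median(axis=0).mean()) < 1e-9
        assert corrected.stage == "abundance_corrected"

    def test_equal_medians_identity(self):
        data = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)),
                            columns=list("abcd"))
        m = SiteQuantMatrix(data)
        corrected, _ = abundance_correct(m, {c: 1000.0 for c in "abcd"})
        pd.testing.assert_frame_equal(corrected.data, data)

    def test_doubling_one_channel_cancels(self, default_study):
        # a x2 loading change entering both the redox channel and its global
        # median cancels: corrected matrices agree up to the documented
        # mean-median scale anchor (a uniform constant), hence exactly after
        # row centering
        matrix = assemble_matrix(default_study.tables, default_study.designs)
        gm = sample_global_medians(default_study)
        base, _ = abundance_correct(matrix, gm)
        col = matrix.data.columns[7]
        bumped = SiteQuantMatrix(matrix.data.copy(), stage="raw")
        bumped.data[col] = bumped.data[col] + 1.0  # doubling in linear scale
        gm2 = dict(gm)
        gm2[col] = 2.0 * gm2[col]
        corrected, _ = abundance_correct(bumped, gm2)
        diff = (corrected.data - base.data).to_numpy()
        assert np.nanmax(diff) - np.nanmin(diff) < 1e-9  # uniform constant
        from redoxsig.normalize import median_center_rows
        np.testing.assert_allclose(
            median_center_rows(corrected).data.to_numpy(),
            median_center_rows(base).data.to_numpy(), atol=1e-9)

    def test_missing_median_listed(self):
        m = SiteQuantMatrix(pd.DataFrame([[1.0, 2.0]], columns=["a", "b"],
                                         index=["s_C1"]))
        with pytest.raises(SchemaError, match="b"):
            abundance_correct(m, {"a": 10.0})


class TestOccupancy:
    def test_hand_toys(self):
        d = tiny_design("p1", ["s1", "s2"], tt=("134C", "135N"), unused=())
        # full oxidation: oxidized mean equals total-thiol mean
        t_full = pd.DataFrame({"126": [100.0], "127N": [100.0],
                               "134C": [100.0], "135N": [100.0]}, index=["A_C1"])
        occ = estimate_occupancy({"p1": t_full}, [d])
        assert occ.loc["A_C1", "occ_p1"] == 100.0
        # (10+30)/2 over (100+100)/2 -> 20%
        t20 = pd.DataFrame({"126": [10.0], "127N": [30.0],
                            "134C": [100.0], "135N": [100.0]}, index=["A_C1"])
        occ = estimate_occupancy({"p1": t20}, [d])
        assert occ.loc["A_C1", "occ_p1"] == pytest.approx(20.0)

    def test_missing_propagation(self):
        d1 = tiny_design("p1", ["s1", "s2"], unused=())
        d2 = tiny_design("p2", ["s3", "s4"], unused=())
        t1 = pd.DataFrame({"126": [np.nan], "127N": [np.nan],
                           "134C": [100.0], "135N": [100.0]}, index=["A_C1"])
        t2 = pd.DataFrame({"126": [10.0], "127N": [30.0],
                           "134C": [100.0], "135N": [100.0]}, index=["A_C1"])
        occ = estimate_occupancy({"p1": t1, "p2": t2}, [d1, d2])
        assert np.isnan(occ.loc["A_C1", "occ_p1"])
        assert occ.loc["A_C1", "occ_avg"] == pytest.approx(20.0)

    def test_total_thiol_zero_gives_missing_not_error(self):
        d = tiny_design("p1", ["s1", "s2"], unused=())
        t = pd.DataFrame({"126": [10.0], "127N": [30.0],
                          "134C": [0.0], "135N": [0.0]}, index=["A_C1"])
        occ = estimate_occupancy({"p1": t}, [d])
        assert np.isnan(occ.loc["A_C1", "occ_p1"])

    def test_noise_free_recovers_mean_theta(self):
        cfg = noise_free_config(seed=3, n_background_proteins=15)
        study = simulate_study(cfg)
        occ = estimate_occupancy(study.tables, study.designs)
        for p, design in enumerate(study.designs):
            block = study.cohort["participant_id"].iloc[p * 14:(p + 1) * 14]
            expected = (study.theta[block].mean(axis=1) * 100.0).reindex(occ.index)
            np.testing.assert_allclose(occ[f"occ_{design.plex_id}"], expected,
                                       rtol=1e-9)

    def test_monotone_in_single_oxidized_intensity(self):
        d = tiny_design("p1", ["s1", "s2"], unused=())
        base = pd.DataFrame({"126": [10.0], "127N": [30.0],
                             "134C": [100.0], "135N": [100.0]}, index=["A_C1"])
        occ0 = estimate_occupancy({"p1": base}, [d]).loc["A_C1", "occ_p1"]
        for bump in (1.0, 10.0, 500.0):
            t = base.copy()
            t.loc["A_C1", "126"] += bump
            occ1 = estimate_occupancy({"p1": t}, [d]).loc["A_C1", "occ_p1"]
            assert occ1 >= occ0
            occ0 = occ1

    def test_clipped_at_100(self):
        d = tiny_design("p1", ["s1", "s2"], unused=())
        t = pd.DataFrame({"126": [500.0], "127N": [300.0],
                          "134C": [100.0], "135N": [100.0]}, index=["A_C1"])
        occ = estimate_occupancy({"p1": t}, [d])
        assert occ.loc["A_C1", "occ_p1"] == 100.0
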