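"""Generator behavior: determinism, calibration targets, degenerate cases."""

import numpy as np
import pytest

from tryplipid import StudyConfig, synthetic as syn
from tryplipid.lipidomics import normalize_to_standard


GENERATORS = {
    "ld_counts": lambda c: syn.gen_ld_counts(c, "fed"),
    "flow": lambda c: syn.gen_flow_population(c, "fed"),
    "growth": syn.gen_growth_curve,
    "decay": syn.gen_decay_experiment,
    "lipidome": lambda c: syn.gen_lipidome(c, "fed"),
    "proteome": syn.gen_proteome_table,
    "activity": syn.gen_activity_table,
    "tlc": lambda c: syn.gen_tlc_lane(c, "fed"),
}


@pytest.mark.parametrize("name", sorted(GENERATORS))
def test_fixed_seed_gives_byte_identical_tables(name, config):
    gen = GENERATORS[name]
    assert gen(config).to_csv() == gen(StudyConfig()).to_csv()


@pytest.mark.parametrize("name", sorted(set(GENERATORS) - {"activity"}))
def test_different_seed_changes_output(name, config):
    gen = GENERATORS[name]
    assert gen(config).to_csv() != gen(config.replace(seed=7)).to_csv()


class TestLdCounts:
    def test_fed_sample_reaches_but_never_exceeds_the_per_cell_maximum(self, config):
        counts = syn.gen_ld_counts(config, "fed")["count"]
        assert counts.max() == config.ld_max == 9
        assert counts.min() >= 0
        assert np.issubdtype(counts.dtype, np.integer)

    def test_fed_unfed_mean_ratio_matches_target(self, config):
        fed = syn.gen_ld_counts(config, "fed")["count"].mean()
        unfed = syn.gen_ld_counts(config, "unfed")["count"].mean()
        assert fed / unfed == pytest.approx(4.7, abs=0.2)

    def test_unit_fold_is_the_identity_case(self, config):
        cfg = config.replace(ld_fold=1.0, flow_fold=1.0)
        fed = syn.gen_ld_counts(cfg, "fed")["count"]
        unfed = syn.gen_ld_counts(cfg, "unfed")["count"]
        se = np.sqrt(fed.var() / len(fed) + unfed.var() / len(unfed))
        assert abs(fed.mean() - unfed.mean()) < 3 * se

    def test_distribution_is_unimodal(self, config):
        freqs = (
            syn.gen_ld_counts(config, "fed")["count"].value_counts().sort_index()
        )
        diffs = np.sign(np.diff(freqs.to_numpy()))
        # rises then falls: at most one sign change in the frequency profile
        changes = np.sum(np.diff(diffs[diffs != 0]) != 0)
        assert changes <= 1

    def test_fed_mean_above_maximum_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="maximum"):
            StudyConfig(unfed_ld_mean=2.5)

    def test_unknown_condition_rejected(self, config):
        with pytest.raises(ValueError, match="condition"):
            syn.gen_ld_counts(config, "starved")


class TestFlowPopulation:
    def test_default_mean_ratio_matches_target(self, config):
        fed = syn.gen_flow_population(config, "fed")["intensity"].mean()
        unfed = syn.gen_flow_population(config, "unfed")["intensity"].mean()
        assert fed / unfed == pytest.approx(4.6, abs=0.2)

    def test_unit_fold_gives_unit_ratio(self, config):
        cfg = config.replace(ld_fold=1.0, flow_fold=1.0)
        fed = syn.gen_flow_population(cfg, "fed")["intensity"].mean()
        unfed = syn.gen_flow_population(cfg, "unfed")["intensity"].mean()
        assert fed / unfed == pytest.approx(1.0, abs=0.05)

    def test_zero_background_single_droplet_mean_is_droplet_intensity(self, config):
        cfg = config.replace(flow_background=0.0, noise_cv=0.0)
        df = syn.gen_flow_population(
            cfg, "fed", counts=np.ones(20000, dtype=int), droplet_intensity_mean=7.0
        )
        assert df["intensity"].mean() == pytest.approx(7.0, rel=0.02)
        assert (df["intensity"] > 0).all()


class TestGrowthCurve:
    def test_noise_free_densities_follow_exact_doubling(self, config):
        cfg = config.replace(noise_cv=0.0, doubling_time_h=12.0)
        df = syn.gen_growth_curve(cfg, timepoints_h=[0.0, 12.0, 24.0])
        assert df["density_cells_per_ml"].iloc[0] == pytest.approx(cfg.growth_n0)
        assert df["density_cells_per_ml"].iloc[2] == pytest.approx(4 * cfg.growth_n0)

    def test_non_increasing_timepoints_rejected(self, config):
        with pytest.raises(ValueError, match="increasing"):
            syn.gen_growth_curve(config, timepoints_h=[0.0, 8.0, 8.0])

    def test_densities_strictly_positive(self, config):
        assert (syn.gen_growth_curve(config)["density_cells_per_ml"] > 0).all()


class TestDecayExperiment:
    def test_noise_free_pure_dilution_halves_at_one_doubling_time(self, config):
        cfg = config.replace(
            noise_cv=0.0, basal_level=0.0, catabolic_rate_h=0.0,
            decay_timepoints_h=(0.0, cfg_td := config.doubling_time_h),
        )
        df = syn.gen_decay_experiment(cfg)
        assert df.loc[df.time_h == cfg_td, "signal"].unique() == pytest.approx(0.5)

    def test_signal_approaches_basal_plateau_at_late_times(self, config):
        cfg = config.replace(
            noise_cv=0.0, basal_level=0.2,
            decay_timepoints_h=tuple(np.arange(0.0, 200.0, 20.0)),
        )
        df = syn.gen_decay_experiment(cfg)
        late = df.loc[df.time_h == df.time_h.max(), "signal"]
        assert late.unique() == pytest.approx(0.2, abs=1e-3)

    def test_replicate_count_and_positivity(self, config):
        df = syn.gen_decay_experiment(config)
        assert set(df["replicate"]) == set(range(config.replicates))
        assert (df["signal"] > 0).all()


class TestLipidome:
    def test_catalog_size_and_single_standard(self, config):
        df = syn.gen_lipidome(config, "fed")
        assert (df["is_standard"] == 0).sum() == 96
        assert (df["is_standard"] == 1).sum() == 1
        assert df["species_label"].is_unique
        assert (df["intensity"] > 0).all()

    def test_fed_54_3_exceeds_unfed(self, config):
        def norm_54_3(condition):
            t = normalize_to_standard(syn.gen_lipidome(config, condition))
            return t.loc[t.species_label == "54:3", "normalized_intensity"].sum()

        assert norm_54_3("fed") > norm_54_3("unfed")

    def test_uniform_dominance_is_symmetric(self, config):
        cfg = config.replace(dominant_classes={})
        df = syn.gen_lipidome(cfg, "fed")
        species = df[df.is_standard == 0]["intensity"]
        assert species.max() < 2 * species.mean()


class TestProteome:
    def test_single_ablated_protein_with_target_ratio(self, config):
        df = syn.gen_proteome_table(config)
        assert len(df) == config.n_proteins
        row = df[df.protein_id == syn.ABLATED_PROTEIN_ID].iloc[0]
        assert row.abundance_wt / row.abundance_ko == pytest.approx(140, rel=0.15)
        assert row.peptides >= 2

    def test_some_rows_have_single_peptide_support(self, config):
        df = syn.gen_proteome_table(config)
        assert (df["peptides"] == 1).sum() >= 1
        assert (df["peptides"] >= 1).all()


class TestActivityTable:
    def test_printed_summary_rows_are_stored_verbatim(self):
        df = syn.gen_activity_table()
        hadh = df[(df.genotype == "WT") & (df.fraction == "WCE")
                  & (df.glucose == "+gluc") & (df.enzyme == "HADH")].iloc[0]
        assert (hadh["mean_mU_per_mg"], hadh["sem"], hadh["n"]) == (6.62, 0.63, 5)
        gpdh = df[(df.genotype == "WT") & (df.fraction == "glyco")
                  & (df.glucose == "+gluc") & (df.enzyme == "GPDH")].iloc[0]
        assert (gpdh["mean_mU_per_mg"], gpdh["sem"], gpdh["n"]) == (213.18, 4.12, 3)

    def test_all_activities_positive(self):
        df = syn.gen_activity_table()
        assert (df["mean_mU_per_mg"] > 0).all()
        assert (df["sem"] >= 0).all()


class TestTlcLane:
    def test_band_map_has_tag_at_expected_rf(self, config):
        df = syn.gen_tlc_lane(config, "fed")
        assert set(df["rf"].unique()) == {0.0, 0.08, 0.29, 0.50, 0.90}

    def test_unfed_tag_area_is_the_normalization_anchor(self, config):
        cfg = config.replace(noise_cv=0.0)
        df = syn.gen_tlc_lane(cfg, "unfed")
        assert df.loc[df.rf == 0.50, "area"].unique() == pytest.approx(1.0)

    def test_fed_tag_fold_matches_target(self, config):
        fed = syn.gen_tlc_lane(config, "fed")
        unfed = syn.gen_tlc_lane(config, "unfed")
        fold = (
            fed.loc[fed.rf == 0.50, "area"].mean()
            / unfed.loc[unfed.rf == 0.50, "area"].mean()
        )
        assert fold == pytest.approx(4.6, rel=0.1)
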