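import numpy as np
import pandas as pd
import pytest

from hsp90cl import interactome, occupancy, proteolysis, silac
from hsp90cl import simulate as sim


def analyze_prm(transitions, panel):
    """Run the full occupancy path on a simulated transition table."""
    quants = silac.peptide_areas_from_transitions(transitions)
    z = silac.protein_reference_ratio(quants, panel.normalization)
    triplets = silac.assemble_ratio_triplets(quants, panel, z)
    return occupancy.occupancy_table(triplets)


class TestPrmSimulator:
    def test_noise_free_forward_model_inverts_exactly(self):
        panel = sim.default_prm_panel()
        truth = sim.PrmTruth(occupancy_light={"S226": 0.95, "S255": 0.95},
                             occupancy_heavy=0.0, mixing_ratio=1.0,
                             noise_sd=0.0)
        transitions, _ = sim.simulate_prm_experiment(truth, panel, seed=1)
        est = analyze_prm(transitions, panel)
        assert np.allclose(est["occ_light"], 0.95, atol=1e-12)
        assert np.allclose(est["occ_heavy"], 0.0, atol=1e-12)

    def test_same_seed_reproduces_identical_tables(self):
        truth = sim.PrmTruth(occupancy_light={"S226": 0.9, "S255": 0.8})
        t1, r1 = sim.simulate_prm_experiment(truth, seed=7)
        t2, r2 = sim.simulate_prm_experiment(truth, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_channel_shared_ionization_cancels_in_ratios(self):
        # at sigma=0 the per-peptide H/L ratio must be independent of the
        # (random) ionization factor: normalization peptides sit exactly
        # at rho
        truth = sim.PrmTruth(occupancy_light={"S226": 0.9, "S255": 0.8},
                             mixing_ratio=1.7, noise_sd=0.0)
        transitions, _ = sim.simulate_prm_experiment(truth, seed=3)
        quants = silac.peptide_areas_from_transitions(transitions)
        norm = quants[quants["modified_sequence"].isin(
            sim.default_prm_panel().normalization)]
        assert np.allclose(norm["hl_ratio"], 1.7, atol=1e-12)

    def test_mean_recovery_under_noise(self):
        # many peptide pairs at one occupancy: the mean estimate is within
        # +/-0.01 of truth (Monte-Carlo check with the simulator as oracle)
        pairs = tuple(
            sim.PeptidePair(f"T{i:03d}", f"AAEK{i:03d}pSK", f"AAEK{i:03d}SK")
            for i in range(100))
        panel = sim.PrmPanel(pairs=pairs, normalization=("NORMPEPK",
                                                         "OTHERNORMK",
                                                         "THIRDNORMK"))
        truth = sim.PrmTruth(
            occupancy_light={p.site: 0.80 for p in pairs},
            occupancy_heavy=0.01, noise_sd=0.05, n_replicates=1)
        transitions, _ = sim.simulate_prm_experiment(truth, panel, seed=11)
        est = analyze_prm(transitions, panel)
        assert abs(est["occ_light"].mean() - 0.80) < 0.01

    def test_panel_without_normalization_peptides_rejected(self):
        panel = sim.PrmPanel(pairs=sim.default_prm_panel().pairs,
                             normalization=())
        with pytest.raises(ValueError, match="normalization"):
            sim.simulate_prm_experiment(
                sim.PrmTruth(occupancy_light={"S226": 0.9, "S255": 0.9}),
                panel, seed=0)

    @pytest.mark.parametrize("bad", [
        dict(occupancy_light={"S226": 1.2, "S255": 0.9}),
        dict(occupancy_light={"S226": 0.9, "S255": 0.9}, mixing_ratio=0.0),
        dict(occupancy_light={"S226": 0.9, "S255": 0.9}, noise_sd=-1.0),
    ])
    def test_invalid_truth_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.simulate_prm_experiment(sim.PrmTruth(**bad), seed=0)


class TestCoipSimulator:
    def test_full_control_missingness_is_forced(self):
        truth = sim.CoipTruth(control_missing_rate=1.0,
                              n_true_interactors=20, n_background=30)
        groups, truth_table, design = sim.simulate_coip_tables(
            truth, "labelfree", seed=5)
        controls = design.loc[design["is_control"], "sample_id"]
        interactors = truth_table.loc[truth_table["is_interactor"],
                                      "protein_ids"]
        sub = groups[groups["protein_ids"].isin(interactors)]
        for s in controls:
            assert sub[f"iBAQ {s}"].isna().all()

    def test_decoys_and_contaminants_never_survive_filters(self):
        groups, _, design = sim.simulate_coip_tables(sim.CoipTruth(),
                                                     "labelfree", seed=6)
        kept, log = interactome.filter_protein_groups(groups, design,
                                                      "labelfree")
        assert not kept["protein_ids"].str.startswith(("REV__",
                                                       "CON__")).any()
        assert (log["reason"] == "decoy").sum() == 8
        assert (log["reason"] == "contaminant").sum() == 8

    def test_nonpositive_replicate_count_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            sim.CoipTruth(n_replicates_labelfree=0)

    def test_silac_bait_row_carries_mixing_offset(self):
        truth = sim.CoipTruth(bait_log2_offset=0.7)
        groups, _, design = sim.simulate_coip_tables(truth, "silac", seed=2)
        bait = groups.loc[groups["protein_ids"] == truth.bait_id]
        ratios = np.log2(bait[[c for c in groups.columns
                               if c.startswith("Ratio")]].to_numpy(float))
        assert np.allclose(ratios, 0.7, atol=0.1)


class TestProteolysisSimulator:
    def test_noise_free_band_fractions_match_truth(self):
        truth = sim.ProteolysisTruth(noise_sd=0.0)
        matrix, truth_table = sim.simulate_proteolysis_bands(truth, seed=4)
        ffl = proteolysis.fraction_full_length(matrix)
        merged = ffl.merge(truth_table, on=["genotype", "dose"])
        assert np.allclose(merged["ratio"], merged["full_length_fraction"],
                           atol=1e-12)

    def test_dose_zero_puts_all_intensity_in_band_a(self):
        matrix, _ = sim.simulate_proteolysis_bands(seed=4)
        at_zero = matrix[matrix["dose"] == 0]
        assert (at_zero["band"] == "A").all()

    def test_after_site_peptides_have_higher_band_a_lane_ratio(self):
        # the C-side cleavage product migrates below the analyzed lane
        # range, so peptides after the cut keep most of their signal in
        # band A while peptides before the cut share it with the N-side
        # fragment band
        matrix, _ = sim.simulate_proteolysis_bands(
            sim.ProteolysisTruth(noise_sd=0.01), seed=9)
        bvl = proteolysis.band_vs_lane_ratio(matrix)
        sides = proteolysis.assign_cleavage_side(
            matrix[["peptide", "start", "end"]].drop_duplicates())
        merged = bvl.merge(sides, on="peptide")
        positive = merged[merged["dose"] > 0]
        before = positive.loc[positive["side"] == "before", "ratio"]
        after = positive.loc[positive["side"] == "after", "ratio"]
        assert after.median() > before.median()

    def test_span_outside_protein_rejected(self):
        panel = pd.DataFrame({"peptide": ["bad"], "start": [700],
                              "end": [900]})
        with pytest.raises(ValueError, match="span"):
            sim.simulate_proteolysis_bands(panel=panel, seed=0)


class TestCwbSimulator:
    def test_analyzed_fraction_must_be_a_proper_fraction(self):
        with pytest.raises(ValueError, match="fraction_analyzed"):
            sim.simulate_cwb_signals(
                sim.CwbTruth(fraction_analyzed={"CM": 0.0, "lysate": 0.5}))

    def test_zero_secretion_recovers_zero(self):
        truth = sim.CwbTruth(secreted_fraction={"WT": 0.0}, noise_sd=0.0)
        meas, _ = sim.simulate_cwb_signals(truth, seed=1)
        from hsp90cl import cwb
        ratios = cwb.absolute_ratio_table(meas)
        est, _ = cwb.secreted_fraction(
            ratios[ratios["target"] == "HA"],
            ratios[ratios["target"] == "actin"], compare=None)
        assert abs(est[0].mean) < 1e-12

    def test_same_seed_is_deterministic(self):
        m1, _ = sim.simulate_cwb_signals(seed=3)
        m2, _ = sim.simulate_cwb_signals(seed=3)
        pd.testing.assert_frame_equal(m1, m2)
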