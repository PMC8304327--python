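import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hsp90cl import interactome

from conftest import make_group_row


class TestFilters:
    def test_quoted_count_and_presence_rules_on_toy_table(self, toy_design):
        rows = [
            make_group_row("keep", 2, 4, 6, design=toy_design),
            make_group_row("few_unique", 1, 4, 6, design=toy_design),
            make_group_row("decoy", 5, 8, 20, reverse=True,
                           design=toy_design),
            make_group_row("patchy", 5, 8, 20, design=toy_design,
                           identified=[True, True, False, True, True,
                                       False]),
        ]
        groups = pd.DataFrame(rows)
        kept, log = interactome.filter_protein_groups(groups, toy_design,
                                                      "labelfree")
        assert kept["protein_ids"].tolist() == ["keep"]
        reasons = dict(zip(log["protein_ids"], log["reason"]))
        assert reasons == {"few_unique": "unique_peptides",
                           "decoy": "decoy", "patchy": "presence"}

    def test_labelfree_presence_needs_one_complete_condition(self,
                                                             toy_design):
        # identified in all control replicates but not all bait replicates
        row = make_group_row("ctrl_only", 3, 6, 9, design=toy_design,
                             identified=[True, False, True,
                                         True, True, True])
        kept, _ = interactome.filter_protein_groups(
            pd.DataFrame([row]), toy_design, "labelfree")
        assert kept["protein_ids"].tolist() == ["ctrl_only"]

    def test_silac_presence_requires_every_replicate(self):
        design = pd.DataFrame({
            "sample_id": [f"rep{i}" for i in range(1, 5)],
            "condition": "WTvsAA", "replicate": range(1, 5),
            "is_control": False})
        row = {"protein_ids": "P1", "gene_names": "P1", "reverse": False,
               "contaminant": False, "only_by_site": False,
               "unique_peptides": 3, "peptides": 6, "msms_count": 9}
        for i, s in enumerate(design["sample_id"]):
            row[f"Ratio H/L normalized {s}"] = 1.5
            row[f"Identification type {s}"] = i != 2  # missing in 1 of 4
        kept, log = interactome.filter_protein_groups(
            pd.DataFrame([row]), design, "silac")
        assert kept.empty
        assert log["reason"].tolist() == ["presence"]

    def test_empty_table_passes_through(self, toy_design):
        cols = list(make_group_row(design=toy_design))
        kept, log = interactome.filter_protein_groups(
            pd.DataFrame(columns=cols), toy_design, "labelfree")
        assert kept.empty and log.empty

    @given(unique=st.integers(0, 6), peptides_extra=st.integers(0, 6),
           msms=st.integers(0, 12), bump=st.integers(1, 50))
    def test_filters_are_monotone_in_counts(self, unique, peptides_extra,
                                            msms, bump):
        design = pd.DataFrame(
            [(f"{c}_{r}", c, r, c == "ctrl")
             for c in ("WT", "ctrl") for r in (1, 2, 3)],
            columns=["sample_id", "condition", "replicate", "is_control"])
        base = make_group_row("P", unique, unique + peptides_extra, msms,
                              design=design)
        kept_base, _ = interactome.filter_protein_groups(
            pd.DataFrame([base]), design, "labelfree")
        bumped = dict(base, unique_peptides=unique + bump,
                      peptides=unique + peptides_extra + bump,
                      msms_count=msms + bump)
        kept_bumped, _ = interactome.filter_protein_groups(
            pd.DataFrame([bumped]), design, "labelfree")
        # increasing counts can never turn a kept group into a removed one
        assert len(kept_bumped) >= len(kept_base)


def matrix_from(values: dict, samples):
    return pd.DataFrame(values, index=samples).T.rename_axis("protein_ids")


class TestImputation:
    def make_matrix(self, n=30, missing=()):
        rng = np.random.default_rng(0)
        samples = ["WT_1", "WT_2", "ctrl_1", "ctrl_2"]
        mat = pd.DataFrame(rng.normal(25, 1, (n, 4)),
                           index=[f"P{i}" for i in range(n)],
                           columns=samples)
        for (row, col) in missing:
            mat.iloc[row, mat.columns.get_loc(col)] = np.nan
        return mat

    def test_without_missing_values_nothing_changes(self):
        mat = self.make_matrix()
        out, mask = interactome.impute_controls(mat, ["ctrl_1", "ctrl_2"],
                                                seed=1)
        pd.testing.assert_frame_equal(out, mat)
        assert not mask.any().any()

    def test_only_control_missing_cells_are_touched(self):
        mat = self.make_matrix(missing=[(0, "ctrl_1"), (1, "WT_1")])
        out, mask = interactome.impute_controls(mat, ["ctrl_1", "ctrl_2"],
                                                seed=1)
        assert mask.to_numpy().sum() == 1
        assert mask.loc["P0", "ctrl_1"]
        assert np.isnan(out.loc["P1", "WT_1"])  # bait-side stays missing
        # untouched cells are bit-identical
        untouched = ~mask
        assert (out[untouched] == mat[untouched]).all().all() \
            or mat[untouched].isna().equals(out[untouched].isna())

    def test_imputed_values_sit_in_the_down_shifted_tail(self):
        missing = [(i, "ctrl_1") for i in range(10)]
        mat = self.make_matrix(n=200, missing=missing)
        out, mask = interactome.impute_controls(mat, ["ctrl_1"], seed=2)
        observed_mean = mat["ctrl_1"].mean()
        imputed = out.loc[mask["ctrl_1"], "ctrl_1"]
        assert imputed.mean() < observed_mean - 1.0

    def test_fixed_seed_reproduces_imputations(self):
        mat = self.make_matrix(missing=[(0, "ctrl_1"), (5, "ctrl_2")])
        out1, _ = interactome.impute_controls(mat, ["ctrl_1", "ctrl_2"],
                                              seed=9)
        out2, _ = interactome.impute_controls(mat, ["ctrl_1", "ctrl_2"],
                                              seed=9)
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_observed_values_rejected(self):
        mat = self.make_matrix(n=4)
        with pytest.raises(ValueError, match="observed"):
            interactome.impute_controls(mat, ["ctrl_1"], seed=0)


class TestBaitNormalization:
    def test_bait_ratio_is_subtracted_per_replicate(self):
        mat = matrix_from({"BAIT": [2.0, 3.0], "P1": [2.5, 3.2]},
                          ["r1", "r2"])
        out = interactome.bait_normalize(mat, "BAIT")
        assert out.loc["BAIT"].tolist() == [0.0, 0.0]
        assert out.loc["P1"].tolist() == pytest.approx([0.5, 0.2])

    def test_constant_replicate_shift_cancels(self):
        mat = matrix_from({"BAIT": [2.0, 3.0], "P1": [2.5, 3.2]},
                          ["r1", "r2"])
        shifted = mat + pd.Series({"r1": 5.0, "r2": -1.0})
        pd.testing.assert_frame_equal(
            interactome.bait_normalize(mat, "BAIT"),
            interactome.bait_normalize(shifted, "BAIT"))

    def test_bait_missing_in_a_replicate_is_fatal_and_named(self):
        mat = matrix_from({"BAIT": [2.0, np.nan], "P1": [2.5, 3.2]},
                          ["r1", "r2"])
        with pytest.raises(ValueError, match="r2"):
            interactome.bait_normalize(mat, "BAIT")


class TestInteractorCalls:
    def test_textbook_specific_interactor(self, toy_design):
        mat = matrix_from(
            {"hit": [3.0, 3.1, 2.9, 0.0, 0.1, -0.1],
             "flat": [0.0, 0.1, -0.1, 0.0, 0.1, -0.1]},
            list(toy_design["sample_id"]))
        calls = interactome.call_interactors(mat, toy_design, "labelfree")
        hit = calls[calls["protein_ids"] == "hit"].iloc[0]
        assert hit["mean_log2_diff"] == pytest.approx(3.0)
        assert hit["t"] == pytest.approx(36.74, abs=0.01)
        assert hit["specific"]
        flat = calls[calls["protein_ids"] == "flat"].iloc[0]
        assert not flat["specific"]
        assert flat["p"] == pytest.approx(1.0)

    def test_significant_but_small_fold_change_is_not_specific(
            self, toy_design):
        mat = matrix_from(
            {"mild": [2.0, 2.01, 1.99, 0.0, 0.01, -0.01]},
            list(toy_design["sample_id"]))
        calls = interactome.call_interactors(mat, toy_design, "labelfree")
        row = calls.iloc[0]
        assert row["p"] < 1e-6 and not row["specific"]

    def test_single_replicate_group_is_skipped_with_reason(self, toy_design):
        mat = matrix_from(
            {"sparse": [3.0, np.nan, np.nan, 0.0, 0.1, -0.1]},
            list(toy_design["sample_id"]))
        calls = interactome.call_interactors(mat, toy_design, "labelfree")
        assert calls.iloc[0]["note"] == "too_few_replicates"
        assert np.isnan(calls.iloc[0]["p"])

    def test_silac_one_sample_test_against_zero(self):
        design = pd.DataFrame({
            "sample_id": [f"rep{i}" for i in range(1, 5)],
            "condition": "WTvsAA", "replicate": range(1, 5),
            "is_control": False})
        mat = matrix_from(
            {"up_in_AA": [-0.52, -0.48, -0.51, -0.49],
             "null": [0.01, -0.01, 0.02, -0.02]},
            [f"rep{i}" for i in range(1, 5)])
        calls = interactome.call_interactors(mat, design, "silac")
        up = calls.set_index("protein_ids").loc["up_in_AA"]
        assert up["specific"] and up["direction"] == "up_in_AA"
        assert not calls.set_index("protein_ids").loc["null", "specific"]


class TestEnrichment:
    def test_exact_hypergeometric_worked_example(self):
        background = {f"P{i}" for i in range(20)}
        annotated = {f"P{i}" for i in range(5)}
        hits = {"P0", "P1", "P2", "P10", "P11"}
        out = interactome.enrichment_test(hits, background,
                                          {"term": annotated})
        # P(X >= 3) with N=20, K=5, n=5 = 1126/15504
        assert out["p"].iloc[0] == pytest.approx(1126 / 15504, rel=1e-12)
        assert out["k"].iloc[0] == 3
        assert out["gene_ratio"].iloc[0] == pytest.approx(3 / 5)

    def test_empty_hit_set_gives_p_one(self):
        background = {"A", "B", "C"}
        out = interactome.enrichment_test(set(), background,
                                          {"term": {"A"}})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_fully_annotated_background_gives_p_one(self):
        background = {"A", "B", "C", "D"}
        out = interactome.enrichment_test({"A", "B"}, background,
                                          {"term": background})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            interactome.enrichment_test({"X"}, {"A"}, {"t": {"A"}})
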