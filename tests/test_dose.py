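"""Conversion-factor lookup, dose estimation and table derivation."""
import numpy as np
import pandas as pd
import pytest

from cathdose import dose
from cathdose.dose import (ConversionFactorTable, derive_cf_table,
                           effective_dose_from_organ_doses,
                           estimate_effective_dose, estimate_organ_doses)
from cathdose.synthetic import (CohortConfig, attach_reference_doses,
                                generate_summaries)

TABLE = ConversionFactorTable.default()


class TestLookup:
    @pytest.mark.parametrize("target,weight,plane,expected", [
        ("ED", 40.0, "total", 20.63),
        ("ED", 40.0, "frontal", 16.71),
        ("lungs", 35.0, "biplane", 77.12),
        ("heart", 3.0, "lateral", 54.48),
        ("ED", 100.0, "total", 25.59),     # above range -> >=80 band
    ])
    def test_published_cells(self, target, weight, plane, expected):
        assert TABLE.lookup(target, weight, plane=plane) == expected

    def test_all_row_only_on_request(self):
        assert TABLE.lookup("ED", group="All", plane="total") == 19.84
        # weight lookup never lands on "All"
        assert TABLE.lookup("ED", 40.0, plane="total") != 19.84

    def test_unknown_target_lists_keys(self):
        with pytest.raises(KeyError, match="spleen|available"):
            TABLE.lookup("spleen", 40.0)

    def test_biplane_total_aliases(self):
        assert TABLE.lookup("lungs", 35.0, plane="total") == \
            TABLE.lookup("lungs", 35.0, plane="biplane")

    def test_structure_complete(self):
        """Every (target, plane) carries all six weight bands plus All."""
        df = TABLE.frame
        for (target, plane), sub in df.groupby(["target", "plane"]):
            assert sorted(sub["weight_group"]) == sorted(
                ["<5", "5-<15", "15-<30", "30-<50", "50-<80", ">=80", "All"]
            ), (target, plane)
        assert (df["slope"] > 0).all()


class TestOrganDoses:
    def test_worked_example_lung(self, worked_example_row):
        od = estimate_organ_doses(worked_example_row, mode="total")
        assert od["lungs"] == pytest.approx(15.05, abs=0.01)

    def test_zero_dap_all_zero(self, worked_example_row):
        row = dict(worked_example_row, total_dap=0.0, dap_frontal=0.0,
                   dap_lateral=0.0, dap_fluoro=0.0, dap_cine=0.0)
        od = estimate_organ_doses(row, mode="total")
        assert all(v == 0.0 for v in od.values())

    def test_per_plane_frontal_only_consistency(self, worked_example_row):
        row = dict(worked_example_row, dap_frontal=683.13, dap_lateral=0.0)
        od = estimate_organ_doses(row, mode="per_plane")
        cf = TABLE.lookup("lungs", 35.0, plane="frontal")
        assert od["lungs"] == pytest.approx(cf * 683.13 / 35.0 / 100.0)

    def test_linear_in_dap(self, worked_example_row):
        od1 = estimate_organ_doses(worked_example_row, mode="total")
        doubled = {k: (v * 2 if "dap" in k else v)
                   for k, v in worked_example_row.items()
                   if isinstance(v, (int, float)) or True}
        doubled = dict(worked_example_row)
        for k in ("total_dap", "dap_frontal", "dap_lateral",
                  "dap_fluoro", "dap_cine"):
            doubled[k] = worked_example_row[k] * 2
        od2 = estimate_organ_doses(doubled, mode="total")
        for organ in od1:
            assert od2[organ] == pytest.approx(2 * od1[organ], rel=1e-12)


class TestEffectiveDose:
    def test_total_mode_hand_value(self, worked_example_row):
        row = dict(worked_example_row, total_dap=780.0, weight_kg=40.0)
        res = estimate_effective_dose(row, mode="total")
        assert res.ed == pytest.approx(20.63 * 0.195, abs=1e-9)
        assert res.provenance == "cf_total"

    def test_per_plane_sums_contributions(self, worked_example_row):
        res_pp = estimate_effective_dose(worked_example_row, mode="per_plane")
        cf_f = TABLE.lookup("ED", 35.0, plane="frontal")
        cf_l = TABLE.lookup("ED", 35.0, plane="lateral")
        expected = (cf_f * 480.0 + cf_l * 203.13) / 35.0 / 100.0
        assert res_pp.ed == pytest.approx(expected, rel=1e-12)


class TestEffectiveDoseFromOrganDoses:
    def test_uniform_dose_gives_itself(self):
        organs = {t: 5.0 for t in dose.TISSUE_WEIGHTS["ICRP103"]}
        res = effective_dose_from_organ_doses(organs)
        assert res.ed == pytest.approx(5.0, abs=1e-9)

    def test_single_tissue(self):
        with pytest.warns(UserWarning, match="treated as 0"):
            res = effective_dose_from_organ_doses({"lungs": 10.0})
        assert res.ed == pytest.approx(0.12 * 10.0)

    def test_hand_computed_mix_with_aliases(self):
        with pytest.warns(UserWarning):
            res = effective_dose_from_organ_doses(
                {"lungs": 10.0, "ovaries": 2.0, "remainder male": 1.0},
                weighting="ICRP103")
        assert res.ed == pytest.approx(0.12 * 10 + 0.08 * 2 + 0.12 * 1)

    def test_icrp60_weights(self):
        with pytest.warns(UserWarning):
            res = effective_dose_from_organ_doses({"ovaries": 1.0},
                                                  weighting="ICRP60")
        assert res.ed == pytest.approx(0.20)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            effective_dose_from_organ_doses({"lungs": 1.0},
                                            weighting={"lungs": 0.5})

    def test_weight_tables_normalized(self):
        for scheme in ("ICRP103", "ICRP60"):
            assert sum(dose.TISSUE_WEIGHTS[scheme].values()) == pytest.approx(
                1.0, abs=1e-9)


class TestDeriveCFTable:
    def _labelled(self, noise_sd, seed=0, n=300):
        summaries, truth = generate_summaries(
            CohortConfig(n_procedures=n, seed=seed))
        return attach_reference_doses(summaries, truth, noise_sd=noise_sd,
                                      seed=seed)

    def test_noiseless_recovers_slopes_exactly(self):
        labelled = self._labelled(0.0)
        derived = derive_cf_table(labelled, targets=["lungs", "ED"],
                                  plane="total")
        for _, row in derived.frame.iterrows():
            if row["weight_group"] == "All":
                continue   # pooled fit mixes bands with different true slopes
            truth = TABLE.lookup(row["target"], group=row["weight_group"],
                                 plane="total")
            assert row["slope"] == pytest.approx(truth, rel=1e-9)
            assert row["ci_high"] - row["ci_low"] == pytest.approx(0, abs=1e-6)

    def test_noisy_ci_covers_truth(self):
        labelled = self._labelled(0.1, seed=4, n=400)
        derived = derive_cf_table(labelled, targets=["lungs"], plane="total")
        row = derived.frame.query("weight_group == '30-<50'").iloc[0]
        assert row["ci_low"] <= 77.12 <= row["ci_high"]

    def test_no_lateral_cohort_has_no_lateral_entries(self):
        labelled = self._labelled(0.0)
        labelled["dap_lateral"] = 0.0
        derived = derive_cf_table(labelled, targets=["ED"], plane="lateral")
        assert len(derived.frame) == 0

    def test_small_groups_absent(self):
        labelled = self._labelled(0.0).head(5)
        labelled = labelled[labelled["weight_kg"] < 15]
        derived = derive_cf_table(labelled, targets=["ED"], plane="total")
        assert set(derived.frame["weight_group"]) <= {"<5", "5-<15", "All"}


def test_csv_round_trip(tmp_path):
    p = tmp_path / "cf.csv"
    TABLE.to_csv(p)
    again = ConversionFactorTable.from_csv(p)
    assert again.lookup("lungs", 35.0, plane="biplane") == 77.12
    assert len(again.frame) == len(TABLE.frame)
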