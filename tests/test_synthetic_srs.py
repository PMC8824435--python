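"""Generator determinism, fixture margins and planted-signal behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from srsafety.frames import reports_to_frame
from srsafety.srs_data import DomainError, bin_onset
from srsafety.synthetic_srs import (
    ConfigError,
    EventSpec,
    PlantedDec,
    default_config,
    expected_cells,
    generate_frame,
    null_config,
    operating_characteristics,
    signal_recovery_config,
)

# Expected fixture margins, frozen independently of the implementation's
# internal tables (counts as published for the 2016-2020 provincial SRS
# comparison these data emulate).
EXPECTED_AGE = {"mab": {"0-5": 3, "6-17": 4, "18-34": 26, "35-59": 265,
                        "60-79": 254, ">=80": 23},
                "non_mab": {"0-5": 193, "6-17": 231, "18-34": 422,
                            "35-59": 6685, "60-79": 7452, ">=80": 308}}
EXPECTED_SEX = {"mab": {"female": 328, "male": 247},
                "non_mab": {"female": 8363, "male": 6959, "unknown": 13}}
EXPECTED_YEAR = {"mab": {2016: 6, 2017: 19, 2018: 33, 2019: 140, 2020: 377},
                 "non_mab": {2016: 1398, 2017: 1834, 2018: 2455,
                             2019: 3865, 2020: 5783}}
EXPECTED_SEVERITY = {"mab": {"serious": 174, "non_serious": 401},
                     "non_mab": {"serious": 5285, "non_serious": 10050}}
EXPECTED_IMPACT = {"mab": {"no_effect": 506, "prolong": 10, "worse": 58,
                           "sequelae": 1, "death": 0},
                   "non_mab": {"no_effect": 12754, "prolong": 123,
                               "worse": 2441, "sequelae": 13, "death": 4}}
EXPECTED_SOC_MAB = {
    "Gastrointestinal disorders": 81,
    "Blood and lymphatic system disorders": 50,
    "Skin and subcutaneous tissue disorders": 87,
    "Investigations": 20,
    "General disorders and administration site conditions": 142,
    "Nervous system disorders": 18,
    "Respiratory, thoracic, and mediastinal disorders": 50,
    "Vascular disorders": 22,
    "Musculoskeletal and connective tissue disorders": 5,
    "Cardiac disorders": 28,
    "Hepatobiliary disorders": 12,
    "Metabolism and nutrition disorders": 5,
    "Immune system disorders": 14,
    "Renal and urinary disorders": 8,
    "Endocrine disorders": 19,
    "Injury, poisoning, and procedural complications": 3,
    "Neoplasms benign, malignant, and unspecified (including cysts and polyps)": 11,
}
EXPECTED_SOC_NONMAB = {
    "Gastrointestinal disorders": 5762,
    "Blood and lymphatic system disorders": 3559,
    "Skin and subcutaneous tissue disorders": 1263,
    "Investigations": 1158,
    "General disorders and administration site conditions": 833,
    "Nervous system disorders": 616,
    "Respiratory, thoracic, and mediastinal disorders": 578,
    "Vascular disorders": 264,
    "Musculoskeletal and connective tissue disorders": 276,
    "Cardiac disorders": 249,
    "Hepatobiliary disorders": 251,
    "Metabolism and nutrition disorders": 204,
    "Immune system disorders": 166,
    "Renal and urinary disorders": 72,
    "Endocrine disorders": 17,
    "Psychiatric disorders": 20,
    "Eye disorders": 16,
    "Injury, poisoning, and procedural complications": 10,
    "Neoplasms benign, malignant, and unspecified (including cysts and polyps)": 1,
    "Ear and labyrinth disorders": 10,
    "Infections and infestations": 6,
    "Reproductive system and breast disorders": 4,
}
EXPECTED_SOC_BRANDED = {
    "General disorders and administration site conditions": 122,
    "Skin and subcutaneous tissue disorders": 75,
    "Gastrointestinal disorders": 74,
    "Blood and lymphatic system disorders": 41,
    "Respiratory, thoracic, and mediastinal disorders": 38,
    "Cardiac disorders": 23,
    "Vascular disorders": 19,
    "Investigations": 17,
    "Endocrine disorders": 18,
    "Nervous system disorders": 15,
    "Immune system disorders": 12,
    "Hepatobiliary disorders": 11,
    "Neoplasms benign, malignant, and unspecified (including cysts and polyps)": 11,
    "Renal and urinary disorders": 6,
    "Metabolism and nutrition disorders": 5,
    "Musculoskeletal and connective tissue disorders": 5,
    "Injury, poisoning, and procedural complications": 3,
}
EXPECTED_SOC_BIOSIMILAR = {
    "General disorders and administration site conditions": 20,
    "Skin and subcutaneous tissue disorders": 12,
    "Gastrointestinal disorders": 7,
    "Blood and lymphatic system disorders": 9,
    "Respiratory, thoracic, and mediastinal disorders": 12,
    "Cardiac disorders": 5,
    "Vascular disorders": 3,
    "Investigations": 3,
    "Endocrine disorders": 1,
    "Nervous system disorders": 3,
    "Immune system disorders": 2,
    "Hepatobiliary disorders": 1,
    "Renal and urinary disorders": 2,
}


class TestFixtureMargins:
    def test_class_totals(self, fixture_frame):
        vc = fixture_frame["drug_class"].value_counts()
        assert vc["mab"] == 575 and vc["non_mab"] == 15_335

    @pytest.mark.parametrize("column, expected", [
        ("sex", EXPECTED_SEX), ("year", EXPECTED_YEAR),
        ("severity", EXPECTED_SEVERITY), ("impact", EXPECTED_IMPACT),
    ])
    def test_raw_column_margins(self, fixture_frame, column, expected):
        for cls, counts in expected.items():
            sub = fixture_frame[fixture_frame["drug_class"] == cls]
            observed = sub[column].value_counts().to_dict()
            for level, count in counts.items():
                assert observed.get(level, 0) == count, (cls, level)

    def test_age_group_margins(self, fixture_frame):
        from srsafety.srs_data import age_group
        for cls, counts in EXPECTED_AGE.items():
            sub = fixture_frame[fixture_frame["drug_class"] == cls]
            groups = sub["age"].dropna().map(lambda a: age_group(int(a)))
            observed = groups.value_counts().to_dict()
            assert observed == counts
        missing = fixture_frame["age"].isna()
        assert int(missing.sum()) == 44
        assert (fixture_frame.loc[missing, "drug_class"] == "non_mab").all()

    def test_disease_polypharmacy_history_margins(self, fixture_frame):
        mab = fixture_frame[fixture_frame["drug_class"] == "mab"]
        non = fixture_frame[fixture_frame["drug_class"] == "non_mab"]
        assert int((mab["n_diseases"] == 1).sum()) == 508
        assert int((non["n_diseases"] == 1).sum()) == 13_539
        assert int((mab["n_medications"] >= 5).sum()) == 37
        assert int((non["n_medications"] >= 5).sum()) == 940
        assert int(mab["past_adr_history"].sum()) == 26
        assert int(non["past_adr_history"].sum()) == 1056

    def test_soc_margins(self, fixture_frame):
        mab = fixture_frame[fixture_frame["drug_class"] == "mab"]
        non = fixture_frame[fixture_frame["drug_class"] == "non_mab"]
        assert mab["soc"].value_counts().to_dict() == EXPECTED_SOC_MAB
        assert non["soc"].value_counts().to_dict() == EXPECTED_SOC_NONMAB

    def test_patent_status_margins(self, fixture_frame):
        mab = fixture_frame[fixture_frame["drug_class"] == "mab"]
        vc = mab["patent_status"].value_counts()
        assert vc["branded"] == 495 and vc["biosimilar"] == 80
        branded = mab[mab["patent_status"] == "branded"]
        biosim = mab[mab["patent_status"] == "biosimilar"]
        assert branded["soc"].value_counts().to_dict() == EXPECTED_SOC_BRANDED
        assert biosim["soc"].value_counts().to_dict() == EXPECTED_SOC_BIOSIMILAR

    def test_onset_margins(self, fixture_frame):
        known = fixture_frame["onset_days"].notna()
        assert int(known.sum()) == 15_904
        bins = fixture_frame.loc[known, "onset_days"].map(
            lambda d: bin_onset(int(d)).value)
        mab = bins[fixture_frame["drug_class"] == "mab"]
        non = bins[fixture_frame["drug_class"] == "non_mab"]
        assert int((mab == "same_day").sum()) == 297
        assert int((non == "d1_3").sum()) == 4929

    def test_death_outcome_consistency(self, fixture_frame):
        died = fixture_frame["outcome_death"]
        assert int(died.sum()) == 4
        assert (fixture_frame.loc[died, "impact"] == "death").all()

    def test_term_soc_map_consistency(self, fixture_frame):
        from srsafety.terminology import soc_for_term
        mapped = fixture_frame["adr_term"].map(soc_for_term)
        assert (mapped == fixture_frame["soc"]).all()

    def test_fixture_is_byte_stable(self, fixture_reports):
        from srsafety.synthetic_srs import reference_fixture
        again = reference_fixture()
        assert again == fixture_reports


class TestGenerator:
    def test_same_seed_identical(self):
        cfg = default_config(n_reports=1000, seed=7)
        a = generate_frame(cfg)
        b = generate_frame(default_config(n_reports=1000, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_frame(default_config(n_reports=1000, seed=7))
        b = generate_frame(default_config(n_reports=1000, seed=8))
        ha = pd.util.hash_pandas_object(a.astype(str)).sum()
        hb = pd.util.hash_pandas_object(b.astype(str)).sum()
        assert ha != hb

    def test_invalid_config_lists_violations(self):
        cfg = default_config(n_reports=100)
        cfg.sex_probs = {"female": 0.6, "male": 0.6}
        cfg.planted_decs = [PlantedDec("NoSuchDrug", "Nausea", -1.0)]
        with pytest.raises(ConfigError) as err:
            generate_frame(cfg)
        msg = str(err.value)
        assert "sex_probs" in msg and "NoSuchDrug" in msg
        assert "rate_ratio" in msg

    def test_marginals_approximate_configuration(self):
        cfg = default_config(n_reports=40_000, seed=11)
        frame = generate_frame(cfg)
        share = (frame["drug_class"] == "mab").mean()
        assert share == pytest.approx(cfg.drug_class_probs["mab"], abs=0.01)
        f_share = (frame["sex"] == "female").mean()
        assert f_share == pytest.approx(cfg.sex_probs["female"], abs=0.01)

    def test_planted_dec_reaches_target_ror(self):
        """Empirical ROR near the analytic expectation of the 2x2 cells."""
        from srsafety.disproportionality import build_dec_tables, ror
        cfg = signal_recovery_config(n_reports=50_000, rate_ratio=10.0,
                                     seed=21)
        exp = expected_cells(cfg, "Drug00", "Event00")
        assert exp["a"] == pytest.approx(30.0, abs=1e-6)
        expected_ror = (exp["a"] * exp["d"]) / (exp["b"] * exp["c"])
        frame = generate_frame(cfg)
        table = next(t for t in build_dec_tables(frame)
                     if (t.drug, t.event) == ("Drug00", "Event00"))
        observed = ror(table)
        # sampling tolerance: +-3 SD of ln(ROR) at these cell sizes
        tol = 3 * math.sqrt(1 / exp["a"] + 1 / exp["b"]
                            + 1 / exp["c"] + 1 / exp["d"])
        assert abs(math.log(observed.value) - math.log(expected_ror)) < tol

    def test_null_ln_ror_centred_at_zero(self):
        """Under rate ratio 1 the mean of ln(ROR) across replicates -> 0."""
        from srsafety.disproportionality import build_dec_tables, ror
        cfg = null_config(n_reports=20_000)
        lnrors = []
        for seed in range(25):
            cfg.seed = 300 + seed
            frame = generate_frame(cfg)
            t = next(t for t in build_dec_tables(frame)
                     if (t.drug, t.event) == ("Drug00", "Event00"))
            lnrors.append(math.log(ror(t).value))
        lnrors = np.array(lnrors)
        se = lnrors.std(ddof=1) / math.sqrt(len(lnrors))
        assert abs(lnrors.mean()) < 3 * se + 1e-12


class TestOperatingCharacteristics:
    def test_zero_replicates_rejected(self):
        with pytest.raises(DomainError):
            operating_characteristics(default_config(n_reports=100), 0)

    def test_planted_dec_detected_in_small_study(self):
        cfg = signal_recovery_config(n_reports=20_000, rate_ratio=10.0,
                                     seed=5, target_a=25)
        oc = operating_characteristics(cfg, n_replicates=3, n_null_sample=5)
        planted = oc[oc["kind"] == "planted"]
        assert len(planted) == 1
        assert planted["flag_fraction"].iloc[0] == 1.0
        null = oc[oc["kind"] == "null"]
        assert (null["flag_fraction"] <= 1 / 3).all()
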