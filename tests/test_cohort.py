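"""Exclusion cascade, imputation, follow-up derivation, sensitivity filters."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from gidiet.cohort import (
    apply_exclusions,
    derive_followup,
    impute_covariates,
    map_icd10_site,
    sensitivity_filters,
)
from gidiet.config import SimulationConfig
from gidiet.simulate import generate_intake, generate_registry


def tiny_registry(n, **flags):
    df = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
            "prevalent_cancer": False,
            "withdrawn": False,
            "missing_genetics": False,
        }
    )
    for col, idx in flags.items():
        df.loc[df.index[idx], col] = True
    return df


def tiny_intake(energies):
    return pd.DataFrame(
        {
            "participant_id": np.arange(1, len(energies) + 1),
            "recall_index": 1,
            "total_energy_kcal": energies,
        }
    )


class TestExclusions:
    def test_planted_cascade_recovers_counts(self):
        cfg = SimulationConfig(
            n_participants=5000,
            exclusion_plant={
                "prevalent_cancer": 400,
                "implausible_energy": 50,
                "withdrawn": 5,
                "missing_genetics": 90,
            },
            seed=13,
        )
        reg = generate_registry(cfg)
        intake = generate_intake(cfg, reg)
        retained, report = apply_exclusions(reg, intake)
        assert dict(report.steps) == {
            "prevalent_cancer": 400,
            "implausible_energy": 50,
            "withdrawn": 5,
            "missing_genetics": 90,
        }
        assert report.n_final == 5000 - 545 == len(retained)

    def test_no_flags_in_bounds_is_identity(self):
        reg = tiny_registry(4)
        intake = tiny_intake([2000, 2000, 2000, 2000])
        retained, report = apply_exclusions(reg, intake)
        assert report.n_final == report.n_initial == 4
        assert len(retained) == 4

    def test_energy_boundary_is_strict(self):
        # males: < 800 excluded, exactly 800 retained
        reg = tiny_registry(4)  # male, female, male, female
        intake = tiny_intake([799.0, 500.0, 800.0, 499.9])
        retained, report = apply_exclusions(reg, intake)
        assert dict(report.steps)["implausible_energy"] == 2
        assert retained["participant_id"].tolist() == [2, 3]

    def test_report_reconciles(self):
        cfg = SimulationConfig(n_participants=800, seed=3)
        reg = generate_registry(cfg)
        intake = generate_intake(cfg, reg)
        retained, report = apply_exclusions(reg, intake)
        assert report.n_initial - sum(n for _, n in report.steps) == len(retained)

    def test_order_permutation_keeps_final_set(self):
        # overlapping flags: order changes per-reason counts, not the set
        rng = np.random.default_rng(9)
        reg = tiny_registry(200)
        for col in ("prevalent_cancer", "withdrawn", "missing_genetics"):
            reg[col] = rng.random(200) < 0.2
        intake = tiny_intake(np.where(rng.random(200) < 0.15, 300.0, 2000.0))
        base_order = (
            "prevalent_cancer",
            "implausible_energy",
            "withdrawn",
            "missing_genetics",
        )
        a, ra = apply_exclusions(reg, intake, order=base_order)
        b, rb = apply_exclusions(reg, intake, order=base_order[::-1])
        assert set(a["participant_id"]) == set(b["participant_id"])
        assert dict(ra.steps) != dict(rb.steps)  # overlapping flags recounted

    def test_unknown_sex_routed_to_own_reason(self):
        reg = tiny_registry(3)
        reg.loc[0, "sex"] = "unknown"
        _, report = apply_exclusions(reg, tiny_intake([2000, 2000, 2000]))
        assert dict(report.steps).get("unknown_sex") == 1

    def test_participant_without_recalls_logged(self):
        reg = tiny_registry(3)
        intake = tiny_intake([2000, 2000, 2000]).iloc[:2]
        retained, report = apply_exclusions(reg, intake)
        assert dict(report.steps).get("no_dietary_recalls") == 1
        assert 3 not in retained["participant_id"].tolist()


class TestImputation:
    def test_mean_and_indicator_imputation(self):
        df = pd.DataFrame(
            {
                "participant_id": [1, 2, 3, 4],
                "townsend": [-2.0, 0.0, 2.0, np.nan],
                "smoking": ["never", None, "current", "previous"],
            }
        )
        out = impute_covariates(df, continuous=("townsend",), categorical=("smoking",))
        assert out.loc[3, "townsend"] == pytest.approx(0.0)
        assert out.loc[1, "smoking"] == "unknown/missing"
        assert out["any_covariate_imputed"].tolist() == [False, True, False, True]

    def test_no_missing_is_identity(self):
        df = pd.DataFrame(
            {"participant_id": [1, 2], "townsend": [1.0, 2.0], "smoking": ["never"] * 2}
        )
        out = impute_covariates(df, continuous=("townsend",), categorical=("smoking",))
        assert not out["any_covariate_imputed"].any()
        pd.testing.assert_frame_equal(
            out.drop(columns="any_covariate_imputed"), df
        )

    def test_fully_missing_continuous_rejected(self):
        df = pd.DataFrame({"participant_id": [1], "townsend": [np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_covariates(df, continuous=("townsend",), categorical=())


class TestFollowup:
    def _cohort(self, baselines):
        return pd.DataFrame(
            {
                "participant_id": np.arange(1, len(baselines) + 1),
                "baseline_date": baselines,
            }
        )

    def test_event_date_arithmetic(self):
        cohort = self._cohort([date(2009, 1, 1)])
        dx = pd.DataFrame(
            {"participant_id": [1], "icd10_code": ["C18"], "date": [date(2012, 1, 1)]}
        )
        out = derive_followup(cohort, dx, pd.DataFrame(columns=["participant_id", "date"]))
        assert out.loc[0, "event_overall"] == 1
        assert out.loc[0, "event_site"] == "CRC"
        assert out.loc[0, "event_CRC"] == 1 and out.loc[0, "event_EC"] == 0
        assert out.loc[0, "followup_years"] == pytest.approx(3.0, abs=0.01)

    def test_administrative_censoring_exact(self):
        cohort = self._cohort([date(2010, 5, 31)])
        out = derive_followup(
            cohort,
            pd.DataFrame(columns=["participant_id", "icd10_code", "date"]),
            pd.DataFrame(columns=["participant_id", "date"]),
            admin_end=date(2022, 5, 31),
        )
        assert out.loc[0, "event_overall"] == 0
        assert out.loc[0, "followup_years"] == pytest.approx(12.0, abs=0.01)

    def test_death_censors_before_later_diagnosis(self):
        cohort = self._cohort([date(2010, 1, 1)])
        dx = pd.DataFrame(
            {"participant_id": [1], "icd10_code": ["C15"], "date": [date(2015, 1, 1)]}
        )
        deaths = pd.DataFrame({"participant_id": [1], "date": [date(2012, 1, 1)]})
        out = derive_followup(cohort, dx, deaths)
        assert out.loc[0, "event_overall"] == 0
        assert out.loc[0, "followup_years"] == pytest.approx(2.0, abs=0.01)

    @pytest.mark.parametrize(
        "code,site",
        [("C15", "EC"), ("C16", "GC"), ("C18", "CRC"), ("C19", "CRC"), ("C20", "CRC"),
         ("C18.9", "CRC"), ("C21", None), ("D12", None)],
    )
    def test_icd10_site_map(self, code, site):
        assert map_icd10_site(code) == site

    def test_event_before_baseline_rejected(self):
        cohort = self._cohort([date(2010, 1, 1)])
        dx = pd.DataFrame(
            {"participant_id": [1], "icd10_code": ["C16"], "date": [date(2009, 1, 1)]}
        )
        with pytest.raises(ValueError, match="prevalent"):
            derive_followup(cohort, dx, pd.DataFrame(columns=["participant_id", "date"]))


class TestSensitivityFilters:
    def _cohort(self):
        return pd.DataFrame(
            {
                "participant_id": [1, 2, 3, 4],
                "event_overall": [1, 1, 0, 0],
                "followup_years": [1.5, 5.0, 1.0, 10.0],
                "n_recalls": [1, 2, 3, 1],
                "any_covariate_imputed": [False, True, False, False],
            }
        )

    def test_landmark_removes_early_events_only(self):
        out, delta = sensitivity_filters(self._cohort(), "landmark_2y")
        assert out["participant_id"].tolist() == [2, 3, 4]
        assert delta["n_removed"] == 1

    def test_multi_recall_only(self):
        out, _ = sensitivity_filters(self._cohort(), "multi_recall_only")
        assert out["participant_id"].tolist() == [2, 3]

    def test_complete_covariates_identity_when_no_missingness(self):
        cohort = self._cohort()
        cohort["any_covariate_imputed"] = False
        out, delta = sensitivity_filters(cohort, "complete_covariates")
        assert delta["n_removed"] == 0
        assert len(out) == 4

    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValueError, match="landmark_2y"):
            sensitivity_filters(self._cohort(), "bogus")

    def test_registry_variant_requires_intake(self):
        with pytest.raises(ValueError, match="intake"):
            sensitivity_filters(self._cohort(), "pulses")

    def test_registry_variant_rescores(self, built_small):
        cohort = built_small["cohort"]
        out, delta = sensitivity_filters(
            cohort, "pulses", mean_intake=built_small["mean_intake"]
        )
        assert len(out) == len(cohort)
        assert out["digm"].max() <= 14
        assert "score_pulses" in out.columns


def test_bmi_formula(built_small):
    c = built_small["cohort"]
    assert np.allclose(c["bmi"], c["weight_kg"] / c["height_m"] ** 2)
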