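"""Synthetic cohort: determinism, structure, moment recovery, cost calibration."""

import numpy as np
import pytest

from glycea.cohort import (
    CohortSpec, cohort_to_frame, generate_cohort, generate_cost_items,
    truncnorm_parent_params,
)
from glycea.costing import TariffCatalog, UnknownTariffError, patient_total_cost


def _arm_values(df, arm, tp, col):
    g = df[(df["arm"] == arm) & (df["timepoint"] == tp)]
    return g[col].to_numpy()


class TestSpecValidation:
    def test_defaults_are_valid(self):
        spec = CohortSpec()
        assert spec.n_intervention == 128 and spec.n_comparator == 73

    @pytest.mark.parametrize("kwargs, match", [
        (dict(n_intervention=0), "sample sizes"),
        (dict(dh_fraction=1.5), "dh_fraction"),
        (dict(longitudinal_corr=1.2), "longitudinal_corr"),
        (dict(tir={"CIRDIA": {"M0": (120, 5), "M12": (70, 5)},
                   "HC": {"M0": (60, 5), "M12": (70, 5)}}), "mean must lie"),
        (dict(gri={"CIRDIA": {"M0": (50, -1), "M12": (30, 5)},
                   "HC": {"M0": (40, 5), "M12": (30, 5)}}), "SD must be"),
        (dict(age_class_props={"CIRDIA": (0.5, 0.5, 0.1, 0.1),
                               "HC": (0.25, 0.25, 0.25, 0.25)}), "sum to 1"),
    ])
    def test_invalid_spec_names_field(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            CohortSpec(**kwargs)

    def test_from_dict_round_trips_nested_lists(self):
        spec = CohortSpec.from_dict({
            "n_intervention": 5, "n_comparator": 4,
            "cost": {"CIRDIA": [8000.0, 100.0], "HC": [8800.0, 100.0]},
        })
        assert spec.cost["CIRDIA"] == (8000.0, 100.0)


class TestGenerateCohort:
    def test_arm_sizes_and_labels(self):
        recs = generate_cohort(CohortSpec(seed=42))
        assert len(recs) == 201
        assert sum(r.arm == "CIRDIA" for r in recs) == 128
        assert sum(r.arm == "HC" for r in recs) == 73

    def test_value_ranges(self):
        df = cohort_to_frame(generate_cohort(CohortSpec(seed=3)))
        assert df["age"].between(16, 80).all()
        assert df["tir"].between(0, 100).all()
        assert df["gri"].between(0, 100).all()

    def test_seed_determinism(self):
        a = cohort_to_frame(generate_cohort(CohortSpec(seed=5)))
        b = cohort_to_frame(generate_cohort(CohortSpec(seed=5)))
        assert a.equals(b)
        c = cohort_to_frame(generate_cohort(CohortSpec(seed=6)))
        assert not a["tir"].equals(c["tir"])

    def test_zero_sd_gives_arm_means(self):
        spec = CohortSpec(
            n_intervention=8, n_comparator=6, seed=1,
            tir={"CIRDIA": {"M0": (52.9, 0.0), "M12": (72.7, 0.0)},
                 "HC": {"M0": (65.9, 0.0), "M12": (71.9, 0.0)}},
            gri={"CIRDIA": {"M0": (56.4, 0.0), "M12": (30.1, 0.0)},
                 "HC": {"M0": (37.8, 0.0), "M12": (30.3, 0.0)}},
        )
        df = cohort_to_frame(generate_cohort(spec))
        assert (_arm_values(df, "CIRDIA", "M0", "tir") == 52.9).all()
        assert (_arm_values(df, "HC", "M12", "gri") == 30.3).all()

    def test_tir_gri_negatively_coupled(self):
        df = cohort_to_frame(generate_cohort(
            CohortSpec(n_intervention=2000, n_comparator=1, seed=8)))
        tir = _arm_values(df, "CIRDIA", "M0", "tir")
        gri = _arm_values(df, "CIRDIA", "M0", "gri")
        assert np.corrcoef(tir, gri)[0, 1] < -0.7

    def test_longitudinal_correlation_positive(self):
        df = cohort_to_frame(generate_cohort(
            CohortSpec(n_intervention=2000, n_comparator=1, seed=8)))
        m0 = _arm_values(df, "CIRDIA", "M0", "tir")
        m12 = _arm_values(df, "CIRDIA", "M12", "tir")
        assert 0.2 < np.corrcoef(m0, m12)[0, 1] < 0.6


class TestMomentRecovery:
    def test_large_n_mean_within_3_se(self):
        spec = CohortSpec(n_intervention=5000, n_comparator=1, seed=42)
        df = cohort_to_frame(generate_cohort(spec))
        tir = _arm_values(df, "CIRDIA", "M0", "tir")
        se = 16.0 / np.sqrt(5000)
        assert abs(tir.mean() - 52.9) < 3 * se

    def test_truncation_corrected_sd(self):
        # the baseline safety score (mean 56.4, SD 21) is the case where
        # naive truncated sampling would shrink the SD by > 1 point
        spec = CohortSpec(n_intervention=5000, n_comparator=1, seed=42)
        df = cohort_to_frame(generate_cohort(spec))
        gri = _arm_values(df, "CIRDIA", "M0", "gri")
        se_mean = 21.0 / np.sqrt(5000)
        se_sd = 21.0 / np.sqrt(2 * 5000)
        assert abs(gri.mean() - 56.4) < 3 * se_mean
        assert abs(gri.std(ddof=1) - 21.0) < 3 * se_sd

    def test_parent_param_solver_matches_targets(self):
        from scipy import stats
        mu, sigma = truncnorm_parent_params(56.4, 21.0)
        a, b = (0 - mu) / sigma, (100 - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        assert float(m) == pytest.approx(56.4, abs=1e-8)
        assert float(np.sqrt(v)) == pytest.approx(21.0, abs=1e-8)
        # far from the bounds the correction is a no-op
        assert truncnorm_parent_params(50.0, 5.0) == (50.0, 5.0)


class TestCostItems:
    def test_hc_patients_all_have_one_dh(self, small_spec, catalog):
        items = generate_cost_items("HC", catalog, small_spec, seed=0)
        dh = [i for i in items if (i.source, i.code) == ("GHS", "1794")]
        assert len(dh) == small_spec.n_comparator
        assert len({i.patient_id for i in dh}) == small_spec.n_comparator

    def test_dh_fraction_zero_means_no_dh(self, catalog):
        spec = CohortSpec(n_intervention=20, n_comparator=5, dh_fraction=0.0, seed=0)
        items = generate_cost_items("CIRDIA", catalog, spec, seed=0)
        assert not any((i.source, i.code) == ("GHS", "1794") for i in items)

    def test_default_dh_fraction_matches_observed_count(self, catalog):
        items = generate_cost_items("CIRDIA", catalog, CohortSpec(), seed=0)
        dh = sum(1 for i in items if (i.source, i.code) == ("GHS", "1794"))
        assert dh == 17  # 13% of 128

    def test_pathway_composition(self, small_spec, catalog):
        items = generate_cost_items("CIRDIA", catalog, small_spec, seed=0)
        per = {}
        for it in items:
            per.setdefault(it.patient_id, []).append(it)
        for its in per.values():
            codes = {(i.source, i.code) for i in its}
            assert ("NGAP", "TCG") in codes and ("NGAP", "CS") in codes
            assert ("LPP", "CL-RENT-M") in codes
            assert ("GHS", "1794") in codes or ("CCAM", "INIT-OV") in codes

    def test_calibrated_means_within_1pct(self, catalog):
        spec = CohortSpec(seed=42)
        for arm, n in (("CIRDIA", 128), ("HC", 73)):
            items = generate_cost_items(arm, catalog, spec, seed=42)
            per = {}
            for it in items:
                per.setdefault(it.patient_id, []).append(it)
            totals = [patient_total_cost(v, catalog, arm=arm, patient_id=k).total_eur
                      for k, v in per.items()]
            target = spec.cost[arm][0]
            assert np.mean(totals) == pytest.approx(target, rel=0.01)
            assert min(totals) > 0

    def test_cost_moment_recovery_large_n(self, catalog):
        spec = CohortSpec(n_intervention=5000, n_comparator=1, seed=9)
        items = generate_cost_items("CIRDIA", catalog, spec, seed=9)
        per = {}
        for it in items:
            per.setdefault(it.patient_id, []).append(it)
        totals = np.array([patient_total_cost(v, catalog, patient_id=k).total_eur
                           for k, v in per.items()])
        mean_t, sd_t = spec.cost["CIRDIA"]
        assert abs(totals.mean() - mean_t) < 3 * sd_t / np.sqrt(5000)
        assert abs(totals.std(ddof=1) - sd_t) < 3 * sd_t / np.sqrt(2 * 5000)

    def test_missing_catalog_code_named(self, small_spec):
        empty = TariffCatalog()
        with pytest.raises(UnknownTariffError, match="CS"):
            generate_cost_items("HC", empty, small_spec, seed=0)

    def test_determinism(self, small_spec, catalog):
        a = generate_cost_items("HC", catalog, small_spec, seed=4)
        b = generate_cost_items("HC", catalog, small_spec, seed=4)
        assert a == b
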