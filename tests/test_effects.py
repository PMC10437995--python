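import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nutricea as nc
from nutricea.effects import DesignError
from .conftest import noise_free_config


def _records(rows):
    """Minimal trial frame from (child, village, arm, wave, score) tuples."""
    return pd.DataFrame(
        rows, columns=["child_id", "village_id", "arm", "wave", "cognitive_score"]
    )


class TestSeFromCi:
    def test_published_interval_implies_se(self):
        assert nc.se_from_ci(11.72, 20.50, 0.95) == pytest.approx(2.2398, abs=5e-5)

    def test_standard_normal_interval(self):
        assert nc.se_from_ci(-1.959964, 1.959964, 0.95) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            nc.se_from_ci(0.0, 0.0, 0.95)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5, 2.0])
    def test_invalid_level_rejected(self, level):
        with pytest.raises(ValueError):
            nc.se_from_ci(0.0, 1.0, level)

    @settings(deadline=None)
    @given(
        point=st.floats(-50, 50),
        se=st.floats(0.01, 20),
        level=st.floats(0.5, 0.999),
    )
    def test_roundtrip_with_ci_from_se(self, point, se, level):
        lo, hi = nc.ci_from_se(point, se, level)
        assert nc.se_from_ci(lo, hi, level) == pytest.approx(se, rel=1e-9)


class TestFitDidMixedModel:
    def test_noise_free_recovers_effect_exactly(self):
        records = nc.simulate_trial(noise_free_config(true_effect=16.11))
        est = nc.fit_did_mixed_model(records, covariates=())
        assert est.point == pytest.approx(16.11, abs=1e-8)

    def test_noise_free_adjusted_fit_matches(self):
        records = nc.simulate_trial(noise_free_config(true_effect=16.11))
        est = nc.fit_did_mixed_model(records)  # all default covariates
        assert est.point == pytest.approx(16.11, abs=1e-6)

    def test_constant_scores_give_null_effect(self):
        records = nc.simulate_trial(
            noise_free_config(
                true_effect=0.0,
                control_followup_drift=0.0,
                baseline_mean_intervention=100.0,
                baseline_mean_control=100.0,
                mid_mean_intervention=100.0,
                mid_mean_control=100.0,
            )
        )
        est = nc.fit_did_mixed_model(records, covariates=())
        assert est.point == pytest.approx(0.0, abs=1e-8)

    def test_did_invariant_to_score_translation(self, small_trial):
        base = nc.fit_did_mixed_model(small_trial, covariates=())
        shifted = small_trial.copy()
        shifted["cognitive_score"] = shifted["cognitive_score"] + 37.5
        est = nc.fit_did_mixed_model(shifted, covariates=())
        assert est.point == pytest.approx(base.point, abs=1e-6)

    def test_did_invariant_to_arm_constant_shift(self, small_trial):
        base = nc.fit_did_mixed_model(small_trial, covariates=())
        shifted = small_trial.copy()
        shifted.loc[shifted["arm"] == "intervention", "cognitive_score"] += 9.0
        est = nc.fit_did_mixed_model(shifted, covariates=())
        assert est.point == pytest.approx(base.point, abs=1e-6)

    def test_reml_vs_ml_insensitive_at_this_scale(self, small_trial):
        reml = nc.fit_did_mixed_model(small_trial, covariates=())
        ml = nc.fit_did_mixed_model(small_trial, covariates=(), reml=False)
        assert ml.point == pytest.approx(reml.point, abs=0.2)

    def test_estimate_interval_is_coherent(self, small_trial):
        est = nc.fit_did_mixed_model(small_trial, covariates=())
        assert est.ci_low <= est.point <= est.ci_high
        assert est.se > 0
        width = est.ci_high - est.ci_low
        assert width == pytest.approx(2 * 1.959964 * est.se, rel=1e-6)
        assert est.n_intervention == 50 and est.n_control == 50

    def test_single_village_per_arm_rejected(self):
        rows = [
            (f"C{i}", "V0" if i < 4 else "V1", "intervention" if i < 4 else "control", w, 100.0)
            for i in range(8)
            for w in ("baseline", "final")
        ]
        with pytest.raises(DesignError, match="villages"):
            nc.fit_did_mixed_model(_records(rows), covariates=())

    def test_unknown_covariate_rejected(self, small_trial):
        with pytest.raises(DesignError, match="not present"):
            nc.fit_did_mixed_model(small_trial, covariates=("no_such_column",))


class TestGroupWaveMeans:
    def test_reported_final_wave_difference(self):
        # the published final-wave means: 114.67 (intervention) vs 99.37 (control)
        rows = []
        for i in range(5):
            rows += [
                (f"I{i}", "V0", "intervention", "baseline", 102.37),
                (f"I{i}", "V0", "intervention", "final", 114.67),
                (f"K{i}", "V1", "control", "baseline", 103.42),
                (f"K{i}", "V1", "control", "final", 99.37),
            ]
        means = nc.group_wave_means(_records(rows))
        diff = means.loc["intervention", "final"] - means.loc["control", "final"]
        assert diff == pytest.approx(15.30, abs=1e-9)

    def test_single_record_is_its_own_mean(self):
        df = _records([("C0", "V0", "control", "final", 87.5)])
        means = nc.group_wave_means(df, completers_only=False)
        assert means.loc["control", "final"] == 87.5

    def test_empty_cell_reported_missing_not_zero(self):
        df = _records(
            [
                ("C0", "V0", "control", "baseline", 100.0),
                ("C0", "V0", "control", "final", 100.0),
            ]
        )
        means = nc.group_wave_means(df)
        assert "intervention" not in means.index

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nc.group_wave_means(_records([]))


class TestBaselineBalance:
    def test_reported_child_sex_contingency_table(self):
        # 139/124 male/female (intervention) vs 123/125 (control)
        rows = []
        i = 0
        for arm, males, females in (
            ("intervention", 139, 124),
            ("control", 123, 125),
        ):
            for sex, n in (("male", males), ("female", females)):
                for _ in range(n):
                    rows.append((f"C{i}", "V0", arm, "baseline", 100.0, sex))
                    i += 1
        df = pd.DataFrame(
            rows,
            columns=["child_id", "village_id", "arm", "wave", "cognitive_score", "child_sex"],
        )
        (row,) = nc.baseline_balance(df, categorical=("child_sex",), numerical=())
        assert row.test == "chi_square"
        assert row.p_value == pytest.approx(0.462, abs=0.005)
        assert not row.significant

    def test_identical_arms_give_p_of_one_for_t_test(self):
        rows = [
            (f"C{i}{arm[0]}", "V0", arm, "baseline", 95.0 + (i % 7))
            for arm in ("intervention", "control")
            for i in range(30)
        ]
        results = nc.baseline_balance(
            _records(rows), categorical=(), numerical=("cognitive_score",)
        )
        assert results[0].p_value == pytest.approx(1.0)

    def test_single_arm_rejected(self):
        rows = [(f"C{i}", "V0", "control", "baseline", 100.0) for i in range(5)]
        with pytest.raises(DesignError):
            nc.baseline_balance(_records(rows))

    def test_default_variable_selection_on_synthetic_data(self, default_trial):
        results = nc.baseline_balance(default_trial)
        names = {r.variable for r in results}
        assert {"child_sex", "dietary_diversity", "cognitive_score"} <= names
        for r in results:
            if r.p_value is not None:
                assert 0.0 <= r.p_value <= 1.0
            if r.variable in ("child_sex", "dietary_diversity", "breastfeeding"):
                assert r.test == "chi_square"
            else:
                assert r.test in ("t_test", "not_applicable")
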