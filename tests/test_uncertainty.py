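import numpy as np
import pytest

import nutricea as nc
from nutricea.uncertainty import DSAParameter


class TestOneWayDsa:
    def test_reference_values_reproduce_base_icer(self, base_costs, printed_effect):
        base_icer = base_costs.per_child_total / printed_effect.point
        params = [
            DSAParameter(cat, 1.0, 1.0, 1.0, "multiplier") for cat in nc.CATEGORIES
        ]
        for entry in nc.one_way_dsa(base_costs, printed_effect, params):
            assert entry.icer_at_low == pytest.approx(base_icer, abs=1e-9)
            assert entry.icer_at_high == pytest.approx(base_icer, abs=1e-9)
            assert entry.span == 0.0

    def test_entries_sorted_by_span_descending(self, base_costs, printed_effect):
        entries = nc.one_way_dsa(base_costs, printed_effect)
        spans = [e.span for e in entries]
        assert spans == sorted(spans, reverse=True)
        assert len(entries) == 5  # four cost categories + the effect

    def test_equal_spans_break_ties_alphabetically(self, printed_effect):
        summary = nc.summarize_costs(
            [nc.CostItem(c, c, amount=100.0) for c in nc.CATEGORIES], n_children=10
        )
        params = [
            DSAParameter(cat, 1.0, 0.8, 1.2, "multiplier") for cat in nc.CATEGORIES
        ]
        entries = nc.one_way_dsa(summary, printed_effect, params)
        assert [e.parameter for e in entries] == sorted(c for c in nc.CATEGORIES)

    def test_unrecognised_parameter_rejected(self, base_costs, printed_effect):
        bad = [DSAParameter("overheads", 1.0, 0.5, 1.5, "multiplier")]
        with pytest.raises(ValueError, match="overheads"):
            nc.one_way_dsa(base_costs, printed_effect, bad)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DSAParameter("personnel", 1.0, 1.5, 0.5, "multiplier")


class TestRunPsa:
    def test_degenerate_distributions_collapse_to_base_case(self, base_costs):
        effect = nc.EffectEstimate(point=16.11, se=1e-12, ci_low=16.11, ci_high=16.11)
        config = nc.PSAConfig(
            n_samples=50, seed=0, cost_ranges={c: (1.0, 1.0) for c in nc.CATEGORIES}
        )
        result = nc.run_psa(config, base_costs, effect)
        assert result.icer_mean == pytest.approx(
            base_costs.per_child_total / 16.11, abs=1e-6
        )
        assert np.allclose(result.samples["delta_e"], 16.11)
        assert np.allclose(result.samples["delta_c"], base_costs.per_child_total)

    def test_seed_reproducibility(self, base_costs, printed_effect):
        config = nc.PSAConfig(n_samples=200, seed=123)
        a = nc.run_psa(config, base_costs, printed_effect)
        b = nc.run_psa(config, base_costs, printed_effect)
        assert a.samples.equals(b.samples)
        assert a.icer_mean == b.icer_mean
        c = nc.run_psa(nc.PSAConfig(n_samples=200, seed=124), base_costs, printed_effect)
        assert not a.samples.equals(c.samples)

    def test_quadrant_counts_partition_samples(self, base_costs, printed_effect):
        result = nc.run_psa(nc.PSAConfig(n_samples=500, seed=2), base_costs, printed_effect)
        assert sum(result.quadrant_counts.values()) == 500
        lo, hi = result.icer_interval
        assert lo <= result.icer_mean <= hi

    def test_invalid_sample_count_rejected(self):
        with pytest.raises(ValueError):
            nc.PSAConfig(n_samples=0)


class TestCeac:
    def test_zero_wtp_with_positive_costs_gives_zero(self, base_costs, printed_effect):
        result = nc.run_psa(nc.PSAConfig(n_samples=200, seed=0), base_costs, printed_effect)
        (point,) = nc.ceac(result, [0.0])
        assert point.probability == 0.0

    def test_empty_grid_returns_empty_list(self, base_costs, printed_effect):
        result = nc.run_psa(nc.PSAConfig(n_samples=10, seed=0), base_costs, printed_effect)
        assert nc.ceac(result, []) == []

    def test_monotone_when_all_effects_positive(self, base_costs, printed_effect):
        result = nc.run_psa(nc.PSAConfig(n_samples=1000, seed=4), base_costs, printed_effect)
        assert (result.samples["delta_e"] > 0).all()
        probs = [p.probability for p in nc.ceac(result, np.arange(0, 60, 1.0))]
        assert all(b >= a for a, b in zip(probs, probs[1:]))
        assert probs[-1] == pytest.approx(1.0, abs=0.01)

    def test_boundary_sample_counts_as_not_cost_effective(self):
        # a draw whose own ICER equals λ exactly (16.5 × 16.0 = 264.0) sits
        # on the NMB = 0 boundary; the strict > rule counts it out
        import pandas as pd

        samples = pd.DataFrame(
            {"draw": [0], "delta_e": [16.0], "delta_c": [264.0],
             "icer": [16.5], "quadrant": ["NE"]}
        )
        result = nc.PSAResult(
            samples=samples,
            icer_mean=16.5,
            icer_ratio_of_means=16.5,
            icer_interval=(16.5, 16.5),
            quadrant_counts={"NE": 1, "SE": 0, "NW": 0, "SW": 0},
            n_excluded_from_icer=0,
        )
        (point,) = nc.ceac(result, [16.5])
        assert point.probability == 0.0
        (above,) = nc.ceac(result, [16.5625])  # any λ above the ICER flips it
        assert above.probability == 1.0

    def test_negative_wtp_rejected(self, base_costs, printed_effect):
        result = nc.run_psa(nc.PSAConfig(n_samples=10, seed=0), base_costs, printed_effect)
        with pytest.raises(ValueError):
            nc.ceac(result, [-1.0])


class TestCePlane:
    def test_single_ne_sample(self, base_costs):
        effect = nc.EffectEstimate(point=16.0, se=1e-12, ci_low=16.0, ci_high=16.0)
        config = nc.PSAConfig(
            n_samples=1, seed=0, cost_ranges={c: (1.0, 1.0) for c in nc.CATEGORIES}
        )
        result = nc.run_psa(config, base_costs, effect)
        scatter, counts = nc.ce_plane(result)
        assert len(scatter) == 1
        assert scatter["quadrant"].iloc[0] == "NE"
        assert counts == {"NE": 1, "SE": 0, "NW": 0, "SW": 0}

    def test_negative_effect_draws_labelled_by_cost_sign(self, base_costs):
        # an effect distribution centred below zero forces NW draws
        effect = nc.EffectEstimate(point=-5.0, se=0.1, ci_low=-5.2, ci_high=-4.8)
        config = nc.PSAConfig(n_samples=50, seed=1)
        with pytest.raises(ValueError, match="NE"):
            nc.run_psa(config, base_costs, effect)


class TestAnalyticCeac:
    def test_degenerate_costs_reduce_to_normal_cdf(self, base_costs, printed_effect):
        from scipy import stats

        ranges = {c: (1.0, 1.0) for c in nc.CATEGORIES}
        wtp = 16.5
        expected = stats.norm.cdf(
            (wtp * printed_effect.point - base_costs.per_child_total)
            / (wtp * printed_effect.se)
        )
        got = nc.ceac_probability_analytic(wtp, base_costs, printed_effect, ranges)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_zero_wtp_is_zero_for_positive_costs(self, base_costs, printed_effect):
        assert nc.ceac_probability_analytic(0.0, base_costs, printed_effect) == 0.0

    def test_monotone_in_wtp(self, base_costs, printed_effect):
        probs = [
            nc.ceac_probability_analytic(w, base_costs, printed_effect)
            for w in (4.0, 8.0, 12.0, 16.5, 20.0, 24.0)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))
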