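import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamtox import mesocosm


class TestTimeWeightedAverage:
    def test_constant_series(self):
        assert mesocosm.time_weighted_average([3, 7, 10, 17, 24], [2.0] * 5) == 2.0

    @pytest.mark.parametrize("days,concs,expected", [
        ([0, 10], [1, 3], 2.0),
        ([0, 5, 10], [0, 0, 4], 1.0),
    ])
    def test_trapezoid_hand_values(self, days, concs, expected):
        assert mesocosm.time_weighted_average(days, concs) == pytest.approx(expected)

    def test_single_measurement_returns_value(self):
        assert mesocosm.time_weighted_average([7], [0.4]) == 0.4

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mesocosm.time_weighted_average([], [])

    def test_day_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            mesocosm.time_weighted_average([3, 35], [1, 1], duration_days=30)

    @given(st.lists(st.tuples(st.floats(0, 30), st.floats(0, 100)),
                    min_size=1, max_size=12, unique_by=lambda t: t[0]))
    @settings(max_examples=60, deadline=None)
    def test_twa_bounded_by_min_max(self, series):
        days = [t for t, _ in series]
        concs = [c for _, c in series]
        twa = mesocosm.time_weighted_average(days, concs)
        assert min(concs) - 1e-9 <= twa <= max(concs) + 1e-9


class TestCommunityMetrics:
    def test_hand_count(self):
        counts = pd.DataFrame({
            "unit_id": ["m1"] * 3,
            "taxon": ["Ephemerella", "Baetis", "Chironominae"],
            "count": [10, 5, 20],
        })
        metrics, warnings = mesocosm.community_metrics(counts)
        row = metrics.iloc[0]
        assert row["richness"] == 3
        assert row["total_abundance"] == 35
        assert row["total_mayfly_abundance"] == 15
        assert row["sensitive_mayfly_abundance"] == 10
        assert warnings == []

    def test_all_zero_counts(self):
        counts = pd.DataFrame({"unit_id": ["m1"] * 2,
                               "taxon": ["Baetis", "Sweltsa"],
                               "count": [0, 0]})
        metrics, _ = mesocosm.community_metrics(counts)
        assert (metrics.iloc[0][["richness", "total_abundance",
                                 "total_mayfly_abundance"]] == 0).all()

    def test_unknown_taxon_warned_and_excluded_from_order_sums(self):
        counts = pd.DataFrame({"unit_id": ["m1"] * 2,
                               "taxon": ["Baetis", "Mysterytaxon"],
                               "count": [5, 7]})
        metrics, warnings = mesocosm.community_metrics(counts)
        assert len(warnings) == 1 and "Mysterytaxon" in warnings[0]
        row = metrics.iloc[0]
        assert row["total_abundance"] == 12  # still counted overall
        assert row["total_mayfly_abundance"] == 5

    def test_merging_units_sums_abundances(self, rng):
        taxa = ["Baetis", "Ephemerella", "Chironominae", "Sweltsa"]
        counts = pd.DataFrame({
            "unit_id": ["u1"] * 4 + ["u2"] * 4,
            "taxon": taxa * 2,
            "count": rng.integers(0, 30, 8),
        })
        merged = counts.assign(unit_id="all").groupby(
            ["unit_id", "taxon"], as_index=False)["count"].sum()
        m_split, _ = mesocosm.community_metrics(counts)
        m_merged, _ = mesocosm.community_metrics(merged)
        for col in ["total_abundance", "total_mayfly_abundance"]:
            assert m_merged[col].iloc[0] == m_split[col].sum()
        assert m_merged["richness"].iloc[0] <= m_split["richness"].sum()

    def test_scaling_linearity(self):
        counts = pd.DataFrame({"unit_id": ["m1"], "taxon": ["Baetis"], "count": [271]})
        metrics, _ = mesocosm.community_metrics(counts)
        factor = 24.0  # per-m2 conversion is a plain multiplicative constant
        assert metrics["total_abundance"].iloc[0] * factor == 271 * 24.0


class TestBiomass:
    COEFFS = pd.DataFrame({"taxon": ["Baetis", "Sweltsa"],
                           "a": [0.005, 0.01],
                           "b_exp": [3.0, 2.5],
                           "ffg": ["collector-gatherer", "predator"]})

    def test_unit_length_mass_equals_a(self):
        lengths = pd.DataFrame({"unit_id": ["m1"], "taxon": ["Baetis"], "length_mm": [1.0]})
        out, _ = mesocosm.biomass_by_ffg(lengths, self.COEFFS)
        assert out["biomass"].iloc[0] == pytest.approx(0.005)

    def test_power_law_hand_value(self):
        lengths = pd.DataFrame({"unit_id": ["m1"], "taxon": ["Baetis"], "length_mm": [2.0]})
        out, _ = mesocosm.biomass_by_ffg(lengths, self.COEFFS)
        assert out["biomass"].iloc[0] == pytest.approx(0.04)

    def test_two_individuals_double_biomass(self):
        one = pd.DataFrame({"unit_id": ["m1"], "taxon": ["Sweltsa"], "length_mm": [3.0]})
        two = pd.concat([one, one], ignore_index=True)
        b1, _ = mesocosm.biomass_by_ffg(one, self.COEFFS)
        b2, _ = mesocosm.biomass_by_ffg(two, self.COEFFS)
        assert b2["biomass"].iloc[0] == pytest.approx(2 * b1["biomass"].iloc[0])

    def test_missing_coefficients_warn(self):
        lengths = pd.DataFrame({"unit_id": ["m1"], "taxon": ["Unknown"], "length_mm": [2.0]})
        out, warnings = mesocosm.biomass_by_ffg(lengths, self.COEFFS)
        assert out.empty and len(warnings) == 1


class TestEmergence:
    def _daily(self, spec):
        rows = [{"unit_id": u, "day": d, "count": c} for u, d, c in spec]
        return pd.DataFrame(rows)

    def test_treatment_equal_to_control_gives_zero_series(self):
        daily = self._daily([("c1", 1, 2), ("c1", 2, 3), ("t1", 1, 2), ("t1", 2, 3)])
        norm, _ = mesocosm.emergence_metrics(daily, ["c1"], control_pool_mean=100)
        t1 = norm[norm.unit_id == "t1"]
        assert (t1["cum_minus_control"] == 0).all()

    def test_percent_emergence_hand_ratio(self):
        daily = self._daily([("c1", 1, 10), ("t1", 1, 30)])
        _, percent = mesocosm.emergence_metrics(daily, ["c1"], control_pool_mean=120)
        assert percent.set_index("unit_id").loc["t1", "percent_emergence"] == pytest.approx(0.25)

    def test_no_emergence_gives_negative_control_series(self):
        daily = self._daily([("c1", 1, 5), ("c1", 2, 5), ("t1", 1, 0), ("t1", 2, 0)])
        norm, percent = mesocosm.emergence_metrics(daily, ["c1"], control_pool_mean=50)
        t1 = norm[norm.unit_id == "t1"].sort_values("day")
        assert list(t1["cum_minus_control"]) == [-5.0, -10.0]
        assert percent.set_index("unit_id").loc["t1", "percent_emergence"] == 0.0

    def test_zero_control_denominator_rejected(self):
        daily = self._daily([("c1", 1, 1)])
        with pytest.raises(ValueError, match="pool mean"):
            mesocosm.emergence_metrics(daily, ["c1"], control_pool_mean=0)


class TestExposureSummary:
    def test_twa_per_unit_compound(self, mesocosm_clean):
        conc, _, _, _ = mesocosm_clean
        summary = mesocosm.exposure_summary(conc)
        treated = summary[summary.unit_id == "IMI-L5-R1"]
        assert treated["twa"].iloc[0] == pytest.approx(10.0)
        assert treated["n_samples"].iloc[0] == 5
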