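import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from streamtox import screening


def _conc(rows):
    return pd.DataFrame(rows, columns=["unit_id", "time", "compound",
                                       "concentration", "reporting_level",
                                       "censored"])


BENCH = screening.EPA_CHRONIC_INVERTEBRATE_BENCHMARKS


class TestDetectionSummary:
    def test_hand_count_frequencies(self, small_conc_table):
        out = screening.detection_summary(small_conc_table)
        imi = out[out.compound == "imidacloprid"].iloc[0]
        assert imi["detect_freq_sample"] == pytest.approx(1 / 8)
        assert imi["detect_freq_site"] == pytest.approx(1 / 2)

    def test_no_detections_all_zero(self, small_conc_table):
        table = small_conc_table.assign(censored=True, concentration=0.0)
        out = screening.detection_summary(table)
        assert (out["detect_freq_sample"] == 0).all()
        assert (out["max"] == 0).all()

    def test_site_freq_at_least_sample_freq(self, small_conc_table):
        out = screening.detection_summary(small_conc_table)
        assert (out["detect_freq_site"] >= out["detect_freq_sample"] - 1e-12).all()

    def test_balanced_inequality_on_random_tables(self, rng):
        rows = []
        for site in range(6):
            for week in range(1, 5):
                detected = rng.random() < 0.3
                rows.append((f"s{site}", week, "imidacloprid",
                             0.05 if detected else 0.0, 0.001, not detected))
        out = screening.detection_summary(_conc(rows))
        imi = out[out.compound == "imidacloprid"].iloc[0]
        assert imi["detect_freq_site"] >= imi["detect_freq_sample"]

    def test_restricts_to_last_k_samples(self):
        rows = [("s1", w, "imidacloprid", 1.0 if w <= 2 else 0.0, 0.001, w > 2)
                for w in range(1, 7)]
        out = screening.detection_summary(_conc(rows), last_k_weeks=4)
        imi = out[out.compound == "imidacloprid"].iloc[0]
        assert imi["detect_freq_sample"] == 0.0  # detections were in weeks 1-2

    def test_too_few_samples_names_site(self):
        rows = [("s1", w, "imidacloprid", 0.0, 0.001, True) for w in (1, 2)]
        with pytest.raises(ValueError, match="s1"):
            screening.detection_summary(_conc(rows))


class TestCibq:
    def test_hand_quotients(self):
        # IMI 0.02 / 0.01 + CLO 0.10 / 0.05 = 2 + 2 = 4
        rows = [("s1", w, c, v if w == 1 else 0.0, 0.001, w != 1)
                for w in (1, 2, 3, 4)
                for c, v in (("imidacloprid", 0.02), ("clothianidin", 0.10))]
        out = screening.cibq(_conc(rows), BENCH)
        assert out["cibq"].iloc[0] == pytest.approx(4.0)

    def test_all_censored_gives_zero(self, small_conc_table):
        table = small_conc_table.assign(censored=True, concentration=0.0)
        out = screening.cibq(table, BENCH)
        assert (out["cibq"] == 0).all()

    def test_site_max_rule(self):
        weekly = {1: 0.1, 2: 4.0, 3: 0.2, 4: 0.3}
        rows = [("s1", w, "imidacloprid", q * 0.01, 0.001, False)
                for w, q in weekly.items()]
        out = screening.cibq(_conc(rows), BENCH)
        assert out["cibq"].iloc[0] == pytest.approx(4.0)

    def test_missing_benchmark_named(self):
        rows = [("s1", w, "mysterycide", 0.5 if w == 1 else 0.0, 0.001, w != 1)
                for w in (1, 2, 3, 4)]
        with pytest.raises(ValueError, match="mysterycide"):
            screening.cibq(_conc(rows), BENCH)

    def test_neonic_scope_bounded_by_total(self, small_conc_table):
        total = screening.cibq(small_conc_table, BENCH, None)
        neonic = screening.cibq(small_conc_table, BENCH, screening.NEONICOTINOIDS)
        merged = total.merge(neonic, on="site_id", suffixes=("_t", "_n"))
        assert (merged["cibq_n"] <= merged["cibq_t"] + 1e-12).all()

    @given(st.fixed_dictionaries({
        "imidacloprid": st.floats(0.0, 1.0),
        "clothianidin": st.floats(0.0, 1.0),
        "thiamethoxam": st.floats(0.0, 1.0),
    }))
    @settings(max_examples=40, deadline=None)
    def test_additivity_over_disjoint_scopes(self, week1):
        # all detections in a single sample: the site max equals that
        # sample's quotient sum, which must be additive over scopes
        rows = []
        for compound, value in week1.items():
            for week in (1, 2, 3, 4):
                v = value if week == 1 else 0.0
                rows.append(("s1", week, compound, v, 0.001, v < 0.001))
        table = _conc(rows)
        a = screening.cibq(table, BENCH, ["imidacloprid"])
        b = screening.cibq(table, BENCH, ["clothianidin", "thiamethoxam"])
        both = screening.cibq(table, BENCH,
                              ["imidacloprid", "clothianidin", "thiamethoxam"])
        assert both["cibq"].iloc[0] == pytest.approx(
            a["cibq"].iloc[0] + b["cibq"].iloc[0], abs=1e-12)

    def test_rl_substitution_variant_upper_bounds(self, small_conc_table):
        low = screening.cibq(small_conc_table, BENCH)
        high = screening.cibq(small_conc_table, BENCH, censored_at_rl=True)
        merged = low.merge(high, on="site_id", suffixes=("_lo", "_hi"))
        assert (merged["cibq_hi"] >= merged["cibq_lo"] - 1e-12).all()


class TestExceedance:
    def test_hand_summary(self):
        table = pd.DataFrame({"site_id": ["a", "b"], "cibq": [0.5, 1.5],
                              "n_samples_used": [4, 4]})
        out = screening.exceedance_and_means(table)
        assert out["exceedance_freq"] == 0.5
        assert out["mean"] == 1.0
        assert out["median"] == 1.0

    def test_all_zero(self):
        table = pd.DataFrame({"site_id": ["a"], "cibq": [0.0], "n_samples_used": [4]})
        out = screening.exceedance_and_means(table)
        assert out["mean"] == 0 and out["exceedance_freq"] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            screening.exceedance_and_means(pd.DataFrame(columns=["site_id", "cibq"]))

    def test_hc5_substitution_scales_quotients_linearly(self):
        rows = [("s1", w, "imidacloprid", 0.05 if w == 2 else 0.0, 0.001, w != 2)
                for w in (1, 2, 3, 4)]
        table = _conc(rows)
        base = screening.cibq(table, BENCH)
        swapped = screening.substitute_benchmarks(BENCH, {"imidacloprid": 0.017})
        new = screening.cibq(table, swapped)
        assert new["cibq"].iloc[0] == pytest.approx(
            base["cibq"].iloc[0] * 0.01 / 0.017, rel=1e-9)

    def test_substitute_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            screening.substitute_benchmarks(BENCH, {"imidacloprid": 0.0})
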