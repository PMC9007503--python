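import math

import numpy as np
import pandas as pd
import pytest

from streamtox import synth
from streamtox.doseresponse import loglogistic


class TestGenMesocosm:
    def test_deterministic_under_seed(self):
        a = synth.gen_mesocosm(seed=1)
        b = synth.gen_mesocosm(seed=1)
        c = synth.gen_mesocosm(seed=2)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        assert not a[1]["value"].equals(c[1]["value"])

    def test_zero_noise_responses_on_curve(self, mesocosm_clean):
        conc, resp, _, _ = mesocosm_clean
        params = synth.DEFAULT_DR_PARAMS["total_mayfly_abundance"]["IMI"]
        sub = resp[(resp.metric == "total_mayfly_abundance")
                   & (resp.treatment_series == "IMI")]
        expected = np.round(loglogistic(sub["nominal_dose"].to_numpy(),
                                        params["b"], params["c"],
                                        params["d"], params["e"]))
        assert np.array_equal(sub["value"].to_numpy(), expected)
        # measured concentrations equal nominals exactly (no jitter)
        treated = conc[~conc.censored & conc.unit_id.str.startswith("IMI")]
        assert set(np.unique(treated["concentration"])) <= set(
            synth.MesocosmDesign().levels)

    def test_controls_sit_on_upper_asymptote(self, mesocosm_clean):
        _, resp, _, _ = mesocosm_clean
        d = synth.DEFAULT_DR_PARAMS["total_mayfly_abundance"]["IMI"]["d"]
        ctrl = resp[(resp.metric == "total_mayfly_abundance")
                    & (resp.treatment_series == "CONTROL")]
        assert (ctrl["value"] == d).all()
        assert (ctrl["nominal_dose"] == 0).all()

    def test_mix_mean_matches_response_addition(self):
        """With gamma=1, empirical MIX means approach the additive
        prediction (Monte Carlo over many replicate mesocosms)."""
        design = synth.MesocosmDesign(replicates_per_level=500, n_controls=3,
                                      series=("MIX",))
        _, resp, _, _ = synth.gen_mesocosm(design, seed=7, synergy=1.0)
        pi = synth.DEFAULT_DR_PARAMS["total_mayfly_abundance"]["IMI"]
        pc = synth.DEFAULT_DR_PARAMS["total_mayfly_abundance"]["CLO"]
        sub = resp[(resp.metric == "total_mayfly_abundance")
                   & (resp.treatment_series == "MIX")]
        for dose_sum, grp in sub.groupby("nominal_dose"):
            level = dose_sum / 2
            fa = loglogistic(np.array([level]), pi["b"], pi["c"], pi["d"], pi["e"])[0] / pi["d"]
            fb = loglogistic(np.array([level]), pc["b"], pc["c"], pc["d"], pc["e"])[0] / pc["d"]
            predicted = pi["d"] * fa * fb
            if predicted < 2:
                continue  # zero limit; relative MC error unbounded
            assert grp["value"].mean() == pytest.approx(predicted, rel=0.1)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            synth.gen_mesocosm(noise={"dispersion": 0.0})

    def test_levels_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            synth.MesocosmDesign(levels=(0.1, 0.1, 1.0, 2.0, 3.0))


class TestGenSsdTaxa:
    def test_lognormal_truth_is_closed_form_quantile(self):
        _, truth = synth.gen_ssd_taxa("log-normal", {"meanlog": 0, "sdlog": 1}, 10, seed=0)
        hc5 = truth.set_index("parameter").loc["hc5_true", "true_value"]
        assert hc5 == pytest.approx(math.exp(-1.6448536269514722), rel=1e-12)

    def test_minimum_rows_and_positivity(self):
        table, _ = synth.gen_ssd_taxa("weibull", {"shape": 1.5, "scale": 0.1}, 5, seed=3)
        assert len(table) == 5
        assert (table["value"] > 0).all()

    def test_same_seed_identical(self):
        a, _ = synth.gen_ssd_taxa("gamma", {"shape": 2, "scale": 0.05}, 8, seed=9)
        b, _ = synth.gen_ssd_taxa("gamma", {"shape": 2, "scale": 0.05}, 8, seed=9)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("dist,params", [
        ("log-normal", {"meanlog": 0, "sdlog": -1}),
        ("gamma", {"shape": -2, "scale": 1}),
        ("nope", {"shape": 1, "scale": 1}),
    ])
    def test_invalid_parameters_rejected(self, dist, params):
        with pytest.raises(ValueError):
            synth.gen_ssd_taxa(dist, params, 8)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="5 taxa"):
            synth.gen_ssd_taxa("log-normal", {"meanlog": 0, "sdlog": 1}, 4)


class TestGenField:
    def test_zero_occurrence_all_censored(self):
        exposure = {c: {**spec, "occur_prob": 0.0}
                    for c, spec in synth.DEFAULT_FIELD_EXPOSURE.items()}
        conc, _, _, _ = synth.gen_field(n_sites=10, exposure=exposure, seed=0)
        assert conc["censored"].all()

    def test_degenerate_sigma_gives_constant_detections(self):
        exposure = {"imidacloprid": {"occur_prob": 1.0, "week_prob": 1.0,
                                     "mu": math.log(0.5), "sigma": 0.0, "rl": 0.001}}
        conc, _, _, _ = synth.gen_field(n_sites=6, exposure=exposure, seed=0)
        detected = conc[~conc.censored]
        assert np.allclose(detected["concentration"], 0.5)

    def test_too_few_weeks_rejected(self):
        with pytest.raises(ValueError, match="4 weekly"):
            synth.gen_field(n_weeks=3)

    def test_truth_records_effect_coefficients(self):
        _, _, _, truth = synth.gen_field(n_sites=10, seed=0)
        params = set(truth["parameter"])
        assert {"beta_imi", "beta_clo", "beta_interaction"} <= params


class TestGenPathData:
    def test_population_coefficients_recovered(self):
        coeffs = {("dose", "scraper_biomass"): -0.89,
                  ("scraper_biomass", "chla"): -0.63}
        data, truth = synth.gen_path_data(coeffs, 100_000, seed=5)
        # simple regressions recover the standardised slopes
        for (a, b), beta in coeffs.items():
            slope = np.polyfit(data[a], data[b], 1)[0]
            est = slope * data[a].std() / data[b].std()
            assert est == pytest.approx(beta, abs=0.01)
        assert np.allclose(data.std(ddof=0), 1.0, atol=0.02)

    def test_null_coefficients_give_independent_noise(self):
        data, _ = synth.gen_path_data({("a", "b"): 0.0}, 50_000, seed=2)
        assert abs(np.corrcoef(data["a"], data["b"])[0, 1]) < 0.02

    def test_deterministic_under_seed(self):
        a, _ = synth.gen_path_data({("x", "y"): 0.5}, 10, seed=3)
        b, _ = synth.gen_path_data({("x", "y"): 0.5}, 10, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_impossible_standardised_system_rejected(self):
        with pytest.raises(ValueError, match="residual variance"):
            synth.gen_path_data({("a", "c"): 0.9, ("b", "c"): 0.9,
                                 ("a", "b"): 0.9}, 10, seed=0)
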