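"""Binary-mixture predictions under response addition and the model
deviation ratio (MDR).

Response addition (independent action) predicts the mixture response as
the product of the components' fractional responses, rescaled to the
control level:

    predicted = control * (f_A(dose_A) / d_A) * (f_B(dose_B) / d_B)

where f is each compound's fitted unary log-logistic curve and d its upper
asymptote.  The MDR is predicted / observed, computed per mixture
replicate on the response scale; MDR > 2 is classed synergistic and
MDR < 0.5 antagonistic.  Predictions below a small floor are flagged
``zero-limit-indeterminate``: when the additive model itself predicts
(essentially) no organisms, no deviation from the 1:1 line can be
distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import LogisticFit, control_level, fit_logistic, predict_response

ADDITIVE = "additive"
SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"
INDETERMINATE = "zero-limit-indeterminate"


@dataclass
class MixturePrediction:
    unit_id: str
    dose_a: float
    dose_b: float
    observed: float
    predicted: float
    mdr: float
    mdr_class: str
    observed_floored: bool = False


def predict_response_addition(fit_a: LogisticFit, fit_b: LogisticFit,
                              dose_a: float, dose_b: float,
                              control: float) -> float:
    """Predicted mixture response under response addition.

    Fractional responses are taken on the original response scale
    (back-transformed when a fit used the log1p error model) relative to
    each fit's response at dose zero, then multiplied and rescaled to the
    supplied control level.
    """
    d_a, d_b = control_level(fit_a), control_level(fit_b)
    if d_a <= 0 or d_b <= 0:
        raise ValueError("unary fits must have positive upper asymptotes")
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be nonnegative")
    frac_a = max(float(predict_response(fit_a, dose_a)[0]) / d_a, 0.0)
    frac_b = max(float(predict_response(fit_b, dose_b)[0]) / d_b, 0.0)
    return control * frac_a * frac_b


def model_deviation_ratio(predicted: float, observed: float, floor: float):
    """MDR = predicted / observed with the zero-limit rules.

    Returns (mdr, class, observed_floored).  A prediction below ``floor``
    is indeterminate (no MDR); an observed zero is substituted by the
    floor and flagged.
    """
    if predicted < 0 or observed < 0:
        raise ValueError("predicted and observed must be nonnegative")
    if floor <= 0:
        raise ValueError("floor must be positive")
    if predicted < floor:
        return np.nan, INDETERMINATE, False
    floored = False
    if observed == 0:
        observed = floor
        floored = True
    mdr = predicted / observed
    if mdr > 2.0:
        cls = SYNERGISTIC
    elif mdr < 0.5:
        cls = ANTAGONISTIC
    else:
        cls = ADDITIVE
    return float(mdr), cls, floored


def default_floor(observed_values) -> float:
    """Half the smallest observed nonzero response, at most 0.5."""
    obs = np.asarray(observed_values, dtype=float)
    nonzero = obs[obs > 0]
    if nonzero.size == 0:
        return 0.5
    return float(min(0.5, nonzero.min() / 2.0))


def mixture_series_analysis(fit_a: LogisticFit, fit_b: LogisticFit,
                            mixture_responses: pd.DataFrame,
                            exposure: pd.DataFrame,
                            compound_a: str = "imidacloprid",
                            compound_b: str = "clothianidin",
                            control: float | None = None,
                            floor: float | None = None):
    """Per-replicate response-addition analysis of a mixture series.

    Parameters
    ----------
    fit_a, fit_b : unary fits for the two compounds.
    mixture_responses : tidy frame (unit_id, value) of one endpoint for
        the mixture units.
    exposure : frame (unit_id, compound, twa) holding both compounds' TWA
        for every mixture unit.
    control : response level at dose zero; defaults to the mean of the two
        fits' (back-transformed) responses at dose zero.
    floor : zero-limit floor; defaults to :func:`default_floor` of the
        observed values.

    Returns
    -------
    (predictions frame, summary dict with min/max MDR and the count of
    synergistic replicates).
    """
    if control is None:
        control = 0.5 * (control_level(fit_a) + control_level(fit_b))
    if floor is None:
        floor = default_floor(mixture_responses["value"])

    twa = exposure.pivot_table(index="unit_id", columns="compound", values="twa")
    rows = []
    for _, rec in mixture_responses.iterrows():
        unit = rec["unit_id"]
        if unit not in twa.index or np.isnan(twa.loc[unit].get(compound_a, np.nan)) \
                or np.isnan(twa.loc[unit].get(compound_b, np.nan)):
            raise ValueError(f"mixture unit {unit!r} lacks TWA for both compounds")
        da = float(twa.loc[unit, compound_a])
        db = float(twa.loc[unit, compound_b])
        pred = predict_response_addition(fit_a, fit_b, da, db, control)
        mdr, cls, floored = model_deviation_ratio(pred, float(rec["value"]), floor)
        rows.append({
            "unit_id": unit, "dose_a": da, "dose_b": db,
            "observed": float(rec["value"]), "predicted": pred,
            "mdr": mdr, "class": cls, "observed_floored": floored,
        })
    out = pd.DataFrame(rows)
    determinate = out[out["class"] != INDETERMINATE]
    summary = {
        "n": len(out),
        "n_indeterminate": int((out["class"] == INDETERMINATE).sum()),
        "n_synergistic": int((out["class"] == SYNERGISTIC).sum()),
        "mdr_min": float(determinate["mdr"].min()) if len(determinate) else np.nan,
        "mdr_max": float(determinate["mdr"].max()) if len(determinate) else np.nan,
    }
    return out, summary


def mixture_endpoint_analysis(responses: pd.DataFrame, exposure: pd.DataFrame,
                              metric: str = "total_mayfly_abundance",
                              transform: str = "log1p",
                              floor: float | None = None):
    """Full response-addition analysis of one endpoint from raw tables.

    Fits the two unary LL3 curves from the IMI/CLO series (plus controls)
    against per-unit summed TWA, then scores every mixture replicate.
    Count endpoints are fitted on the log1p response scale by default so
    that near-zero high-dose observations constrain the upper tail of the
    curve (which is what lets the zero-limit rule engage where it should).

    Returns (unary fits dict, predictions frame, summary dict).
    """
    twa = exposure.groupby("unit_id")["twa"].sum()
    sub = responses[responses["metric"] == metric]
    if sub.empty:
        raise ValueError(f"no responses for metric {metric!r}")
    fits = {}
    for series in ("IMI", "CLO"):
        part = sub[sub["treatment_series"].isin([series, "CONTROL"])]
        dose = part["unit_id"].map(twa).where(part["treatment_series"] == series, 0.0)
        fits[series] = fit_logistic(dose.to_numpy(dtype=float),
                                    part["value"].to_numpy(dtype=float),
                                    "LL3", transform=transform)
    mix_resp = sub[sub["treatment_series"] == "MIX"][["unit_id", "value"]]
    table, summary = mixture_series_analysis(fits["IMI"], fits["CLO"],
                                             mix_resp, exposure, floor=floor)
    return fits, table, summary
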