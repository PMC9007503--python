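"""Exposure summaries and biological endpoints for mesocosm tables.

Exposure is summarised as a time-weighted average (TWA): the trapezoidal
integral of the linearly interpolated measurement series over the span
from the first to the last sampling day, divided by that span.  Community
endpoints (richness, total abundance, mayfly abundance, sensitive-mayfly
abundance), length-mass biomass by functional feeding group, and
control-normalised emergence series are computed from tidy input tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Mayfly genera with demonstrated sensitivity to contaminants; their
#: summed abundance is the "sensitive mayfly" endpoint.
SENSITIVE_MAYFLIES = ("Ephemerella", "Rhithrogena", "Drunella", "Epeorus")

#: Default taxon -> order lookup covering the common Rocky Mountain stream
#: taxa used by the synthetic generator; callers may extend or override.
DEFAULT_TAXON_ORDERS = {
    "Ephemerella": "Ephemeroptera",
    "Rhithrogena": "Ephemeroptera",
    "Drunella": "Ephemeroptera",
    "Epeorus": "Ephemeroptera",
    "Baetis": "Ephemeroptera",
    "Cinygmula": "Ephemeroptera",
    "Lepidostoma": "Trichoptera",
    "Hydropsyche": "Trichoptera",
    "Brachycentrus": "Trichoptera",
    "Chironominae": "Diptera",
    "Orthocladiinae": "Diptera",
    "Tanypodinae": "Diptera",
    "Simulium": "Diptera",
    "Sweltsa": "Plecoptera",
    "Isoperla": "Plecoptera",
    "Hyalella": "Amphipoda",
}


@dataclass
class ExposureSummary:
    unit_id: str
    compound: str
    twa: float
    n_samples: int


def time_weighted_average(days, concentrations, duration_days: int | None = None) -> float:
    """Trapezoidal time-weighted average concentration.

    The series is linearly interpolated between sampling days and averaged
    over [first day, last day].  A single measurement returns that value.
    ``duration_days``, when given, only bounds-checks the days.
    """
    t = np.asarray(days, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size == 0:
        raise ValueError("empty measurement series")
    if t.size != c.size:
        raise ValueError("days and concentrations must have equal length")
    if duration_days is not None and (np.any(t < 0) or np.any(t > duration_days)):
        raise ValueError(f"sampling days outside [0, {duration_days}]")
    order = np.argsort(t)
    t, c = t[order], c[order]
    if t.size == 1 or t[-1] == t[0]:
        return float(c.mean())
    return float(np.trapezoid(c, t) / (t[-1] - t[0]))


def exposure_summary(conc_table: pd.DataFrame, duration_days: int | None = None) -> pd.DataFrame:
    """Per-unit, per-compound TWA from a tidy concentration table.

    Censored rows contribute their stored concentration (0 by convention).
    """
    rows = []
    for (unit, compound), grp in conc_table.groupby(["unit_id", "compound"], sort=True):
        rows.append({
            "unit_id": unit,
            "compound": compound,
            "twa": time_weighted_average(grp["time"], grp["concentration"], duration_days),
            "n_samples": len(grp),
        })
    return pd.DataFrame(rows)


def community_metrics(counts: pd.DataFrame, taxon_orders: dict[str, str] | None = None):
    """Community endpoints per unit from per-taxon abundances.

    Parameters
    ----------
    counts : tidy frame (unit_id, taxon, count).
    taxon_orders : taxon -> insect order mapping; defaults to the built-in
        lookup.  Taxa with no mapping are listed in the warnings report and
        excluded from order-level sums (they still count toward richness
        and total abundance).

    Returns
    -------
    (metrics frame, warnings list).  Metrics: richness, total_abundance,
    total_mayfly_abundance, sensitive_mayfly_abundance.
    """
    if (counts["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    orders = dict(DEFAULT_TAXON_ORDERS)
    if taxon_orders:
        orders.update(taxon_orders)
    unknown = sorted(set(counts["taxon"]) - set(orders))
    warnings = [f"no order mapping for taxon {t!r}; excluded from order-level sums"
                for t in unknown]

    rows = []
    for unit, grp in counts.groupby("unit_id", sort=True):
        present = grp[grp["count"] > 0]
        is_mayfly = present["taxon"].map(lambda t: orders.get(t) == "Ephemeroptera")
        is_sensitive = present["taxon"].isin(SENSITIVE_MAYFLIES)
        rows.append({
            "unit_id": unit,
            "richness": int(present["taxon"].nunique()),
            "total_abundance": float(grp["count"].sum()),
            "total_mayfly_abundance": float(present.loc[is_mayfly, "count"].sum()),
            "sensitive_mayfly_abundance": float(present.loc[is_sensitive, "count"].sum()),
        })
    return pd.DataFrame(rows), warnings


def biomass_by_ffg(lengths: pd.DataFrame, coefficients: pd.DataFrame):
    """Length-mass biomass summed within functional feeding group.

    Individual mass follows the power law ``m = a * L**b_exp`` with
    taxon-specific coefficients.  Taxa without coefficients are excluded
    and reported in the warnings list.

    Parameters
    ----------
    lengths : tidy frame (unit_id, taxon, length_mm), lengths > 0.
    coefficients : frame (taxon, a, b_exp, ffg) with a > 0.
    """
    if (lengths["length_mm"] <= 0).any():
        raise ValueError("lengths must be positive")
    if (coefficients["a"] <= 0).any():
        raise ValueError("length-mass coefficient a must be positive")
    coef = coefficients.set_index("taxon")
    known = lengths["taxon"].isin(coef.index)
    warnings = [f"no length-mass coefficients for taxon {t!r}; excluded"
                for t in sorted(set(lengths.loc[~known, "taxon"]))]
    df = lengths[known].copy()
    df["mass"] = (coef.loc[df["taxon"], "a"].to_numpy()
                  * df["length_mm"].to_numpy() ** coef.loc[df["taxon"], "b_exp"].to_numpy())
    df["ffg"] = coef.loc[df["taxon"], "ffg"].to_numpy()
    out = (df.groupby(["unit_id", "ffg"], sort=True)["mass"].sum()
             .rename("biomass").reset_index())
    return out, warnings


def emergence_metrics(daily: pd.DataFrame, control_units, control_pool_mean: float):
    """Control-normalised cumulative emergence and percent emergence.

    Parameters
    ----------
    daily : tidy frame (unit_id, day, count) of adult emergers per day.
    control_units : unit ids forming the control group; their mean
        cumulative series is subtracted from every unit's series.
    control_pool_mean : mean (larvae + adults) per control unit — the
        percent-emergence denominator.

    Returns
    -------
    (normalised cumulative frame (unit_id, day, cum_minus_control),
     percent frame (unit_id, percent_emergence)).
    Percent can exceed 1 if a treatment out-emerges the control pool.
    """
    control_units = list(control_units)
    if not control_units:
        raise ValueError("need at least one control unit")
    if control_pool_mean <= 0:
        raise ValueError("control (larvae + adults) pool mean must be positive")

    days = np.arange(int(daily["day"].min()), int(daily["day"].max()) + 1)
    cum = {}
    for unit, grp in daily.groupby("unit_id"):
        series = grp.groupby("day")["count"].sum().reindex(days, fill_value=0)
        cum[unit] = series.cumsum().to_numpy(dtype=float)
    missing = [u for u in control_units if u not in cum]
    if missing:
        raise ValueError(f"control unit(s) {missing} absent from emergence table")
    control_mean = np.mean([cum[u] for u in control_units], axis=0)

    rows = []
    for unit, series in cum.items():
        for day, value in zip(days, series - control_mean):
            rows.append({"unit_id": unit, "day": int(day), "cum_minus_control": float(value)})
    normalised = pd.DataFrame(rows)

    percent = pd.DataFrame({
        "unit_id": sorted(cum),
        "percent_emergence": [float(cum[u][-1]) / control_pool_mean for u in sorted(cum)],
    })
    return normalised, percent
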