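"""Synthetic datasets with known ground truth for every pipeline stage.

Each generator returns tidy tables matching the :mod:`streamtox.io`
schemas plus a "truth" table (parameter, true_value) so that recovery
tests read ground truth from a single sidecar rather than from the
generator internals.

The mesocosm generator emulates a 30-day dosed-stream experiment: three
exposure series (two single compounds and their 1:1-by-mass binary
mixture), five duplicated treatment levels spanning 0.001-10 ug/L plus
three undosed controls, weekly-ish water samples on days 3/7/10/17/24,
negative-binomial count endpoints following log-logistic dose-response
curves, and binomial adult emergence out of a larval pool.  The field
generator emulates an 85-site, 4-week multi-compound screen with
left-censoring at the reporting level and covariate-driven mayfly
abundance with an optional imidacloprid x clothianidin synergy term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import COVARIATE_NAMES
from .ssd import _quantile
from .doseresponse import loglogistic


# ---------------------------------------------------------------------------
# Mesocosm experiment
# ---------------------------------------------------------------------------

@dataclass
class MesocosmDesign:
    """Layout of the dosed-stream experiment."""

    series: tuple = ("IMI", "CLO", "MIX")
    levels: tuple = (0.001, 0.01, 0.1, 1.0, 10.0)  # unary nominals, ug/L
    mix_levels: tuple = (0.0005, 0.005, 0.05, 0.5, 5.0)  # per compound, ug/L
    replicates_per_level: int = 2
    n_controls: int = 3
    sample_days: tuple = (3, 7, 10, 17, 24)
    duration_days: int = 30

    def __post_init__(self):
        for levels in (self.levels, self.mix_levels):
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise ValueError("treatment levels must be strictly increasing")
        if self.replicates_per_level < 1 or self.n_controls < 1:
            raise ValueError("need at least one replicate and one control")


#: Default per-metric, per-compound log-logistic parameters.  The upper
#: asymptote d and lower asymptote c are shared across compounds within a
#: metric (the undosed community is the same); the dose-scale parameter e
#: is the true EC50.
DEFAULT_DR_PARAMS = {
    "total_mayfly_abundance": {
        "IMI": {"b": 2.3, "c": 0.0, "d": 150.0, "e": 1.05},
        "CLO": {"b": 2.3, "c": 0.0, "d": 150.0, "e": 1.35},
    },
    "total_abundance": {
        "IMI": {"b": 1.8, "c": 0.0, "d": 250.0, "e": 2.5},
        "CLO": {"b": 1.8, "c": 0.0, "d": 250.0, "e": 2.0},
    },
}

DEFAULT_EMERGENCE = {
    # fraction of the larval pool emerging in controls, and the
    # log-logistic suppression curve per compound
    "pool_size": 200,
    "control_fraction": 0.6,
    "IMI": {"b": 1.0, "e": 0.8},
    "CLO": {"b": 1.0, "e": 0.5},
}

DEFAULT_NOISE = {
    "conc_cv": 0.2,        # lognormal jitter of measured around nominal
    "dispersion": 16.0,    # negative-binomial size; inf = Poisson
    "deterministic": False,  # True: counts = round(mean), no jitter
    "reporting_level": 0.001,
}


def _unit_ids(design: MesocosmDesign):
    units = []
    for series in design.series:
        levels = design.mix_levels if series == "MIX" else design.levels
        for li, level in enumerate(levels, start=1):
            for rep in range(1, design.replicates_per_level + 1):
                units.append((f"{series}-L{li}-R{rep}", series, level))
    for rep in range(1, design.n_controls + 1):
        units.append((f"CTRL-R{rep}", "CONTROL", 0.0))
    return units


def _draw_counts(rng, mean, dispersion, deterministic):
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    if deterministic:
        return np.round(mean)
    if math.isinf(dispersion):
        return rng.poisson(mean).astype(float)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive (or inf for Poisson)")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def _emergence_day_weights(duration_days):
    # triangular pulse peaking around two-thirds of the experiment
    days = np.arange(1, duration_days + 1)
    peak = 2 * duration_days / 3
    w = np.maximum(0.0, 1.0 - np.abs(days - peak) / (duration_days / 2))
    return days, w / w.sum()


def gen_mesocosm(design: MesocosmDesign | None = None,
                 dr_params: dict | None = None,
                 noise: dict | None = None,
                 seed: int = 0,
                 synergy: float = 1.0,
                 emergence: dict | None = None):
    """Generate a full mesocosm dataset.

    Parameters
    ----------
    dr_params : metric -> compound ("IMI"/"CLO") -> {b, c, d, e}; the
        upper/lower asymptotes must agree across compounds of one metric.
    noise : see DEFAULT_NOISE; ``deterministic`` gives the zero-noise
        limit (measured = nominal, counts = round(mean)).
    synergy : mixture synergy multiplier gamma; observed mixture means are
        the response-addition prediction divided by gamma (gamma = 1 is
        exact response addition).
    emergence : see DEFAULT_EMERGENCE.

    Returns
    -------
    (concentration table, response table, emergence table, truth table).
    """
    design = design or MesocosmDesign()
    dr_params = dr_params if dr_params is not None else DEFAULT_DR_PARAMS
    noise = {**DEFAULT_NOISE, **(noise or {})}
    emergence = {**DEFAULT_EMERGENCE, **(emergence or {})}
    if noise["dispersion"] != math.inf and noise["dispersion"] <= 0:
        raise ValueError("dispersion must be positive (or inf)")
    if synergy <= 0:
        raise ValueError("synergy multiplier must be positive")
    rng = np.random.default_rng(seed)
    units = _unit_ids(design)
    rl = noise["reporting_level"]
    cv = 0.0 if noise["deterministic"] else noise["conc_cv"]
    sigma = math.sqrt(math.log(1.0 + cv**2))

    # --- measured concentrations -------------------------------------------------
    conc_rows = []
    for unit, series, level in units:
        compounds = {"IMI": ["imidacloprid"], "CLO": ["clothianidin"],
                     "MIX": ["imidacloprid", "clothianidin"],
                     "CONTROL": ["imidacloprid", "clothianidin"]}[series]
        for compound in compounds:
            nominal = level if series != "CONTROL" else 0.0
            for day in design.sample_days:
                if nominal == 0.0:
                    measured, censored = 0.0, True
                else:
                    jitter = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
                    measured = nominal * jitter
                    censored = measured < rl
                    if censored:
                        measured = 0.0
                conc_rows.append({"unit_id": unit, "time": day, "compound": compound,
                                  "concentration": measured, "reporting_level": rl,
                                  "censored": censored})
    conc_table = pd.DataFrame(conc_rows)

    # --- responses ---------------------------------------------------------------
    def metric_mean(params, series, level):
        if series == "CONTROL":
            return params["IMI"]["d"]
        if series in ("IMI", "CLO"):
            p = params[series]
            return float(loglogistic(np.array([level]), p["b"], p["c"], p["d"], p["e"])[0])
        # MIX: response addition of the two unary curves, per-compound dose
        pa, pb = params["IMI"], params["CLO"]
        fa = float(loglogistic(np.array([level]), pa["b"], pa["c"], pa["d"], pa["e"])[0]) / pa["d"]
        fb = float(loglogistic(np.array([level]), pb["b"], pb["c"], pb["d"], pb["e"])[0]) / pb["d"]
        return pa["d"] * fa * fb / synergy

    resp_rows = []
    for metric, params in dr_params.items():
        if params["IMI"]["d"] != params["CLO"]["d"] or params["IMI"]["c"] != params["CLO"]["c"]:
            raise ValueError(f"{metric}: asymptotes must agree across compounds")
        for unit, series, level in units:
            mean = metric_mean(params, series, level)
            value = float(_draw_counts(rng, [mean], noise["dispersion"],
                                       noise["deterministic"])[0])
            dose = 2 * level if series == "MIX" else level  # nominal sum for MIX
            resp_rows.append({"unit_id": unit, "treatment_series": series,
                              "nominal_dose": dose, "metric": metric, "value": value})
    response_table = pd.DataFrame(resp_rows)

    # --- emergence ---------------------------------------------------------------
    pool = int(emergence["pool_size"])
    p0 = float(emergence["control_fraction"])
    days, weights = _emergence_day_weights(design.duration_days)

    def emergence_fraction(series, level):
        if series == "CONTROL":
            return p0
        if series in ("IMI", "CLO"):
            p = emergence[series]
            return p0 * float(loglogistic(np.array([level]), p["b"], 0.0, 1.0, p["e"])[0])
        pa, pb = emergence["IMI"], emergence["CLO"]
        fa = float(loglogistic(np.array([level]), pa["b"], 0.0, 1.0, pa["e"])[0])
        fb = float(loglogistic(np.array([level]), pb["b"], 0.0, 1.0, pb["e"])[0])
        return p0 * fa * fb / synergy

    emer_rows = []
    for unit, series, level in units:
        frac = min(1.0, emergence_fraction(series, level))
        if noise["deterministic"]:
            total = int(round(pool * frac))
        else:
            total = int(rng.binomial(pool, frac))
        daily = (np.round(total * weights).astype(int) if noise["deterministic"]
                 else rng.multinomial(total, weights))
        for day, count in zip(days, daily):
            if count > 0:
                emer_rows.append({"unit_id": unit, "day": int(day), "count": int(count)})
    emergence_table = pd.DataFrame(emer_rows, columns=["unit_id", "day", "count"])

    # --- truth -------------------------------------------------------------------
    truth_rows = [{"parameter": "synergy", "true_value": synergy},
                  {"parameter": "conc_cv", "true_value": cv},
                  {"parameter": "emergence_pool_size", "true_value": pool},
                  {"parameter": "emergence_control_fraction", "true_value": p0}]
    for metric, params in dr_params.items():
        for compound in ("IMI", "CLO"):
            for name, value in params[compound].items():
                truth_rows.append({"parameter": f"{metric}:{compound}:{name}",
                                   "true_value": float(value)})
    for compound in ("IMI", "CLO"):
        for name, value in emergence[compound].items():
            truth_rows.append({"parameter": f"emergence:{compound}:{name}",
                               "true_value": float(value)})
    truth = pd.DataFrame(truth_rows)
    return conc_table, response_table, emergence_table, truth


# ---------------------------------------------------------------------------
# SSD taxa
# ---------------------------------------------------------------------------

_SSD_PARAM_KEYS = {
    "log-normal": ("meanlog", "sdlog"),
    "log-gumbel": ("locationlog", "scalelog"),
    "gamma": ("shape", "scale"),
    "weibull": ("shape", "scale"),
}

_GROUP_CYCLE = ("mayfly", "caddisfly", "midge/fly", "crustacean")


def gen_ssd_taxa(dist: str, params: dict, n_taxa: int, seed: int = 0,
                 compound: str = "imidacloprid"):
    """Draw a taxon-sensitivity table from a named distribution.

    The truth table records the distribution, its parameters and the true
    5th percentile (the quantity HC5 estimates).
    """
    if dist not in _SSD_PARAM_KEYS:
        raise ValueError(f"unknown distribution {dist!r}")
    if n_taxa < 5:
        raise ValueError("need at least 5 taxa")
    keys = _SSD_PARAM_KEYS[dist]
    missing = [k for k in keys if k not in params]
    if missing:
        raise ValueError(f"{dist} needs parameter(s) {missing}")
    a, b = (float(params[k]) for k in keys)
    if dist in ("gamma", "weibull") and (a <= 0 or b <= 0):
        raise ValueError("shape and scale must be positive")
    if dist in ("log-normal", "log-gumbel") and b <= 0:
        raise ValueError("scale parameter must be positive")

    rng = np.random.default_rng(seed)
    if dist == "log-normal":
        values = rng.lognormal(a, b, n_taxa)
    elif dist == "log-gumbel":
        values = np.exp(rng.gumbel(a, b, n_taxa))
    elif dist == "gamma":
        values = rng.gamma(a, b, n_taxa)
    else:
        values = b * rng.weibull(a, n_taxa)

    table = pd.DataFrame({
        "taxon": [f"taxon_{i:02d}" for i in range(1, n_taxa + 1)],
        "group": [_GROUP_CYCLE[i % len(_GROUP_CYCLE)] for i in range(n_taxa)],
        "compound": compound,
        "endpoint": "EC20",
        "duration_days": 30,
        "value": values,
        "source": "synthetic",
    })
    true_hc5 = float(_quantile(dist, (a, b), 0.05))
    truth = pd.DataFrame([
        {"parameter": "distribution_index", "true_value": float(list(_SSD_PARAM_KEYS).index(dist))},
        {"parameter": f"{dist}:{keys[0]}", "true_value": a},
        {"parameter": f"{dist}:{keys[1]}", "true_value": b},
        {"parameter": "hc5_true", "true_value": true_hc5},
    ])
    return table, truth


# ---------------------------------------------------------------------------
# Field screen
# ---------------------------------------------------------------------------

DEFAULT_FIELD_EXPOSURE = {
    # per-compound site occurrence probability, probability that an
    # occupied site carries the compound in a given week, and
    # lognormal(mu, sigma) of weekly concentrations (ug/L) when present;
    # rl = laboratory reporting level
    "imidacloprid": {"occur_prob": 0.42, "week_prob": 0.75,
                     "mu": math.log(0.008), "sigma": 1.8, "rl": 0.001},
    "clothianidin": {"occur_prob": 0.45, "week_prob": 0.75,
                     "mu": math.log(0.005), "sigma": 1.9, "rl": 0.001},
    "dinotefuran": {"occur_prob": 0.61, "week_prob": 0.80,
                    "mu": math.log(0.002), "sigma": 1.2, "rl": 0.001},
    "thiamethoxam": {"occur_prob": 0.32, "week_prob": 0.75,
                     "mu": math.log(0.002), "sigma": 1.9, "rl": 0.001},
    "acetamiprid": {"occur_prob": 0.05, "week_prob": 0.75,
                    "mu": math.log(0.01), "sigma": 1.0, "rl": 0.001},
    "sulfoxaflor": {"occur_prob": 0.02, "week_prob": 0.75,
                    "mu": math.log(0.008), "sigma": 1.0, "rl": 0.001},
    "thiacloprid": {"occur_prob": 0.0, "week_prob": 0.75,
                    "mu": math.log(0.005), "sigma": 1.0, "rl": 0.001},
}

#: Plausible location/scale for each natural covariate (effects are
#: defined on the standardised scale, so these only set realistic units).
DEFAULT_COVARIATE_SPEC = {
    "latitude": (36.5, 1.2), "longitude": (-121.5, 1.0),
    "site_elevation": (250.0, 180.0), "elevation_range": (600.0, 300.0),
    "basin_size": (120.0, 90.0), "air_temperature": (14.5, 1.5),
    "precipitation_longterm": (600.0, 200.0), "precipitation_summer": (15.0, 8.0),
    "soil_bulk_density": (1.45, 0.12), "soil_erodibility": (0.32, 0.08),
}

DEFAULT_FIELD_EFFECT = {
    # log10(mayfly + 1) scale
    "intercept": 2.9,
    "covariate_betas": {"site_elevation": -0.30, "soil_bulk_density": 0.25,
                        "precipitation_summer": -0.20},
    "beta_imi": -0.08,
    "beta_clo": -0.08,
    "beta_interaction": -0.12,
    "dispersion": 6.0,
}

#: Effect spec emulating the published variance split for mayfly abundance:
#: natural covariates alone describe roughly half the variation and a
#: strong IMI x CLO interaction lifts the explained variance substantially
#: above the covariate-only model.
FIELD_EFFECT_STRONG_INTERACTION = {
    "intercept": 2.9,
    "covariate_betas": {"site_elevation": -0.28, "soil_bulk_density": 0.23,
                        "precipitation_summer": -0.19},
    "beta_imi": -0.05,
    "beta_clo": -0.05,
    "beta_interaction": -0.33,
    "dispersion": 1.8,
}


def _detection_lift(max_conc, compound):
    """Exposure covariate used by the field effect model:
    t(max) - t(0) with the half-lowest-value log10 transform (>= 0, and 0
    for undetected sites)."""
    from .fieldmodels import HALF_LOWEST
    half = HALF_LOWEST.get(compound, 1e-3)
    return np.log10(np.asarray(max_conc, dtype=float) + half) - math.log10(half)


def gen_field(n_sites: int = 85, n_weeks: int = 4,
              exposure: dict | None = None,
              covariate_spec: dict | None = None,
              effect: dict | None = None,
              seed: int = 0):
    """Generate a multi-site field screen with known effect structure.

    Weekly concentrations are lognormal at sites where a compound occurs
    (site-level Bernoulli occurrence) and censored below the reporting
    level.  Total mayfly abundance follows a negative-binomial around a
    mean set, on the log10(X + 1) scale, by standardised covariates plus
    imidacloprid/clothianidin exposure terms and an optional interaction.

    Returns (concentration table, covariates, biology, truth).
    """
    if n_weeks < 4:
        raise ValueError("need at least 4 weekly samples per site (CIBQ window)")
    exposure = exposure if exposure is not None else DEFAULT_FIELD_EXPOSURE
    covariate_spec = {**DEFAULT_COVARIATE_SPEC, **(covariate_spec or {})}
    effect = {**DEFAULT_FIELD_EFFECT, **(effect or {})}
    rng = np.random.default_rng(seed)
    sites = [f"site_{i:03d}" for i in range(1, n_sites + 1)]

    conc_rows = []
    site_max = {c: np.zeros(n_sites) for c in exposure}
    for ci, (compound, spec) in enumerate(exposure.items()):
        occupied = rng.random(n_sites) < spec["occur_prob"]
        week_prob = spec.get("week_prob", 1.0)
        for si, site in enumerate(sites):
            for week in range(1, n_weeks + 1):
                if occupied[si] and rng.random() < week_prob:
                    value = float(rng.lognormal(spec["mu"], spec["sigma"]))
                else:
                    value = 0.0
                censored = value < spec["rl"]
                if censored:
                    value = 0.0
                site_max[compound][si] = max(site_max[compound][si], value)
                conc_rows.append({"unit_id": site, "time": week, "compound": compound,
                                  "concentration": value, "reporting_level": spec["rl"],
                                  "censored": censored})
    conc_table = pd.DataFrame(conc_rows)

    cov = {"site_id": sites}
    z = {}
    for name in COVARIATE_NAMES:
        loc, scale = covariate_spec[name]
        zval = rng.standard_normal(n_sites)
        z[name] = zval
        cov[name] = loc + scale * zval
    covariates = pd.DataFrame(cov)

    eta = np.full(n_sites, float(effect["intercept"]))
    for name, beta in effect["covariate_betas"].items():
        eta += beta * z[name]
    u_imi = _detection_lift(site_max.get("imidacloprid", np.zeros(n_sites)), "imidacloprid")
    u_clo = _detection_lift(site_max.get("clothianidin", np.zeros(n_sites)), "clothianidin")
    eta += effect["beta_imi"] * u_imi + effect["beta_clo"] * u_clo
    eta += effect["beta_interaction"] * u_imi * u_clo
    mean = np.maximum(10.0 ** eta - 1.0, 0.0)
    counts = _draw_counts(rng, mean, effect["dispersion"], False)
    biology = pd.DataFrame({"site_id": sites,
                            "metric": "total_mayfly_abundance",
                            "value": counts})

    truth_rows = [{"parameter": "intercept", "true_value": effect["intercept"]},
                  {"parameter": "beta_imi", "true_value": effect["beta_imi"]},
                  {"parameter": "beta_clo", "true_value": effect["beta_clo"]},
                  {"parameter": "beta_interaction", "true_value": effect["beta_interaction"]},
                  {"parameter": "dispersion", "true_value": effect["dispersion"]}]
    for name, beta in effect["covariate_betas"].items():
        truth_rows.append({"parameter": f"beta_cov:{name}", "true_value": beta})
    for compound, spec in exposure.items():
        truth_rows.append({"parameter": f"occur_prob:{compound}",
                           "true_value": spec["occur_prob"]})
    truth = pd.DataFrame(truth_rows)
    return conc_table, covariates, biology, truth


# ---------------------------------------------------------------------------
# Path-model data
# ---------------------------------------------------------------------------

def gen_path_data(coefficients: dict, n: int, seed: int = 0) -> tuple:
    """Simulate a standardised linear recursive system from a DAG.

    ``coefficients`` maps edges ``(parent, child)`` to standardised path
    coefficients.  Every variable has unit population variance; residual
    variances are solved from the implied covariance, and a configuration
    that would force a negative residual variance raises.

    Returns (data frame with one column per node, truth table).
    """
    g = nx.DiGraph()
    for (a, b), beta in coefficients.items():
        g.add_edge(a, b, beta=float(beta))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("coefficient edges must form a DAG")
    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(g))
    k = len(order)
    idx = {v: i for i, v in enumerate(order)}
    cov = np.zeros((k, k))  # population covariance, built in topological order
    data = {}
    for v in order:
        i = idx[v]
        parents = sorted(g.predecessors(v))
        if not parents:
            cov[i, i] = 1.0
            data[v] = rng.standard_normal(n)
            continue
        pidx = [idx[p] for p in parents]
        beta = np.array([g.edges[p, v]["beta"] for p in parents])
        explained = float(beta @ cov[np.ix_(pidx, pidx)] @ beta)
        resid_var = 1.0 - explained
        if resid_var <= 0:
            raise ValueError(
                f"coefficients into {v!r} imply explained variance "
                f"{explained:.3f} >= 1 (negative residual variance)")
        data[v] = sum(b * data[p] for b, p in zip(beta, parents)) \
            + math.sqrt(resid_var) * rng.standard_normal(n)
        for j in range(k):  # cov with previously defined variables
            cov[i, j] = cov[j, i] = float(beta @ cov[np.ix_(pidx, [j])].ravel())
        cov[i, i] = 1.0
    frame = pd.DataFrame({v: data[v] for v in order})
    truth = pd.DataFrame([{"parameter": f"beta:{a}->{b}", "true_value": beta}
                          for (a, b), beta in sorted(coefficients.items())])
    return frame, truth
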