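"""Field model-comparison workflow for total mayfly abundance.

The workflow mirrors common practice for relating stream invertebrate
metrics to pesticide exposure while controlling for natural gradients:

1. screen sites for multivariate outliers in the natural covariates
   (Mahalanobis D^2 against a chi-square quantile);
2. build a covariate-only model of log10(total mayfly abundance + 1) by
   backward elimination from ten natural covariates, each entering as a
   fixed-knot natural cubic regression spline with per-term degrees of
   freedom (1 = linear, 2 or 3) chosen by AIC;
3. add one of eight pesticide-toxicity predictors (site CIBQs, maximum
   concentrations, and two interaction models) and rank the candidate
   models by AIC.  A pesticide metric "improves" the model when its slope
   is significant (P <= 0.05) and the AIC drops below the covariate-only
   model.

Pesticide metrics are transformed log10(X + half the lowest reported
value); for IMI and CLO concentrations the conventional half-lowest
constants are 0.005 and 0.0004 ug/L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import COVARIATE_NAMES
from .screening import NEONICOTINOIDS, cibq

logger = logging.getLogger("streamtox")

#: Additive constants (half the lowest reported concentration, ug/L) for
#: the log10 transform of maximum-concentration metrics.
HALF_LOWEST = {"imidacloprid": 0.005, "clothianidin": 0.0004}

PESTICIDE_METRICS = (
    "cibq_total",
    "cibq_neonicotinoids",
    "cibq_imi",
    "cibq_clo",
    "max_imi",
    "max_clo",
    "cibq_imi_x_cibq_clo",
    "max_imi_x_max_clo",
)


# ---------------------------------------------------------------------------
# Outlier screen
# ---------------------------------------------------------------------------

def mahalanobis_screen(covariates: pd.DataFrame, quantile: float = 0.999):
    """Mahalanobis D^2 per site against the chi-square(p) quantile.

    ``covariates`` must contain ``site_id`` plus the ten covariate
    columns.  Returns a frame (site_id, d2, outlier).
    """
    cols = [c for c in COVARIATE_NAMES if c in covariates.columns]
    X = covariates[cols].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more sites than covariates")
    S = np.cov(X, rowvar=False)
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariate covariance; remove redundant covariates"
        ) from exc
    centred = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centred, S_inv, centred)
    cutoff = stats.chi2.ppf(quantile, p)
    return pd.DataFrame({
        "site_id": covariates["site_id"].to_numpy(),
        "d2": d2,
        "outlier": d2 > cutoff,
    })


# ---------------------------------------------------------------------------
# Natural cubic regression spline basis (fixed knots at quantiles)
# ---------------------------------------------------------------------------

def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis (ns-style, without intercept).

    With K knots the basis has K - 1 columns: the linear term plus K - 2
    curvature terms that are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)
    if K < 2:
        raise ValueError("need at least two knots")

    def d(k):
        num = (np.maximum(x - knots[k], 0) ** 3
               - np.maximum(x - knots[-1], 0) ** 3)
        return num / (knots[-1] - knots[k])

    cols = [x]
    if K > 2:
        dK1 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK1)
    return np.column_stack(cols)


def spline_knots(x, df: int) -> np.ndarray:
    """Quantile knots for a df-column natural spline (df=1 -> linear)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return np.array([np.min(x), np.max(x)])
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(np.asarray(x, dtype=float), probs)
    if len(np.unique(knots)) < len(knots):
        raise ValueError("tied quantile knots; reduce df")
    return knots


@dataclass
class SmoothTerm:
    name: str
    df: int
    knots: np.ndarray

    def design(self, data: pd.DataFrame) -> np.ndarray:
        x = data[self.name].to_numpy(dtype=float)
        if self.df == 1:
            return x[:, None]
        return natural_spline_basis(x, self.knots)


@dataclass
class TermModel:
    """An OLS model built from named smooth terms plus an intercept."""

    terms: list
    result: object
    slices: dict
    aic: float
    r2: float
    n: int
    extra_columns: dict = field(default_factory=dict)
    data: pd.DataFrame | None = None

    def term_p_value(self, name: str) -> float:
        """F-test p-value for all columns of one term."""
        idx = self.slices[name]
        k = len(self.result.params)
        R = np.zeros((idx.stop - idx.start, k))
        for row, col in enumerate(range(idx.start, idx.stop)):
            R[row, col] = 1.0
        return float(self.result.f_test(R).pvalue)


def _fit_terms(y: np.ndarray, data: pd.DataFrame, terms,
               extra_columns: dict | None = None) -> TermModel:
    blocks = [np.ones((len(y), 1))]
    slices = {}
    start = 1
    for term in terms:
        block = term.design(data)
        blocks.append(block)
        slices[term.name] = slice(start, start + block.shape[1])
        start += block.shape[1]
    for name, col in (extra_columns or {}).items():
        blocks.append(np.asarray(col, dtype=float)[:, None])
        slices[name] = slice(start, start + 1)
        start += 1
    X = np.column_stack(blocks)
    result = sm.OLS(y, X).fit()
    return TermModel(list(terms), result, slices, float(result.aic),
                     float(result.rsquared), len(y),
                     dict(extra_columns or {}))


def choose_smooth(data: pd.DataFrame, y: np.ndarray, name: str,
                  base_terms=(), max_df: int = 3) -> SmoothTerm:
    """Pick the spline df in {1..max_df} minimising AIC given base terms."""
    best = None
    for df in range(1, max_df + 1):
        try:
            term = SmoothTerm(name, df, spline_knots(data[name], df))
            model = _fit_terms(y, data, list(base_terms) + [term])
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or model.aic < best[0]:
            best = (model.aic, term)
    if best is None:
        raise ValueError(f"no spline fit possible for {name!r}")
    return best[1]


# ---------------------------------------------------------------------------
# Covariate-only model
# ---------------------------------------------------------------------------

def prepare_response(biology: pd.DataFrame,
                     metric: str = "total_mayfly_abundance") -> pd.DataFrame:
    """Extract the response metric and apply the log10(X + 1) transform."""
    sub = biology[biology["metric"] == metric]
    if sub.empty:
        raise ValueError(f"biology table has no metric {metric!r}")
    return pd.DataFrame({
        "site_id": sub["site_id"].to_numpy(),
        "log_abundance": np.log10(sub["value"].to_numpy(dtype=float) + 1.0),
    })


def fit_covariate_model(biology: pd.DataFrame, covariates: pd.DataFrame,
                        alpha: float = 0.05, max_df: int = 3) -> TermModel:
    """Backward-eliminated natural-covariate model.

    All ten covariates enter with spline df chosen per term by AIC; the
    least significant term with p > alpha is dropped each iteration until
    every remaining term contributes significantly.  If nothing survives,
    the intercept-only model is returned with a warning.
    """
    resp = prepare_response(biology)
    data = resp.merge(covariates, on="site_id", how="inner").reset_index(drop=True)
    y = data["log_abundance"].to_numpy()

    terms = [choose_smooth(data, y, name, max_df=max_df)
             for name in COVARIATE_NAMES if name in data.columns]
    while terms:
        model = _fit_terms(y, data, terms)
        pvals = {t.name: model.term_p_value(t.name) for t in terms}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            model.data = data
            return model
        terms = [t for t in terms if t.name != worst]
    logger.warning("no covariate survived backward elimination; intercept-only base model")
    model = _fit_terms(y, data, [])
    model.data = data
    return model


# ---------------------------------------------------------------------------
# Pesticide-toxicity metrics and model comparison
# ---------------------------------------------------------------------------

def compute_site_toxicity_metrics(conc_table: pd.DataFrame,
                                  benchmarks: pd.DataFrame,
                                  last_k_weeks: int = 4) -> pd.DataFrame:
    """Per-site pesticide metrics feeding the model comparison.

    Columns: cibq_total, cibq_neonicotinoids, cibq_imi, cibq_clo (site
    maxima of per-sample quotient sums) and max_imi, max_clo (maximum
    detected concentrations over the last k samples).
    """
    out = cibq(conc_table, benchmarks, None, last_k_weeks)[["site_id", "cibq"]]
    out = out.rename(columns={"cibq": "cibq_total"})
    for name, scope in [("cibq_neonicotinoids", NEONICOTINOIDS),
                        ("cibq_imi", ["imidacloprid"]),
                        ("cibq_clo", ["clothianidin"])]:
        part = cibq(conc_table, benchmarks, scope, last_k_weeks)
        out[name] = out["site_id"].map(part.set_index("site_id")["cibq"]).fillna(0.0)
    for name, compound in [("max_imi", "imidacloprid"), ("max_clo", "clothianidin")]:
        sub = conc_table[(conc_table["compound"] == compound)]
        conc = np.where(sub["censored"], 0.0, sub["concentration"])
        site_max = pd.Series(conc, index=sub["unit_id"].to_numpy()).groupby(level=0).max()
        out[name] = out["site_id"].map(site_max).fillna(0.0)
    return out


def transform_metric(values: np.ndarray, half_lowest: float | None = None) -> np.ndarray:
    """log10(X + half the lowest reported value)."""
    x = np.asarray(values, dtype=float)
    if half_lowest is None:
        positive = x[x > 0]
        half_lowest = positive.min() / 2.0 if positive.size else 1e-4
    return np.log10(x + half_lowest)


def compare_toxicity_metrics(base: TermModel, metrics: pd.DataFrame,
                             max_df: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """AIC ranking of the eight pesticide-toxicity predictor models.

    Each single-metric model adds one transformed metric as a smooth term
    to the covariate-only model; the interaction models add both main
    smooths plus the product of the transformed metrics.  Returns a frame
    (model, aic, r2, metric_slope_p, rank, improves) sorted by AIC, with
    the covariate-only model included for reference.
    """
    data = base.data.merge(metrics, on="site_id", how="inner").reset_index(drop=True)
    if len(data) != base.n:
        # refit base on the common sites so AICs are comparable
        base = _fit_terms(data["log_abundance"].to_numpy(), data, base.terms)
        base.data = data
    y = data["log_abundance"].to_numpy()

    transformed = {}
    for col, constant in [("max_imi", HALF_LOWEST["imidacloprid"]),
                          ("max_clo", HALF_LOWEST["clothianidin"]),
                          ("cibq_total", None), ("cibq_neonicotinoids", None),
                          ("cibq_imi", None), ("cibq_clo", None)]:
        transformed[col] = transform_metric(data[col].to_numpy(), constant)
    tdata = data.assign(**{f"t_{k}": v for k, v in transformed.items()})

    rows = [{"model": "covariate_only", "aic": base.aic, "r2": base.r2,
             "metric_slope_p": np.nan, "improves": False}]
    for metric in PESTICIDE_METRICS:
        try:
            if metric.endswith("_x_cibq_clo") or metric.endswith("_x_max_clo"):
                a, b = ("cibq_imi", "cibq_clo") if metric.startswith("cibq") else ("max_imi", "max_clo")
                ta, tb = f"t_{a}", f"t_{b}"
                _constant_guard(tdata[ta]), _constant_guard(tdata[tb])
                term_a = choose_smooth(tdata, y, ta, base.terms, max_df)
                term_b = choose_smooth(tdata, y, tb, base.terms + [term_a], max_df)
                product = tdata[ta].to_numpy() * tdata[tb].to_numpy()
                model = _fit_terms(y, tdata, base.terms + [term_a, term_b],
                                   {"interaction": product})
                slope_p = model.term_p_value("interaction")
            else:
                tcol = f"t_{metric}"
                _constant_guard(tdata[tcol])
                term = choose_smooth(tdata, y, tcol, base.terms, max_df)
                model = _fit_terms(y, tdata, base.terms + [term])
                slope_p = model.term_p_value(tcol)
        except ValueError as exc:
            logger.warning("metric %s skipped: %s", metric, exc)
            continue
        rows.append({"model": metric, "aic": model.aic, "r2": model.r2,
                     "metric_slope_p": slope_p,
                     "improves": bool(slope_p <= alpha and model.aic < base.aic)})
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _constant_guard(series):
    if np.ptp(np.asarray(series, dtype=float)) == 0:
        raise ValueError("metric constant across sites")


def field_workflow(biology: pd.DataFrame, covariates: pd.DataFrame,
                   conc_table: pd.DataFrame, benchmarks: pd.DataFrame,
                   outlier_quantile: float = 0.999, last_k_weeks: int = 4):
    """Outlier screen + covariate model + toxicity-metric comparison.

    Returns (screen frame, base TermModel, comparison frame).
    """
    screen = mahalanobis_screen(covariates, outlier_quantile)
    keep = set(screen.loc[~screen["outlier"], "site_id"])
    cov_clean = covariates[covariates["site_id"].isin(keep)]
    bio_clean = biology[biology["site_id"].isin(keep)]
    base = fit_covariate_model(bio_clean, cov_clean)
    metrics = compute_site_toxicity_metrics(conc_table, benchmarks, last_k_weeks)
    comparison = compare_toxicity_metrics(base, metrics)
    return screen, base, comparison
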