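"""Log-logistic concentration-response models.

The fitted curve is the three- or four-parameter log-logistic

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with ``f(0) = d`` by convention (controls sit on the upper asymptote) and
``b > 0`` giving a response that decreases with dose.  ``e`` is the dose
at which the response is halfway between the asymptotes, so for the
symmetric log-logistic EC50 = e.  LL3 fixes the lower asymptote ``c = 0``.

Model selection between LL3 and LL4 is by AIC (Gaussian log-likelihood
from the residual sum of squares); effect concentrations are relative to
the span (d - c), ``EC_p = e * (p / (100 - p))**(1/b)``, with delta-method
standard errors.  An EC is gated (withheld) when the 95% confidence
interval of the fitted response at dose zero includes zero — under the
decreasing-curve convention that interval is the one around ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats


@dataclass
class LogisticFit:
    """A fitted log-logistic concentration-response model."""

    form: str  # "LL3" or "LL4"
    b: float
    c: float
    d: float
    e: float
    rss: float
    n: int
    loglik: float
    aic: float
    vcov: np.ndarray  # covariance of the free parameters, order (b, [c,] d, log e)
    nse: float
    converged: bool = True
    param_names: tuple = field(default=())
    transform: str = "identity"  # response scale the fit was done on

    @property
    def k_free(self) -> int:
        return 3 if self.form == "LL3" else 4


@dataclass
class ECEstimate:
    p: float
    value: float
    se: float
    ci95: tuple
    gated: bool


def loglogistic(x, b, c, d, e):
    """Evaluate the log-logistic curve; x = 0 maps to the upper asymptote."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, float(d))
    pos = x > 0
    z = b * (np.log(x[pos]) - np.log(e))
    # clip to avoid overflow in exp for extreme starts
    out[pos] = c + (d - c) / (1.0 + np.exp(np.clip(z, -700, 700)))
    return out


def _residuals(theta, x, y, form):
    if form == "LL3":
        b, d, loge = theta
        c = 0.0
    else:
        b, c, d, loge = theta
    return loglogistic(x, b, c, d, np.exp(loge)) - y


def _starts(x, y, form):
    """Deterministic multi-start grid from data heuristics."""
    pos = x[x > 0]
    d0 = float(np.mean(y[x == 0])) if np.any(x == 0) else float(np.max(y))
    if d0 <= 0:
        d0 = max(float(np.max(y)), 1e-6)
    e_grid = np.exp(np.quantile(np.log(pos), [0.2, 0.5, 0.8]))
    b_grid = [0.5, 1.5, 4.0]
    starts = []
    for e0 in e_grid:
        for b0 in b_grid:
            if form == "LL3":
                starts.append(np.array([b0, d0, np.log(e0)]))
            else:
                c0 = max(float(np.min(y)), 0.0)
                starts.append(np.array([b0, c0, d0, np.log(e0)]))
    return starts


def fit_logistic(dose, response, form: str = "LL3",
                 transform: str = "identity") -> LogisticFit:
    """Least-squares fit of the log-logistic model.

    ``dose`` may include zeros (controls); they anchor the upper asymptote.
    The optimiser is deterministic: a fixed grid of starts derived from
    data heuristics, each polished with a trust-region least-squares solve,
    keeping the best RSS.

    ``transform`` selects the response scale of the homoscedastic Gaussian
    error model: ``identity`` (default) fits the raw response, ``log1p``
    fits ln(1 + response) — the standard variance-stabilising choice for
    overdispersed counts, which also makes near-zero observations at high
    doses informative instead of RSS-negligible.  Parameters b and e (and
    hence every EC_p) are on the dose scale either way; c and d live on
    the fitted response scale (use :func:`predict_response` /
    :func:`control_level` for response-scale values).

    Raises
    ------
    ValueError : fewer than 5 distinct dose levels, or non-finite input.
    """
    x = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if transform not in ("identity", "log1p"):
        raise ValueError("transform must be 'identity' or 'log1p'")
    if transform == "log1p":
        if np.any(y < 0):
            raise ValueError("log1p transform needs nonnegative responses")
        y = np.log1p(y)
    if x.shape != y.shape:
        raise ValueError("dose and response must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("dose and response must be finite")
    if np.any(x < 0):
        raise ValueError("doses must be nonnegative")
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct dose levels (including controls)")
    if form not in ("LL3", "LL4"):
        raise ValueError("form must be LL3 or LL4")

    n = len(y)
    p_free = 3 if form == "LL3" else 4
    if form == "LL3":
        lo = np.array([-50.0, 0.0, -50.0])
        hi = np.array([50.0, np.inf, 50.0])
    else:
        lo = np.array([-50.0, 0.0, 0.0, -50.0])
        hi = np.array([50.0, np.inf, np.inf, 50.0])

    best = None
    for theta0 in _starts(x, y, form):
        theta0 = np.clip(theta0, lo + 1e-9, np.minimum(hi, 1e12))
        try:
            res = optimize.least_squares(
                _residuals, theta0, args=(x, y, form), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return LogisticFit(form, np.nan, np.nan, np.nan, np.nan, np.nan, n,
                           np.nan, np.nan, np.full((p_free, p_free), np.nan),
                           np.nan, converged=False, transform=transform)

    theta = best.x
    rss = float(2 * best.cost)
    if form == "LL3":
        b, d, loge = theta
        c = 0.0
        names = ("b", "d", "loge")
    else:
        b, c, d, loge = theta
        names = ("b", "c", "d", "loge")

    # Gaussian log-likelihood with sigma^2 = rss/n (its MLE)
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k = p_free + 1  # free curve parameters + error variance
    aic = 2 * k - 2 * loglik

    J = best.jac
    dof = max(n - p_free, 1)
    s2 = rss / dof
    try:
        JTJ_inv = np.linalg.pinv(J.T @ J)
        vcov = s2 * JTJ_inv
    except np.linalg.LinAlgError:
        vcov = np.full((p_free, p_free), np.nan)

    pred = loglogistic(x, b, c, d, np.exp(loge))
    nse = nash_sutcliffe(y, pred) if np.std(y) > 0 else np.nan

    return LogisticFit(form, float(b), float(c), float(d), float(np.exp(loge)),
                       rss, n, float(loglik), float(aic), vcov, float(nse),
                       converged=True, param_names=names, transform=transform)


def predict_response(fit: LogisticFit, dose) -> np.ndarray:
    """Fitted response on the original (back-transformed) response scale."""
    curve = loglogistic(np.atleast_1d(np.asarray(dose, dtype=float)),
                        fit.b, fit.c, fit.d, fit.e)
    if fit.transform == "log1p":
        return np.expm1(curve)
    return curve


def control_level(fit: LogisticFit) -> float:
    """Fitted response at dose zero on the original response scale."""
    return float(predict_response(fit, 0.0)[0])


def select_model(fit3: LogisticFit, fit4: LogisticFit) -> LogisticFit:
    """Pick the fit with the lower AIC; ties go to LL3 (parsimony)."""
    if fit3.n != fit4.n:
        raise ValueError("fits compare different data (n mismatch)")
    if not fit4.converged:
        return fit3
    if not fit3.converged:
        return fit4
    return fit4 if fit4.aic < fit3.aic else fit3


def effect_concentration(fit: LogisticFit, p: float) -> ECEstimate:
    """Relative effect concentration EC_p with delta-method uncertainty.

    EC_p = e * (p / (100 - p))**(1/b); the estimate is gated (value and SE
    withheld as NaN) when the 95% CI of the fitted response at dose 0
    (the upper asymptote d) includes zero.
    """
    if not (0 < p < 100):
        raise ValueError("p must be in (0, 100)")
    if not fit.converged:
        raise ValueError("cannot derive an EC from a failed fit")

    names = list(fit.param_names)
    i_b, i_d, i_loge = names.index("b"), names.index("d"), names.index("loge")
    se_d = float(np.sqrt(fit.vcov[i_d, i_d])) if np.isfinite(fit.vcov[i_d, i_d]) else np.inf
    gated = bool(fit.d - 1.96 * se_d <= 0.0)
    if gated:
        return ECEstimate(p, np.nan, np.nan, (np.nan, np.nan), True)

    r = p / (100.0 - p)
    ec = fit.e * r ** (1.0 / fit.b)
    # gradient in (b, loge): d(ec)/db = -ec*ln(r)/b^2 ; d(ec)/d(loge) = ec
    g = np.zeros(len(names))
    g[i_b] = -ec * np.log(r) / fit.b**2
    g[i_loge] = ec
    var = float(g @ fit.vcov @ g)
    se = float(np.sqrt(var)) if var > 0 else 0.0
    ci = (ec - 1.96 * se, ec + 1.96 * se)
    return ECEstimate(p, float(ec), se, ci, False)


def nash_sutcliffe(observed, predicted) -> float:
    """Nash-Sutcliffe model efficiency: 1 - SSE / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors (n >= 2)")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; NSE undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def fit_and_select(dose, response) -> LogisticFit:
    """Fit LL3 and LL4 and return the AIC-preferred model."""
    return select_model(fit_logistic(dose, response, "LL3"),
                        fit_logistic(dose, response, "LL4"))


def fit_table(response_table, exposure, metrics=None, ec_levels=(20, 50)):
    """Fit every metric x series combination and return a flat result table.

    Parameters
    ----------
    response_table : tidy frame (unit_id, treatment_series, nominal_dose,
        metric, value).
    exposure : frame (unit_id, compound, twa) used as the dose axis; for
        MIX units the per-compound TWAs are summed.  Controls get dose 0.
    metrics : metrics to fit (default: all present).
    ec_levels : EC percentages to report.

    Returns a :class:`pandas.DataFrame` with one row per metric x series,
    mirroring a summary-table layout: parameters, AIC, NSE and gated ECs.
    """
    import pandas as pd

    twa_by_unit = exposure.groupby("unit_id")["twa"].sum()
    rows = []
    if metrics is None:
        metrics = sorted(response_table["metric"].unique())
    for metric in metrics:
        sub = response_table[response_table["metric"] == metric]
        for series in ("IMI", "CLO", "MIX"):
            part = sub[sub["treatment_series"].isin([series, "CONTROL"])]
            if part.empty or (part["treatment_series"] == series).sum() == 0:
                continue
            dose = np.where(
                part["treatment_series"] == "CONTROL", 0.0,
                part["unit_id"].map(twa_by_unit).to_numpy(dtype=float),
            )
            try:
                fit = fit_and_select(dose, part["value"].to_numpy(dtype=float))
            except ValueError:
                continue
            row = {
                "metric": metric, "series": series, "form": fit.form,
                "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
                "aic": fit.aic, "nse": fit.nse, "converged": fit.converged,
            }
            for p in ec_levels:
                if fit.converged:
                    ec = effect_concentration(fit, p)
                    row[f"ec{p}"] = ec.value
                    row[f"ec{p}_se"] = ec.se
                    row[f"ec{p}_gated"] = ec.gated
                else:
                    row[f"ec{p}"] = np.nan
                    row[f"ec{p}_se"] = np.nan
                    row[f"ec{p}_gated"] = True
            rows.append(row)
    return pd.DataFrame(rows)
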