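"""Model-averaged species sensitivity distributions (SSDs).

A species sensitivity distribution is a statistical distribution fitted to
per-taxon effect concentrations; its 5th percentile (HC5) is the hazard
concentration affecting 5% of species.  Four candidate families are fitted
by maximum likelihood on the concentration scale:

- log-normal
- log-Gumbel (ln X ~ Gumbel; CDF exp(-exp(-(ln x - mu)/sigma)))
- gamma
- Weibull

Candidates are combined by small-sample Akaike weights
(AICc = AIC + 2k(k+1)/(n-k-1), k = 2 per family) and the hazard
concentration is the weight-averaged quantile, HC_p = sum_i w_i Q_i(p).
Uncertainty comes from a parametric bootstrap that resamples from each
fitted family, refits that family, and recombines quantiles with the
original weights held fixed.

The fitters are closed-form (log-normal) or small Newton/fixed-point
solves vectorised across bootstrap replicates, so a 500-replicate
bootstrap costs a few milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger("streamtox")

DISTRIBUTIONS = ("log-normal", "log-gumbel", "gamma", "weibull")

_EULER = float(np.euler_gamma)


# ---------------------------------------------------------------------------
# Vectorised ML fitters.  Each takes x of shape (..., n) and returns
# (params, loglik) where every entry has shape x.shape[:-1].
# ---------------------------------------------------------------------------

def _fit_lognormal(x):
    y = np.log(x)
    mu = y.mean(axis=-1)
    sigma = y.std(axis=-1)  # MLE (ddof=0)
    n = x.shape[-1]
    with np.errstate(divide="ignore"):
        loglik = (-y.sum(axis=-1) - n * np.log(sigma)
                  - 0.5 * n * np.log(2 * np.pi) - 0.5 * n)
    loglik = np.where(sigma > 0, loglik, -np.inf)
    return (mu, sigma), loglik


def _fit_loggumbel(x, n_iter=80):
    """Gumbel (max) MLE on ln x by the standard fixed-point iteration."""
    y = np.log(x)
    n = y.shape[-1]
    ybar = y.mean(axis=-1)
    sigma = y.std(axis=-1) * np.sqrt(6) / np.pi
    sigma = np.maximum(sigma, 1e-10)
    for _ in range(n_iter):
        # stabilised weights e^{-y/sigma}
        z = -y / sigma[..., None]
        z -= z.max(axis=-1, keepdims=True)
        w = np.exp(z)
        sigma_new = ybar - (y * w).sum(axis=-1) / w.sum(axis=-1)
        sigma = np.maximum(sigma_new, 1e-10)
    z = -y / sigma[..., None]
    zmax = z.max(axis=-1, keepdims=True)
    log_mean_w = np.log(np.exp(z - zmax).mean(axis=-1)) + zmax[..., 0]
    mu = -sigma * log_mean_w
    u = (y - mu[..., None]) / sigma[..., None]
    loglik = (-n * np.log(sigma) - u.sum(axis=-1)
              - np.exp(-u).sum(axis=-1) - y.sum(axis=-1))
    return (mu, sigma), loglik


def _fit_gamma(x, n_iter=40):
    n = x.shape[-1]
    xbar = x.mean(axis=-1)
    logx_bar = np.log(x).mean(axis=-1)
    s = np.log(xbar) - logx_bar
    s = np.maximum(s, 1e-12)
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(n_iter):
        h = np.log(k) - special.digamma(k) - s
        hp = 1.0 / k - special.polygamma(1, k)
        k = np.maximum(k - h / hp, 1e-8)
    theta = xbar / k
    loglik = ((k - 1.0) * n * logx_bar - n * xbar / theta
              - n * k * np.log(theta) - n * special.gammaln(k))
    return (k, theta), loglik


def _fit_weibull(x, n_iter=60):
    n = x.shape[-1]
    logx = np.log(x)
    logx_bar = logx.mean(axis=-1)
    sd = logx.std(axis=-1)
    c = np.where(sd > 0, (np.pi / np.sqrt(6)) / np.maximum(sd, 1e-10), 10.0)
    c = np.clip(c, 1e-3, 1e3)
    for _ in range(n_iter):
        # work with x scaled by its max for overflow safety
        xc = np.exp(c[..., None] * (logx - logx.max(axis=-1, keepdims=True)))
        s0 = xc.sum(axis=-1)
        s1 = (xc * logx).sum(axis=-1)
        s2 = (xc * logx**2).sum(axis=-1)
        g = s1 / s0 - 1.0 / c - logx_bar
        gp = (s2 * s0 - s1**2) / s0**2 + 1.0 / c**2
        c = np.clip(c - g / gp, 1e-3, 1e3)
    lam = (np.exp(c[..., None] * (logx - logx.max(axis=-1, keepdims=True))).mean(axis=-1)) ** (1.0 / c) \
        * np.exp(logx.max(axis=-1))
    z = (x / lam[..., None]) ** np.where(c[..., None] > 0, c[..., None], np.nan)
    loglik = (n * np.log(c) - n * c * np.log(lam)
              + (c - 1.0) * n * logx_bar - z.sum(axis=-1))
    return (c, lam), loglik


_FITTERS = {
    "log-normal": _fit_lognormal,
    "log-gumbel": _fit_loggumbel,
    "gamma": _fit_gamma,
    "weibull": _fit_weibull,
}


def _quantile(name, params, p):
    """Quantile of one family; params entries may be arrays."""
    if name == "log-normal":
        mu, sigma = params
        return np.exp(mu + sigma * stats.norm.ppf(p))
    if name == "log-gumbel":
        mu, sigma = params
        return np.exp(mu - sigma * np.log(-np.log(p)))
    if name == "gamma":
        k, theta = params
        return stats.gamma.ppf(p, k, scale=theta)
    if name == "weibull":
        c, lam = params
        return lam * (-np.log1p(-p)) ** (1.0 / c)
    raise ValueError(f"unknown distribution {name!r}")


def _sample(name, params, size, rng):
    if name == "log-normal":
        mu, sigma = params
        return rng.lognormal(mu, sigma, size=size)
    if name == "log-gumbel":
        mu, sigma = params
        return np.exp(rng.gumbel(mu, sigma, size=size))
    if name == "gamma":
        k, theta = params
        return rng.gamma(k, theta, size=size)
    if name == "weibull":
        c, lam = params
        return lam * rng.weibull(c, size=size)
    raise ValueError(f"unknown distribution {name!r}")


# ---------------------------------------------------------------------------


@dataclass
class DistFit:
    name: str
    params: tuple
    loglik: float
    aicc: float
    weight: float


@dataclass
class SSDFit:
    dists: dict
    n: int

    def weights(self):
        return {name: f.weight for name, f in self.dists.items()}


@dataclass
class HCEstimate:
    p: float
    value: float
    se: float
    ci95: tuple
    n_boot: int
    seed: int


def assemble_ssd_dataset(records: pd.DataFrame, min_duration_days: int = 10) -> pd.DataFrame:
    """Filter a taxon-sensitivity table to a chronic, one-row-per-taxon set.

    Drops records shorter than ``min_duration_days`` or with group
    ``other`` (non-insect, non-crustacean), then keeps the minimum effect
    value per (taxon, compound).  Idempotent.
    """
    if records.empty:
        raise ValueError("empty taxon-sensitivity table")
    keep = (records["duration_days"] >= min_duration_days) & (records["group"] != "other")
    filtered = records[keep]
    if filtered.empty:
        raise ValueError("no records survive the chronic/group filter")
    idx = filtered.groupby(["taxon", "compound"])["value"].idxmin()
    return filtered.loc[sorted(idx)].reset_index(drop=True)


def fit_ssd(values, distributions=DISTRIBUTIONS) -> SSDFit:
    """Fit the candidate families by ML and compute AICc Akaike weights.

    Families whose fit fails (non-finite likelihood) are dropped with a
    warning and the weights renormalised.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ValueError("need a vector of >= 5 effect concentrations")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("effect concentrations must be positive and finite")
    n = len(x)
    k = 2
    fits = {}
    for name in distributions:
        params, loglik = _FITTERS[name](x[None, :])
        params = tuple(float(p[0]) for p in params)
        loglik = float(loglik[0])
        if not np.isfinite(loglik):
            logger.warning("SSD fit failed for %s; dropped", name)
            continue
        aic = 2 * k - 2 * loglik
        if n - k - 1 > 0:
            aicc = aic + 2 * k * (k + 1) / (n - k - 1)
        else:  # small-sample correction undefined; fall back to AIC
            aicc = aic
        fits[name] = DistFit(name, params, loglik, aicc, 0.0)
    if not fits:
        raise ValueError("all SSD candidate fits failed")
    best = min(f.aicc for f in fits.values())
    raw = {name: np.exp(-(f.aicc - best) / 2.0) for name, f in fits.items()}
    total = sum(raw.values())
    for name, f in fits.items():
        f.weight = raw[name] / total
    return SSDFit(fits, n)


def hc(fit: SSDFit, p: float = 0.05) -> float:
    """Model-averaged hazard concentration: the weighted mean of the
    candidate families' p-quantiles."""
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    return float(sum(f.weight * _quantile(name, f.params, p)
                     for name, f in fit.dists.items()))


def bootstrap_hc(values, p: float = 0.05, n_boot: int = 500, seed: int = 0,
                 max_failure_rate: float = 0.2) -> HCEstimate:
    """Parametric-bootstrap HC estimate with SE and percentile 95% CI.

    Per replicate, one dataset of ``n`` values is drawn from the fitted
    model-averaged mixture (each observation picks a family with
    probability equal to its Akaike weight), every candidate family is
    refitted to that same dataset, and the weighted HC is recomputed with
    the original weights held fixed.  Refitting all families to a shared
    dataset preserves the strong positive correlation between their
    quantile estimates; resampling families independently would shrink
    the spread of the weighted HC and give over-narrow intervals.
    Replicates where any weighted family's refit fails are dropped; more
    than ``max_failure_rate`` failures is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    x = np.asarray(values, dtype=float)
    fit = fit_ssd(x)
    point = hc(fit, p)
    rng = np.random.default_rng(seed)
    n = fit.n

    names = [name for name, f in fit.dists.items() if f.weight > 0]
    weights = np.array([fit.dists[name].weight for name in names])
    # shared mixture draw: component label per observation, then values
    labels = rng.choice(len(names), size=(n_boot, n), p=weights / weights.sum())
    samples = np.empty((n_boot, n))
    for i, name in enumerate(names):
        mask = labels == i
        samples[mask] = _sample(name, fit.dists[name].params, int(mask.sum()), rng)

    q_total = np.zeros(n_boot)
    ok = np.ones(n_boot, dtype=bool)
    for name in names:
        f = fit.dists[name]
        params_b, loglik_b = _FITTERS[name](samples)
        q = _quantile(name, params_b, p)
        good = np.isfinite(q) & np.isfinite(loglik_b)
        ok &= good
        q_total += np.where(good, f.weight * q, 0.0)

    fail_rate = 1.0 - ok.mean()
    if fail_rate > max_failure_rate:
        raise RuntimeError(f"bootstrap failure rate {fail_rate:.1%} exceeds "
                           f"{max_failure_rate:.0%}")
    reps = q_total[ok]
    se = float(reps.std(ddof=1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return HCEstimate(p, point, se, (float(lo), float(hi)), n_boot, seed)


def ssd_report(fit: SSDFit, estimate: HCEstimate) -> pd.DataFrame:
    """Flat per-distribution report plus the model-averaged HC row."""
    rows = []
    for name, f in fit.dists.items():
        rows.append({"distribution": name, "loglik": f.loglik, "aicc": f.aicc,
                     "weight": f.weight,
                     "hc": float(_quantile(name, f.params, estimate.p))})
    rows.append({"distribution": "model-averaged", "loglik": np.nan,
                 "aicc": np.nan, "weight": 1.0, "hc": estimate.value})
    return pd.DataFrame(rows)


def ecdf_plot_data(values) -> pd.DataFrame:
    """Empirical CDF points (Hazen plotting position) for SSD plots."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    return pd.DataFrame({"value": x, "fraction_affected": (np.arange(1, n + 1) - 0.5) / n})
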