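"""Field occurrence summaries and benchmark-quotient toxicity screening.

The chronic invertebrate benchmark quotient (CIBQ) for a water sample is
the sum over detected in-scope compounds of concentration / chronic
invertebrate benchmark; a site's CIBQ is the maximum over its last k
(default 4) weekly samples.  Censored (below reporting level)
concentrations contribute zero, matching the censoring convention used
for detection frequencies.  An upper-bound variant substituting the
reporting level for censored values is available but off by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The seven neonicotinoid parent compounds screened in the field study.
NEONICOTINOIDS = (
    "acetamiprid",
    "clothianidin",
    "dinotefuran",
    "imidacloprid",
    "sulfoxaflor",
    "thiacloprid",
    "thiamethoxam",
)

#: EPA chronic aquatic-life benchmarks for invertebrates (ug/L).  Open
#: bounds (">") are stored at face value with the flag set.
EPA_CHRONIC_INVERTEBRATE_BENCHMARKS = pd.DataFrame({
    "compound": list(NEONICOTINOIDS),
    "benchmark": [2.1, 0.05, 95300.0, 0.01, 50500.0, 0.97, 0.74],
    "open_bound": [False, False, True, False, True, False, False],
})


def _last_k(table: pd.DataFrame, last_k_weeks: int) -> pd.DataFrame:
    """Restrict each site to its last k sampling times (all compounds)."""
    frames = []
    for site, grp in table.groupby("unit_id", sort=True):
        times = np.sort(grp["time"].unique())
        if len(times) < last_k_weeks:
            raise ValueError(
                f"site {site!r} has {len(times)} sampling times; need {last_k_weeks}"
            )
        frames.append(grp[grp["time"].isin(times[-last_k_weeks:])])
    return pd.concat(frames, ignore_index=True)


def detection_summary(table: pd.DataFrame, last_k_weeks: int = 4,
                      neonicotinoids=NEONICOTINOIDS) -> pd.DataFrame:
    """Per-compound occurrence summary plus aggregate rows.

    Restricts to the last ``last_k_weeks`` samples per site, then reports
    detection frequency per sample and per site, and the 50th/75th
    percentile and maximum concentration (censored values set to 0).
    Aggregate rows sum per-sample concentrations over all compounds
    ("sum_all_pesticides") and over the neonicotinoids
    ("sum_all_neonicotinoids").
    """
    sub = _last_k(table, last_k_weeks)
    detected = ~sub["censored"]
    conc = np.where(detected, sub["concentration"], 0.0)
    sub = sub.assign(_detected=detected, _conc=conc)

    n_sites = sub["unit_id"].nunique()
    rows = []

    def _row(name, per_sample):
        # per_sample: frame (unit_id, detected, conc) with one row per sample
        return {
            "compound": name,
            "detect_freq_sample": float(per_sample["detected"].mean()),
            "detect_freq_site": float(
                per_sample.groupby("unit_id")["detected"].any().mean()
            ),
            "p50": float(per_sample["conc"].quantile(0.5)),
            "p75": float(per_sample["conc"].quantile(0.75)),
            "max": float(per_sample["conc"].max()),
        }

    for name, mask in [
        ("sum_all_pesticides", np.ones(len(sub), dtype=bool)),
        ("sum_all_neonicotinoids", sub["compound"].isin(neonicotinoids).to_numpy()),
    ]:
        agg = (sub[mask].groupby(["unit_id", "time"])
               .agg(detected=("_detected", "any"), conc=("_conc", "sum"))
               .reset_index())
        rows.append(_row(name, agg))

    for compound, grp in sub.groupby("compound", sort=True):
        per_sample = grp.rename(columns={"_detected": "detected", "_conc": "conc"})
        rows.append(_row(compound, per_sample))
    return pd.DataFrame(rows)


def cibq(table: pd.DataFrame, benchmarks: pd.DataFrame,
         scope=None, last_k_weeks: int = 4,
         censored_at_rl: bool = False) -> pd.DataFrame:
    """Site-level chronic invertebrate benchmark quotients.

    Parameters
    ----------
    table : tidy concentration table (unit_id = site).
    benchmarks : frame (compound, benchmark); every detected in-scope
        compound must be covered.
    scope : compound subset; None = all compounds in the table.
    censored_at_rl : if True, censored rows contribute reporting_level /
        benchmark (upper-bound variant) instead of zero.

    Returns a frame (site_id, cibq, n_samples_used) where cibq is the
    maximum per-sample quotient sum over the site's last k samples.
    """
    sub = _last_k(table, last_k_weeks)
    if scope is not None:
        sub = sub[sub["compound"].isin(set(scope))]
    bench = benchmarks.set_index("compound")["benchmark"]
    detected = sub[~sub["censored"]]
    missing = sorted(set(detected["compound"]) - set(bench.index))
    if missing:
        raise ValueError(f"detected compound(s) without a benchmark: {missing}")

    conc = np.where(sub["censored"],
                    sub["reporting_level"] if censored_at_rl else 0.0,
                    sub["concentration"])
    quotient = conc / sub["compound"].map(bench).to_numpy(dtype=float)
    per_sample = (sub.assign(_q=quotient)
                  .groupby(["unit_id", "time"])["_q"].sum())
    out = (per_sample.groupby("unit_id")
           .agg(cibq="max", n_samples_used="size")
           .reset_index()
           .rename(columns={"unit_id": "site_id"}))
    out["n_samples_used"] = out["n_samples_used"].astype(int)
    return out


def exceedance_and_means(cibq_table: pd.DataFrame) -> dict:
    """Summary statistics over site CIBQs: mean, median, exceedance rate."""
    if cibq_table.empty:
        raise ValueError("need at least one site")
    values = cibq_table["cibq"].to_numpy(dtype=float)
    return {
        "n_sites": int(len(values)),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "exceedance_freq": float((values > 1.0).mean()),
    }


def substitute_benchmarks(benchmarks: pd.DataFrame,
                          replacements: dict[str, float]) -> pd.DataFrame:
    """Replace selected compounds' benchmarks (e.g. with mesocosm HC5s)."""
    out = benchmarks.copy()
    for compound, value in replacements.items():
        if value <= 0:
            raise ValueError(f"replacement benchmark for {compound!r} must be positive")
        mask = out["compound"] == compound
        out.loc[mask, "benchmark"] = value
        out.loc[mask, "open_bound"] = False
    return out
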