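# streamtox

Statistical toolkit for assessing the ecological effects of neonicotinoid
insecticides (imidacloprid, IMI; clothianidin, CLO) on stream invertebrate
communities, linking a dosed stream-mesocosm experiment to a multi-site
field screen.  It is written for ecotoxicologists and biostatisticians who
need the full analysis chain — concentration–response fitting, mixture
synergy assessment, species sensitivity distributions, benchmark-quotient
screening, path analysis, and field model comparison — as tested, reusable
Python, exercised end-to-end on synthetic data with known ground truth.

## What it computes

**Concentration–response** (`streamtox.doseresponse`).  Three- and
four-parameter log-logistic models

    f(x) = c + (d − c) / (1 + exp(b (ln x − ln e)))

are fitted by deterministic multi-start least squares to time-weighted
average (TWA) exposures, selected by AIC, and summarised by relative
effect concentrations EC_p = e (p/(100−p))^(1/b) with delta-method
standard errors.  ECs are withheld ("gated") when the 95% CI of the fitted
response at dose zero includes zero; fit quality is reported as the
Nash–Sutcliffe efficiency.

**Mixture synergy** (`streamtox.mixture`).  Response addition (independent
action) predicts a binary-mixture response as the product of the unary
fractional responses; the model deviation ratio MDR = predicted/observed
is computed per mixture replicate, with MDR > 2 classed synergistic,
MDR < 0.5 antagonistic, and predictions below a small floor flagged as
zero-limit indeterminate.

**Species sensitivity distributions** (`streamtox.ssd`).  Log-normal,
log-Gumbel, gamma and Weibull candidates are fitted by maximum likelihood
to per-taxon effect concentrations, combined by AICc Akaike weights, and
the hazard concentration HC_p = Σᵢ wᵢ Qᵢ(p) (default p = 0.05, the HC5) is
reported with a parametric-bootstrap SE and percentile 95% CI.

**Field screening** (`streamtox.screening`).  Detection frequencies per
sample and per site, concentration percentiles with below-reporting-level
censoring, and the chronic invertebrate benchmark quotient: per sample,
CIBQ = Σ concentration/benchmark over detected compounds; per site, the
maximum over the last four weekly samples.  Exceedance rates (CIBQ > 1)
and HC5-substituted variants are included.

**Path models** (`streamtox.pathmodels`).  Piecewise path analysis of
trophic-cascade and predator–prey hypotheses: OLS component regressions
with standardised coefficients, indirect effects as coefficient products,
and global fit by d-separation (Fisher's C = −2 Σ ln pᵢ ~ χ²(2k)).

**Field model comparison** (`streamtox.fieldmodels`).  Mahalanobis-D²
outlier screening of ten natural site covariates, a backward-eliminated
covariate model of log10(total mayfly abundance + 1) built from natural
cubic regression splines (per-term df ∈ {1,2,3} chosen by AIC), and AIC
ranking of eight pesticide-toxicity predictors, including IMI × CLO
interaction models.

**Synthetic data** (`streamtox.synth`) generates every input — mesocosm
exposure/response/emergence tables, taxon-sensitivity sets, 85-site
field screens, path-model data — from known parameters, writing a truth
sidecar alongside each dataset.

## Worked example

```python
import numpy as np
from streamtox import synth, mesocosm, doseresponse, mixture, ssd

# a dosed mesocosm experiment: 3 series x 5 duplicated levels + 3 controls
conc, resp, emer, truth = synth.gen_mesocosm(seed=2)
exposure = mesocosm.exposure_summary(conc)

# unary EC50s for total mayfly abundance
fits = doseresponse.fit_table(resp, exposure, metrics=["total_mayfly_abundance"])
print(fits[["series", "form", "e", "ec50", "ec50_se", "nse"]].round(3))

# response-addition analysis of the mixture series
_, table, summary = mixture.mixture_endpoint_analysis(resp, exposure)
print(summary)

# model-averaged HC5 from a 16-taxon sensitivity set
taxa, taxa_truth = synth.gen_ssd_taxa("log-normal",
                                      {"meanlog": -2.0, "sdlog": 1.2}, 16, seed=2)
est = ssd.bootstrap_hc(taxa["value"].to_numpy(), n_boot=500, seed=2)
print(f"HC5 = {est.value:.4f} ug/L, 95% CI ({est.ci95[0]:.4f}, {est.ci95[1]:.4f})")
```

Output:

```
  series form      e   ec50  ec50_se    nse
0    IMI  LL3  0.994  0.994    0.345  0.769
1    CLO  LL3  1.485  1.485    1.048  0.632
2    MIX  LL3  1.349  1.349    1.946  0.685
{'n': 10, 'n_indeterminate': 2, 'n_synergistic': 1, 'mdr_min': 0.8307868121016476, 'mdr_max': 2.076721991073339}
HC5 = 0.0156 ug/L, 95% CI (0.0047, 0.0489)
```

The unary EC50 estimates recover the generating values (1.05 and
1.35 µg/L for IMI and CLO; the MIX row is on the summed-dose axis).  The
mixture replicates sit near MDR = 1 because this dataset was generated
under exact response addition — the two indeterminate replicates are the
top treatment, where the additive prediction falls below the
0.5-individual zero-limit floor, and one replicate lands just over the
MDR > 2 line by sampling noise.  The HC5 interval covers this taxa set's
true 5th percentile (0.0188 µg/L, recorded in `taxa_truth`).

A command-line interface mirrors the library:

```sh
streamtox simulate --seed 1 --out data/
streamtox fit-dr -c config.yaml
streamtox ssd -c config.yaml
streamtox screen -c config.yaml
streamtox field-models -c config.yaml
```

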