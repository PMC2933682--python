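# geostruct

Does the administrative structure of a country's population confound
comparisons of geographic health inequality?

Geographic health inequality is routinely summarised by the variation in
standardised mortality ratios (SMRs) between the administrative regions of
a country. But countries carve themselves into regions of very different
number and size, and aggregation into arbitrary areal units distorts
variance estimates (the *modifiable areal unit problem*). `geostruct`
implements, end to end, the analysis that asks whether the within-country
between-region variation in mortality depends on two descriptors of
administrative structure: the **Gini coefficient** of region population
sizes, G<sub>j</sub>, and the **mean region size** in millions,
R<sub>j</sub>.

## The model

Observed deaths O<sub>ij</sub> in region *i* of country *j* follow a
Poisson multilevel model with the expected deaths E<sub>ij</sub> (from
indirect standardisation against the pooled all-country reference) as
offset:

    O_ij ~ Poisson(mu_ij)
    log(mu_ij) = log(E_ij) + beta0 + nu_j + u_ij
    nu_j ~ N(0, sigma_v^2)          (country level)
    u_ij ~ N(0, sigma_u(j)^2)       (region level, country-specific SD)

The quantity of interest is sigma_u(j), the within-country SD of log
relative mortality — the variance measure of geographic inequality. It is
itself modelled by one of eleven structures, e.g.

    log(sigma_u(j)) ~ N(beta1 + beta2 * G_j, sigma_r^2)        (log-Gini)
    sigma_u(j)      ~ N(beta1 + beta3 * R_j, 0.0001), > 0.0001 (linear-size)

with a free-U(0,1)-per-country baseline as null model. Fitting is by
adaptive Metropolis-within-Gibbs MCMC (two chains, Gelman–Rubin
diagnostics) and models are compared by DIC. A positive beta2 means that
countries whose regions are more unequally populated show greater apparent
inequality in mortality purely through their administrative geometry.

Because the underlying 1990–91 European regional dataset was never
published, the package ships a synthetic-cohort generator that reproduces
its structure (20 countries, 8–79 regions each, 14 age bands, males 0–64,
region-size Gini 0.1–0.5) with recorded ground truth, so every stage is
testable and parameter recovery is verifiable.

## Worked example

```python
from geostruct import (SimulationConfig, generate_dataset, region_summaries,
                       country_structure_table, ModelData, MCMCConfig,
                       fit_all_variants)

config = SimulationConfig(n_countries=20, regions_per_country=20,
                          target_gini=(0.1, 0.5), mean_region_pop=4e5,
                          variance_structure_true=3,   # log-Gini generating law
                          beta1_true=-2.7, beta2_true=1.3,
                          sigma_v_true=0.36, seed=42)
table, truth = generate_dataset(config)
data = ModelData.from_frames(region_summaries(table),
                             country_structure_table(table))
comparison, fits = fit_all_variants(data, [1, 3], MCMCConfig.desk(seed=1))
print(comparison[["variant", "description", "beta2", "dic", "delta_dic"]])
```

prints (desk-scale MCMC, a few seconds):

```
 variant         description  beta2      dic  delta_dic
       1              Random    NaN 4372.180      0.000
       3 Log (deterministic)  0.864 4366.814     -5.365
```

The log-Gini structure (variant 3) lowers the DIC by ~5 points relative to
the free-SD baseline, and its beta2 95% credible interval (0.29, 1.50)
covers the generating value 1.3: inequality in region population size is
recovered as a driver of apparent mortality inequality. The
interpretation helpers translate such estimates to readable scales — e.g.
`pct_change_log_model(1.28, 0.1)` → 13.7% more between-region variation
per 0.1 Gini, and `excess_between_centiles(0.07)` → a region on the 95th
centile carrying a 26% higher SMR than one on the 5th.

Narrative scripts in `examples/` walk through each capability; the
`geostruct` CLI (`simulate`, `standardize`, `structure`, `fit`, `report`,
`pipeline`) exposes the same stages from the shell, writing every artifact
as delimited text with a manifest.

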