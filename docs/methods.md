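# Methods

## Indirect standardisation

The pipeline's single input is a tidy count table
`(country_id, region_id, age_band, population, deaths)` with 14 age bands
indexed 0–13, mapping to the half-open intervals 0, 1–4, 5–9, …, 60–64
(males under 65). Observed deaths per region are the band sums
O<sub>ij</sub>; expected deaths are
E<sub>ij</sub> = Σ<sub>bands</sub> population × reference rate, with the
reference rates computed from the pooled table itself (all regions of all
countries). Using the internal pooled reference makes ΣE = ΣO an exact
identity and the overall SMR exactly 1, which the tests assert to 1e-9
relative. A region whose E is zero has no defined log offset and is
dropped with a logged warning rather than imputed. Missing age-band rows
are an error, never silently zero. Externally supplied reference rates
are accepted for experimentation but flagged in the log.

## Structure descriptors

Lorenz curves rank regions by population ascending (the standard
convention; ties broken by input order, which provably cannot change the
result) and cumulate population share. The Gini coefficient uses the
trapezoid (Brown) closed form

G = |1 − Σ<sub>k</sub> (X<sub>k</sub> − X<sub>k−1</sub>)(Y<sub>k</sub> + Y<sub>k−1</sub>)|,  (X₀, Y₀) = (0, 0),

which equals twice the area between the Lorenz polyline and the equality
diagonal; a property test checks agreement with dense numerical area
integration to 1e-10 over random instances. G is computed from region
*total* populations (all ages summed). Mean region size is reported in
millions of inhabitants, the unit in which it enters the models. The
association between the two descriptors uses a weighted Pearson
correlation (weights = region counts) with a two-sided t-test on n − 2
degrees of freedom, n being the number of countries — the weights rescale
moments, not the sample size.

## The hierarchical model and its eleven variance structures

Region deaths are Poisson with log link and offset log E; country effects
nu_j and region effects u_ij are zero-mean normal, with the region-level
SD sigma_u(j) varying by country. The eleven structures for sigma_u(j)
(free baseline; log or linear in G, R or both; residual SD sigma_r either
fitted or fixed) are tabulated in `geostruct.model`. Two readings of the
"0.0001" in the deterministic rows are possible under BUGS conventions
(variance or precision); it is implemented as a **variance** (SD 0.01),
the only reading consistent with those rows being nearly deterministic
regressions. Priors are flat on beta0–beta3 and U(0, 1) on sigma_v, on
sigma_r where fitted, and on each free sigma_u(j) in the baseline; the
published prior list is garbled in the source text and this is the
coherent reconstruction. Linear-link sigma_u(j) is truncated below at
1e-4, with the truncation properly renormalised so that coefficient
updates see it.

For log-link structures the sampled variance coordinate is
log sigma_u(j) and the structure density is a plain normal in that
coordinate (the BUGS parameterisation); sampler proposals live in the same
coordinate, so no Jacobian terms arise anywhere.

## MCMC

The sampler is adaptive random-walk Metropolis within Gibbs with
vectorised blocks exploiting conditional independence: all u_ij update
simultaneously (regions are independent given the rest), as do all nu_j
and all per-country variance coordinates. Two deterministic-direction
"translation" moves — shifting beta0 against all nu_j, and each nu_j
against its country's u_ij — walk along the intercept ridges that
otherwise make beta0 mix extremely slowly (the same slow mode the original
analysis reported needing long runs for). The variance-regression
coefficients are drawn by exact Gibbs from their Gaussian conditional
(flat priors, linear regression of the variance coordinate on the
covariates); for linear links this Gaussian is used as an independence
proposal with a Metropolis correction for the truncation factor.
Additional joint moves shift all variance coordinates together with the
matching coefficient (level and tilt), leaving the structure residuals
invariant — without these, the near-deterministic structures (residual SD
0.01) would pin the chain. Proposal scales adapt by Robbins–Monro toward
0.44 acceptance during burn-in only; the post-burn-in kernel is fixed,
keeping the monitored draws exactly Markov.

Defaults follow the full protocol (two chains, 50,000 burn-in, 100,000
monitored iterations); `MCMCConfig.desk()` (2,000 / 5,000) is the scale
used throughout the test suite and examples, where a 20-country ×
20-region fit takes a few seconds. Chains start from independent
overdispersed points. Convergence is flagged (never raised) when any
monitored scalar's Gelman–Rubin statistic reaches 1.05.

The Gelman–Rubin statistic is computed as sqrt(1 + B/(nW)) from
between-chain variance B and mean within-chain variance W. This omits the
(n−1)/n degrees-of-freedom correction of some textbook forms so that
identical chains give exactly 1; the two forms differ by O(1/n) and agree
with arviz's rank-normalised R-hat to well under 0.01 on mixed chains
(asserted in tests).

Point estimates are posterior medians with equal-tailed 95% credible
intervals; the median is chosen for robustness, as the summary functional
used in the published tables is not stated. DIC uses the conditional
focus: deviance D = −2 log Poisson likelihood, pD = D̄ − D(θ̄) with θ̄
the posterior means of (beta0, nu, u), and DIC = D̄ + pD.

## Synthetic cohort generator

The generator emulates the unavailable 1990–91 dataset's structure; its
defaults are the study conditions, not tuning knobs:

* **Region-size law**: log-normal, chosen because its Gini has the closed
  form G = 2Φ(σ/√2) − 1, so the log-scale SD can be calibrated to any
  target Gini; draws are rescaled to the requested mean (Gini-invariant)
  and redrawn (≤ 200 attempts) until the sample Brown Gini is within
  tolerance (default 0.02) of target, since finite samples drift from the
  population value.
* **Scale**: 20 countries, 8–40 regions per country, Gini targets spread
  linearly over 0.1–0.5 and mean sizes geometrically over 0.12–2.0
  million, matching the published order of magnitude. Parameter-recovery
  experiments use 20 × 20 with ~4×10⁵ people per region.
* **Age schedule and reference rates**: a packaged synthetic schedule
  (`data/age_schedule.tsv`) with plausible European male 0–64 proportions
  and all-cause rates (monotone increasing after childhood, crude rate
  ≈ 3.7 per 1,000) — constructed values, since the real rates are not
  printed anywhere. Band populations are real-valued (person-year
  semantics); deaths are always integer.
* **Effects**: nu_j and u_ij are drawn exactly as the model assumes, with
  sigma_u(j) set from the configured variance structure evaluated at the
  *realised* G_j and R_j (or given explicitly per country); linear
  structures are floored at 1e-4 with a warning. Default generating
  coefficients (beta1 = −2.7, beta2 = 1.3, sigma_v = 0.36) sit at the
  published point estimates, giving sigma_u(j) ≈ 0.08–0.13.

The generator reproduces the model's own assumptions by construction —
independent Poisson counts, exactly normal effects, no spatial
autocorrelation, no covariate measurement error, and exposure treated as
generic person-years. Passing recovery tests therefore demonstrates
correctness of the inference machinery, not robustness to the
misspecification real data would add.

A YAML config drives the CLI; per-country fields accept scalars, explicit
lists, or two-element `[low, high]` ranges (interpreted as ranges except
when exactly two countries are configured with a two-element list).

## Numerical and design choices

* Gini of a single region is defined as 0; nonpositive populations are
  domain errors.
* The weighted correlation refuses zero weighted variance rather than
  returning NaN.
* Seed handling: one `numpy` Generator per dataset; chains get spawned
  `SeedSequence` children, so results are reproducible bit-for-bit given
  (config, seed) while chains stay independent.
* Centile-excess arithmetic, 100(exp((z_p − z_{1−p})σ) − 1), is reported
  unrounded; recomputing the published 59% from the rounded σ = 0.14
  gives 58.5%, so rounding of inputs, not the formula, explains one-point
  discrepancies. Similarly, recomputing the descriptor correlation from
  the *printed* (2 dp) country table gives r = 0.283 rather than the
  published 0.29 obtained from unrounded data; the printed p = 0.22 is in
  fact the p-value of r ≈ 0.283–0.287 at n = 20.

## Known limitations

* The real region-level data are unavailable, so the published
  country-level fits (their sigma_u(j), coefficient estimates, DICs near
  5600) serve as fixtures for arithmetic and layout checks only; nothing
  here refits them.
* DIC is the only model-comparison criterion implemented (no WAIC/LOO),
  matching the original protocol.
* No spatial priors, boundary geometry, or zoning-effect analysis: the
  scale effect of areal aggregation is the object of study, the partition
  itself is taken as given.
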