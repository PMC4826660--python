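# Methods

## Case ascertainment

A person is a prevalent MS case on the prevalence day (default 2011-12-31)
if, during the study window (default 2006-01-01 to 2011-12-31), they have at
least one qualifying record in any of three administrative sources:

- **HDR** (hospital discharges): any diagnosis slot, primary or secondary,
  whose ICD-9-CM code begins with `340` after dot-stripping. ICD-9-CM 340 has
  no subdivisions, so prefix matching absorbs coding dialects (`340`,
  `340.0`, `3400`) without admitting neighbouring codes.
- **PHARMED** (drug claims): a dispensing of interferon beta-1a or -1b,
  glatiramer acetate, or natalizumab. Drugs are recognized through a
  canonical token vocabulary plus an alias table of brand names and ATC codes
  (L03AB07/08, L03AX13, L04AA23), because real claims files mix all three
  representations.
- **TER** (ticket exemptions): the MS-specific exemption code `046.340`
  (exact match after whitespace normalization; exemption codes keep their
  dot, unlike ICD codes).

Sources are linked by exact string equality of the pseudonymous person ID —
the region assigns a unique identifier recorded in every database, so
deterministic linkage suffices and no probabilistic matching is attempted.
Each case's `first_claim_date` is the minimum qualifying date over all
sources; ties across sources are harmless because all tied sources are
retained in the case's source set and nothing downstream depends on which
"won".

Exclusions are applied in a fixed order — deaths first, then residency —
matching the selection flow of the study design. A death record dated *after*
the prevalence day does not exclude (alive on the prevalence day is the
criterion). A surviving candidate with no assistance record at all is counted
as non-resident, never silently dropped. Demographics and area of residence
always come from the assistance file, not from claims, so numerators and
denominators share one demographic frame. The order affects only the
attribution of exclusion counts, not the final case set; both counts are
reported.

## Prevalence and standardization

Rates are per 100,000. The default 95 % CI is the normal approximation on the
rate scale, `rate · (1 ± 1.96/√d)`; this is the interval the study's tables
use and it reproduces every printed bound. An exact Garwood (gamma) interval
is available via `ci_method="exact"`. For zero cases the normal interval
degenerates and the exact one-sided Poisson bound `3.69/n · 10⁵` is reported.

Direct standardization uses the 1976 European Standard Population, shipped as
a versioned CSV of 5-year weights and aggregated at run time to the working
banding (each 5-year band joins the analysis band containing its lower
bound). The working banding is 0–14, 15–24, …, 55–64, 65+, giving aggregated
weights 0.22, 0.14, 0.14, 0.14, 0.14, 0.11, 0.11. The 2013 ESP revision would
give materially different standardized rates and is deliberately not bundled.
The standardized rate is Σ w_b·rate_b with variance Σ w_b²·10¹⁰·d_b/n_b².

## Small-area model

Counts per area × age band × gender stratum are Poisson with log link and
log-population offset. The design has no intercept and one indicator per
area; age-band and gender indicators (reference levels: first band, female)
are centered by subtracting their population-share-weighted regional means.
The centering scheme is a design choice: it makes `exp(area coefficient)` an
at-regional-average rate, which is the interpretation the adjusted-rate
comparison needs. Single-level covariates (e.g. one gender present) are
dropped rather than centered into a zero column.

Fitting is iteratively reweighted least squares with convergence declared at
a relative log-likelihood change below 1e-10 (cap: 100 iterations; the linear
predictor is floored at −30 to keep zero-event areas finite, and such areas
are flagged — their Wald intervals are one-sided in substance). The
coefficient covariance is the inverse Fisher information at convergence.

Expected rates p_j average the model's cell predictions over the regional
age × gender population shares. Because the model is log-linear, the summed
expected events Σ (p_j/10⁵)·n_j do not automatically equal observed events;
the multiplicative correction factor **K = actual events / Σ p_j·n_j**
restores that identity exactly, and adjusted rates are K·p_j. CIs for
adjusted rates propagate the coefficient covariance through the p_j gradient
(delta method on the log scale), then scale by K — K is treated as a
calibration constant, not a random quantity. Prevalence ratios divide the
adjusted rate by the regional crude rate; p-values are two-sided Wald tests
of the contrast "area coefficient minus the population-weighted mean area
effect", which is the model-scale analogue of PR = 1. Whether the original
analysis tested the coefficient or the PR directly is not documented; the
Wald-on-contrast choice is this package's, stated here rather than asserted
as the original method's.

## Natural-breaks classification

The Jenks optimum is found by exact dynamic programming over the sorted
values with prefix-sum segment costs — O(k·n²) with n ≤ 56 areas, so the
classic heuristic reallocation variant would save nothing. Ties between
equally good partitions break toward the lexicographically smallest boundary
index vector, making results reproducible. `k` is a required report
parameter (default 4 in the CLI, ordinary choropleth practice); it is never
inferred from the data.

## Validation

Clinic cohort records link to ascertained cases by exact ID. Records without
a usable ID stay in the accounting: the headline sensitivity keeps them in
the denominator (matched/total), because a case-finding algorithm that cannot
link a real patient has, operationally, missed them; the linkable-only
variant (matched/with-ID) is reported alongside for linkage-quality auditing.
The cohort contains only true cases, so specificity and PPV are not
estimable from it.

## Synthetic registries

The generator emulates the study's data ecosystem with known ground truth.
Per (district, age band, gender) stratum, case counts are
Binomial(population, prevalence); each true case is captured independently by
each source with probability p_source; captured cases accrue 1 + Poisson(λ)
claims dated uniformly over the window; cases die within the window with
probability `death_prob` or are unregistered on the prevalence day with
probability `emigration_prob`; clinic records lose their ID with probability
`clinic_missing_id_prob`. Only persons who touch some registry are
materialized — denominators come from the population table — which keeps a
5.6-million-resident region simulable in seconds.

Defaults are anchored to the published aggregates:

- **Strata**: the published regional age × gender rates and population
  shares, crossed with the 12 LHUs at their published populations and
  prevalence ratios; 56 districts split each LHU's population evenly.
- **Capture probabilities** 0.63 (HDR), 0.53 (PHARMED), 0.60 (TER): solved
  from the published exclusive-source shares (15.6 %, 10.4 %, 14.0 %) and
  ~27 % triple overlap under the independence assumption.
- **Repeat-claim means** 0.337 (HDR) and 1.524 (PHARMED): from the published
  multi-claim shares via P(extra ≥ 1) = 1 − e^(−λ) (28.6 % and 78.2 %);
  0 for TER, where registration is a one-off act.
- **Missing clinic IDs**: 171/3881 ≈ 4.4 %.
- **Deaths and emigration** (6 % and 2 % over the six-year window): the
  published flow counts for these exclusions are not available, so these are
  one-time choices of plausible magnitude for an MS cohort of mean age ~46 —
  they shape only the exclusion accounting, not any calibrated quantity.

What the generator does **not** emulate — and hence what passing tests do not
show about real registries: inter-source capture dependence (real sources
share latent severity: hospitalized patients are likelier treated),
seasonality or disease-course structure in claim dates, address changes,
ICD miscoding beyond a flat false-positive rate, and under-capture of benign
untreated MS, which in real data biases prevalence downward in a way no
within-simulation check can detect.

## Numerical and reporting conventions

Rates and CI bounds are computed at full precision and rounded to 1 decimal
for reporting; prevalence ratios to 2 decimals; overlap shares to 0.1 %;
headline sensitivity to a whole percent. Dates are ISO-8601 in all files.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; a fixed seed makes bundles, pipeline outputs and
the run manifest byte-identical across runs.

## Problem sizes used in the checks

The test suite runs the generator at stratum populations of a few thousand
(tens of thousands for calibration checks), 200 replicates at stratum
population 10,000 for prevalence-ratio recovery, brute-force likelihood
maximization on 3-area instances, and exhaustive partition enumeration for
the Jenks oracle at n ≤ 12 — sizes at which the independent oracles are
exact or near-instant while the statistical checks retain power.
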