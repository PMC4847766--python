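# Methods

`streamcits` analyses the variability of stream macroinvertebrate data
collected by volunteer ("citizen") groups using a nonlethal field
subsampling protocol, and asks what such data can and cannot detect.  The
package separates three scales of variation — subsampling, within-reach
spatial, and long-term temporal — and couples each to the statistical
machinery used to evaluate it.  Because the underlying field data are not
redistributable, a synthetic generator reproduces the sampling process,
and every analysis stage is validated against it plus closed-form or
enumeration oracles.

## The observation model

A *group sample* is a composite of three 0.1 m² D-net samples (~0.3 m² of
substrate) from which volunteers sort and count roughly one third of the
individuals (~0.1 m² worth).  A *sampling event* collects 5–14 group
samples from the same reach on one day.  Densities are counts per 0.1 m²
of subsampled substrate; the event mean density is the event total divided
by the number of groups.

The generator (`streamcits.synthetic`) draws, for each group,

* a latent total `Poisson(λ · G)`, where `G ~ Gamma(shape = k, mean = 1)`
  is a reach-heterogeneity factor shared by nothing else (`k` =
  `spatial_dispersion`, default 4.5).  A pure Poisson count at these
  densities has CV ≈ 0.09; replicate group samples show CV ≈ 0.45–0.50,
  and the gamma term supplies the difference (CV ≈ 1/√k ≈ 0.47);
* a multinomial split of the total over families by the community's true
  relative abundances (optionally reweighted per family in spring by
  `seasonal_shift`, emulating seasonal assemblage turnover);
* per-individual binomial retention.  The field channel retains by body
  size class (defaults: small 0.55, medium 0.90, large 1.00) because
  volunteers sorting live animals in ambient light miss small taxa; the
  lab channel retains everything with probability 0.98 under
  magnification.  `expected_density` is specified on the *observed* scale
  and the latent rate is inflated by the mean capture probability, so
  detection bias distorts composition without deflating density targets.

For the paired field/lab comparison, the full ~0.3 m² latent composite is
generated once; the field subsample is a multivariate hypergeometric draw
of one third of its individuals (the tray's 18 unequal cells are not
modelled cell-by-cell) passed through field retention; the lab subsample
is an independent hypergeometric re-subsample matched to the field count,
passed through lab retention; the total is the full composite at lab
retention, floored at the subsample counts (a full count of the same
physical sample cannot be smaller than a subsample of it).

Default community: 15 western-Oregon riffle families with round relative
abundances (Chironomidae 0.18, Baetidae 0.15, … summing to 1) and size
classes matching typical family body sizes.  `reference_community()` is
an undeveloped-watershed variant (richer EPT, few midges) used for
two-stream comparisons.  Default effort: 9 groups per event (the field
programme used 5–14), target mean subsample count 130 (observed subsample
means were 115–151).

Monthly ENSO state is generated as a stationary AR(1) (marginal SD 1,
month-to-month autocorrelation 0.9), giving water-year mean MEI values
spanning roughly the −2 to 2.5 range of the study period.

### What the generator deliberately omits

Spatial heterogeneity acts on *abundance* only; group samples share the
composite's composition up to multinomial noise.  Real paired samples
also share compositional patchiness, so the simulated field/lab
ordination concordance (~0.6) is lower than observed values (~0.94),
although PROTEST still finds it significant.  There is no hydrological or
temperature process, no autocorrelated residual, and no observer learning
over years.  Passing calibration tests therefore demonstrates internal
consistency of the estimators under a plausible sampling model, not
fidelity to any particular stream.

With the stated retention defaults the simulated field mean absolute
taxon deviation is ~0.36–0.45 (lab ~0.26–0.32).  The field programme
reported 62% (lab 33%); reproducing the field figure would need a harsher
small-taxon retention than the default 0.55.  The rates are configuration
(`CommunitySpec.field_capture_prob`), and the ordering field > lab — the
property the analyses depend on — is robust to them.

## Subsampling null model

For a sample with fully enumerated total counts, the null distribution of
an honest random subsample of `m` individuals is multivariate
hypergeometric (drawing *without* replacement — a physical subsample
cannot pick the same animal twice).  `resample_null` draws `R = 1000`
replicates; the mean relative abundance over replicates is the null
benchmark.  `m` is the median of the field and lab subsample counts,
rounded half-up (183 and 179 give 181).

The per-taxon statistic is the relative deviation
`(X_obs − X_null) / X_null`.  Signed deviations measure bias direction;
summaries use absolute deviations, because under- and over-estimates
would otherwise cancel.  Taxa never drawn by the null (null mean 0) are
excluded from the ratio and reported as missed taxa.  Summaries are
offered pooled across taxa×samples and as per-sample means; the paired
t-test comparing field and lab operates on per-sample means.  An optional
filter retains only taxa above a null relative abundance threshold
(default 5%).

## CV estimation and partitioning

CV is sample SD over mean (n − 1 denominator throughout; group counts are
few).  Event CV is computed over group densities within one event;
within-reach CV is the *unweighted* mean of event CVs at a stream (events
with one group are skipped); temporal CV is the CV of event mean
densities (or one family's event counts) across years.  Partitioning is
multiplicative: a component's CV is its fraction times the total, the
remainder unexplained, so components plus remainder conserve the total
exactly.

`detectable_change` estimates the minimum density change detectable at
80% power (α = 0.05, two-sided two-sample t on log densities) by
bisecting a Monte-Carlo power curve under lognormal group variation with
the observed CV; common random numbers across bisection evaluations keep
the empirical curve monotone.  At CV ≈ 0.5 with 9 groups per arm and two
events this lands near a ~95% change — a deliberately conservative,
simulation-based counterpart to the programme-level claim that changes
above 50% would likely be detected with more events.

## Ordination

Bray-Curtis dissimilarity on event-level relative abundances feeds a 2-D
NMDS minimising Kruskal stress-1 with isotonic-regression disparities and
Guttman-transform updates.  Initialisation is classical (Torgerson)
metric scaling plus 19 random restarts; tolerance 1e-6 on stress change;
the best configuration over all starts *and all iterations* is kept, so
the result can never be worse than its metric start.  Configurations are
centred and principal-axis rotated; per-axis "variance explained" is the
squared correlation between observed dissimilarities and distances
reconstructed from the leading axes, differenced — a descriptive quantity
only.

ANOSIM uses average ranks on tied dissimilarities and
`R = (r̄_between − r̄_within) / (n(n−1)/4)`; Procrustes centres and
unit-scales both configurations and allows reflections (ordination axes
have arbitrary orientation), reporting the residual `m²` and the
concordance `√(1 − m²)` — the latter is the statistic comparable to
published "similarity" values near 1.  Permutation tests (ANOSIM
relabelling, PROTEST row permutation) use the add-one convention so p is
never zero, with resolution 1/(N + 1) at N random permutations; both also
offer exact enumeration for small n, which the tests check against
independent brute-force oracles.

## IBI

Six family-level metrics — total, mayfly, stonefly and caddisfly richness
(higher better), % Diptera and % single-family dominance (lower better) —
each score 1/3/5 against two breakpoints; totals (6–30) map to severely
impaired (≤ 16), moderately impaired (17–23), unimpaired (> 23).  The
published category wording leaves 16 unassigned; it is placed in the
severe band to make the mapping total.  Breakpoints are region-specific
calibration values that the source programme took from an external
protocol; the shipped defaults are documented placeholders and all tests
exercise scoring mechanics (range, monotonicity, category totality)
rather than particular breakpoints.  Metrics are computed on event-level
summed counts, not per group.

## Temporal model

`log(mean density) = b0 + b1·MEI_wy + b2·year_index + ε`, ordinary least
squares, natural log (intercepts ≈ 3.3–3.8 match ln of mean densities
29–39 per 0.1 m²; log10 would not).  `MEI_wy` averages monthly MEI over
the water-year window preceding the sample — September–October of the
sampling year for fall, September of the previous calendar year through
April for spring; the window definition is configuration so alternative
readings are runnable.  `year_index` is a 0-based integer from the first
survey year.

LMG relative importance averages each predictor's sequential R² increment
over all predictor orderings, implemented by exact enumeration of all 2^p
subset regressions with ordering weights (p = 2 here; capped at 10).
Contributions sum to the full-model R² by construction; note that a
published LMG total exceeding the same model's R² is arithmetically
impossible under this definition, and the implementation enforces the sum
identity.  The temporal CV partition multiplies the temporal CV by the
summed predictor percents of *total* variance (environmental component)
and by the unexplained percent (remainder), mirroring the multiplicative
within-reach partition.

## Problem sizes and numerical choices

Analyses and tests use 11 years × 2 seasons × 2 streams (44 events, ~9
groups each), 6 paired samples per stream, null-model R = 1000,
permutation N = 999, NMDS 20 restarts.  The acceptance script averages
survey-level quantities over 10 survey realisations and slope recovery
over 100 replicates.  Degenerate cases are explicit: zero-variance paired
differences warn and return the 0/1 edge p; identical Mann-Whitney
samples return p = 1 with a warning; all-zero abundance rows, singleton
ANOSIM groups, single-group events and zero-variance Procrustes
configurations raise validation errors.  All randomness flows through
`numpy.random.Generator`; a seed fixes every dataset bit for bit.
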