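# streamcits

Variability analysis for long-term stream macroinvertebrate data
collected by citizen scientists.

Volunteer stream-monitoring programmes count benthic invertebrates with
nonlethal field protocols: composite D-net samples are subsampled, sorted
and identified to family in the field, then returned to the stream alive.
Managers who receive such data need to know how noisy it is and what it
can detect.  `streamcits` implements the statistical toolkit for that
question:

* **Subsampling null model** — the total count of a fully enumerated
  sample is re-subsampled `R = 1000` times without replacement
  (multivariate hypergeometric) to the median of the field/lab subsample
  counts; each method's relative abundances are scored per taxon as the
  relative deviation `(X_obs − X_null) / X_null`, and field vs lab are
  compared with a paired t-test on per-sample mean deviations.
* **CV estimation and partitioning** — within-reach CV (mean over events
  of the CV of group densities), long-term temporal CV, multiplicative
  partitions (component CV = fraction × total CV), and a Monte-Carlo
  minimum-detectable-change power analysis on log densities.
* **Community ordination** — Bray-Curtis distances, 2-D NMDS (Kruskal
  stress-1, isotonic disparities, metric-scaling + random restarts),
  ANOSIM with permutation or exact p, Procrustes superposition with
  PROTEST.
* **IBI scoring** — six family-level metrics (total/mayfly/stonefly/
  caddisfly richness, % Diptera, % dominance) scored 1/3/5, summed to
  6–30 and categorised (severely impaired ≤ 16, moderately impaired
  17–23, unimpaired > 23).
* **Temporal model** — `log(mean density) = B0 + B1·MEI_wy + B2·year + ε`
  with water-year mean ENSO MEI windows, plus an exact LMG decomposition
  of the model R² and the environmental/unexplained partition of the
  temporal CV.
* **Synthetic generator** — an overdispersed Poisson-gamma sampling
  process with size-biased field detection and ENSO-forced log density,
  so the whole pipeline is testable without restricted field data.

## Worked example

```sh
python analysis/01_simulate.py --seed 1    # synthetic 2-stream, 11-year survey
python analysis/02_nullmodel.py            # subsampling deviations, field vs lab
python analysis/03_variability.py          # within-reach CVs + partition + power
python analysis/04_ordination.py           # NMDS / ANOSIM / PROTEST
python analysis/05_ibi.py                  # IBI scores and comparisons
python analysis/06_temporal.py             # ENSO model, LMG, temporal partition
```

Output of the run above (abridged):

```
[all_taxa] field 36% (SD 30%)  lab 29% (SD 29%)  paired t = 3.07, df = 11, p = 0.0107
SimBalch: mean within-reach CV 0.52 (range 0.24-0.78, n=22); subsampling component 0.19; min detectable change 96%
streams: ANOSIM R = 0.58, p = 0.001 (stress 0.092, axis variance [0.66, 0.27])
SimBalch seasons: ANOSIM R = 0.97, p = 0.001
field vs lab ordinations: concordance 0.58 (m2 = 0.66), PROTEST p = 0.035
SimBalch: median IBI 26 (range 24-26); unimpaired 100%
SimBalch: temporal CV 0.45; y = 0.34*MEI + 3.3 (R2 0.14); multi R2 0.28; environmental CV 0.13 (28%)
```

Reading it: the field method's taxon deviations exceed the lab's (36% vs
29%, significant on the paired test), replicate groups in the same reach
vary with CV ≈ 0.5 of which the measured subsampling deviation accounts
for a 0.19 CV component, the two simulated streams and the two seasons
separate cleanly in ordination space, and about a quarter of the
long-term temporal variance in log density is attributable to ENSO state
plus sampling year.

The same operations are exposed as a CLI
(`streamcits simulate|nullmodel|cv|ordinate|ibi|temporal|report`) and, of
course, as library functions (`streamcits.nullmodel`,
`streamcits.variability`, `streamcits.ordination`, `streamcits.ibi`,
`streamcits.temporal`, `streamcits.synthetic`).

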