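# Methods

## Generative model

Genes belong to one of six classes: `autosome`, `PAR`, `X_specific`,
`XY_shared_X`, `XY_shared_Y` (the two members of a gametologue pair) and
`Y_specific`. Default class sizes are 13,164 autosomal (on three 80 Mb
scaffolds), 667 X-specific, 39 PAR, 47 gametologue pairs (5 of them
silent) and 15 Y-specific genes on a 71.2 Mb X (first 2.8 Mb = PAR) and
a 21.7 Mb Y. Gene footprints are placed uniformly without overlap; each
gene carries a small multi-interval feature model whose interval union
defines its length.

### Counts

Counts are negative binomial with mean

```
mu[g,s] = baseline[g] * dosage(class(g), genotype(s))
          * length[g]/1e3 * library_size/1e6
```

and variance `mu + phi * mu^2` (`phi = dispersion`; `phi = 0` falls back
to Poisson). Baselines are log-normal (default log-mean 2.1, log-sd 1.0)
and are rescaled once so that the expected total of an XX sample equals
`library_size` exactly. The dosage factor encodes the biology:

| class        | XX genotype | XY genotype |
|--------------|-------------|-------------|
| autosome, PAR| 1           | 1           |
| X_specific   | 1           | rho         |
| XY_shared_X  | 1           | kappa       |
| XY_shared_Y  | 0           | 1 − kappa   |
| Y_specific   | 0           | 1           |

so a gametologue pair shares a single baseline and its summed expected
output is conserved in XY males, split X:Y as `kappa : 1 − kappa`.
Groups are XX females (n = 3), XY males (n = 3) and sex-reversed XX
males (n = 2); the XX-male columns are drawn from the same XX dosage
model, so any X difference between them and XX females is pure noise.

Note one realism the model keeps deliberately: RPKM uses the realized
per-sample totals, and in XY males the down-dosed X itself depresses the
realized library size. Ratios of raw group means therefore sit ~1–2%
above the planted parameter at default sizes (more in small genomes
where the X carries a larger read share); ratios taken relative to the
autosomal median cancel the effect, which is why the report's primary
panels are autosome-referenced.

### Depth

DNA depth is simulated per 20 kb window (the last window may be partial
and is scaled by its width): Poisson with mean `depth_mean` (default
100) over diploid sequence and `depth_mean/2` over hemizygous sequence
(X beyond the PAR, and the whole Y, in a male). A `depth_noiseless` mode
emits the exact means for changepoint ground-truthing.

## Estimators

- **Depth normalisation.** Windows are divided by the median depth over
  autosomal scaffolds, putting diploid sequence at ratio ≈ 1 and
  hemizygous at ≈ 0.5.
- **Scaffold calls.** Median ratio ≤ 0.75 → hemizygous-like, ≥ 0.85 →
  diploid-like, else mixed; a two-segment scan upgrades a scaffold to
  mixed when a changepoint separates diploid- from hemizygous-level
  segments (the X itself).
- **PAR boundary.** Exhaustive single-changepoint two-segment SSE fit,
  O(n) via prefix sums. A boundary is reported only when the best split
  cuts the total SSE by ≥ 10% and separates segment means by ≥ 0.2
  (diploid-vs-hemizygous geometry puts the true gap near 0.5).
  `boundary_bp` is the changepoint coordinate — the start of the first
  window after the split — which is orientation-symmetric: mirroring the
  scaffold maps the boundary to `length − boundary_bp`.
- **Expression.** RPKM/CPM with library size = column total, optionally
  multiplied by hand-implemented TMM factors (trimmed mean of M-values,
  30%/5% trims, inverse-variance weights; cross-checked against edgeR in
  the test suite). Ratios are of group-mean RPKM; genes at zero in
  either group are excluded rather than pseudocounted, and the report
  states how many. `X_total` pools X-specific genes with the X-borne
  gametologue copies — the whole output of the X chromosome.
- **Class slopes.** Zero-intercept regression of group A on group B
  mean CPM per class, with uncentred R²; the slope reads directly as a
  dose factor.

## Tests

- **Mood's median test.** 2×2 table of counts above vs at-or-below the
  pooled grand median (`ties="below"`; `ties="ignore"` drops values equal
  to the grand median). The chi-square statistic uses the closed form
  `N(ad − bc)² / (row and column margins)` with 1 df and no continuity
  correction; when any expected cell is < 5 the test switches
  automatically to Fisher's exact test. Constant pooled input is
  degenerate and returns p = 1 with a warning.
- **Permutation test.** Statistic |median(a) − median(b)| under label
  permutation. When the number of distinct splits C(n, n_a) does not
  exceed `n_perm` the test enumerates all of them and the p-value is the
  exact tail proportion `#{stat ≥ observed}/N_splits`; otherwise it
  Monte-Carlo samples with the unbiased-valid estimator
  `(k + 1)/(n_perm + 1)`. Seeded, chunked to bounded memory, and
  bit-for-bit reproducible.
- **Invariances.** Mood's test is invariant under any strictly monotone
  transform of the pooled data. The permutation statistic is only
  guaranteed invariant under positive affine transforms: a nonlinear
  monotone map can reorder median gaps across splits. The test suite
  checks exactly those two properties.
- **Calibration.** Under null simulations (two lognormal samples of 500)
  both tests reject at 0.048/0.046 with alpha = 0.05 over 1,000
  replicates.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded with
`[seed, stream]` pairs, one stream per generator stage, so annotation,
counts and depth are independently reproducible. Reports contain no
timestamps; identical config + seed reproduces every output file byte
for byte (asserted in the test suite).

## Limitations

- The simulator draws genes independently: no co-expression, GC/mappability
  bias, batch effects or within-class variation in the dosage factor, so
  real-data dispersion of the per-gene ratio distribution will be wider
  than simulated at the same `phi`.
- Library-size realism stops at the realized-total effect described
  above; no differential sample quality or 3' bias.
- The boundary detector fits exactly one changepoint; scaffolds with
  multiple ploidy transitions (e.g. X-autosome fusions with interior
  strata) are only flagged as mixed, not segmented fully.
- Class-median summaries over small classes (39 PAR genes, 42 expressed
  gametologue pairs) carry ~5–10% sampling noise per simulation from the
  log-normal baselines alone; headline checks therefore average over
  many seeds.
- Mood's test compares medians only; it has low power against
  scale-only alternatives by construction.
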