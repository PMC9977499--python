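# Methods

## Scope and model

`detargets` implements a promoter-binding enrichment screen on top of a
classical two-group expression analysis. The statistical chain is:

quantile normalization → (log2 if linear) → pooled-variance Student
t-test per gene → Benjamini–Hochberg (BH) step-up FDR → directional DE
calls at q < 0.05 → (a) hypergeometric over-representation against gene
sets and (b) per-subunit binding assignment by the 1 kb rule followed by
a two-sided Fisher exact test of the DE × bound 2×2 table, target-gene
definition (DE ∩ bound) and target fractions.

Assumptions: exactly two sample groups; log2 intensities approximately
normal per gene with equal group variances (the pooled test is the
default; Welch is available behind a flag); genes treated independently
by BH; binding treated as a binary per-gene property derived from given
peak calls — no peak calling, motif analysis or enhancer–gene linking.

## Conventions and numerical choices

* Coordinates are 0-based half-open (BED) everywhere. The gap between a
  gene `[gs, ge)` and peak `[ps, pe)` is `max(gs − pe, ps − ge)`; a gene
  is bound iff gap ≤ window (default 1000 bp, boundary **inclusive**).
  The rule is anchored on the gene body; `anchor="tss"` restricts it to
  the 5′ end. Assignment runs as a sorted sweep per chromosome
  (searchsorted + running maximum of peak ends), exactly equivalent to
  the quadratic all-pairs check, which the test suite verifies.
* Quantile normalization replaces rank r in each column by the mean of
  the r-th order statistics across columns; ties within a column receive
  the average of the reference values of their tied ranks (the behaviour
  of limma's `normalizeQuantiles(ties=TRUE)`, against which it is
  cross-checked). With ties the tie-averaged map is not an exact
  projection; on tie-free data it is idempotent.
* For linear input the order is normalize, then log2. Zero-variance
  genes are kept with sentinel statistics (t = 0, p = 1 for equal means;
  t = ±∞, p = 0 otherwise) so gene counts are conserved.
* BH q-values use the step-up minimum `q_(i) = min_{j≥i} m·p_(j)/j`,
  capped at 1; DE requires **strict** q < threshold.
* Probe-level tables are collapsed to genes after BH: the representative
  probe has the smallest q (ties: smallest p, then lexicographic probe
  ID); genes whose significant probes disagree in sign are flagged
  ambiguous and excluded from the up/down sets; unmapped probes are
  dropped with a logged count. This collapsing rule is a declared
  convention of this package.
* Fisher's two-sided p sums the conditional hypergeometric pmf (in log
  space via `gammaln`) over all tables with the observed margins whose
  pmf ≤ observed × (1 + 1e-7). The reported odds ratio is the
  unconditional sample estimate `ad/bc` with sentinels ∞ / 0 / 1 for
  zero products; when no gene is bound at all the enrichment record
  reports the depletion sentinel 0. The conditional-MLE odds ratio is
  available as `targets.conditional_odds_ratio`.
* The hypergeometric upper tail is likewise summed in log space; ORA
  applies the minimum set size (default 2) to the within-background set
  size K, and BH runs across the sets actually tested in one run.
* The ORA background defaults to the gene universe of the DE table; the
  binding background is that universe intersected with the genes that
  have coordinates (genes without coordinates are excluded and counted).
* Result floats are written in scientific notation with six significant
  digits, so identical inputs yield byte-identical outputs.
* Target fractions round half-up to whole percent.

## The synthetic-data generator

The generator emulates a small two-colour-free microarray study — two
groups of `n_per_group = 3` arrays, `n_genes = 12000` genes — together
with coupled gene models and per-subunit peak calls:

| parameter | default | meaning |
|---|---|---|
| `pi_de` | 0.01 | fraction of DE genes, split evenly up/down |
| `effect_size_range` | (0.8, 2.0) | log2 group shift per DE gene |
| `mu0`, `sd_mu` | 7, 2 | per-gene baseline mean hyperparameters (log2) |
| `sd_noise_range` | (0.15, 0.45) | per-gene sample noise SD (log2) |
| `p0_bound` | 0.15 | baseline promoter-binding probability |
| `or_true` | RelB 4.0, others 1.0 | binding-odds multiplier for up-DE genes |
| `gene_length_range` | (2000, 10000) bp | uniform gene lengths |
| `intergap_range` | (5000, 50000) bp | uniform intergenic gaps |
| `n_bg_peaks` | 2000 | intergenic decoy peaks per subunit |
| `peak_length`, `window_bp` | 300, 1000 bp | peak size, binding window |

Genes are laid end to end on one synthetic chromosome. Each truth-bound
gene receives exactly one peak placed uniformly at gap ≤ `window_bp`;
decoys land strictly beyond the window from every gene. Because the
minimum intergenic gap (5 kb) exceeds twice the window plus a peak
length, a truth peak can never reach a neighbouring gene — the 1 kb rule
therefore recovers the truth **exactly**, which the tests assert. Up-DE
genes carry the binding enrichment by default (`enriched_direction`).
Expression is simulated directly on the log2 scale; `exponentiate`
produces linear intensities to exercise the normalization/log path.
Each stage draws from a child random stream derived from the master seed
by a fixed label, so every generator is a pure function of
(config, seed) and outputs are byte-identical per seed.

What the simulation does **not** model: probe-level artifacts
(background, GC effects), batch effects, correlated genes, multi-peak
promoters, more than two groups, or a three-way premature/mature/adult
structure (the emulated contrast pools the fetal samples). Passing tests
therefore validate the statistical machinery and its calibration, not
robustness to those real-data features.

## Calibration and problem sizes

`detargets.calibration` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) measures, at the generator's default study
conditions:

* **Odds-ratio recovery** — the sample OR of binding among the *true*
  up-DE set (~60 genes), through the real peak → binding → Fisher chain,
  median over 25 seeds. The true-set convention isolates the enrichment
  estimator's sampling behaviour at the design's DE-set size from the
  separate question of DE power. Expected near the planted OR of 4.
* **Null Fisher calibration** — with every true OR at 1, the fraction of
  200 replicates with p < 0.05; the discrete exact test is conservative,
  so this stays at or below the nominal level.
* **Null FDR behaviour** — 50 simulations with `pi_de = 0` at 2,000
  genes; under the global null BH makes any call with probability ≈ α,
  so ≥ 90% of seeds yield zero calls.
* **DE recall** — the fraction of spiked genes recovered at FDR < 5% on
  default simulations (5 seeds). With three samples per group the pooled
  t has 4 degrees of freedom, so even the strongest admissible gene
  (δ = 2.0, σ = 0.15, |t| ≈ 16) has p ≈ 8 × 10⁻⁵, above the BH cutoff at
  rank i of i × 4.2 × 10⁻⁶ for small i; recall under these defaults is
  accordingly a few percent, and the corresponding acceptance test
  documents the gap between this design and a 50% power floor rather
  than relaxing either. Recall rises quickly with larger `pi_de`,
  smaller gene universes or stronger effects (see the README example:
  `pi_de = 0.05` at 2,000 genes recovers ~38%).

These replicate counts (25 / 200 / 50 / 5) are the package's chosen
Monte-Carlo sizes; they keep the whole validation run under a minute
while leaving comfortable margins on the asserted bounds.

## Applying the pipeline to the original public data

The desk-scale validation above needs no downloads. To reproduce the
original screen end to end:

1. Fetch the series matrix of GEO accession **GSE222156** (Affymetrix
   HG-U133 Plus 2.0, three fetal and three adult neutrophil samples) and
   export it as a TSV intensity matrix plus a two-column sample-group
   table. The deposited matrix is already background-corrected,
   quantile-normalized and log2-scaled, so run `detargets deg
   --skip-normalize`.
2. Map probe sets to Ensembl gene IDs (e.g. biomaRt) into a two-column
   `--probe-map` TSV, and export gene coordinates as BED.
3. Obtain the GM12878 ChIP-Seq peak calls for p65, p50, RelB and p52 as
   BED, and run `detargets targets --genes genes.bed --peaks
   RelB=relb.bed …`.

Expected headline values at the default gene-body ± 1 kb anchor: 124 DE
genes (56 up, 68 down), RelB the most over-represented subunit among
up-regulated genes (OR ≈ 4, p ≈ 5 × 10⁻⁷), 40 up- and 24 down-regulated
RelB targets (71% / 35%). Exact numbers shift with the annotation
release and the gene-body vs TSS anchor; neither convention is fixed by
the original description.

## Known limitations

* The pooled t-test is anti-conservative under strong variance
  heterogeneity; use `--welch` where that matters.
* No moderated (empirical-Bayes) variance shrinkage — at n = 3 per group
  a limma-style approach would have far more power than the plain
  t-test implemented here.
* ORA ignores gene-set overlap/redundancy and gene length bias.
* Binding is binary; peak strength and distance weighting are ignored.
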