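# detargets

Identify transcription-factor target genes among differentially expressed
genes. `detargets` re-implements, as a tested and reusable pipeline, the
computational analysis used to show that the noncanonical NF-κB subunit
RelB shapes the gene-expression signature of human fetal neutrophils:

1. **Differential expression** — quantile normalization of a feature ×
   sample intensity matrix (e.g. microarray probe sets), log2 transform of
   linear intensities, a pooled-variance Student t-test per gene between
   two groups, Benjamini–Hochberg FDR control and directional DE calls at
   q < 0.05.
2. **Over-representation analysis (ORA)** — hypergeometric upper-tail
   tests of the DE list against GMT gene-set collections, with fold
   enrichment `(k/n)/(K/N)`, a minimum within-background set size of 2 and
   BH correction across tested sets.
3. **ChIP-peak target assignment** — a gene counts as *bound* by a subunit
   when a peak overlaps the gene body or lies within 1 kb of it
   (boundary inclusive); per subunit and DE direction a 2×2 DE × bound
   table over the gene universe is tested with a two-sided Fisher exact
   test, *target genes* are the DE-and-bound intersection, and the target
   fraction is their rounded percentage of the directional DE genes.
4. **Synthetic data** — a generator that emulates the study design (two
   groups of 3 arrays, ~1% DE genes at log2 effects 0.8–2.0, promoter
   binding whose odds are multiplied by a configurable true odds ratio
   among up-regulated genes) with full ground truth, so the whole chain
   can be validated with no external download.

It is aimed at computational biologists who want the statistics of a
promoter-binding enrichment screen — not peak calling or motif analysis —
in a deterministic, scriptable form.

## The statistics in brief

For each gene the pooled two-sample t statistic with
`df = n_A + n_B − 2` is converted to a two-tailed p-value and adjusted by
the BH step-up `q_(i) = min_{j≥i} m·p_(j)/j`. For binding enrichment the
table `[[a, b], [c, d]]` (a = DE ∩ bound … d = neither) gives the sample
odds ratio `ad/bc` and an exact two-sided p summing the conditional
hypergeometric pmf over tables as extreme as observed (log-space, 1e-7
tie tolerance). Fractions are reported as `round(100·a/(a+b))`.

## Worked example

```bash
cat > demo.toml <<'EOF'
[simulate]
n_genes = 2000
pi_de = 0.05
EOF
detargets all --config demo.toml --out-dir demo_run --seed 42
```

prints

```
INFO detargets: pipeline finished: 38 DE genes (20 up / 18 down)
```

and writes `de_table.tsv`, `volcano.tsv`, `target_enrichment.tsv` and a
deterministic `run_summary.json` manifest. Of the 100 simulated DE genes
(50 up, 50 down), 38 pass FDR < 5% with three samples per group. The
RelB rows of `target_enrichment.tsv`:

```
subunit direction  a   b    c     d    odds_ratio   p_value      n_targets  fraction_pct
RelB    up         9   11   328   1652 4.12084e+00  2.91790e-03  9          45
RelB    down       7   11   330   1652 3.18567e+00  2.13174e-02  7          39
```

The generator planted a true RelB binding odds ratio of 4 among
up-regulated genes; the estimated odds ratio for the recovered up-set is
4.12 (p = 2.9 × 10⁻³), while the other subunits stay near 1. Re-running
with the same seed reproduces every output byte for byte.

The same stages are available separately (`detargets simulate | deg |
ora | targets`) for real data: a TSV expression matrix plus sample-group
table, gene models and per-subunit peak calls as BED, and gene sets as
GMT.

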