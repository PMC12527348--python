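# polytail

Differential poly(A) tail-length analysis from basecaller-tagged BAM files.

Modern nanopore basecallers (dorado with `--estimate-poly-a`) estimate the
length of each read's poly(A) tail and store it as an integer auxiliary tag
(`pt:i:<n>`) in the output BAM. Because tail length modulates mRNA stability
and translation, comparing tail-length distributions between conditions —
globally, per transcript, and per gene — is a question of direct biological
interest for anyone running direct RNA or cDNA nanopore experiments.
`polytail` turns a set of tagged, transcriptome-aligned BAMs plus a samples
design (BAM → sample → group) and a GTF into per-read tail tables,
per-feature differential polyadenylation calls, matrices, PCA, windowed
length distributions, dendrograms and publication plots.

## The statistics at the core

For each feature (gene or transcript) with tail-length samples per group,
the engine selects a test from the data rather than imposing one:

* **Normality** per group: Shapiro–Wilk (3 ≤ n ≤ 5000) or Lilliefors
  (n > 5000; Kolmogorov–Smirnov with estimated μ, σ and the
  Dallal–Wilkinson p-approximation). Groups with n < 3 or constant values
  are treated as non-normal.
* **Variance homogeneity**: Brown–Forsythe Levene test (one-way F on
  |x − median|).
* **Two groups**: Student's t (normal + homogeneous), Welch's t (normal +
  heterogeneous), otherwise the Wilcoxon rank-sum test (exact null when both
  n ≤ 25 and tie-free, else the tie- and continuity-corrected normal
  approximation). A Wilcoxon-only mode is also available.
* **k > 2 groups**: one-way ANOVA + Tukey HSD, Welch's ANOVA + Games–Howell,
  or Kruskal–Wallis (tie-corrected H) + Dunn's z-tests with Bonferroni.
* **Effect sizes**: Cohen's *d* = (x̄_T − x̄_C)/s_pooled and
  log2FC = log2(x̄_T / x̄_C), so negative values mean tail shortening.
* **Multiple testing**: holm, hochberg, hommel, bonferroni, BH, BY, fdr.
  Features with adjusted p < 0.05 are called differentially polyadenylated
  (DPGs): *collapsed* (log2FC < 0) or *expansion* (log2FC > 0).

Genes with fewer than 10 poly(A) tails are excluded by the default filter,
and within-gene duplicate assignments (same read, gene and tail length) can
be collapsed before gene-level testing.

## Worked example

```bash
polytail --seed 1 simulate --out-dir sim/
polytail extract  --samples sim/samples.csv --tag pt --policy primary --out polya.tsv
polytail annotate --polya polya.tsv --gtf sim/annotation.gtf --out polya_gene.tsv
polytail filter   --polya polya_gene.tsv --min-tails 10 --out filtered.tsv
polytail stats2   --polya filtered.tsv --control CTR --treated HIGH \
                  --mode adaptive --adjust BH --out stats.tsv
polytail plot volcano --stats stats.tsv --out volcano.png
```

The same pipeline from Python (see `examples/02_differential_tails.py`)
prints, for a simulated experiment with 6 of 40 genes shortened by 20 nt:

```
feature_id   test_id      p_value         padj  cohens_d    log2fc  dpg_call
     g0001 student_t 1.011007e-27 2.022014e-26 -2.213388 -0.512260 collapsed
     g0002  wilcoxon 3.323297e-19 2.658638e-18 -2.119017 -0.506484 collapsed
     ...
6 differentially polyadenylated genes (planted: 6).
```

Each row is one gene: the test the engine chose for that gene's data, the
raw and BH-adjusted p, the standardized effect size, the log2 ratio of mean
tail lengths (negative = shorter in the treated group), and the DPG call.
All six planted genes are recovered and none of the 34 null genes is called.

The `examples/` directory holds one short script per capability (extraction
and annotation, two-group testing, global/k-group testing, matrices + PCA +
clustering); each prints the numbers it computes and what they mean.

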