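# Methods

## Input model and extraction

The unit of observation is a sequenced mRNA molecule whose poly(A) tail
length has been estimated upstream by the basecaller and stored as an
integer auxiliary tag on the read's alignment (default tag `pt`, the one
dorado writes; the tag name is configurable because other tools may choose
another). Alignments are assumed to be against a *transcriptome*, so the
reference name of an alignment identifies a transcript. Extraction walks
every alignment of every BAM in the samples table and emits one record per
alignment that (a) is mapped, (b) passes the alignment-filter policy, and
(c) carries a tag value ≥ 1. Tail estimates ≤ 0 are treated as "no
estimate" and skipped, since a non-positive length is not a measurement.
Two policies exist: `primary` (default — one tail estimate per molecule;
secondary/supplementary alignments dropped) and `all` (keep everything and
let the duplicate-handling step decide). Every skipped alignment is counted
by reason (`unmapped`, `filtered_by_policy`, `tag_missing`,
`tag_nonpositive`) and the accounting identity
`emitted + skipped = scanned` is enforced by tests. Reads are never
re-assigned between transcripts; resolving the true source transcript of a
multi-mapping read is out of scope.

## Annotation and duplicate handling

Gene ids come from the attribute column of a GTF (both `key "value";` and
`key value;` dialects are parsed). A transcript mapped to two different
genes is a hard error — silently picking one would bias gene-level counts.
Records whose transcript is absent from the annotation are *kept* with a
missing gene id rather than dropped: transcript-level analyses remain valid
on the same table, and gene-level operations exclude and count them.

A read id can legitimately appear on several transcripts. Multiplicity is
summarized per sample as unique (×1), duplicated (×2), multiple (≥3).
At the transcript level duplicates are left in place (the molecule's true
transcript is unknowable here). At the gene level, records sharing
(sample, read, gene, tail length) are collapsed to one — the same molecule
counted twice within a gene would inflate that gene's evidence — keeping
the first record in input order so the operation is deterministic and
idempotent. Records differing in gene or length are never collapsed.

## Filters

Features with too few tails cannot support a distributional comparison.
The default filter removes genes with fewer than 10 tails; the threshold is
applied per compared group by default (a gene with 100 control tails but 2
treated tails is not testable) with a `total` scope offered for users who
prefer the looser overall-count reading. Per-feature tests additionally
report `not_tested` for any feature where a group has fewer than `min_n`
(default 3) observations — below that, none of the tests in the decision
tree is meaningful, so the feature is excluded from the multiple-testing
family rather than given a noise p-value.

## The adaptive test engine

Assumption checks: per-group normality via Shapiro–Wilk for 3 ≤ n ≤ 5000
and the Lilliefors test above 5000 (Shapiro–Wilk's classical implementation
limit makes the switch deterministic); Lilliefors p-values use the
Dallal–Wilkinson approximation (statsmodels `pvalmethod="approx"`, which
falls back to the simulation table when p > 0.1 — only sharpening the
non-significant region). Constant or n < 3 groups are *not assessable* and
are routed to the non-parametric branch instead of erroring. Variance
homogeneity uses the Brown–Forsythe variant of Levene's test (absolute
deviations from group medians), which is robust to the skewness typical of
tail-length data. Both gates use α = 0.05 by default; the threshold is a
parameter (`alpha_assumption`) because reasonable analysts differ on it.

Decision table (identical for the global, per-feature two-group and
per-feature k-group engines):

| normality (all groups) | variances | k = 2 | k > 2 |
|---|---|---|---|
| normal, all n ≥ 3 | homogeneous | Student's t | ANOVA + Tukey HSD |
| normal, all n ≥ 3 | heterogeneous | Welch's t | Welch ANOVA + Games–Howell |
| otherwise | — | Wilcoxon rank-sum | Kruskal–Wallis + Dunn (Bonferroni) |

Numerical details and tie-breaks:

* Wilcoxon uses the exact null distribution when both n ≤ 25 and the pooled
  data are tie-free; otherwise the normal approximation with tie correction
  and continuity correction. A pooled sample with all values identical
  returns p = 1 (no evidence of a shift by definition). When both groups
  have zero variance, the t statistic is undefined and callers fall back to
  the rank-sum test.
* Welch's ANOVA and Games–Howell are implemented from the closed forms
  (heteroscedastic F with λ-correction and 1/(3λ) denominator df; pairwise
  Welch t with studentized-range p at q = |t|√2, k groups). Dunn's test is
  the tie-corrected rank z-test with variance
  (N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ) and Bonferroni over all pairs.
  None of these has a scipy implementation; tests verify them against
  literal-formula oracles and (where available) pingouin.
* Kruskal–Wallis H is tie-corrected with a χ²(k−1) p.

Effect direction: log2FC = log2(mean_treated / mean_control), so
"collapsed" (tail shortening) is negative — matching the red/green volcano
semantics. Cohen's d uses the pooled standard deviation and is reported as
missing when the pooled variance is zero. Multiple-testing adjustment is
computed across features with a valid p only (missing p-values do not
inflate m); `fdr` is an alias of BH. The DPG call is strict:
adjusted p < α (default 0.05), never ≤.

## Matrices, PCA, binning, clustering

Feature matrices pivot the per-(feature, sample) molecule summaries into
features × samples of one statistic (count, mean or median tail length;
median is the default PCA input, being robust to the long right tail of
length distributions). PCA treats samples as observations, centers features
but does not scale them (the variables share units — nucleotides), and is
computed by SVD. Features missing in any sample are dropped, not imputed:
inventing a 0-nt tail for an unobserved gene would fabricate signal. Signs
are fixed by making the largest-magnitude loading of each component
positive, so results are reproducible across runs and platforms.

Tail-length binning assigns length L to window ⌈L/frame⌉ (frame 10 → 10 in
"1–10", 11 in "11–20"); windows tile from 1 to the tile containing the
longest observed tail — no trailing empty windows are padded. `normalized`
mode converts rows to percentages summing to 100 exactly. Group clustering
is agglomerative with Euclidean distance and complete linkage (the common
defaults of the heatmap stacks this feeds); rows are sorted by label before
linkage so distance ties break deterministically. The dendrogram exports to
Newick with branch lengths equal to merge-height differences.

## Plots

The plotting layer is a pure renderer: point classes come from the DPG
calls, the density plot's dashed lines are the group means or medians
computed once upstream, and the statistic annotated on a density plot is
the global adaptive test's — nothing is recomputed at plot time. Every
figure writes a sidecar TSV of exactly the coordinates drawn, which is what
the tests assert on. Adjusted p-values are floored at 1e-300 before −log10.
Six named two-color heatmap ramps are supported (red_green, green_red,
blue_green, green_blue, blue_red, red_blue); anything else is rejected.
The MA plot's x-axis is the n-weighted mean tail length across both groups
(a knob in `prepare_plot_points` callers can change by precomputing).

## Synthetic experiments

The generator draws per-gene, per-sample tail lengths from a chosen family
— truncated normal (default), lognormal, or shifted negative binomial —
rounds to integers ≥ 1, and plants per-group mean shifts in a designated
gene set. Defaults: baseline mean 70 nt, sd 25 nt (the middle of the
50–100 nt range typical of eukaryotic mRNA), 2 groups × 3 samples ×
60 genes × 30 reads. Optional duplicate (×2) and multimap (×3) fractions
re-emit a read on additional transcripts with the same tail length,
exercising the QC taxonomy. BAMs are written with a dummy 50-nt sequence
(the tail estimate lives only in the tag, as in real basecaller output),
first occurrence primary and subsequent occurrences flagged secondary.

What the generator does *not* emulate: basecalling error in the tail
estimate itself (lengths are exact draws), transcript-abundance skew,
coverage differences between samples, fragmented or chimeric reads, and
tail-length/expression coupling. Passing tests therefore demonstrate the
correctness of the accounting, the statistics and the pipeline plumbing
under the stated distributional families — not robustness to every artifact
of real nanopore data.

## Problem sizes and acceptance runs

The acceptance script uses 120 genes × 6 samples × 25 reads for the
end-to-end pipeline (18,000 reads), 200 features × 30 reads/group for null
calibration, and 100 random small-sample datasets for the enumeration
check — sizes chosen so each property is measured with comfortable
statistical resolution while the whole run stays interactive. Sensitivity
and FDR are reported against the planted truth; with a −20 nt shift at
sd 10 and n = 75/group the planted effect (d = 2) is essentially always
detectable, so sensitivity near 100% and FDR near the BH-controlled level
are the expected outcome, not a tuned one.

## Known limitations

* Gene/transcript analysis requires transcriptome-space alignments; BAMs
  aligned to a genome support only the global comparison.
* No differential *expression* testing on the count matrix, no paired
  designs, no permutation tests.
* The Hommel adjustment is delegated to statsmodels and is O(m²); avoid it
  for very large feature sets.
* PCA requires every retained feature to be observed in all samples; very
  sparse designs may drop most features.
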