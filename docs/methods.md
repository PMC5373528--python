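# Methods

This note documents the models behind each stage of `zfscreen`, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Library model and site-frequency expectations

Fingers are abstract tokens bound to 5'-GNN-3' triplets; protein-level
affinity is deliberately out of scope. A 3F array is an ordered triple of
fingers, and its predicted 9-bp site concatenates the three triplets. The
triplet order of the printed site relative to finger order (protein
N→C polarity vs 5'→3' DNA) is a genuine ambiguity; the default
`orientation="as_printed"` puts position 1 leftmost (5'), reproducing how
screen isolates' sites are conventionally written, and
`orientation="reversed"` models the opposite polarity. Subpools are
numbered 1–16 by the founder's lexicographic triplet rank (no authoritative
pool→founder table exists); the GAA-founder pool is flagged as never
constructed.

Expected site frequencies use a linear (per-window Bernoulli) model:
the per-window *double-stranded* rate is defined as the sum of the
forward-match and reverse-complement-match probabilities — i.e. expected
strand hits per window, matching a scanner that reports one hit per strand.
For an exact 9-mer (no odd-length DNA word equals its own reverse
complement) this equals 2·4⁻⁹, giving the 4⁹/2 = 131,072-bp spacing; for
heavily degenerate patterns the two strands' hit sets can overlap within a
window, and the hit-rate definition keeps the identity
`spacing × per-bp hit rate = 1` exact. Word self-overlap corrections
(which affect the variance, not the mean, of occurrence counts) are
ignored; at genomic scales the approximation error is far below Monte-Carlo
noise. Base composition defaults to equiprobable; `base_probs_from_gc`
builds a strand-symmetric composition from a GC fraction.

## Degenerate scanning

A pattern is a 9-bp GNN-GNN-GNN consensus plus a per-triplet mismatch
budget (0–2) at the two N positions; G anchors never mismatch. This is a
*per-triplet* budget, not a global one: allowance 1 admits 7 words per
triplet (343 total), allowance 2 all 16 (4096 = the GNN consensus). The
scanner encodes sequences numerically and evaluates all windows
vectorially; 'N' bases never match an anchor and count as mismatches at N
positions. All overlapping matches are reported, and a window matching on
both strands yields one hit per strand. Tests hold the scanner equal to an
explicit per-window oracle across lengths and allowances.

Enrichment of a gene set's promoters is tested two ways. The binomial null
treats each 9-bp window of the target promoters as a Bernoulli trial at
the pattern's double-stranded match probability under the universe's
empirical base composition — fast, slightly approximate (windows overlap
and are not independent). The permutation null draws equally sized gene
sets uniformly from the universe and reports the upper-tail fraction with
the (r+1)/(n+1) pseudocount, which never returns zero and is exact up to
Monte-Carlo error; default 1000 permutations, explicit seed. The two
agree closely in rank (ρ > 0.9 in the acceptance checks) when background
hit counts actually vary; for near-zero background rates (exact 9-mers in
small universes) both collapse to p = 1 except under planting.

Promoters default to the 1000 bp immediately upstream of the annotated
start (0-based half-open; the gene's strand selects the genomic strand
when extracting from a genome with `extract_promoters`). No trimming for
overlaps with neighbouring genes is applied.

## Growth screening statistics

Relative RSA divides each plant's rosette area by the mean control area
(×100%), so the control population has mean exactly 100%. The relative
growth rate is the least-squares slope of ln(area) against day, by default
over the 10–28 dpg window in which rosette growth is near-exponential; it
is invariant to area-unit changes. T1 selection keeps plants ≥ 1.8× the
tray mean (the mean includes the candidate — "tray average" unqualified);
T2 selection keeps lines whose mean RSA is ≥ 1.2× the control mean at the
selection day (25 dpg); ties at either threshold are selected. Group
comparisons use Welch's unequal-variance t-test (scipy, with
Welch–Satterthwaite df) at the screen's 0.05 threshold; two zero-variance
samples with equal means return p = 1 by convention. The 4×6 tray grid
yields 4/24, 12/24 and 8/24 cells with 2, 3 and 4 rook-adjacent
neighbours; degenerate 1×n grids have cells outside all three classes, so
fractions are reported per class rather than forced to sum to one.

## Count-level transcriptomics

**Size factors.** Robust library-size estimation uses the trimmed mean of
M-values: against a reference sample (the one whose 75th count-proportion
percentile is most typical), per-gene log2 proportion ratios are trimmed at
30% per tail, mean log abundances at 5% per tail, and the surviving genes'
precision-weighted mean M gives the sample's factor; factors are
normalized to geometric mean 1 and multiply the raw depth to give an
effective library size. When heavy ties push entire rank blocks outside the
trim window (only possible in near-duplicate data), the untrimmed weighted
mean is used. Normalized expression divides counts by the relative
effective depth and by the gene's mean transcript length in kbp, so
doubling every count of a sample leaves its values unchanged.

**Active expression.** Per sample, the log2 distribution of positive
values is smoothed with a Gaussian KDE (Scott bandwidth); the density
maximum locates the active-population mode μ, and σ is estimated from the
right half-width as (mean of values above μ − μ)·√(π/2), the half-normal
correction. A gene is active in a sample when its z-score exceeds
z_min = −3, and globally active when active in every replicate of at least
one group. The defaults (z_min, the all-replicates rule, the 100-positive-
gene minimum for density support) are exposed parameters. All-equal
degenerate distributions raise a diagnostic error rather than returning an
arbitrary threshold.

**Differential expression.** The test is a deliberately transparent
negative-binomial Wald test, not a wrapper around an external DE package:
counts are scaled to common effective depth; per-gene NB dispersions come
from the method of moments, φ̂ = (s² − m)/m² pooled over both groups and
clipped at 0; the per-gene value is shrunk toward the common (mean)
dispersion with weight 0.8. The Wald statistic is
z = (log m_a − log m_b)/√(V_a + V_b) with V_g = (1/n_g)(1/m_g + φ), the
delta-method variance of the log of an NB mean; means carry a 0.5
pseudo-count so zero-count groups stay finite, genes with identical group
means are assigned p = 1, and two-sided normal p-values follow.
Positive log2FC means up in the line (first group) versus control. The
shrinkage default was set so the test meets its calibration contract —
empirical type-I ≈ 0.05 on null NB data at n = 3 — while retaining
per-gene dispersion signal; exact replication of any particular external
DE tool's p-values is a non-goal, calibration and planted-effect recovery
are the contract. BH adjustment is the standard step-up procedure
(statsmodels), and DEG calling uses adjusted p < 10⁻⁴ by default with an
optional fold-change criterion.

**Set algebra and enrichment.** Venn partitioning counts every membership
region (regions sum to the union); background subtraction computes
(∩ line DEG sets) − (∪ background-pool DEG sets), the operation that
strips effector-generic responses. Category enrichment is the upper-tail
hypergeometric probability of the observed number of labelled genes in the
set against a labelled universe — a generic replacement for GO-database
queries that works with any user-supplied boolean annotation.

**QC and qPCR.** Replicate QC flags samples whose Euclidean distance on
log2(x+1) to the component-wise *median* of their group's replicates
exceeds the median distance by 5 MADs; the median centroid keeps a single
bad replicate among three from masking itself. Flagging only — exclusion
is a user decision. qPCR relative expression is E^(mean(Cq_ref1, Cq_ref2) −
Cq_target) with efficiency E ∈ (1, 2], default 2; averaging reference Cq
values is equivalent to the geometric mean of the reference expression
values, the convention adopted for the stated "average of the reference
expression values".

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed). Promoters are i.i.d.
bases at a set GC content with at most one exact site planted per promoter
at a uniform position/strand. Counts follow NB laws with log-normal
baseline means (median 100, log-sd 1.5 — a realistic dynamic range whose
low-expression shoulder gives the active-expression threshold two modes to
separate), dispersion 0.05, three replicates per group, log-normal depth
variation (CV 0.1), planted line-specific DEGs (2% of genes per line,
4-fold, random sign) and a shared background DEG set (5%) carried by every
transgenic group including the background pool. Growth is exponential with
multiplicative log-normal noise sampled every 3 days over 10–28 dpg.

None of this emulates real-data pathologies: promoter sequence is
composition-homogeneous (no CpG/TA structure, no shared cis-elements
between co-regulated genes), counts have no GC/length bias, no outlier
samples unless constructed, no correlated genes; growth noise is
independent across days. Passing tests therefore demonstrate correctness
of the statistics under their own assumptions, not robustness to every
artefact of real screens.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale sizes chosen to give
stable statistics: 2000-gene matrices, 200 null replicates for
calibration, 5 simulations (10 contrasts) for recovery, 10 Mbp for the
Monte-Carlo spacing check, 200 gene sets × 120 permutations for the
null-agreement check. Every stochastic step is seeded; the acceptance
script derives all seeds from its `--seed` argument.

## Known limitations

- The binomial enrichment null ignores window overlap and promoter-length
  heterogeneity beyond total window count; the permutation null is the
  recommended reference when the two disagree.
- Method-of-moments dispersion with n = 3 is noisy; heavy shrinkage makes
  the test behave like a common-dispersion test, which can lose power for
  genuinely high-dispersion genes and be slightly liberal for low ones.
- The active-expression σ estimate assumes the high mode is approximately
  half-normal above its peak; strongly skewed active populations shift μ.
- Occurrence expectations are means; observed counts of self-overlapping
  degenerate patterns have larger variance than Poisson.
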