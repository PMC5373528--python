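# zfscreen

Analysis toolkit for **zinc-finger artificial-transcription-factor (ZF-ATF)
genome-interrogation screens** in plants.

In genome interrogation, libraries of artificial transcription factors —
arrays of three zinc-finger modules (3Fs), each module binding one
5'-GNN-3' DNA triplet, fused to an activator (VP16) or repressor (EAR)
domain — are transformed into Arabidopsis to perturb genome-wide expression
at random, after which plants with a phenotype of interest (here: enlarged
rosettes) are selected and characterized. `zfscreen` implements the
computational stages of such a screen:

- **Library combinatorics** (`zfscreen.zf_library`): the 16 GNN-binding
  fingers span 16³ = 4096 ordered 3F arrays, organized as founder subpools
  of ≤ 256 members. An exact 9-bp site, counted on both strands of random
  equiprobable DNA, recurs once per 4⁹/2 = 131,072 bp, i.e. ~10³ times in
  an Arabidopsis-sized (1.3×10⁸ bp) genome.
- **Degenerate motif scanning** (`zfscreen.scanner`): 9-bp GNN-GNN-GNN
  patterns with a per-triplet mismatch allowance at the N positions
  (matching 1, 7³ = 343 or 16³ = 4096 words at allowances 0/1/2), scanned
  on both strands; gene-set enrichment against a binomial null (per-window
  match probability under the universe's base composition) and a
  permutation null (equally sized random gene sets, upper-tail
  (r+1)/(n+1)).
- **Rosette phenotyping** (`zfscreen.growth`): relative rosette surface
  area (% of the control mean), relative growth rate (slope of ln area vs
  day over 10–28 dpg), the two-stage selection rules (T1: ≥ 80% above the
  tray mean; T2: line mean ≥ 20% above control at 25 dpg), Welch's
  unequal-variance t-test, and the 4×6 pot-grid neighbour design
  (~17% / 50% / ~33% cells with 2/3/4 rook neighbours).
- **Count-level transcriptomics** (`zfscreen.transcriptomics`): TMM-style
  robust size factors, per-kbp length normalization, kernel-density
  active-expression thresholding, a negative-binomial Wald test
  (method-of-moments dispersions shrunk toward the common dispersion) with
  Benjamini–Hochberg correction and DEG calling at adjusted p < 10⁻⁴,
  Venn partitioning, subtraction of effector-generic "background" DEGs
  ((∩ lines) − (∪ background pools)), hypergeometric label enrichment, and
  efficiency-corrected qPCR normalization
  (E^(mean(Cq_ref) − Cq_target)).
- **Synthetic data** (`zfscreen.simulate`): seeded generators for promoters
  with planted sites, NB count matrices with planted line-specific and
  shared-background DEGs, and exponential growth trajectories — every
  dataset ships with its ground truth, so each stage is testable end to
  end without any external download.

## Worked example

```sh
python examples/library_design.py
```

```
finger modules: 16 (GAA .. GTT)
full library: 4096 3F arrays; GAG-founder subpool: 256
exact site GGTGATGGA: one hit per 131,072 bp (both strands)
expected occurrences in a 1.3e8-bp genome: 992
```

Every 3F array addresses on the order of a thousand loci in an
Arabidopsis-sized genome — the reason a 4096-member library can interrogate
genome-wide expression. Planting that site into 20 of 300 random 1-kb
promoters and testing that gene set (`examples/motif_scanning.py`):

```
total GGTGATGGA hits in 300 promoters: 21
target-set hits: 20 (expected 0.15)
binomial p = 1.37e-35, permutation p = 0.0010
random set, allowance 1: 88 hits (expected 77.7), permutation p = 0.132
```

The planted set reaches the permutation floor 1/(n+1); a random gene set
scanned with a degenerate (1-mismatch-per-triplet) pattern shows hit
frequencies consistent with random occurrence. The other examples cover
the growth screen (`examples/growth_screen.py`), differential expression
with background subtraction (`examples/differential_expression.py`) and
the end-to-end pipeline (`examples/full_pipeline.py`). A thin CLI mirrors
the library: `zfscreen design|scan|enrich|phenotype|de|venn|
enrich-category|qpcr|simulate|run`.

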