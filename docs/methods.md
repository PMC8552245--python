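# Methods

`dreamtargets` implements an integrative ChIP-seq + RNA-seq analysis that
classifies targets of the *C. elegans* DREAM co-repressors LIN-35/Rb,
LIN-36 and LIN-15B, and characterizes the resulting classes by gene-body
H2A.Z (HTZ-1), promoter H3K9me2, differential factor binding, germline
expression specificity, and promoter motif content.  This note records the
models, the parameter choices, and the limits of what the synthetic
validation demonstrates.

## Coordinate model

All internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted at the parse boundary.  Midpoints of even-length intervals are
the floor of the average (left-biased).  Book-ended intervals merge.
Intervals are clipped at chromosome start at parse time; right clipping is
deferred to operations that know the chromosome length.

## Peak calling

Candidate peaks are maximal runs where the Gaussian-smoothed coverage has a
negative central second difference and height at least `min_height`; runs
shorter than 3 bins are discarded.  Concavity rather than thresholding
separates summits that share a shoulder.  The smoothing sigma defaults to
75 bp — the order of the sonication fragment size (~250 bp) — and is a
config knob, since no single bandwidth is canonical.  Calls are invariant
to adding a constant (when `min_height` is raised by the same constant) and
to amplitude scaling, which the tests assert.

Replicate agreement uses overlap support in place of IDR (an external
published method, out of scope): candidates are the merged union of all
replicate peaks and survive when >= `min_support` (default 2) distinct
replicates overlap them by >= 1 bp.

Broad histone-mark domains use a sliding-window Poisson test against
max(global mean, local flank mean), with the scan window excluded from its
own local background.  The local window defaults to 20 kb: a background
window must be several times the largest domain expected, otherwise the
domain dominates its own background and can never reach the fold
threshold (a 10 kb window cannot call a 5 kb domain at fold >= 2).  Other
defaults: fold >= 2, min length 500 bp, upper-tail p < 1e-5.

## Quantification

Gene-body windows run from the 5'-most TSS advanced 500 bp in the direction
of transcription to the 3'-most TTS; genes shorter than 500 bp are
excluded.  Promoter-peak windows are peaks overlapping >= 1 bp of the
strand-aware 500 bp upstream of any transcript TSS.  "Coverage" is the mean
(or sum) of per-base normalized signal.  Where integer counts are required
downstream, summed coverage is divided by a fragment-length scale and
rounded; the divisor is 1 for the synthetic tracks (their replicate noise
is independent per base, so window sums are already Poisson counts) and
should be the mean fragment length for real fragment-correlated coverage.
The top-90% filter retains rows at or above the 10% quantile (linear
interpolation) of the reference sample; ties at the cutoff are kept.

## Differential testing

A plain negative-binomial Wald test (variance mu + alpha mu^2), without
fold-change shrinkage or outlier refitting:

* size factors by median-of-ratios over features positive in all samples;
* per-feature dispersion by method of moments on within-condition
  residuals of normalized counts, then a convex combination with a fitted
  mean-dispersion trend alpha(mu) = a0 + a1/mu, weighted df/(df+prior_df)
  with prior_df = 40.  The combination is arithmetic because the raw MoM
  estimate is approximately unbiased and log-space averaging would bias
  dispersions low (Jensen), inflating type-I error.  With 4+4 replicates
  the trend dominates, which is what keeps the null fraction of p < 0.05
  inside [0.04, 0.06] at 5,000 genes while planted 4-fold effects are
  detected at > 0.98;
* LFC = log2((mean_case + 0.5) / (mean_control + 0.5)); the Wald statistic
  is the difference of log means over its delta-method standard error,
  with two-sided normal p-values and Benjamini-Hochberg adjustment.

Threshold rules, applied with strict inequalities: expression up requires
padj < 0.01 and LFC > 0.5849 (log2 of ~1.5), down requires padj < 0.01 and
LFC < -1; gene-body H2A.Z loss requires LFC < 0 at padj < 0.001 on genes in
the top 90% of wild-type coverage; promoter H3K9me2 loss requires LFC < 0
at padj < 0.01; differential binding requires padj < 0.001 with the LFC
sign giving the direction.

## Target taxonomy

A peak is assigned to a gene when it overlaps the window from the gene's
furthest-upstream annotated promoter (strand-aware; only 5'-side promoters
extend the window) through the gene's 3' end, falling back to the gene span
for promoter-less genes.  A peak may map to several genes and contributes
to each.  Direct targets of a factor are genes upregulated in that factor's
mutant and carrying an assigned peak for the factor.  LIN-36-shared targets
are direct targets of both LIN-35 and LIN-36 not upregulated in *lin-15B*;
LIN-15B-shared targets are direct targets of both LIN-35 and LIN-15B not
upregulated in *lin-36*.  The two classes are disjoint by construction
whenever direct sets are subsets of their up sets.  Overlap enrichment
between gene sets is fold = |A∩B| / (|A||B|/|U|) with an upper-tail
hypergeometric p; the default universe is all genes with nonzero total
counts, a choice the data do not dictate and which is configurable.

Germline expression specificity is germline TPM over summed TPM across all
cell types; all-zero genes are flagged undefined and excluded from tests.
Class comparisons use the two-sided Wilcoxon rank-sum test (exact null when
min(n) <= 10 without ties, tie-corrected normal approximation otherwise);
expression-shift comparisons use Welch's t.

## Motif analysis

Scanning follows FIMO conventions: log2-odds against a 0-order background
(default uniform; configurable), both strands, windows containing N
skipped, hits reported at p <= 1e-4.  Per-hit p-values are exact:
P(score >= s) under the background, computed by dynamic programming over
the score lattice discretized at 1e-3 bits — the only approximation, and
the tests validate it against exhaustive 4^L word enumeration.  Zero PWM
entries are floored at 1e-4 before log-odds.  Overlapping hits on a peak
are resolved by the family hierarchy CDE-CHR > LONG > E2F (best p within
the winning family); a motif enters downstream analysis only when present
in strictly more than 30% of at least one peak class; class association
uses two-sided Fisher tests with BH correction.  The bundled PWMs are
synthetic consensus-based stand-ins for the seven motif variants (an
E2F-like GCGC-core family, a bipartite CDE-CHR-like element with a TTTGAA
CHR half, and an 18-bp LONG family), not published matrices.

## Synthetic data

The generator plants a machine-readable ground truth.  Default scenario:
1,000 non-overlapping genes on a 3 Mb chromosome (3 kb pitch, so promoters
and 200 bp peak windows never collide across neighbours), 150 LIN36_shared
/ 50 LIN15B_shared / 100 LIN35_only genes, derepression LFC 2, NB
dispersion 0.1, 4 replicates per expression condition, and 2 ChIP
replicates (matching common practice for factor ChIP).  Genes carry 1-3
transcripts; 90% have one annotated promoter ([TSS-500, TSS)).

ChIP tracks are Gaussian peaks (sigma 75 bp) at promoter summits on a flat
background of 0.25, with per-base Poisson replicate noise.  Class structure
drives co-binding: LIN36_shared promoters carry LIN-35 + LIN-36 peaks
(amplitude 25), LIN15B_shared promoters LIN-35 + LIN-15B peaks (amplitude
12 — the weaker signal observed at germline-class targets), LIN35_only
genes a LIN-35 peak; decoy peaks on null genes co-bind LIN-35 at rates
0.95 (LIN-36) and 0.72 (LIN-15B).  Binding changes are planted as
multipliers: LIN-35 signal halves at 60% of LIN36_shared peaks in
*lin-36*, LIN-15B signal doubles at 60% of LIN15B_shared peaks in
*lin-35*.

RNA counts are NB with per-gene lognormal base means (median 150, sigma
0.7, clipped to [20, 5000]): LIN36_shared genes go up in *lin-35* and
*lin-36* only; LIN15B_shared in *lin-35*, *lin-15B* and *met-2*;
LIN35_only in *lin-35* only.  Histone-mark tables are deep-coverage
pseudo-counts (mean 800, dispersion 0.02 — gene-body/promoter windows pool
many fragments, so their replicate dispersion is far below gene-level
RNA): LIN36_shared gene bodies are 3x enriched for H2A.Z in wild type and
70% of them lose half their signal in *lin-35*/*lin-36*; LIN15B_shared
promoters are 4x enriched for H3K9me2 and 60% lose half in *lin-15B* (40%
in *lin-35*).  The promoter H3K9me2 table is keyed by target gene (one
promoter-peak feature per promoter-bearing gene).  The cell-type TPM table
gives LIN15B_shared genes a germline share of 0.8; other genes draw
Beta(1, 9) shares.  Motif consensus instances are planted into shared-class
promoter-peak windows (>= 30 bp from the edges, so rescaled called-peak
windows still contain them) at class-specific rates.

Every generator stage draws from `default_rng([seed, crc32(stage)])`, so
outputs are deterministic given the seed and independent of stage order.

What the synthetic data does **not** emulate: mappability/GC structure,
fragment-length autocorrelation in coverage (hence the count divisor of 1
above), repeat-driven artefactual peaks, isoform-level expression,
unbalanced library sizes beyond what Poisson thinning induces, and any
dependence between classes beyond the planted rules.  Passing the planted
recovery tests demonstrates that the pipeline's logic and statistics are
correct under its own assumptions; it does not certify performance on real
ChIP-seq, where normalization and peak-calling artefacts dominate.

## Numerical choices and degenerate inputs

All combinatorics in log space (p-values down to ~1e-300 are exact in the
scipy backends).  All-zero features get LFC 0, p 1.  Degenerate 2x2 tables
(a zero margin) get p 1 and an undefined odds ratio.  Empty query sets give
overlap fraction 0 with a warning.  Dispersions are clipped to
[1e-8, 10].  The Wilcoxon exact branch requires min(n) <= 10 and no ties.
Quantile cutoffs use linear interpolation with ties kept.  BH output is
capped at 1.

## Known limitations

* The NB test is not numerically identical to DESeq2 (no LFC shrinkage, no
  Cook's-distance outlier handling); it is validated by calibration and
  power on synthetic data instead.
* The binding-change stage has modest power with 2 ChIP replicates and
  weak peaks; the default scenario plants 2-fold changes on strong peaks,
  where recovery is complete.
* Multi-bandwidth concave calling (union over smoothing scales) is a noted
  possible extension; a single default bandwidth is used.
* Peaks on unplaced contigs or organellar chromosomes are not treated
  specially; exclude them upstream if needed.
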