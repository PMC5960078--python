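# Methods

`brmmode` re-implements, as a tested pipeline, the analysis by which target
genes of the Drosophila SWI/SNF remodeler's ATPase subunit BRM are classified
into ATPase-dependent and ATPase-independent regulatory classes. The study
design it models is a four-condition rescue experiment in S2 cells: dsGFP
control, dsBRM depletion, and dsBRM plus re-expression of either wild-type
BRM or the catalytically dead K804R mutant. This note records the models, the
parameters that matter, and the choices made where the design was open.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on read and write, BED passes through unchanged. This removes
off-by-one ambiguity at the cost of one conversion at the boundary. Coverage
is held per-base (`CoverageTrack`), read from and written to bedGraph with a
chrom.sizes sidecar; overlapping bedGraph intervals are an error by default
(an opt-in "last wins" mode exists) because silent overwrite hides corrupt
input. The promoter window is the region from 50 bp to 10 bp upstream of the
TSS, both ends inclusive (41 bp), reported 5'→3' of the gene. Alternative
TSSs are supported in the promoter analysis only, as extra windows named
`gene@k`; the core binding/classification path uses one interval per gene.

## Gene-level binding calls

The enrichment score of a gene is

    score = (mean IP over [start − 200, end + 200) + c) / (mean Input + c)

a ratio of means, not a mean of per-base ratios: it is defined even where
Input is locally zero and corresponds most directly to an average fold
change over the scoring region. The flank default of 200 bp covers the
TSS-upstream and polyadenylation-site-downstream margins on either strand.
The pseudocount `c = 0.5` (raw coverage units) stabilizes low-coverage genes
and keeps the null ratio at 1; it is exposed as a parameter, and formal
scale invariance of the score holds in the limit c → 0. A gene is bound when
score ≥ 1.1 (inclusive). Replicate IP or Input tracks are summed before
scoring, the coverage-space analogue of merging replicate alignments.
Length classes are short < 1.5 kb, long > 15 kb, medium otherwise; the
boundary values fall in the medium class because the defining inequalities
are strict.

## Differential expression

The DE stage is a self-contained empirical-Bayes moderated t on log2-CPM
(`log2(CPM + 0.5)`). For each gene the pooled within-group variance s²_g with
d = nA + nB − 2 degrees of freedom is shrunk toward an inverse-gamma prior,

    s̃²_g = (d0·s0² + d·s²_g) / (d0 + d),

with (s0², d0) estimated by moment-matching the distribution of log s²_g:
writing e_g = log s²_g − ψ(d/2) + log(d/2), the mean and variance of e_g
identify log s0² and d0 through the digamma/trigamma functions, and d0 is
obtained by Newton inversion of the trigamma function. When the observed
spread of e_g does not exceed the chi-square floor, d0 is taken as infinite
and all genes share s0². The moderated statistic
t̃ = Δmean / (s̃·√(1/nA + 1/nB)) is referred to a Student t with d0 + d
degrees of freedom (normal in the d0 = ∞ limit), two-sided. The test suite
verifies this implementation digit-for-digit against limma's `eBayes` on the
same matrix, and checks its calibration by simulation (null type-I error,
power at |log2FC| = 2, dispersion 0.1, 3 replicates).

Multiple testing uses Benjamini–Hochberg step-up, implemented from the
definition q_(i) = min_{j≥i} p_(j)·m/j and cross-checked against both a
brute-force loop and statsmodels. Significance is q < 0.05 (strict), with no
fold-change cutoff; the threshold is a parameter. Each contrast is one
condition versus the dsGFP control, computed independently; genes with zero
counts across a contrast's samples are dropped from that contrast before
prior estimation. Moderation with shrinkage keeps the test usable at the
study's own depth of two biological replicates.

## Target classification

The classification is pure set logic on per-gene flags (bound; signed DE
calls in the wild-type-rescue, mutant-rescue and depletion contrasts):

* target ⇔ bound ∧ DE in the wild-type contrast;
* ATPase-independent ⇔ target ∧ DE in the mutant contrast with the same
  sign as in the wild-type contrast;
* ATPase-dependent ⇔ target ∧ not independent. Genes significant in both
  contrasts with opposite signs react differently to active and inactive
  BRM and therefore fall in the dependent class — this keeps the partition
  exact (dependent + independent = targets, asserted on every run).

Gene universes from binding and DE are reconciled by intersection. The
depletion control counts independent-class genes that also respond to BRM
depletion alone; a small count supports the interpretation that the mutant
rescue acts through the mutant protein rather than through residual BRM
loss. The percentage of independent targets is reported to two decimals.

## Metagene profiles and group comparison

Each gene body is rescaled to B = 100 bins (near-equal bp widths, the
remainder of length ÷ B spread one bp at a time over the leading bins);
fixed 1 kb flanks contribute F = 50 bins of 20 bp each side, and the axis is
reversed for − strand genes so it always runs 5'→3'. Genes shorter than B bp
are skipped and logged rather than up-sampled, avoiding interpolation
artifacts. Group averages apply a robustness filter that removes the genes
above the (100 − 0.5)th expression percentile before averaging (a two-sided
variant is available): a single extreme gene otherwise dominates a group
mean.

Group-versus-group significance uses a two-sample Kolmogorov–Smirnov test.
D is the exact supremum ECDF difference; the p-value uses the asymptotic
Kolmogorov distribution at D·√(n_eff), n_eff = nx·ny/(nx + ny). Because the
underlying per-gene quantity is not uniquely determined by the plots being
emulated, the test is run on per-gene mean signal over a named window (gene
body, TSS ± 200 bp, or TES ± 200 bp), and the window is stated in the
output.

## Promoter hexamers and TATA boxes

All 4⁶ = 4096 hexamers are counted over the promoter windows with
overlapping occurrences allowed (step 1, the standard k-mer convention); a
hexamer's antisense count is the sense-strand count of its reverse
complement, so the table satisfies r(h) = −r(revcomp(h)) exactly, with
r = log2((S + 1)/(A + 1)) (the +1 guards zero counts). N bases block any
overlapping hexamer. The TATA-box frequency is the fraction of genes whose
window contains TATAAA at least once (each gene counts once, across all its
alternative-TSS windows), compared against a genome-average baseline of 19%
with an exact two-sided binomial test (minimum-likelihood form). The
alternative-motif set defaults to TATAAA plus its A→T substitutions at
positions 4–6 (TATTAA, TATATA, TATAAT) and is configurable, since no
canonical list of alternative TATA sequences exists.

## Nucleosome-change clustering

MNase control and depleted tracks are each rescaled to genome-wide mean 1
before differencing — without this, library-depth differences masquerade as
occupancy change. Per-gene Δ profiles (depleted − control) are binned on the
metagene axis, and the ATPase-independent genes are partitioned by k-means
with k = 2 (two clusters are the reported structure), Euclidean distance on
the gene-body bins only (Cluster 1 is defined by gene-body gain, so flanks
are excluded from the distance), 10 restarts, seeded. Genes enter in
sorted-id order, making the result independent of input order; the cluster
with the larger mean body Δ is labelled Cluster 1.

## Synthetic data: what it emulates and what it does not

The generator lays out non-overlapping genes on one synthetic chromosome
with log-normal lengths (median 3 kb, σ = 1) so all three length classes are
populated; real-genome length proportions are not enforced. It plants, per
gene: bound status (IP = Input × enrichment fold over the body ± 200 bp,
default fold 1.5), signed log2 effects per contrast encoding the
target/independent/dependent structure, TATAAA presence in the promoter
window at class-specific frequencies (7.4% dependent, 9.3% independent, 19%
background — the published class rates; accidental motifs are scrubbed from
non-planted windows so the planted frequency is exact), and a Cluster-1
flag giving a +1.5 gene-body occupancy gain in the depleted MNase track,
with a 40% occupancy drop upstream of every TSS upon depletion. Counts are
negative binomial with fixed dispersion 0.1 (no dispersion trend) at depth
10⁶ per sample and two replicates per condition, matching the study's
design; calibration simulations use three replicates where stated. Input
coverage is a smoothed positive baseline with multiplicative gamma noise
(cv 0.05 on IP by default).

All randomness flows from one seed through spawned generator streams;
identical configurations give identical outputs, and each written file
carries the config hash in a header comment.

The generator does not emulate read-level artifacts (mappability, GC bias,
duplicates), peak-shaped binding, dispersion trends, batch effects, or real
promoter sequence composition. Passing tests therefore demonstrate that the
pipeline's logic and statistics behave as specified under the stated noise
model — not that the thresholds would reproduce the published gene lists on
resequenced data. The published sequencing-derived quantities (genome-wide
bound-gene totals, real K-S p-values, the 62/205 cluster sizes) are outside
desk scale by construction; the published classification arithmetic itself
is reproduced exactly on the fixed count fixture.

## Problem sizes and numerics

Simulation-based checks run at 200–400 genes on a ~2 Mb chromosome, 20
seeds for calibration rates; these sizes give stable rates while keeping
the full suite fast. k-means ties and degenerate (all-identical) profiles
resolve deterministically under the seed. The trigamma inversion uses
Newton iteration to 1e-10 relative tolerance; BH uses a stable mergesort so
tied p-values keep input order. Known limitations: the binding caller has no
peak model, so partial-gene binding is diluted over the scoring region; the
moderated test assumes a common variance prior without trend; k-means
assumes roughly spherical clusters on the Δ bins.
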