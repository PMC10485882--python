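# Methods

## Strand-aware editing classification

Adenosine deamination yields inosine, read as G by reverse
transcriptase; cytidine deamination yields uridine, read as T. An
off-target event therefore appears as A→G (A-to-I) or C→T (C-to-U) on
the *transcribed* strand, which on the genomic forward strand means
A→G / C→T for `+` genes and T→C / G→A for `−` genes. The classifier
resolves the strand from the gene whose span ± 10 kb covers the
variant, picking the gene with the most specific region when several
overlap (CDS exon > 5′UTR > 3′UTR > non-coding exon > intron >
up-10 kb > down-10 kb; ties are kept with a multi-gene flag). A site
covered by genes on both strands whose strand-resolved classes
disagree is `ambiguous`: it is counted in genome-wide distributions
but excluded from coding-effect and association analyses, avoiding
double counting. Variants overlapping no gene territory are classified
on the `+` strand convention and flagged hostless, so chromosome-wide
tallies drop nothing; this convention is recorded in the distribution
output metadata.

Editing efficiency at a site is alt/(ref+alt) per sample; group
efficiency is the unweighted mean over replicates (not pooled depths).
A sample with zero coverage has an *undefined* frequency — never 0 —
and is excluded and reported.

## Regions and coding effects

Each (variant, feature) pair receives exactly one region by the
precedence above; `exon` is reported for CDS and non-coding exons
alike in region tallies, while the coding-effect classifier
distinguishes them. The CDS (stop codon included) is spliced in
transcript order, reverse-complemented for `−` genes, and the affected
codon located by CDS offset, so codons spanning exon junctions are
handled transparently. Effects form a three-way partition: silent
(amino acid unchanged, including stop→stop), nonsense (sense→stop),
missense (everything else, including stop-loss). The classifier is
validated exhaustively against enumeration over all 61 sense codons ×
3 positions × 12 substitutions; two structural facts of the genetic
code are load-bearing for interpretation: A→G cannot create a stop
codon (A-to-I events are only silent or missense) and C→T creates
stops exactly from CAA, CAG, CGA.

## Normalization and differential expression

Per-class units follow the assay: FPKM = count / (length_kb ×
library_millions) for mRNA and lncRNA, RPM = count / library_millions
for circRNA back-splice-junction counts, TPM (tags per million; each
column scaled to 1e6) for miRNA. Library size is the column sum of the
class's own matrix — the per-class mapped totals of the original
libraries are not recoverable from count matrices, and this proxy is
recorded in output metadata.

The DE test is deliberately simple and fully specified: two-sided
Welch t on log2(normalized + 0.5), log2 fold change from group means
of normalized values with the same pseudo-count 0.5, BH adjustment
within each RNA class, and calls at log2FC > 1 / < −1 with q < 0.05.
The 0.5 pseudo-count avoids log(0) and bounds fold changes from
all-zero groups. Features with all-zero counts in both groups are
excluded; surviving zero-variance features get p = 1. The module
boundary admits swapping in a negative-binomial GLM without touching
callers.

The default contrast pools the three editing conditions (9 samples)
against the pooled eGFP + WT controls (6 samples); any subset is
selectable via `contrast.treated_groups`. The pooled default is a
power decision: with a per-gene Welch test at 3 vs 6 replicates, a
2-fold planted change at NB dispersion 0.1 is recovered with
sensitivity only ≈ 0.5 after BH, versus ≈ 0.99 under the pooled
contrast at the same per-group replication.

BH is implemented once (`editscape.stats.bh_adjust`) and reused by DE,
association and enrichment. q-values are clamped to q ≥ p, which the
step-up definition implies mathematically but raw floating-point
evaluation of p·m/j can violate by one ulp.

## SNV-frequency / expression association

Per feature, off-target SNVs of one editing channel within span
± 10 kb are collected ("inside, upstream, and downstream", matching
the up-/down-10 kb region definition). A variant enters the test only
if every control sample has a defined frequency (total depth ≥
`min_depth`, default 20, the coverage selection standard) that is
exactly 0 — an observed zero, not missing data. The correlation is
Pearson (Spearman selectable) between per-sample frequency and log2
normalized expression over the treated replicates plus the control
replicates; controls anchor the zero-frequency end. Samples with
undefined frequency are dropped pairwise; fewer than 3 usable samples
or zero variance skips the variant with a logged reason. The
feature-level p is the best variant p Bonferroni-corrected by the
number of variants tested within the feature (conservative and
order-independent), FDR is BH across features within one editing
channel × RNA class stratum, and significance requires P < 0.05 and
FDR < 0.5. The 0.5 FDR cutoff is deliberately permissive and kept as
the default for fidelity to the published procedure; a warning is
logged and the threshold is configurable. WT samples are excluded from
the zero-filter and the correlation by default (`control_groups =
("eGFP",)`), configurable.

## Interaction networks and enrichment

Nodes are the SNV-associated DE features, typed DEG/DEC/DEL/DEM. The
edge rule is co-expression: |Pearson r| ≥ 0.9 and p < 0.05 on log2
normalized expression across the common sample set. This is this
package's own edge definition — no claim is made that it reproduces
any particular published interaction semantics (target-prediction or
database-derived edges would need external resources). Tallies count
DEC–DEG, DEL–DEG and DEL–DEC edges and DEL–DEC–DEG triangles; DEM
nodes stay in the graph but are not tallied. At the default synthetic
scale the network is sparse and often empty: two features coupled to
the same variant at coupling strength r each correlate with each other
at only ≈ r², i.e. ≈ 0.81 for r = 0.9, below the 0.9 edge threshold.
That threshold is kept deliberately high to keep synthetic networks
sparse; tally correctness is guaranteed by exact equivalence to
brute-force triangle enumeration, not by fixture density.

Enrichment is hypergeometric upper-tail over-representation of a study
list in user-supplied GMT sets (each set intersected with the
universe), BH-adjusted across sets.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not sequencing reads:

- **Design**: groups (CTNNB1, KRAS, non-target, eGFP, WT) × 3
  replicates; all parameters in `SimulationConfig`. One global seed is
  split into named per-stage substreams (CRC32 of the stage name), so
  stages regenerate independently and identical configs produce
  byte-identical outputs.
- **Annotation**: random genome; coding genes with ATG…stop CDS
  (length divisible by 3, no internal stops), 5′/3′ UTRs ≥ 30 bp, ≥ 2
  exons; lncRNA genes without CDS; single-exon miRNA genes; circRNAs
  as contiguous exon runs of coding hosts (TSV sidecar). Strands are
  balanced. Adjacent genes are separated by more than twice the 10 kb
  flank so every position has at most one host territory — planted
  events have unambiguous intended hosts, making the
  classifier-vs-sidecar agreement test exact. Dual-strand ambiguity is
  exercised by constructed overlaps in unit tests instead.
- **Variants**: off-target events are placed in regions drawn from a
  configurable mix, with strand-consistent alleles; treated-sample
  frequencies are Beta(2, 6) draws (mean 0.25, a plausible bystander
  editing level; the study reports no off-target frequency
  distribution); control samples get alt depth exactly 0. One on-target
  A-to-I CDS site per guided condition carries tight Beta frequencies
  around the published 32.7% / 42.7% efficiencies. Intergenic decoys
  are germline-like hets (~0.5 VAF in all samples, controls included),
  exercising the `other`-class path and the control-zero rejection
  path. Per-sample depths are Poisson(20) truncated below at 20: the
  VCF emulates the *post-selection* callset of a 20× coverage
  standard, so reported sites meet the minimum-depth requirement by
  construction.
- **Expression**: counts ~ NB(mean, dispersion 0.1) with per-feature
  base means log-normal around 500; DE features (fraction `frac_de`,
  default 0.1) have treated-group means shifted by 2^±2; coupled genes
  (fraction `frac_coupled` of coding genes hosting a window variant)
  receive per-sample log2 shifts that are an affine function of that
  sample's planted variant frequency, with the slope solving
  r² = var(signal)/(var(signal)+var(noise)) under the delta-method NB
  log-count noise variance, so the population frequency–expression
  correlation is ≈ `coupling_r` in sign and magnitude.
- **Sidecar**: every planted variant (with intended class, region, and
  codon effect computed at planting time by the same genetic-code
  table the annotator uses), every planted DE feature, and every
  planted coupling appears exactly once in `ground_truth.json`.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: read-level error and alignment artifacts,
editing sequence context (ADAR neighbor preferences, codon-usage bias;
exon mutation-class fractions here follow the genetic code under
near-uniform codon usage), per-condition off-target catalogs with
partial overlap, isoform switching, library-composition effects, and
any causal structure beyond the planted monotone couplings.

## Numerical and interface choices

- Coordinates 1-based inclusive at every boundary (GTF/VCF
  convention); chromosome names must match exactly across files.
- One representative transcript per gene: longest CDS, ties by longest
  exonic span, then lexicographic transcript id.
- CDS includes the stop codon so stop-codon substitutions are
  classifiable within the three-class contract.
- Deterministic outputs: tables sorted on stable keys, JSON with
  sorted keys, manifests free of timestamps with input paths
  relativized to the output directory; re-running a config reproduces
  results byte for byte.
- Problem sizes in the test suite are desk-scale by design (tens of
  genes for end-to-end runs; 2000 genes/features for calibration and
  power checks), chosen so the whole suite runs in well under a
  minute while keeping Monte-Carlo error small relative to the
  asserted bounds.

## Known limitations

The DE test ignores count overdispersion sharing across genes (no
shrinkage), so it is conservative at small n relative to NB-GLM
methods. The association test treats variants within a feature by
Bonferroni, conservative when window variants are correlated. The
network edge rule is co-expression only. Enrichment assumes a
user-chosen universe and independence between sets.
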