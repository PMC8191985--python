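# Methods

## Design of the reciprocal-hybrid ASE analysis

The analysis targets F1 female hybrids of two highly inbred lines (in
haplodiploid insects, females are the diploid offspring; males are
haploid and carry no paternal genome, so all ASE work is restricted to
females). Because the lines are inbred, every informative site is a
*fixed difference*: homozygous reference in all replicates of line V and
homozygous alternate in all replicates of line G. Any heterozygous or
missing parental call disqualifies a site — with true inbreeding these
calls are genotyping noise or residual polymorphism, and a mistaken site
would contaminate allele assignment in every hybrid sample.
Multi-allelic records and indels are excluded outright rather than
decomposed: the pseudo-reference substitution step (below) is defined
for exactly one single-base alternate allele, and a site that is not a
clean biallelic SNP cannot be interpreted as "one allele per line".
Sites where the alternate line is homozygous for a third allele are
therefore also dropped (tallied in `excluded_counts`).

### Pseudo-reference

Mapping hybrid reads against one parent's assembly biases allele counts
toward the reference allele (reads carrying the alternate allele face an
extra mismatch). The pipeline builds a pseudo-alternate-line genome by
substituting the alternate base at every fixed-difference position.
Substitutions are SNP-only, so coordinates and the shared gene
annotation stay valid on both references. The builder refuses to edit a
position whose current base does not equal the recorded reference base —
this catches assembly/VCF version skew immediately rather than letting it
corrupt downstream counts. Two diffs at one position are an error, not
last-wins. `verify_pseudo_reference` recomputes the per-position
difference set from the two sequences and checks it equals the input
exactly; applying the builder to its own output with ref/alt swapped
returns the original genome (an involution, tested).

### Filtering and aggregation

Hybrid allele counts arrive as per-SNP, per-sample tables (allele-counter
output: contig, position, refAllele, altAllele, refCount, altCount,
totalCount). On ingestion the total is re-derived as refCount + altCount;
bases that match neither allele are ignored. Records are kept only at
fixed-difference positions **with matching alleles** — an allele mismatch
at a known site signals an inconsistency and is dropped and counted
separately from plain off-site records. The depth filter keeps records
with total ≥ 30 reads (inclusive). SNPs are assigned to every gene whose
full span contains the position (1-based inclusive ends); spans rather
than exons are used because allele counts from any transcribed region of
the gene are informative and the exon model may be incomplete. A SNP in
two overlapping genes counts for both, with the genes flagged ambiguous
(a strict mode discards such records; note that with double-counting the
count-conservation audit applies to unambiguous genes only).

Within each cross direction, counts are **summed** over SNPs and
replicates. Summation (rather than averaging per replicate) weights
observations by depth, yields the single per-hybrid allelic ratio the
analysis reports, and gives the Fisher test its natural counting units.
Per-replicate ratios remain available from the raw records for
dispersion QC. A gene is testable only with ≥ 2 informative SNPs in
*both* hybrids — one SNP cannot distinguish a genuine allelic bias from
a site-specific artefact.

### Testing and classification

The primary significance criterion is the two-sided Fisher's exact test
comparing pooled (ref-line, alt-line) counts between the two hybrids,
with BH FDR control at α = 0.05 applied across the testable set of each
dataset separately (the combined analysis gets its own BH family). The
per-hybrid binomial test against a 0.5 fraction is emitted as a
diagnostic only: a gene can deviate from 0.5 identically in both hybrids
(a symmetric cis effect) without any between-hybrid difference, and the
between-hybrid comparison is the quantity of scientific interest here.

Classification uses the reference-line allele fraction in each hybrid
(f_VG, f_GV). Imprinting calls require the two fractions on opposite
sides of 0.5 with a consistent parental direction; same-side fractions
are cis calls toward the favoured line. A fraction exactly at 0.5
carries no direction: the call falls to the cis side of the other
fraction, or to no-difference when both are tied. Note the detectability
limit this implies: a *perfectly symmetric* cis effect (same fraction in
both hybrids) produces no between-hybrid difference and is reported as
no-difference by design.

### Combined-dataset analysis

Two datasets genotyped against the same reference are combined by
intersecting their fixed-difference sets (positions must agree on both
alleles; disagreeing positions are dropped and logged), restricting both
record sets to the shared sites, pooling per gene and cross across
datasets, and rerunning the analysis. With identical inputs this reduces
exactly to the single-dataset analysis with doubled counts (tested).

## Genetic-map tools

Two linkage maps of the same chromosomes are reconciled by
piecewise-linear interpolation between markers anchored on both maps;
with exactly two anchors this reduces to a single conversion ratio.
Queries outside the anchor range extrapolate with the terminal segment's
ratio. cM-to-physical interpolation requires physically monotone anchors
and errors on the offending pair otherwise.

The introgression scan emulates a genotyping-array analysis of a strain
expected to carry line G's nuclear genome after repeated backcrossing. A
marker is usable only when both parental controls type correctly with no
missing control calls; a usable marker is flagged when **every** test
sample calls the V allele with none missing (missing or discordant test
calls disqualify — conservative by construction, so noise can only
shrink the flagged set, never grow it; tested as a property). A locus is
the interval strictly between the nearest usable non-flagged markers on
either side of a flagged run, extending to the chromosome end (or the
outermost marker, when no chromosome length is supplied) at termini.

Locus/gene-set enrichment uses the one-sided upper-tail hypergeometric
probability; the recommended universe is the ASE-testable gene set.

## Expression QC stage

The dual-reference design counts each sample against both genomes;
the elementwise mean of the two matrices is the working count matrix
(non-integer values are expected and accepted downstream). Genes are
kept when mean FPKM ≥ 0.5 within at least one sample group — the filter
keeps, not removes, adequately expressed genes, with the boundary
inclusive. FPKM uses exonic length (union of exons; gene span when an
annotation has no exon features — documented approximation). logCPM is
log2((count + 0.5) / (library + 1) × 1e6). PCA is scaled and centred
over genes with nonzero variance; proportions of variance sum to 1.

The differential-expression stage is a deliberately simple per-gene
Welch t-test on logCPM with BH correction and thresholds q ≤ 0.01,
|log2FC| ≥ 2 (both inclusive). It exists so the pipeline runs end to
end and its outputs have the right shape; it does not implement
precision weighting or variance moderation, and real studies should
substitute a dedicated DE package. Zero-variance genes get p = 1 (no
evidence, rather than NaN propagation).

## Synthetic-data generator

The generator emits data at the pipeline's actual input boundary —
allele-counter tables, a jointly genotyped parental VCF, count matrices,
a marker panel — not reads; read simulation would add no testable
surface since alignment and counting are upstream tools' jobs.

Study conditions (defaults): 3 parental and 3 hybrid replicates per
line/cross, 5 fixed differences per kb of gene (5 SNPs in a 1 kb gene),
per-SNP depth negative-binomial with mean 100 and size 10, allelic
effect ratio 0.8 for non-null classes, binomial allele sampling
(beta-binomial with intra-class correlation rho when overdispersion is
configured: variance n·p·q·(1 + (n−1)·rho), tested against the closed
form). Gene classes and their true reference-allele fractions per cross:

| class | f_VG | f_GV |
|-------|------|------|
| null | 0.5 | 0.5 |
| cis | e | (0.5 + e)/2 |
| paternal imprint | 1 − e | e |
| maternal imprint | e | 1 − e |

with e the effect ratio. The cis class is planted same-side but
*unequal* between hybrids: a perfectly symmetric cis bias is invisible
to the between-hybrid test (see above), and observed cis effects in
real crosses are of this unequal kind; the midpoint (0.5 + e)/2 keeps
the second hybrid clearly biased while remaining distinguishable from
the first.

Randomness flows from one seed through named substreams (genome, SNPs,
VCF, classes, ASE, counts, markers), each keyed by a hash of its name,
so enlarging one component never perturbs another and identical
configurations are byte-identical on disk. Genotyping errors convert a
parental call to heterozygous — the realistic failure mode, and the one
that breaks the fixed-difference rule; errors can therefore only remove
sites from the called set, never add false ones (tested).

What the generator does **not** emulate: linkage disequilibrium,
sequence-evolution realism, mapping bias itself (counts are generated
as if bias were already removed — the pseudo-reference stage is
verified structurally, not by simulating biased alignments),
inter-gene expression correlation, and batch effects. Passing tests
therefore demonstrate the statistical machinery and plumbing are
correct under the stated sampling model, not that any particular real
dataset satisfies that model.

## Numerical and testing choices

* Fisher's two-sided p sums hypergeometric probabilities ≤ the observed
  table's; the test suite checks exact agreement with an independent
  enumeration for every table with row margins ≤ 30, and transposition
  symmetry. Tables with a zero margin are not testable (no p-value).
* BH q-values are checked against the step-up definition on random
  p-vectors; input order is preserved.
* Null calibration at the study conditions (2,000 genes, 5 SNPs × 3
  replicates × depth 100 per cross): the raw Fisher rejection rate at
  α = 0.05 must sit within 3 Monte-Carlo standard errors of 0.05, and
  the fraction of replicates with zero BH discoveries must be ≥ 95%.
  The true clean-replicate probability under these conditions is ≈ 0.956
  (slightly above 1 − α because the exact test is discrete), so the
  calibration uses 10,000 replicates to make the Monte-Carlo error small
  against that ~0.6-point margin; repeated tables are memoised through
  the package's own Fisher routine.
* Recovery at the study conditions (100 imprinted genes at effect 0.8
  among 1,900 nulls, pooled depth 1,500): sensitivity ≥ 0.9 and
  category-label accuracy ≥ 0.95 are the acceptance gates; observed
  values are ~1.0. Sensitivity is monotone in the planted effect size
  (checked on a grid with common random numbers).
* Problem sizes in tests and the acceptance script (2,000 genes, 4
  chromosomes × 600 kb, 5 SNPs per gene) were chosen as the smallest
  sizes at which the calibration and recovery quantities are estimated
  with useful precision.

## Known limitations

* Replicate-level overdispersion is simulated (beta-binomial) but the
  test is a pooled-count Fisher test: with strong intra-gene correlation
  the test is anti-conservative, which is why the calibration suite runs
  at rho = 0 and rho-sensitivity belongs to the user's QC.
* SNP-level phasing, beta-binomial or mixed-effect inference, and
  annotation liftover are out of scope.
* The DE stage is a stand-in (see above).
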