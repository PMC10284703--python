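# Methods

`uvclone` reimplements, as a tested pipeline on synthetic data, an integrated
clonal-evolution analysis of a skin-tropic leukaemia (BPDCN): premalignant
clones arise in the bone marrow, progression clones acquire UV-damage
mutations in the skin, and single-cell expression plus expressed-variant
genotyping resolve premalignant from malignant cells. This note records the
models, the tunable parameters, the numerical choices, and what the
synthetic data do and do not show.

## Clonal-tree and bulk VAF model

A clonal tree is a rooted acyclic map of clones; each clone acquires a fixed
number of new SNVs whose trinucleotide contexts are drawn from that clone's
mixture of signature-catalogue columns. A bulk sample is a mixture of clone
cell fractions (exclusive per clone, summing to at most 1, remainder normal
cells). The true VAF of a heterozygous autosomal mutation is half the summed
fraction of the clones carrying it (the clone of origin and its
descendants), modified by any copy-number event overlapping the site:
one-copy loss, copy-neutral LOH, or focal homozygous deletion, each assigned
to a clone and inherited by its descendants. Observed depth is Poisson at
the sample's mean depth and alt reads are binomial at the true VAF — the
simplest noise model consistent with count data; it omits FFPE damage,
mapping artefacts and overdispersion from library PCR.

The default "patient-10-like" tree encodes the study conditions the analysis
targets: a founder lineage of four nested marrow subclones carrying 16
clock-like mutations in total (gradual acquisition produces the wide founder
VAF range summarised by the coefficient of variation), one UV-dominated
transformed precursor with 60 mutations shared by two skin tumours, and 26
private UV-dominated mutations per skin clone, so that roughly half of the
UV-class TC>TT mutations are shared between the two tumours. Marrow depth
defaults to 200x.

UV biology in the simulator: each clone has a `uv_dinucleotide_rate` (the
fraction of its C>T events emitted as adjacent CC>TT pairs on the same
pyrimidine strand) and a `nontemplate_bias` (the probability that a genic
dipyrimidine C>T lies on the non-template strand, emulating
transcription-coupled repair of the template strand).

## Signature catalogue

The canonical 30-column reference catalogue is an external download, so the
package ships a deterministic SYNTHETIC catalogue of the same shape
(`uvclone.catalogue.synthetic_catalogue`): column 7 is UV-like (C>T mass at
dipyrimidines, TpC > CpC), column 1 is clock-like (C>T at NpCpG), column 5
is flat, and the rest are fixed random compositions. All tests and the
acceptance script use it; no published signature values are claimed. A real
catalogue TSV (96 labelled rows x signatures) can be supplied everywhere a
catalogue is accepted.

Refitting is non-negative least squares (`scipy.optimize.nnls`) of the
96-bin spectrum on the catalogue, with exposures normalised to relative
contributions; a relative UV contribution above 0.2 calls a sample
UV-exposed. On exact mixtures of up to three independent columns the refit
is accurate to 1e-6; on Poisson-noised 10,000-mutation spectra to about
0.01.

## Somatic filtering and phylogenomics

Filtering rules (per patient): keep variants reaching VAF >= 0.1 in at least
one sample unless whitelisted (e.g. confirmed by targeted sequencing); drop
variants whose germline VAF exceeds one fifth of the highest sample VAF;
drop variants recurring across patients unless on a user-supplied hotspot
whitelist (the whitelist is an input file, never inferred); and require
coverage above 20 (cryopreserved) or 10 (FFPE) in **every** sample of the
patient. Filtering is idempotent and fully audited (one boolean per rule per
variant).

Attribution assigns each variant to the first sample, in chronological/
anatomical order, with VAF > 0.1, and marks it present in all later samples;
founder mutations are those first detected in marrow, progression mutations
those first detected in skin. The sample phylogeny is a greedy perfect
phylogeny on presence patterns: patterns are accepted in decreasing support
order while they remain laminar (nested or disjoint) with the accepted set;
violating variants are reported as conflicts, never silently dropped.

Clonal architecture within one sample is deterministic 1-D clustering: sort
VAFs, split at gaps wider than 0.08, double each cluster mean to a
cancer-cell fraction, and chain clusters largest-first checking the
pigeonhole rule with tolerance 0.05. The gap and tolerance defaults were
chosen to separate clones differing by at least ~0.1 VAF at depth >= 100;
closely spaced subclones merge, which is reported, not hidden. Variants
inside called CNA segments are masked from clustering rather than corrected.

The VAF coefficient of variation uses the population SD (divide by n) by
default; the sample-SD alternative is one flag away (`ddof=1`).

## Copy-number inference and phasing

Germline-heterozygous SNV tracks carry mirrored BAF |BAF-0.5| and log2
coverage ratio versus the germline. Both are smoothed by a centred rolling
median over 50 SNVs; runs with |dBAF| > 0.1 and ratio drop > 0.3 (log2)
become loss segments, BAF shift without a coverage drop becomes CN-LOH, and
a linear coverage ratio below 0.25 becomes focal homozygous deletion.
Segments supported by fewer than half a window of SNVs are discarded as
flicker. These thresholds are package choices (no published values exist for
them) sized to detect arm-level events at tumour purity >= 0.5. Phasing
within a segment anchors on the most allele-imbalanced sample: SNVs above
0.5 there form one haplotype, and the assignment is applied across samples
so different-allele losses appear as mirrored tracks; segments with no
sample shifted beyond 0.05 are declared indeterminate and single-SNV
segments are flagged low-confidence.

## Expressed-variant genotyping (XV-seq computational half)

Reads are matched against wild-type and mutant discriminating sequences with
a 20% mismatch tolerance; a read must be within tolerance of one template
and strictly closer to it than to the other, otherwise it is ambiguous
(ties are never guessed). UMI consensus requires at least 3 informative
(WT/MUT) reads — ambiguous reads do not count toward the threshold, an
interpretation recorded here — and a threefold majority of one allele;
otherwise the UMI is discarded. The per-locus read threshold (1 for one
highly expressed transcript in the source analysis) is a locus field, not a
global flag. Cell calls use mutant dominance (any mutant UMI makes the cell
mutant); wild-type calls are definitive only at single-allele (hemizygous)
loci, where detecting the wild-type transcript excludes the mutant. Cells
with zero surviving UMIs are reported as NONE so denominators stay explicit.
Focal-deletion junctions are detected by running the same consensus rule
against each junction product; any positive product marks the cell
event-positive. Cis multi-mutation ambiguity (two mutations on one
transcript) is flagged via a shared transcript-group id, not resolved.

The genotyping simulator assigns each (cell, locus) a transcript allele from
the cell's clone genotype: a mutant cell transcribes mutant copies unless
the whole cell-locus drops out (probability `allelic_dropout`, default 0.2);
captured UMIs are Poisson (lambda = 2 per cell per locus by default), reads
per UMI are Poisson (mean 5, floor 1), and each read flips allele with
probability epsilon (default 0.005). Under these defaults the per-UMI
miscall probability is bounded by the chance that a majority of >= 3 reads
flip, below 1e-3.

## Cell typing and projection

QC keeps cells with > 2,000 UMIs, > 1,000 detected genes and < 20%
mitochondrial counts (strict inequalities); mitochondrial (`MT-*`) and rRNA
genes are removed after the mitochondrial fraction is computed, and X/Y
genes are retained. Marker genes are one-vs-rest rank-sum markers (top 50
per type by fold change among significant genes, via scanpy's Wilcoxon
ranking). The classifier is a 300-tree random forest on log-normalised
marker expression with stratified five-fold cross-validated accuracy and
out-of-fold probability vectors stored per reference cell; any probabilistic
multi-class model could be swapped in. Patient cells get probability
vectors, argmax calls (lexicographic tie-break), and doublet exclusion when
the argmax is the doublet class. Projection places each patient cell at the
2-D coordinates of the reference cell whose out-of-fold probability vector
best Pearson-correlates with the patient cell's vector; constant vectors
have undefined correlation and receive no coordinates.

The expression simulator is gamma-Poisson with type-specific marker shifts
on the log scale and a `biology_seed` separate from the run seed, so a
reference and a query dataset share gene-level biology while cells are
independent. Synthetic doublets are averaged profiles of two types. What
this does not emulate: batch effects between platforms, ambient RNA,
cell-cycle structure — so passing tests show algorithmic correctness, not
robustness to those artefacts.

## Malignancy signature and scoring

The malignant-pDC signature contrasts pDCs from involved marrows against
reference pDCs (healthy plus uninvolved-marrow pDCs without progression
mutations), after seeded downsampling to at most 50 cells per sample.
Genes pass with log2 fold change > 1 (fold change computed on expm1 of
log-normalised means with a pseudocount of 1) and adjusted rank-sum
p < 1e-30. The adjustment is Bonferroni by default (Benjamini-Hochberg by
flag); the source analysis says only "adjusted P", and at this extreme
threshold the two differ little. The module score bins genes by
dataset-average expression into 24 equal-frequency bins and samples 100
control genes per signature gene from the same bin (seeded); the score is
mean signature minus mean control expression per cell. Malignancy rules, in
precedence order: pDC in an involved sample, or score > 0.5 anywhere, is
malignant (score > 0.5 in an uninvolved sample is reported as
occult-malignant); a pDC in an uninvolved sample with score <= 0.5 and no
progression mutation is premalignant; everything else is normal. The 0.5
threshold is a config value. Progression-mutation enrichment in high-score
cells uses the shared Fisher exact test.

## Host/donor chimerism

The host genotype at each SNV is read from the germline BAF (homozygous
within 0.05 of 0 or 1); the donor's B-allele dosage is the genotype in
{0, 1/2, 1} whose predicted mixed-sample BAF (hf x host + (1-hf) x donor,
bulk host fraction hf defaulting to 0.5) is nearest the observed BAF, with
sites missing every model by more than 0.1 discarded. An allele present in
one genome and absent from the other is genome-specific; opposite
homozygotes are informative for both. Sites on X/Y or inside supplied
copy-number regions are excluded (a missing mask warns and proceeds).
Per-cell UMI-deduplicated coverage of host- and donor-specific alleles is
aggregated; cells with total informative coverage >= 10 are host when the
donor fraction is < 10%, donor when > 90%, and otherwise removed as
potential multiplets but retained in the output. The bulk thresholds are
package decisions — the source analysis applied unspecified thresholds.

## Exact statistics

Fisher's exact test: two-sided by the minimum-likelihood convention (sum of
hypergeometric probabilities <= the observed table's, with a 1 + 1e-7
relative guard), the convention that reproduces the printed lesion-site
p = 0.0112 from the 13 + 13 patient table; the odds ratio is the sample
odds ratio. The binomial test doubles the smaller exact tail, capped at 1.
The rank-sum test is exact (enumeration) for both groups under 20 without
ties, otherwise normal with tie correction. Both exact tests are verified
against exhaustive enumeration for all inputs with n <= 12.

## Problem sizes and determinism

Default verification sizes — 130-mutation patient-10-like catalogue at
depth 200; 10,000-mutation spectra for refit noise; 200 replicates for
threshold and power checks; 500-1,000 cells for single-cell stages;
500 cells / 250 panel sites for chimerism — were chosen so the whole suite
and the acceptance script complete in minutes on one core while leaving
Monte-Carlo margins well clear of the asserted bounds. Every generator
takes an explicit seed; the pipeline derives per-stage streams from one
top-level seed and records them in the run manifest, so identical
configuration yields byte-identical reports.

## Known limitations

Subclonal deconvolution is deterministic interval clustering, not a
posterior over tree structures; CNA inference has no breakpoint
optimisation (bounds are accurate to about one smoothing window); the
chimerism panel assumes a two-genome mixture; and all recovery guarantees
are statements about the synthetic generative models above, not about any
patient dataset.
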