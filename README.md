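# uvclone

Clonal phylogenomics, UV mutational-signature forensics and single-cell
expressed-variant genotyping for skin-tropic leukaemias.

Blastic plasmacytoid dendritic cell neoplasm (BPDCN) is an acute leukaemia
that originates from clonal precursors in the bone marrow yet often presents
as skin tumours. Resolving how it develops requires stitching together
several analyses that are usually run separately: multi-sample tumour
phylogenies from bulk variant allele fractions (VAFs), mutational-signature
refitting with UV-specific forensics (TC>TT / CC>CT fractions, CC>TT
dinucleotides, transcriptional strand asymmetry), copy-number inference from
B-allele frequencies, single-cell genotyping of expressed variants by UMI
consensus (XV-seq), reference-based cell typing with malignancy scoring, and
host/donor deconvolution after stem-cell transplant. `uvclone` implements
that whole chain as a library with a thin CLI, together with
synthetic-data generators that plant known ground truth for every stage, so
each method's recovery guarantees are tested end to end without any data
download.

## The models in brief

* **Clonal tree → bulk VAFs.** A mutation arising in clone *c* is carried by
  *c* and its descendants; its true VAF in a sample is
  ½ · Σ fractions of carrying clones (copy-number events modify the copy
  counts). Observed alt reads are Binomial(depth, VAF) with Poisson depth.
* **Spectra and refitting.** SNVs are folded onto the pyrimidine strand into
  the 96 trinucleotide classes; exposures solve
  min ‖catalogue · x − spectrum‖₂, x ≥ 0 (NNLS), and a relative UV
  contribution > 0.2 calls a sample UV-exposed.
* **Strand asymmetry.** A genic dipyrimidine C>T is non-template when the
  pyrimidine strand is the coding strand; enrichment is tested with an exact
  binomial test against 0.5 (two-sided, tail doubling).
* **UMI consensus genotyping.** A transcript (UMI) needs ≥ 3 informative
  reads and a ≥ 3-fold allele majority; any mutant UMI makes the cell
  mutant; wild-type calls are definitive only at single-allele loci.
* **Malignancy score.** Mean expression of the malignant-pDC signature minus
  expression-matched binned controls; score > 0.5 (or pDC identity in an
  involved marrow) marks a cell malignant.
* **Chimerism.** Genome-specific alleles from bulk germline + mixed-sample
  BAFs; a cell with ≥ 10 informative reads is host if < 10% of them support
  donor-specific alleles, donor if > 90%.

The 30-column signature catalogue shipped with the package is a clearly
labelled synthetic stand-in with the UV/clock/flat structure the analysis
needs (see `docs/methods.md`); any real catalogue TSV can be supplied.

## Worked example

Simulate the default study-condition dataset (a marrow founder lineage with
16 clock-like mutations, a UV-exposed precursor shared by two skin tumours,
and private UV progression mutations per tumour), then run the
phylogenomic and signature stages:

```
$ uvclone simulate --seed 1 --outdir demo
wrote 135 mutations x 3 samples to demo

$ uvclone phylo --variants demo/variants.tsv --out demo/phylo
retained 135 variants; 14 founder / 121 progression

$ uvclone signatures --variants demo/variants.tsv \
    --catalogue demo/catalogue.tsv --sample skin1 --out demo/sig
TC>TT fraction 0.485; CC>TT dinucleotides 5
```

The 135 simulated mutations split into 14 marrow-founder and 121
skin-progression events (two founder-lineage mutations sit near the 0.1
presence threshold at this seed and are attributed to skin — the kind of
binomial-noise misattribution the tests bound at < 5%). In the skin tumour,
48.5% of single-base substitutions are UV-associated TC>TT changes and five
CC>TT dinucleotide events appear — the UV fingerprint that is absent from
the clock-dominated marrow. `demo/phylo/phylogeny.json` holds the
founder/progression sets and the sample clades; `demo/sig/uv_report.json`
adds the strand-asymmetry counts per UV category.

The same operations are plain library calls
(`uvclone.phylo.partition_founder_progression`,
`uvclone.signatures.uv_metrics`, ...); `uvclone run --seed 1 --outdir out`
executes every stage, including single-cell genotyping, cell typing,
malignancy scoring and chimerism, and writes one JSON report with a
reproducibility manifest.

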