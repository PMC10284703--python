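"""Trinucleotide spectra, signature refitting and UV forensics.

Builds 96-class mutation spectra, refits them against a reference signature
catalogue by non-negative least squares, computes the UV-diagnostic metrics
(TC>TT and CC>CT fractions, CC>TT dinucleotide events) and tests
transcriptional strand asymmetry of UV-class mutations with an exact binomial
test. Transcription-coupled repair removes damage from the template strand,
so UV mutations accumulate on the non-template (coding) strand: a
pyrimidine-strand mutation inside a gene is non-template when the pyrimidine
strand is the gene's coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalogue import UV_SIGNATURE, validate_catalogue
from .contexts import (
    CONTEXT_LABELS,
    ContextError,
    classify_snv,
    is_cc_to_ct,
    is_tc_to_tt,
)
from .stats import binomial_test
from .tables import VariantTable


@dataclass
class TrinucSpectrum:
    counts: pd.Series  # indexed by the 96 labels
    n_snvs: int
    n_skipped: int = 0
    n_indels: int = 0

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(CONTEXT_LABELS):
            raise ValueError("spectrum must be indexed by the 96 labels in order")
        if int(self.counts.sum()) != self.n_snvs:
            raise ValueError("spectrum counts do not sum to the SNV total")


def _present_ids(table: VariantTable, sample: str | None, threshold: float) -> pd.Index:
    if sample is None:
        return table.variants.index
    vafs = table.vaf_matrix()
    return vafs.index[vafs[sample] > threshold]


def build_spectrum(
    table: VariantTable, sample: str | None = None, presence_threshold: float = 0.1
) -> TrinucSpectrum:
    """Count a sample's SNVs into the 96 trinucleotide substitution classes.

    ``sample=None`` uses every variant in the table; otherwise only variants
    present (VAF above threshold) in that sample. Indels are ignored with a
    count; records whose context contradicts their ref allele are skipped and
    counted.
    """
    ids = _present_ids(table, sample, presence_threshold)
    counts = pd.Series(0, index=list(CONTEXT_LABELS), dtype=int)
    n_indels = n_skipped = 0
    for vid in ids:
        row = table.variants.loc[vid]
        ref, alt = str(row["ref"]), str(row["alt"])
        if len(ref) != 1 or len(alt) != 1:
            n_indels += 1
            continue
        try:
            label = classify_snv(ref, alt, str(row["context"]))
        except ContextError:
            n_skipped += 1
            continue
        counts[label] += 1
    return TrinucSpectrum(
        counts=counts, n_snvs=int(counts.sum()), n_skipped=n_skipped, n_indels=n_indels
    )


@dataclass
class ContributionVector:
    exposures: pd.Series
    relative: pd.Series
    residual: float
    undefined: bool = False

    def uv_contribution(self, uv_signature: str = UV_SIGNATURE) -> float:
        return float(self.relative.get(uv_signature, 0.0))


def refit_contributions(
    spectrum: TrinucSpectrum | pd.Series, catalogue: pd.DataFrame
) -> ContributionVector:
    """Non-negative least-squares refit of a spectrum against a catalogue.

    Solves ``min ||catalogue @ x - spectrum||_2`` subject to ``x >= 0`` and
    normalises exposures to relative contributions. A zero spectrum yields
    all-zero exposures flagged undefined.
    """
    validate_catalogue(catalogue)
    y = spectrum.counts if isinstance(spectrum, TrinucSpectrum) else spectrum
    y = y.reindex(list(CONTEXT_LABELS)).to_numpy(dtype=float)
    if y.sum() == 0:
        zeros = pd.Series(0.0, index=catalogue.columns)
        return ContributionVector(zeros, zeros.copy(), 0.0, undefined=True)
    x, rnorm = nnls(catalogue.to_numpy(), y)
    exposures = pd.Series(x, index=catalogue.columns)
    total = exposures.sum()
    relative = exposures / total if total > 0 else exposures * 0.0
    return ContributionVector(exposures, relative, float(rnorm), undefined=total == 0)


@dataclass
class UVMetrics:
    n_snvs: int                 # single-base C>T denominator (pair members excluded)
    tc_tt_fraction: float
    cc_ct_fraction: float
    n_tc_tt: int
    n_cc_ct: int
    n_cc_tt_dinucleotides: int
    tc_tt_variant_ids: list = field(default_factory=list)


def uv_metrics(
    table: VariantTable,
    sample: str | None = None,
    presence_threshold: float = 0.1,
    max_vaf_difference: float = 0.1,
) -> UVMetrics:
    """UV-diagnostic mutation classes for one sample.

    TC>TT: C>T with a 5' T on the pyrimidine strand; CC>CT: C>T with a 5' C.
    CC>TT dinucleotides are adjacent same-sample C>T calls at consecutive
    positions on the same pyrimidine strand whose VAFs differ by at most
    ``max_vaf_difference``; their constituents are excluded from the
    single-base tallies.
    """
    ids = _present_ids(table, sample, presence_threshold)
    variants = table.variants.loc[ids]
    vafs = table.vaf_matrix()

    labels: dict[str, str] = {}
    for vid, row in variants.iterrows():
        ref, alt = str(row["ref"]), str(row["alt"])
        if len(ref) != 1 or len(alt) != 1:
            continue
        try:
            labels[vid] = classify_snv(ref, alt, str(row["context"]))
        except ContextError:
            continue

    # pair adjacent C>T calls into CC>TT dinucleotide events
    ct_ids = [v for v, lab in labels.items() if lab[2:5] == "C>T"]
    sub = variants.loc[ct_ids].sort_values(["chrom", "pos"])
    in_pair: set[str] = set()
    n_pairs = 0
    prev_vid = None
    for vid, row in sub.iterrows():
        if prev_vid is not None and prev_vid not in in_pair:
            prow = sub.loc[prev_vid]
            same_strand = (str(prow["ref"]) in "CT") == (str(row["ref"]) in "CT")
            adjacent = prow["chrom"] == row["chrom"] and row["pos"] == prow["pos"] + 1
            if adjacent and same_strand:
                if sample is not None:
                    dv = abs(vafs.loc[vid, sample] - vafs.loc[prev_vid, sample])
                else:
                    dv = 0.0
                if dv <= max_vaf_difference:
                    in_pair.update((vid, prev_vid))
                    n_pairs += 1
        prev_vid = vid

    singles = {v: lab for v, lab in labels.items() if v not in in_pair}
    n = len(singles)
    tc = [v for v, lab in singles.items() if is_tc_to_tt(lab)]
    cc = [v for v, lab in singles.items() if is_cc_to_ct(lab)]
    return UVMetrics(
        n_snvs=n,
        tc_tt_fraction=len(tc) / n if n else 0.0,
        cc_ct_fraction=len(cc) / n if n else 0.0,
        n_tc_tt=len(tc),
        n_cc_ct=len(cc),
        n_cc_tt_dinucleotides=n_pairs,
        tc_tt_variant_ids=tc,
    )


@dataclass
class StrandCounts:
    category: str
    template: int
    nontemplate: int
    untestable: int
    p_value: float | None

    @property
    def nontemplate_fraction(self) -> float | None:
        n = self.template + self.nontemplate
        return self.nontemplate / n if n else None


def classify_strand(ref: str, gene_strand: str) -> str:
    """template / nontemplate / untestable for one pyrimidine-strand mutation.

    The pyrimidine strand is the reference plus strand when ``ref`` is C or T.
    The mutation is non-template when the pyrimidine strand is the gene's
    coding (sense) strand.
    """
    if gene_strand not in ("+", "-"):
        return "untestable"
    pyr_strand = "+" if ref.upper() in "CT" else "-"
    return "nontemplate" if pyr_strand == gene_strand else "template"


def strand_asymmetry(
    table: VariantTable,
    categories: dict[str, callable] | None = None,
    sample: str | None = None,
    presence_threshold: float = 0.1,
) -> dict[str, StrandCounts]:
    """Exact binomial test of non-template enrichment per mutation category.

    ``categories`` maps a name to a predicate over the 96-class label;
    defaults to the UV classes TC>TT and CC>CT. Intergenic mutations and
    mutations in overlapping opposite-strand genes (``gene_strand == '.'``)
    are untestable. The two-sided p doubles the smaller exact tail, capped
    at 1; it is None when no mutation is testable.
    """
    if categories is None:
        categories = {"TC>TT": is_tc_to_tt, "CC>CT": is_cc_to_ct}
    ids = _present_ids(table, sample, presence_threshold)
    variants = table.variants.loc[ids]
    out: dict[str, StrandCounts] = {}
    for name, pred in categories.items():
        t = nt = un = 0
        for _, row in variants.iterrows():
            ref, alt = str(row["ref"]), str(row["alt"])
            if len(ref) != 1 or len(alt) != 1:
                continue
            try:
                label = classify_snv(ref, alt, str(row["context"]))
            except ContextError:
                continue
            if not pred(label):
                continue
            cls = classify_strand(ref, str(row.get("gene_strand", "")))
            if cls == "template":
                t += 1
            elif cls == "nontemplate":
                nt += 1
            else:
                un += 1
        p = binomial_test(nt, t + nt, 0.5) if (t + nt) > 0 else None
        out[name] = StrandCounts(name, t, nt, un, p)
    return out
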