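"""Computational half of expressed-variant single-cell genotyping (XV-seq).

Reads from targeted enrichment of scRNA-seq libraries are matched to
wild-type or mutant discriminating sequences, collapsed per UMI by a
read-support + majority-fold consensus rule, and aggregated per cell with
mutant dominance. Wild-type calls are definitive only at single-allele
(hemizygous) loci, where detecting the wild-type transcript excludes the
mutant; at heterozygous loci the mutant allele may simply have been missed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LocusSpec:
    """Per-locus genotyping configuration."""

    locus_id: str
    wt_sequence: str
    mut_sequence: str
    mismatch_tolerance: float = 0.20
    min_reads: int = 3
    majority_fold: float = 3.0
    zygosity: str = "heterozygous"  # heterozygous | hemizygous
    transcript_group: str | None = None  # shared id flags cis multi-mutation ambiguity

    def __post_init__(self) -> None:
        if not 0.0 <= self.mismatch_tolerance < 1.0:
            raise ValueError("mismatch tolerance must be in [0, 1)")
        if self.min_reads < 1 or self.majority_fold < 1:
            raise ValueError("min_reads and majority_fold must be >= 1")
        if self.zygosity not in ("heterozygous", "hemizygous"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass
class SpliceProductSpec:
    """Junction products diagnostic of a structural event (e.g. a focal deletion)."""

    locus_id: str
    junction_sequences: list[str]
    reference_sequence: str
    event_label: str = "focal deletion"
    mismatch_tolerance: float = 0.20
    min_reads: int = 3
    majority_fold: float = 3.0

    def __post_init__(self) -> None:
        if not self.junction_sequences:
            raise ValueError("need at least one junction sequence")


def _mismatch_fraction(read: str, template: str) -> float:
    n = min(len(read), len(template))
    if n == 0:
        return 1.0
    mism = sum(1 for a, b in zip(read[:n], template[:n]) if a != b)
    mism += abs(len(read) - len(template)) if len(read) < len(template) else 0
    return mism / max(len(template), 1)


def match_read(read: str, spec: LocusSpec) -> str:
    """Call one read WT / MUT / AMB against the locus's discriminating sequences.

    A call is made when the mismatch fraction against that template is within
    tolerance and strictly smaller than against the other template; ties
    within tolerance, or neither within tolerance, give AMB.
    """
    read = read.upper()
    d_wt = _mismatch_fraction(read, spec.wt_sequence.upper())
    d_mut = _mismatch_fraction(read, spec.mut_sequence.upper())
    tol = spec.mismatch_tolerance
    wt_ok, mut_ok = d_wt <= tol, d_mut <= tol
    if wt_ok and (not mut_ok or d_wt < d_mut):
        return "WT"
    if mut_ok and (not wt_ok or d_mut < d_wt):
        return "MUT"
    return "AMB"


def collapse_umi(read_calls, spec: LocusSpec) -> str:
    """UMI consensus: 'WT', 'MUT' or 'discard'.

    Only informative (WT/MUT) reads count toward the read-support threshold;
    the consensus requires at least ``min_reads`` informative reads and a
    ``majority_fold``-fold majority of one allele over the other.
    """
    counts = Counter(read_calls)
    wt, mut = counts.get("WT", 0), counts.get("MUT", 0)
    if wt + mut < spec.min_reads:
        return "discard"
    if wt >= spec.majority_fold * mut and wt > mut:
        return "WT"
    if mut >= spec.majority_fold * wt and mut > wt:
        return "MUT"
    return "discard"


@dataclass
class CellGenotype:
    cell_barcode: str
    locus: str
    n_wt_umis: int
    n_mut_umis: int
    call: str            # MUT | WT | NONE
    definitive: bool
    cis_ambiguous: bool = False


def genotype_cell(
    umi_calls, cell_barcode: str, spec: LocusSpec
) -> CellGenotype:
    """Aggregate one cell's UMI consensus calls with mutant dominance.

    Any mutant UMI makes the cell MUT; otherwise any wild-type UMI makes it
    WT; otherwise NONE. WT calls are definitive only for single-allele
    (hemizygous) loci. A shared ``transcript_group`` marks the possibility of
    a cis mutation elsewhere on the same transcript; the flag is recorded,
    not resolved.
    """
    counts = Counter(umi_calls)
    wt, mut = counts.get("WT", 0), counts.get("MUT", 0)
    if mut >= 1:
        call, definitive = "MUT", True
    elif wt >= 1:
        call = "WT"
        definitive = spec.zygosity == "hemizygous"
    else:
        call, definitive = "NONE", False
    return CellGenotype(
        cell_barcode=cell_barcode,
        locus=spec.locus_id,
        n_wt_umis=wt,
        n_mut_umis=mut,
        call=call,
        definitive=definitive,
        cis_ambiguous=spec.transcript_group is not None,
    )


def genotype_cells(read_table: pd.DataFrame, spec: LocusSpec) -> pd.DataFrame:
    """Full pipeline from a read table (locus, cell_barcode, umi, read_index,
    allele) to per-cell genotypes for one locus.

    ``allele`` may already be WT/MUT/AMB calls, or raw sequences (then each is
    matched against the locus templates first). Cells with zero surviving
    UMIs are reported as NONE so denominators stay explicit.
    """
    sub = read_table
    if "locus" in read_table.columns:
        sub = read_table[read_table["locus"] == spec.locus_id]
    rows = []
    all_cells = sub["cell_barcode"].unique()
    for cell, cell_reads in sub.groupby("cell_barcode"):
        umi_calls = []
        for _, umi_reads in cell_reads.groupby("umi"):
            calls = [
                a if a in ("WT", "MUT", "AMB") else match_read(a, spec)
                for a in umi_reads["allele"]
            ]
            consensus = collapse_umi(calls, spec)
            if consensus != "discard":
                umi_calls.append(consensus)
        rows.append(genotype_cell(umi_calls, cell, spec))
    df = pd.DataFrame([vars(g) for g in rows])
    if df.empty:
        df = pd.DataFrame(
            columns=["cell_barcode", "locus", "n_wt_umis", "n_mut_umis", "call",
                     "definitive", "cis_ambiguous"]
        )
    missing = set(all_cells) - set(df["cell_barcode"])
    assert not missing
    return df.set_index("cell_barcode")


def detect_deletion_junction(read_table: pd.DataFrame, spec: SpliceProductSpec) -> pd.DataFrame:
    """Per-cell structural-event call from junction-spanning transcripts.

    Each junction product is treated as the mutant template of a separate
    locus (reference product as wild type); a cell is event-positive when any
    junction product yields a mutant UMI passing the consensus rule.
    """
    per_product = []
    for j, junction in enumerate(spec.junction_sequences):
        sub_spec = LocusSpec(
            locus_id=spec.locus_id,
            wt_sequence=spec.reference_sequence,
            mut_sequence=junction,
            mismatch_tolerance=spec.mismatch_tolerance,
            min_reads=spec.min_reads,
            majority_fold=spec.majority_fold,
        )
        geno = genotype_cells(read_table, sub_spec)
        per_product.append(geno["call"] == "MUT")
    if not per_product:
        return pd.DataFrame(columns=["event_positive", "event_label"])
    pos = pd.concat(per_product, axis=1).fillna(False).any(axis=1)
    return pd.DataFrame({"event_positive": pos, "event_label": spec.event_label})


def quantify_pre_enrichment(pileup: pd.DataFrame, mutations: list[str]) -> pd.DataFrame:
    """Detected-cell and detected-UMI counts per mutation before enrichment.

    ``pileup`` rows carry ``mutation_id, cell_barcode, umi, base_matches_alt``
    (boolean). Returns per-mutation counts sorted descending by detected
    cells (the enrichment-primer ranking).
    """
    rows = []
    for m in mutations:
        sub = pileup[(pileup["mutation_id"] == m) & pileup["base_matches_alt"]]
        rows.append(
            {
                "mutation_id": m,
                "n_cells": sub["cell_barcode"].nunique(),
                "n_umis": sub[["cell_barcode", "umi"]].drop_duplicates().shape[0],
            }
        )
    out = pd.DataFrame(rows).set_index("mutation_id")
    out = out.sort_values(["n_cells", "n_umis"], ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class ConcordanceResult:
    n_mut_a: int
    n_mut_b: int
    n_mut_both: int
    n_wt_a: int
    n_wt_b: int
    n_wt_both: int
    jaccard_mut: float
    jaccard_wt: float
    disagreements: list = field(default_factory=list)


def replicate_concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> ConcordanceResult:
    """Overlap of per-cell calls between two primer designs at the same locus."""

    def _sets(df):
        mut = set(df.index[df["call"] == "MUT"])
        wt = set(df.index[df["call"] == "WT"])
        return mut, wt

    mut_a, wt_a = _sets(calls_a)
    mut_b, wt_b = _sets(calls_b)
    jm = len(mut_a & mut_b) / len(mut_a | mut_b) if (mut_a | mut_b) else 1.0
    jw = len(wt_a & wt_b) / len(wt_a | wt_b) if (wt_a | wt_b) else 1.0
    disagreements = sorted((mut_a & wt_b) | (wt_a & mut_b))
    return ConcordanceResult(
        n_mut_a=len(mut_a),
        n_mut_b=len(mut_b),
        n_mut_both=len(mut_a & mut_b),
        n_wt_a=len(wt_a),
        n_wt_b=len(wt_b),
        n_wt_both=len(wt_a & wt_b),
        jaccard_mut=jm,
        jaccard_wt=jw,
        disagreements=disagreements,
    )
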