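"""Bulk multi-sample VAF simulator with arm-level and focal copy-number events.

The sampling model per variant and sample: the true VAF is the mutant-copy
fraction over the cell populations present in the sample (0.5 x summed
carrier-clone fraction for a heterozygous autosomal site, modified by any
copy-number event overlapping the site); observed depth is Poisson around the
sample's mean depth and alt reads are binomial at the true VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..tables import VariantTable, make_sample_frame
from .tree import ClonalTreeSpec


@dataclass
class SamplePlan:
    """Cellular composition and sequencing plan for one bulk sample."""

    sample_id: str
    tissue: str  # marrow | skin | other
    clone_fractions: dict[str, float]
    mean_depth: float = 150.0
    sample_type: str = "cryopreserved"

    def __post_init__(self) -> None:
        if self.tissue not in ("marrow", "skin", "other"):
            raise ValueError(f"unknown tissue {self.tissue!r}")
        for c, f in self.clone_fractions.items():
            if f < 0:
                raise ValueError(f"negative fraction for clone {c!r}")
        if sum(self.clone_fractions.values()) > 1 + 1e-9:
            raise ValueError("clone fractions sum above 1")


@dataclass
class CNAEvent:
    """A somatic copy-number event acquired by one clone.

    ``kind`` is one of ``loss`` (one-copy arm loss), ``cnloh`` (copy-neutral
    LOH) and ``homdel`` (focal homozygous deletion). ``lost_allele`` states
    which allele is removed at heterozygous somatic sites inside the event:
    ``"other"`` (the wild-type allele, so mutations become hemizygous or are
    duplicated) or ``"mutant"``.
    """

    clone: str
    chrom: str
    start: int
    end: int
    kind: str
    lost_allele: str = "other"

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "cnloh", "homdel"):
            raise ValueError(f"unknown CNA kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("CNA end before start")

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def lineage_fraction(spec: ClonalTreeSpec, clone: str, fractions: dict[str, float]) -> float:
    """Summed fraction of cells carrying ``clone``'s mutations (its subtree)."""
    return sum(fractions.get(c, 0.0) for c in spec.descendants(clone))


def _copies_at(events: list[CNAEvent], cell_clone_lineage: set[str], chrom: str, pos: int,
               carrier: bool) -> tuple[float, float]:
    """(mutant copies, total copies) at a site in a cell of the given lineage."""
    total, mutant = 2.0, (1.0 if carrier else 0.0)
    for ev in events:
        if ev.clone in cell_clone_lineage and ev.covers(chrom, pos):
            if ev.kind == "homdel":
                return 0.0, 0.0
            if ev.kind == "loss":
                total = 1.0
                if carrier:
                    mutant = 0.0 if ev.lost_allele == "mutant" else 1.0
            elif ev.kind == "cnloh":
                total = 2.0
                if carrier:
                    mutant = 0.0 if ev.lost_allele == "mutant" else 2.0
    return mutant, total


def true_vaf(
    spec: ClonalTreeSpec,
    catalogue_row: pd.Series,
    plan: SamplePlan,
    events: list[CNAEvent],
) -> float:
    """Expected VAF of one mutation in one sample under the copy-number model."""
    origin = catalogue_row["clone"]
    carriers = spec.descendants(origin)
    chrom, pos = catalogue_row["chrom"], int(catalogue_row["pos"])
    num = den = 0.0
    # tumour clones
    for clone, frac in plan.clone_fractions.items():
        if frac == 0:
            continue
        lineage = {c for c in spec.nodes if clone in spec.descendants(c)}
        # lineage = set of clones whose events this cell inherits: ancestors of
        # `clone` (inclusive); a cell of clone X carries events of all ancestors.
        mut, tot = _copies_at(events, lineage, chrom, pos, carrier=clone in carriers)
        num += frac * mut
        den += frac * tot
    normal = 1.0 - sum(plan.clone_fractions.values())
    den += normal * 2.0
    return num / den if den > 0 else 0.0


def _validate_nesting(spec: ClonalTreeSpec, plans: list[SamplePlan], tol: float = 1e-9) -> None:
    for plan in plans:
        unknown = set(plan.clone_fractions) - set(spec.nodes)
        if unknown:
            raise ValueError(f"sample {plan.sample_id!r} references unknown clones: {sorted(unknown)}")
        for child, parent in spec.parent_of.items():
            cf = lineage_fraction(spec, child, plan.clone_fractions)
            pf = lineage_fraction(spec, parent, plan.clone_fractions)
            if cf > pf + tol:
                raise ValueError(
                    f"sample {plan.sample_id!r}: lineage fraction of clone {child!r} "
                    f"({cf:.3f}) exceeds parent {parent!r} ({pf:.3f})"
                )


def simulate_bulk_vafs(
    spec: ClonalTreeSpec,
    catalogue: pd.DataFrame,
    plans: list[SamplePlan],
    seed: int,
    cna_events: list[CNAEvent] | None = None,
) -> VariantTable:
    """Sample observed multi-sample VAFs for a simulated mutation catalogue.

    Adds ``true_vaf:<sample>`` and ``is_cna_affected`` truth columns to the
    variant annotations.
    """
    events = cna_events or []
    _validate_nesting(spec, plans)
    rng = np.random.default_rng(seed)
    variants = catalogue.copy()
    call_rows = []
    truth_cols = {p.sample_id: [] for p in plans}
    affected = []
    for _, row in variants.iterrows():
        hit = any(
            ev.covers(row["chrom"], int(row["pos"])) for ev in events
        )
        affected.append(hit)
    variants["is_cna_affected"] = affected
    for plan in plans:
        for vid, row in variants.iterrows():
            tv = true_vaf(spec, row, plan, events)
            truth_cols[plan.sample_id].append(tv)
            depth = int(rng.poisson(plan.mean_depth))
            alt = int(rng.binomial(depth, tv)) if depth > 0 else 0
            call_rows.append(
                {
                    "variant_id": vid,
                    "sample_id": plan.sample_id,
                    "vaf": alt / depth if depth > 0 else 0.0,
                    "depth": depth,
                    "alt_reads": alt,
                }
            )
    for sid, vals in truth_cols.items():
        variants[f"true_vaf:{sid}"] = vals
    samples = make_sample_frame([(p.sample_id, p.tissue, p.sample_type) for p in plans])
    calls = pd.DataFrame(call_rows)
    return VariantTable(variants=variants, calls=calls, samples=samples,
                        meta={"seed": seed, "n_cna_events": len(events)})


@dataclass
class BAFCoveragePlan:
    """Plan for a germline-heterozygous SNV track used for CNA inference."""

    chrom: str = "chr9"
    n_snvs: int = 2000
    chrom_length: int = 100_000_000
    mean_depth: float = 120.0
    purity: float = 0.8
    segments: list = field(default_factory=list)  # list of (start, end, kind)


def simulate_baf_coverage(plan: BAFCoveragePlan, seed: int) -> pd.DataFrame:
    """Simulate per-SNV B-allele frequency and coverage ratio along a chromosome.

    ``segments`` carry ``(start, end, kind)`` with kind in loss / cnloh /
    homdel; tumour purity dilutes the allelic and coverage shifts. The B
    allele is the lost allele for every segment (phasing tests flip it per
    sample instead). Returns columns ``chrom, pos, baf, coverage, log2_ratio``.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(plan.chrom_length, size=plan.n_snvs, replace=False))
    p = plan.purity
    baf_true = np.full(plan.n_snvs, 0.5)
    cn = np.full(plan.n_snvs, 2.0)
    for start, end, kind in plan.segments:
        m = (pos >= start) & (pos <= end)
        if kind == "loss":
            # tumour has one copy (A); B allele fraction across the mixture
            baf_true[m] = (1 - p) * 1.0 / ((1 - p) * 2 + p * 1)
            cn[m] = (1 - p) * 2 + p * 1
        elif kind == "cnloh":
            baf_true[m] = (1 - p) * 1.0 / 2.0
            cn[m] = 2.0
        elif kind == "homdel":
            baf_true[m] = 0.5  # only normal cells contribute reads
            cn[m] = (1 - p) * 2
        else:
            raise ValueError(f"unknown segment kind {kind!r}")
    depth = rng.poisson(plan.mean_depth * cn / 2.0)
    depth = np.maximum(depth, 1)
    b_reads = rng.binomial(depth, baf_true)
    return pd.DataFrame(
        {
            "chrom": plan.chrom,
            "pos": pos,
            "baf": b_reads / depth,
            "coverage": depth,
            "log2_ratio": np.log2(depth / plan.mean_depth),
        }
    )
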