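"""Somatic-variant filtering, sample attribution and clonal phylogenomics.

The operations here mirror a multi-sample tumour-evolution analysis: filter a
merged somatic call set with per-patient rules, attribute each retained
variant to the first sample (in chronological/anatomical order) where it is
detected above a presence threshold, split variants into marrow founder
versus skin progression events, reconstruct a sample-level phylogeny from
shared mutation sets, and cluster one sample's VAFs into nested clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import VariantTable

PRESENCE_THRESHOLD = 0.1


@dataclass
class FilterParams:
    """Per-patient somatic filtering rules.

    ``min_vaf``: a variant must reach this VAF in at least one sample unless
    whitelisted. ``germline_ratio``: drop when germline VAF exceeds the
    highest sample VAF divided by this factor. Coverage floors apply per
    sample type and a variant is dropped only when it fails in every sample.
    Cross-patient recurrent variants are dropped unless in the hotspot
    whitelist.
    """

    min_vaf: float = 0.1
    germline_ratio: float = 5.0
    min_coverage_cryopreserved: float = 20.0
    min_coverage_ffpe: float = 10.0
    whitelist: set = field(default_factory=set)          # e.g. targeted-panel confirmed
    hotspot_whitelist: set = field(default_factory=set)  # recurrence-exempt hotspots


def filter_somatic_variants(
    table: VariantTable,
    germline_vaf: pd.Series | None = None,
    params: FilterParams | None = None,
    recurrent_ids: set | None = None,
) -> tuple[VariantTable, pd.DataFrame]:
    """Apply the somatic filtering rules; returns (filtered table, audit report).

    The audit report has one row per input variant with a boolean per rule and
    the final ``retained`` flag.
    """
    params = params or FilterParams()
    if germline_vaf is None:
        raise ValueError("germline VAFs are required (pass a Series indexed by variant_id)")
    germline_vaf = germline_vaf.reindex(table.variants.index)
    if germline_vaf.isna().any():
        missing = germline_vaf.index[germline_vaf.isna()].tolist()
        raise ValueError(f"germline VAF missing for variants: {missing[:5]}")
    recurrent_ids = recurrent_ids or set()

    vafs = table.vaf_matrix()
    depths = table.depth_matrix()
    max_vaf = vafs.max(axis=1)

    wl = vafs.index.isin(params.whitelist)
    pass_vaf = (max_vaf >= params.min_vaf) | wl
    pass_germline = germline_vaf.to_numpy() <= (max_vaf.to_numpy() / params.germline_ratio)
    hot = vafs.index.isin(params.hotspot_whitelist)
    pass_recurrent = ~vafs.index.isin(recurrent_ids) | hot

    floors = np.array(
        [
            params.min_coverage_ffpe
            if table.samples.loc[s, "sample_type"] == "FFPE"
            else params.min_coverage_cryopreserved
            for s in depths.columns
        ]
    )
    # retained only when coverage clears the floor in EVERY sample
    pass_coverage = (depths.to_numpy() > floors[None, :]).all(axis=1)

    report = pd.DataFrame(
        {
            "pass_vaf": pass_vaf,
            "pass_germline": pass_germline,
            "pass_recurrent": pass_recurrent,
            "pass_coverage": pass_coverage,
        },
        index=vafs.index,
    )
    report["retained"] = report.all(axis=1)
    kept = report.index[report["retained"]]
    return table.subset(kept), report


def attribute_variants(table: VariantTable, threshold: float = PRESENCE_THRESHOLD) -> pd.DataFrame:
    """Attribute each variant to the first ordered sample with VAF > threshold.

    Returns a frame indexed by variant_id with ``first_sample`` (NaN when the
    variant never crosses the threshold) and boolean ``present:<sample>``
    columns marking the attributed sample and all subsequent samples.
    """
    vafs = table.vaf_matrix()
    order = table.sample_order
    arr = vafs[order].to_numpy()
    above = arr > threshold
    first_idx = np.where(above.any(axis=1), above.argmax(axis=1), -1)
    out = pd.DataFrame(index=vafs.index)
    out["first_sample"] = [order[i] if i >= 0 else np.nan for i in first_idx]
    for j, s in enumerate(order):
        out[f"present:{s}"] = (first_idx >= 0) & (first_idx <= j)
    return out


def partition_founder_progression(
    table: VariantTable, attribution: pd.DataFrame | None = None
) -> tuple[set, set]:
    """Split retained variants into marrow-founder and skin-progression sets."""
    if attribution is None:
        attribution = attribute_variants(table)
    tissue = table.samples["tissue"]
    founder, progression = set(), set()
    for vid, first in attribution["first_sample"].items():
        if pd.isna(first):
            continue
        if tissue[first] == "marrow":
            founder.add(vid)
        elif tissue[first] == "skin":
            progression.add(vid)
    return founder, progression


@dataclass
class PhylogenyResult:
    presence: pd.DataFrame          # variants x samples boolean
    clades: dict                    # frozenset(samples) -> list of variant_ids
    tree: dict                      # child frozenset -> parent frozenset
    conflicts: list                 # variant_ids violating nesting
    founder: set = field(default_factory=set)
    progression: set = field(default_factory=set)


def build_sample_phylogeny(
    table: VariantTable, threshold: float = PRESENCE_THRESHOLD
) -> PhylogenyResult:
    """Greedy perfect phylogeny on presence/absence patterns.

    Variants are grouped by the set of samples in which they are present
    (VAF > threshold). Groups are kept when their sample sets form a laminar
    family (pairwise nested or disjoint) with the groups already accepted, in
    decreasing order of variant support; variants in rejected groups are
    reported as conflicts, not silently dropped.
    """
    vafs = table.vaf_matrix()
    presence = vafs > threshold
    patterns: dict[frozenset, list] = {}
    for vid, row in presence.iterrows():
        key = frozenset(presence.columns[row.to_numpy()])
        if key:
            patterns.setdefault(key, []).append(vid)
    accepted: dict[frozenset, list] = {}
    conflicts: list = []
    for key in sorted(patterns, key=lambda k: (-len(patterns[k]), -len(k), sorted(k))):
        ok = all(
            key <= other or other <= key or not (key & other) for other in accepted
        )
        if ok:
            accepted[key] = patterns[key]
        else:
            conflicts.extend(patterns[key])
    # parent of each clade = smallest accepted strict superset
    tree: dict[frozenset, frozenset] = {}
    all_samples = frozenset(presence.columns)
    for key in accepted:
        supers = [o for o in accepted if key < o]
        if supers:
            tree[key] = min(supers, key=len)
        elif key != all_samples:
            tree[key] = all_samples
    founder, progression = partition_founder_progression(table)
    return PhylogenyResult(
        presence=presence,
        clades=accepted,
        tree=tree,
        conflicts=conflicts,
        founder=founder,
        progression=progression,
    )


@dataclass
class Clone:
    clone_id: str
    variant_ids: list
    vaf_centre: float
    cancer_cell_fraction: float
    parent: str | None = None


@dataclass
class CloneModel:
    clones: list
    nesting_ok: bool
    masked_variants: list = field(default_factory=list)


def infer_clonal_architecture(
    vafs: pd.Series,
    cna_mask: pd.Index | None = None,
    gap: float = 0.08,
    tau: float = 0.05,
) -> CloneModel:
    """Deterministic 1-D clustering of one sample's VAFs into nested clones.

    Sort the (unmasked) VAFs, split at gaps wider than ``gap``, take each
    cluster's mean VAF doubled as its cancer-cell fraction, and chain clusters
    from largest to smallest, checking the pigeonhole rule with tolerance
    ``tau``. Variants inside called CNA segments should be masked via
    ``cna_mask`` (they are reported, not clustered).
    """
    masked = []
    if cna_mask is not None:
        masked = [v for v in vafs.index if v in set(cna_mask)]
        vafs = vafs.drop(masked)
    vafs = vafs[vafs > 0]
    if vafs.empty:
        return CloneModel(clones=[], nesting_ok=True, masked_variants=masked)
    order = vafs.sort_values(ascending=False)
    clusters: list[list] = [[order.index[0]]]
    for prev, vid in zip(order.index[:-1], order.index[1:]):
        if order[prev] - order[vid] > gap:
            clusters.append([vid])
        else:
            clusters[-1].append(vid)
    clones = []
    nesting_ok = True
    for i, ids in enumerate(clusters):
        centre = float(vafs.loc[ids].mean())
        ccf = min(1.0, 2.0 * centre)
        parent = f"clone{i - 1}" if i > 0 else None
        if i > 0 and ccf > clones[-1].cancer_cell_fraction + tau:
            nesting_ok = False
        clones.append(Clone(f"clone{i}", list(ids), centre, ccf, parent))
    return CloneModel(clones=clones, nesting_ok=nesting_ok, masked_variants=masked)


def compute_vaf_dispersion(vafs, ddof: int = 0) -> float:
    """Coefficient of variation (SD / mean) of a set of VAFs.

    Uses the population SD (``ddof=0``) by default; pass ``ddof=1`` for the
    sample SD. Requires at least two values and a positive mean.
    """
    arr = np.asarray(vafs, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two VAFs")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean VAF must be positive")
    return float(arr.std(ddof=ddof) / mean)
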