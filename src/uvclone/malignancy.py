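"""Malignant-pDC signature derivation, module scoring and malignancy calls.

The malignant signature contrasts pDCs from involved marrows against
reference pDCs (healthy donors plus uninvolved-marrow pDCs without
progression mutations), downsampled per sample so no single sample dominates.
Cells are scored with a binned-control module score, and classified as
malignant, premalignant pDC, occult malignant or normal by combining cell
type, sample involvement, score and genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps

from .celltyping import normalize_log
from .stats import fisher_exact

SCORE_THRESHOLD = 0.5


@dataclass
class GroupSpec:
    """Cell groups for signature derivation (disjoint barcode lists)."""

    reference_cells: list
    involved_cells: list
    max_cells_per_sample: int = 50

    def __post_init__(self) -> None:
        if set(self.reference_cells) & set(self.involved_cells):
            raise ValueError("groups must be disjoint")


def _downsample(cells: list, sample_of: pd.Series, cap: int, rng: np.random.Generator) -> list:
    out = []
    by_sample: dict = {}
    for c in cells:
        by_sample.setdefault(sample_of.get(c, ""), []).append(c)
    for s in sorted(by_sample):
        group = sorted(by_sample[s])
        if len(group) > cap:
            group = list(rng.choice(group, size=cap, replace=False))
        out.extend(group)
    return out


@dataclass
class SignatureGeneSet:
    genes: list
    table: pd.DataFrame  # per tested gene: log2_fc, p, p_adj, selected


def derive_signature(
    adata: ad.AnnData,
    groups: GroupSpec,
    seed: int = 0,
    log2_fc_threshold: float = 1.0,
    p_adj_threshold: float = 1e-30,
    adjust: str = "bonferroni",
) -> SignatureGeneSet:
    """Rank-sum differential expression of involved-marrow pDCs vs reference pDCs.

    Both groups are first downsampled to at most ``max_cells_per_sample``
    cells per sample (seeded). Genes with log2 fold change above the
    threshold and adjusted p below the threshold are retained. ``adjust`` is
    ``bonferroni`` (default) or ``bh``.
    """
    rng = np.random.default_rng(seed)
    sample_of = adata.obs["sample_id"] if "sample_id" in adata.obs else pd.Series("", index=adata.obs_names)
    g1 = _downsample(groups.reference_cells, sample_of, groups.max_cells_per_sample, rng)
    g2 = _downsample(groups.involved_cells, sample_of, groups.max_cells_per_sample, rng)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty after downsampling")
    norm = normalize_log(adata)
    X1 = np.asarray(norm[g1].X)
    X2 = np.asarray(norm[g2].X)
    # fold change on expm1 of log-normalised means with a pseudocount
    m1 = np.expm1(X1).mean(axis=0)
    m2 = np.expm1(X2).mean(axis=0)
    log2_fc = np.log2((m2 + 1.0) / (m1 + 1.0))
    pvals = sps.mannwhitneyu(X2, X1, alternative="two-sided", axis=0).pvalue
    # genes identical in both groups carry no evidence
    constant = (X1.std(axis=0) == 0) & (X2.std(axis=0) == 0) & (X1[0] == X2[0])
    pvals = np.where(constant, 1.0, pvals)
    n_tests = norm.n_vars
    if adjust == "bonferroni":
        p_adj = np.minimum(1.0, pvals * n_tests)
    elif adjust == "bh":
        order = np.argsort(pvals)
        ranked = pvals[order] * n_tests / (np.arange(n_tests) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty(n_tests)
        p_adj[order] = np.minimum(1.0, ranked)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    selected = (log2_fc > log2_fc_threshold) & (p_adj < p_adj_threshold)
    table = pd.DataFrame(
        {"log2_fc": log2_fc, "p": pvals, "p_adj": p_adj, "selected": selected},
        index=norm.var_names,
    )
    return SignatureGeneSet(genes=list(norm.var_names[selected]), table=table)


def module_score(
    adata: ad.AnnData,
    gene_set: list,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    On log-normalised data: genes are binned by dataset-average expression
    into ``n_bins`` equal-frequency bins; for each signature gene ``n_ctrl``
    control genes are sampled (with replacement if the bin is small) from its
    bin; the score is the mean signature expression minus the mean control
    expression per cell. Deterministic for a fixed seed; signature genes
    missing from the matrix are dropped.
    """
    rng = np.random.default_rng(seed)
    norm = normalize_log(adata)
    genes = [g for g in gene_set if g in norm.var_names]
    if not genes:
        raise ValueError("no signature genes present in the matrix")
    X = np.asarray(norm.X)
    var_names = list(norm.var_names)
    avg = X.mean(axis=0)
    ranks = pd.Series(avg, index=var_names).rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(var_names)), labels=False, duplicates="drop")
    bin_members: dict[int, np.ndarray] = {
        b: np.flatnonzero(bins.to_numpy() == b) for b in np.unique(bins)
    }
    gene_idx = [var_names.index(g) for g in genes]
    ctrl_idx: list[np.ndarray] = []
    for gi in gene_idx:
        members = bin_members[int(bins.iloc[gi])]
        pool = members[members != gi]
        if len(pool) == 0:
            pool = members
        take = rng.choice(pool, size=min(n_ctrl, len(pool)), replace=len(pool) < n_ctrl)
        ctrl_idx.append(take)
    sig_mean = X[:, gene_idx].mean(axis=1)
    ctrl_mean = np.mean([X[:, idx].mean(axis=1) for idx in ctrl_idx], axis=0)
    return pd.Series(sig_mean - ctrl_mean, index=norm.obs_names, name="module_score")


@dataclass
class MalignancyCall:
    label: str       # malignant | premalignant-pDC | normal | occult-malignant
    provenance: str


def classify_malignancy(
    annotations: pd.DataFrame,
    scores: pd.Series,
    involvement: dict,
    genotypes: pd.DataFrame | None = None,
    threshold: float = SCORE_THRESHOLD,
    pdc_label: str = "pDC",
) -> pd.DataFrame:
    """Per-cell malignancy classification.

    Rules, in order of precedence per cell:

    * pDC in an involved sample -> ``malignant``;
    * score > threshold in an involved sample (any type) -> ``malignant``;
    * score > threshold in an uninvolved sample -> ``occult-malignant``;
    * pDC in an uninvolved sample, score <= threshold, and no progression
      mutation -> ``premalignant-pDC``;
    * otherwise ``normal``.

    ``annotations`` needs ``predicted_type`` and ``sample_id`` columns;
    ``genotypes`` (optional) needs a boolean ``has_progression_mutation``.
    """
    has_prog = pd.Series(False, index=annotations.index)
    if genotypes is not None and "has_progression_mutation" in genotypes:
        has_prog.update(genotypes["has_progression_mutation"].astype(bool))
    rows = []
    for cell, row in annotations.iterrows():
        involved = bool(involvement.get(row["sample_id"], False))
        is_pdc = row["predicted_type"] == pdc_label
        high = scores.get(cell, 0.0) > threshold
        if is_pdc and involved:
            lab, why = "malignant", "pDC in involved sample"
        elif high and involved:
            lab, why = "malignant", "score above threshold (reclassified)"
        elif high:
            lab, why = "occult-malignant", "score above threshold in uninvolved sample"
        elif is_pdc and not involved and not has_prog[cell]:
            lab, why = "premalignant-pDC", "pDC in uninvolved sample, founder-only genotype"
        else:
            lab, why = "normal", "no rule fired"
        rows.append({"label": lab, "provenance": why})
    return pd.DataFrame(rows, index=annotations.index)


def genotype_enrichment(
    calls: pd.DataFrame, genotypes: pd.DataFrame, high_labels=("occult-malignant", "malignant")
) -> dict:
    """Fisher's exact test of progression-mutation enrichment in high-score cells.

    Returns the 2x2 table (high/low score class x progression-mutant or not),
    odds ratio and two-sided p. Cells without genotype information are
    excluded; an empty genotype table yields a flagged result without a test.
    """
    if genotypes is None or genotypes.empty:
        return {"table": None, "odds_ratio": None, "p_value": None, "flagged": True}
    joined = calls.join(genotypes[["has_progression_mutation"]], how="inner")
    high = joined["label"].isin(high_labels)
    prog = joined["has_progression_mutation"].astype(bool)
    table = [
        [int((high & prog).sum()), int((high & ~prog).sum())],
        [int((~high & prog).sum()), int((~high & ~prog).sum())],
    ]
    res = fisher_exact(table)
    return {
        "table": table,
        "odds_ratio": res.odds_ratio,
        "p_value": res.p_value,
        "flagged": False,
    }
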