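"""Single-cell expression and expressed-variant genotyping-read simulator.

Expression counts follow a gamma-Poisson (negative binomial) model with
cell-type-specific marker-gene shifts on the log scale; a configurable slice
of each cell's library is mitochondrial so that QC filtering is exercisable.
Genotyping reads emulate targeted enrichment of expressed variants: per cell
and locus the number of captured transcripts (UMIs) is Poisson, each UMI
carries the allele implied by the cell's clone genotype subject to allelic
dropout, and every read of a UMI flips allele with a symmetric per-read error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd


@dataclass
class SingleCellPlan:
    """Shape of the simulated single-cell experiment."""

    cells_per_type: dict[str, int]
    n_genes: int = 1500
    n_markers_per_type: int = 10
    marker_log_effect: float = 2.0
    mean_umis_per_cell: float = 8000.0
    dispersion: float = 0.3  # NB over-dispersion (1/size)
    mito_fraction_mean: float = 0.05
    n_mito_genes: int = 10
    # genotyping
    capture_rate: float = 2.0       # lambda: UMIs per cell per locus
    allelic_dropout: float = 0.2    # P(mutant allele silenced at a cell-locus)
    per_read_error: float = 0.005   # epsilon
    mean_reads_per_umi: float = 5.0
    doublet_rate: float = 0.0
    biology_seed: int = 0  # fixes gene means/markers so datasets share biology

    def __post_init__(self) -> None:
        for name in ("allelic_dropout", "per_read_error", "doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(n < 0 for n in self.cells_per_type.values()):
            raise ValueError("cell counts must be non-negative")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_sc_data(
    plan: SingleCellPlan,
    seed: int,
    mutation_ids: list[str] | None = None,
    clone_of_cell: dict[str, str] | None = None,
    carriers_of: dict[str, set[str]] | None = None,
    hemizygous: set[str] | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate an expression matrix with truth labels plus a genotyping read table.

    Returns ``(adata, read_table)``. ``adata.obs`` carries ``true_type`` (and
    ``clone`` when a clone assignment is given); ``adata.uns['markers']`` maps
    each type to its planted marker genes. The read table has columns
    ``locus, cell_barcode, umi, read_index, allele`` with allele in
    {WT, MUT} (ambiguous reads are produced downstream by read matching, not
    here). ``carriers_of`` maps mutation id -> set of clones carrying it.
    """
    rng = np.random.default_rng(seed)
    rng_bio = np.random.default_rng(plan.biology_seed)
    types = sorted(plan.cells_per_type)
    n_cells = sum(plan.cells_per_type.values())
    n_genes = plan.n_genes
    gene_names = [f"GENE{j:04d}" for j in range(n_genes - plan.n_mito_genes)]
    gene_names += [f"MT-{j}" for j in range(plan.n_mito_genes)]
    mito_mask = np.array([g.startswith("MT-") for g in gene_names])

    base = rng_bio.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base[mito_mask] = base[mito_mask].mean()  # uniform mito pool
    markers: dict[str, list[str]] = {}
    type_mean = {}
    nonmito = np.where(~mito_mask)[0]
    for i, t in enumerate(types):
        mu = base.copy()
        idx = nonmito[i * plan.n_markers_per_type: (i + 1) * plan.n_markers_per_type]
        mu[idx] = mu[idx] * np.exp(plan.marker_log_effect)
        markers[t] = [gene_names[j] for j in idx]
        type_mean[t] = mu

    barcodes, truth, rows = [], [], []
    ci = 0
    for t in types:
        for _ in range(plan.cells_per_type[t]):
            barcodes.append(f"CELL{ci:05d}")
            truth.append(t)
            ci += 1
    X = np.zeros((n_cells, n_genes), dtype=np.int64)
    is_doublet = rng.random(n_cells) < plan.doublet_rate
    for i, t in enumerate(truth):
        mu = type_mean[t]
        if is_doublet[i] and len(types) > 1:
            other = types[(types.index(t) + 1 + rng.integers(len(types) - 1)) % len(types)]
            mu = 0.5 * (mu + type_mean[other])
        size = rng.lognormal(np.log(plan.mean_umis_per_cell), 0.3)
        mito_target = np.clip(rng.normal(plan.mito_fraction_mean, 0.02), 0.0, 0.9)
        mu = mu.copy()
        mu[mito_mask] = mu[mito_mask] / mu[mito_mask].sum() * mito_target * mu[~mito_mask].sum() / max(1e-12, 1 - mito_target)
        mu = mu / mu.sum() * size
        X[i] = _nb_counts(rng, mu, plan.dispersion)
    obs = pd.DataFrame({"true_type": truth, "is_doublet_truth": is_doublet}, index=barcodes)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=gene_names))
    adata.uns["markers"] = markers

    # genotyping reads
    if clone_of_cell:
        adata.obs["clone"] = [clone_of_cell.get(b, "") for b in barcodes]
    read_rows = []
    if mutation_ids:
        carriers_of = carriers_of or {}
        hemizygous = hemizygous or set()
        for locus in mutation_ids:
            carriers = carriers_of.get(locus, set())
            for b in barcodes:
                clone = (clone_of_cell or {}).get(b, "")
                is_mut = clone in carriers
                n_umis = rng.poisson(plan.capture_rate)
                for u in range(n_umis):
                    allele = "MUT" if is_mut else "WT"
                    if is_mut and rng.random() < plan.allelic_dropout:
                        allele = "WT" if locus not in hemizygous else "MUT"
                        # at a single-allele locus there is no second allele to
                        # fall back on; dropout there removes the UMI instead
                        if locus in hemizygous:
                            continue
                    n_reads = max(1, rng.poisson(plan.mean_reads_per_umi))
                    for r in range(n_reads):
                        obs_allele = allele
                        if rng.random() < plan.per_read_error:
                            obs_allele = "WT" if allele == "MUT" else "MUT"
                        read_rows.append(
                            {
                                "locus": locus,
                                "cell_barcode": b,
                                "umi": f"{b}.{locus}.u{u}",
                                "read_index": r,
                                "allele": obs_allele,
                            }
                        )
    read_table = pd.DataFrame(
        read_rows, columns=["locus", "cell_barcode", "umi", "read_index", "allele"]
    )
    return adata, read_table
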