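"""Host/donor deconvolution of post-transplant single cells.

Bulk B-allele frequencies of the germline (host) genome and of a mixed
post-transplant sample identify SNVs informative for each genome; aggregated
UMI-deduplicated single-cell coverage over informative alleles then labels
each cell host or donor with conservative 10%/90% donor-fraction thresholds.

A site's host genotype is read directly from the germline BAF; the donor
genotype is inferred from the mixed-sample BAF given the bulk host fraction.
An allele is host-specific when the host carries it and the donor does not
(and vice versa); sites where the two genomes are homozygous for opposite
alleles are informative for both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PanelParams:
    t_hom: float = 0.05            # bulk BAF within t_hom of 0/1 => homozygous
    max_residual: float = 0.1      # mixed BAF must sit this close to a genotype model
    host_fraction: float = 0.5     # bulk host fraction of the mixed sample
    exclude_chroms: tuple = ("chrX", "chrY")


def _host_dosage(g: np.ndarray, t: float) -> np.ndarray:
    """B-allele dosage of the host genome (0, 0.5, 1) from germline BAF."""
    d = np.full(len(g), 0.5)
    d[g <= t] = 0.0
    d[g >= 1 - t] = 1.0
    return d


def select_informative_snvs(
    bulk: pd.DataFrame,
    cna_mask: list | None = None,
    params: PanelParams | None = None,
) -> pd.DataFrame:
    """Build the informative-SNV panel from bulk germline and mixed-sample BAFs.

    ``bulk`` is indexed by site id with columns ``chrom, pos, germline_baf,
    mixed_baf``. The donor's B-allele dosage at each site is the genotype in
    {0, 1/2, 1} whose predicted mixed BAF (``hf*host + (1-hf)*donor``) is
    nearest to the observed one; sites whose best model still misses by more
    than ``max_residual`` are discarded. Classes:

    * ``host-informative``: an allele present in the host but not the donor
      (and no donor-specific allele);
    * ``donor-informative``: the mirror image;
    * ``dual-informative``: the genomes are homozygous for opposite alleles.

    ``cna_mask`` is a list of ``(chrom, start, end)`` regions to exclude
    (broad somatic copy-number changes distort the mixed BAF); X/Y are always
    excluded. A missing mask warns and proceeds with the chromosome filter
    only.
    """
    params = params or PanelParams()
    if cna_mask is None:
        warnings.warn("no CNA mask supplied; proceeding with autosome/XY filtering only")
        cna_mask = []
    hf = params.host_fraction
    g = bulk["germline_baf"].to_numpy(dtype=float)
    m = bulk["mixed_baf"].to_numpy(dtype=float)
    h = _host_dosage(g, params.t_hom)

    donor_options = np.array([0.0, 0.5, 1.0])
    pred = hf * h[:, None] + (1 - hf) * donor_options[None, :]
    resid = np.abs(m[:, None] - pred)
    d = donor_options[resid.argmin(axis=1)]
    ok = resid.min(axis=1) <= params.max_residual

    host_has_b, host_has_a = h > 0, h < 1
    donor_has_b, donor_has_a = d > 0, d < 1

    host_allele = np.full(len(bulk), "", dtype=object)
    donor_allele = np.full(len(bulk), "", dtype=object)
    host_allele[host_has_b & ~donor_has_b] = "B"
    host_allele[host_has_a & ~donor_has_a] = "A"
    donor_allele[donor_has_b & ~host_has_b] = "B"
    donor_allele[donor_has_a & ~host_has_a] = "A"

    cls = np.full(len(bulk), "uninformative", dtype=object)
    cls[(host_allele != "") & (donor_allele == "")] = "host-informative"
    cls[(host_allele == "") & (donor_allele != "")] = "donor-informative"
    cls[(host_allele != "") & (donor_allele != "")] = "dual-informative"
    cls[~ok] = "uninformative"

    panel = bulk.copy()
    panel["class"] = cls
    panel["host_allele"] = host_allele
    panel["donor_allele"] = donor_allele
    keep = (panel["class"] != "uninformative") & ~panel["chrom"].isin(params.exclude_chroms)
    for chrom, start, end in cna_mask:
        keep &= ~((panel["chrom"] == chrom) & (panel["pos"] >= start) & (panel["pos"] <= end))
    return panel[keep].copy()


def aggregate_cell_alleles(pileup: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summed coverage of host-specific and donor-specific alleles.

    ``pileup`` carries ``cell_barcode, site_id, base, umi``; duplicate reads
    of one UMI at one site count once. Only panel sites contribute; a read
    supports the host when its base equals the site's host-specific allele
    and the donor when it equals the donor-specific allele.
    """
    sub = pileup[pileup["site_id"].isin(panel.index)]
    sub = sub.drop_duplicates(subset=["cell_barcode", "site_id", "umi"])
    host_of = panel["host_allele"].reindex(sub["site_id"]).fillna("").to_numpy()
    donor_of = panel["donor_allele"].reindex(sub["site_id"]).fillna("").to_numpy()
    base = sub["base"].to_numpy()
    agg = (
        pd.DataFrame(
            {
                "cell_barcode": sub["cell_barcode"].to_numpy(),
                "host_cov": (base == host_of).astype(int),
                "donor_cov": (base == donor_of).astype(int),
            }
        )
        .groupby("cell_barcode")
        .sum()
    )
    agg["total"] = agg["host_cov"] + agg["donor_cov"]
    return agg


def classify_cells(
    coverage: pd.DataFrame,
    min_coverage: int = 10,
    host_max_donor_fraction: float = 0.10,
    donor_min_fraction: float = 0.90,
) -> tuple[pd.DataFrame, dict]:
    """Label each cell host / donor / ambiguous-removed / insufficient.

    A cell needs informative-allele coverage of at least ``min_coverage``;
    a donor fraction (donor / (host + donor)) below 10% labels it host,
    above 90% donor, and anything between is removed as a potential multiplet
    but retained in the output for auditability. Also returns sample-level
    chimerism summaries.
    """
    out = coverage.copy()
    total = out["total"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, out["donor_cov"] / np.maximum(total, 1), np.nan)
    out["donor_fraction"] = frac
    label = np.full(len(out), "ambiguous-removed", dtype=object)
    label[total < min_coverage] = "insufficient"
    ok = total >= min_coverage
    label[ok & (frac < host_max_donor_fraction)] = "host"
    label[ok & (frac > donor_min_fraction)] = "donor"
    out["label"] = label
    n_host = int((out["label"] == "host").sum())
    n_donor = int((out["label"] == "donor").sum())
    n_amb = int((out["label"] == "ambiguous-removed").sum())
    n_assigned = n_host + n_donor
    summary = {
        "n_host": n_host,
        "n_donor": n_donor,
        "n_ambiguous": n_amb,
        "n_insufficient": int((out["label"] == "insufficient").sum()),
        "donor_chimerism": n_donor / n_assigned if n_assigned else np.nan,
        "annotated_fraction": (n_assigned + n_amb) / len(out) if len(out) else np.nan,
    }
    return out, summary
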