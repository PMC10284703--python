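"""Host/donor chimerism simulator for post-transplant samples.

Generates (i) bulk B-allele frequencies of the germline (host) and of a
post-transplant mixed sample, (ii) a ground-truth informative-SNV panel, and
(iii) a single-cell UMI pileup over panel sites. Abstract alleles 'A' and 'B'
stand for the two bases at each site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ChimeraPlan:
    n_host_informative: int = 60
    n_donor_informative: int = 60
    n_dual_informative: int = 30
    n_uninformative: int = 100   # both genomes het or same homozygote
    n_cells: int = 500
    host_fraction: float = 0.5
    mean_site_coverage: float = 0.25  # UMIs per cell per panel site
    per_base_error: float = 0.002
    bulk_depth: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ValueError("host_fraction must be in [0, 1]")


def _genotypes(plan: ChimeraPlan) -> pd.DataFrame:
    """Truth genotype table: B-allele dosage (0, 1, 2) per genome per site.

    host-informative: host het A/B, donor A/A — allele B occurs only in host.
    donor-informative: host A/A, donor het A/B — allele B occurs only in donor.
    dual-informative: host B/B, donor A/A — each genome homozygous for its
    own allele, so both alleles are genome-specific.
    """
    rows = []
    i = 0
    for _ in range(plan.n_host_informative):
        rows.append({"site_id": f"s{i:05d}", "host_b": 1, "donor_b": 0, "true_class": "host-informative"})
        i += 1
    for _ in range(plan.n_donor_informative):
        rows.append({"site_id": f"s{i:05d}", "host_b": 0, "donor_b": 1, "true_class": "donor-informative"})
        i += 1
    for _ in range(plan.n_dual_informative):
        rows.append({"site_id": f"s{i:05d}", "host_b": 2, "donor_b": 0, "true_class": "dual-informative"})
        i += 1
    for j in range(plan.n_uninformative):
        hb = [1, 0, 2][j % 3]
        rows.append({"site_id": f"s{i:05d}", "host_b": hb, "donor_b": hb, "true_class": "uninformative"})
        i += 1
    df = pd.DataFrame(rows).set_index("site_id")
    n_chroms = 10
    df["chrom"] = [f"chr{(k % n_chroms) + 1}" for k in range(len(df))]
    df["pos"] = [1000 + 137 * k for k in range(len(df))]
    return df


def simulate_chimera(plan: ChimeraPlan, seed: int) -> dict:
    """Simulate a chimeric sample.

    Returns a dict with keys:

    ``genotypes``  truth genotype table per site;
    ``bulk``       per-site germline and mixed-sample BAF/depth;
    ``pileup``     per-UMI single-cell records (cell_barcode, site_id, chrom,
                   pos, base in {A,B}, umi);
    ``cells``      truth labels per cell (host|donor).
    """
    rng = np.random.default_rng(seed)
    geno = _genotypes(plan)
    hf = plan.host_fraction

    depth = rng.poisson(plan.bulk_depth, size=len(geno)).clip(min=1)
    host_p = geno["host_b"].to_numpy() / 2.0
    donor_p = geno["donor_b"].to_numpy() / 2.0
    mixed_p = hf * host_p + (1 - hf) * donor_p
    e = plan.per_base_error
    germ_b = rng.binomial(depth, host_p * (1 - e) + (1 - host_p) * e)
    mixed_depth = rng.poisson(plan.bulk_depth, size=len(geno)).clip(min=1)
    mixed_b = rng.binomial(mixed_depth, mixed_p * (1 - e) + (1 - mixed_p) * e)
    bulk = pd.DataFrame(
        {
            "chrom": geno["chrom"],
            "pos": geno["pos"],
            "germline_baf": germ_b / depth,
            "germline_depth": depth,
            "mixed_baf": mixed_b / mixed_depth,
            "mixed_depth": mixed_depth,
        },
        index=geno.index,
    )

    n_host = int(round(plan.n_cells * hf))
    labels = np.array(["host"] * n_host + ["donor"] * (plan.n_cells - n_host))
    rng.shuffle(labels)
    barcodes = [f"CB{i:05d}" for i in range(plan.n_cells)]
    cells = pd.DataFrame({"true_origin": labels}, index=barcodes)

    pile_rows = []
    b_dose = {"host": geno["host_b"].to_numpy(), "donor": geno["donor_b"].to_numpy()}
    site_ids = geno.index.to_numpy()
    chroms = geno["chrom"].to_numpy()
    poss = geno["pos"].to_numpy()
    for b, origin in zip(barcodes, labels):
        n_umis = rng.poisson(plan.mean_site_coverage, size=len(geno))
        dose = b_dose[origin]
        for si in np.nonzero(n_umis)[0]:
            p_b = dose[si] / 2.0
            for u in range(n_umis[si]):
                base = "B" if rng.random() < p_b else "A"
                if plan.per_base_error > 0 and rng.random() < plan.per_base_error:
                    base = "A" if base == "B" else "B"
                pile_rows.append(
                    {
                        "cell_barcode": b,
                        "site_id": site_ids[si],
                        "chrom": chroms[si],
                        "pos": poss[si],
                        "base": base,
                        "umi": f"{b}.{site_ids[si]}.u{u}",
                    }
                )
    pileup = pd.DataFrame(
        pile_rows, columns=["cell_barcode", "site_id", "chrom", "pos", "base", "umi"]
    )
    return {"genotypes": geno, "bulk": bulk, "pileup": pileup, "cells": cells}
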