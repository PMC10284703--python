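import numpy as np
import pandas as pd
import pytest

from uvclone.catalogue import synthetic_catalogue
from uvclone.sim import SamplePlan, patient10_like_tree
from uvclone.sim.bulk import simulate_bulk_vafs
from uvclone.sim.tree import simulate_clonal_tree
from uvclone.tables import VariantTable, make_sample_frame


@pytest.fixture(scope="session")
def catalogue():
    return synthetic_catalogue()


@pytest.fixture(scope="session")
def demo_tree(catalogue):
    return patient10_like_tree(catalogue)


@pytest.fixture(scope="session")
def demo_table(catalogue, demo_tree):
    """Patient-10-like three-sample variant table with planted truth."""
    mut_cat = simulate_clonal_tree(demo_tree, 11, catalogue)
    plans = [
        SamplePlan("marrow", "marrow",
                   {"f1": 0.2, "f2": 0.2, "f3": 0.14, "f4": 0.2, "shared_skin": 0.04},
                   mean_depth=200.0),
        SamplePlan("skin1", "skin",
                   {"f4": 0.05, "shared_skin": 0.1, "skin1": 0.65}, mean_depth=200.0),
        SamplePlan("skin2", "skin",
                   {"f4": 0.05, "shared_skin": 0.1, "skin2": 0.65}, mean_depth=200.0),
    ]
    return simulate_bulk_vafs(demo_tree, mut_cat, plans, 12)


def make_variant_table(vaf_rows, samples, depth=100.0, **variant_cols):
    """Small hand-built VariantTable: vaf_rows is {variant_id: [vaf per sample]}."""
    ids = list(vaf_rows)
    n = len(ids)
    variants = pd.DataFrame(
        {
            "chrom": variant_cols.get("chrom", ["chr1"] * n),
            "pos": variant_cols.get("pos", list(range(1000, 1000 + n))),
            "ref": variant_cols.get("ref", ["C"] * n),
            "alt": variant_cols.get("alt", ["T"] * n),
            "gene": variant_cols.get("gene", [""] * n),
            "gene_strand": variant_cols.get("gene_strand", [""] * n),
            "context": variant_cols.get("context", ["ACA"] * n),
        },
        index=pd.Index(ids, name="variant_id"),
    )
    calls = []
    sample_ids = [s[0] for s in samples]
    for vid, vafs in vaf_rows.items():
        for s, v in zip(sample_ids, vafs):
            calls.append({"variant_id": vid, "sample_id": s, "vaf": v, "depth": depth})
    return VariantTable(
        variants=variants,
        calls=pd.DataFrame(calls),
        samples=make_sample_frame(samples),
    )
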