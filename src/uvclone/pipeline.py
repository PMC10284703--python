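"""End-to-end orchestration of the demo analysis on simulated data.

Stages run in dependency order: simulate -> phylogenomics -> signatures ->
single-cell genotyping -> cell typing -> malignancy -> chimerism -> report.
Each stage's headline numbers are collected in a JSON-serialisable report,
and a manifest records the seed, configuration and per-stage row counts so a
run can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalogue import UV_SIGNATURE, synthetic_catalogue
from .celltyping import find_markers, predict_cells, qc_filter, train_classifier
from .chimerism import aggregate_cell_alleles, classify_cells, select_informative_snvs
from .malignancy import GroupSpec, classify_malignancy, derive_signature, module_score
from .phylo import (
    FilterParams,
    attribute_variants,
    build_sample_phylogeny,
    compute_vaf_dispersion,
    filter_somatic_variants,
    partition_founder_progression,
)
from .signatures import build_spectrum, refit_contributions, strand_asymmetry, uv_metrics
from .sim import ChimeraPlan, SamplePlan, SingleCellPlan, patient10_like_tree
from .sim.bulk import simulate_bulk_vafs
from .sim.chimera import simulate_chimera
from .sim.singlecell import simulate_sc_data
from .sim.tree import simulate_clonal_tree
from .xvseq import LocusSpec, genotype_cells


DEFAULT_SAMPLE_PLANS = [
    # marrow: founder lineage dominates with nested subclone fractions; the
    # transformed precursor is present at trace level only
    dict(sample_id="marrow", tissue="marrow",
         clone_fractions={"f1": 0.2, "f2": 0.2, "f3": 0.14, "f4": 0.2, "shared_skin": 0.04},
         mean_depth=200.0),
    dict(sample_id="skin1", tissue="skin",
         clone_fractions={"f4": 0.05, "shared_skin": 0.1, "skin1": 0.65},
         mean_depth=200.0),
    dict(sample_id="skin2", tissue="skin",
         clone_fractions={"f4": 0.05, "shared_skin": 0.1, "skin2": 0.65},
         mean_depth=200.0),
]


def default_config(seed: int = 0) -> dict:
    return {
        "seed": int(seed),
        "sample_plans": DEFAULT_SAMPLE_PLANS,
        "n_sc_cells_per_type": {"pDC": 120, "Mono": 120, "HSC": 120},
        "chimera": {"n_cells": 300, "host_fraction": 0.5},
        "stages": ["simulate", "phylo", "signatures", "genotype",
                   "celltype", "malignancy", "chimerism"],
    }


def _shared_tc_tt_fraction(table, sample_a: str, sample_b: str) -> dict:
    """Fraction of UV-class TC>TT mutations shared between two samples."""
    a = set(uv_metrics(table, sample_a).tc_tt_variant_ids)
    b = set(uv_metrics(table, sample_b).tc_tt_variant_ids)
    union = a | b
    shared = a & b
    return {
        "n_shared": len(shared),
        "n_total": len(union),
        "fraction": len(shared) / len(union) if union else float("nan"),
    }


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run the demo pipeline; returns the report (with ``manifest`` inside).

    Every stage consumes only simulated inputs generated under the run seed,
    so two runs with identical config produce identical reports.
    """
    config = config or default_config()
    seed = int(config.get("seed", 0))
    rng_seeds = {name: (seed * 1000003 + i) % (2**31) for i, name in enumerate(
        ["tree", "bulk", "sc", "chimera", "classifier", "signature", "score"]
    )}
    stages = config.get("stages", ["simulate", "phylo", "signatures", "genotype",
                                   "celltype", "malignancy", "chimerism"])
    report: dict = {"schema_version": 1, "seed": seed}
    counts: dict = {}

    catalogue = synthetic_catalogue()
    tree = patient10_like_tree(catalogue)
    mut_catalogue = simulate_clonal_tree(tree, rng_seeds["tree"], catalogue)
    plans = [SamplePlan(**p) for p in config["sample_plans"]]
    table = simulate_bulk_vafs(tree, mut_catalogue, plans, rng_seeds["bulk"])
    counts["mutations"] = len(table.variants)

    if "phylo" in stages:
        germline = pd.Series(0.0, index=table.variants.index)
        filtered, audit = filter_somatic_variants(table, germline, FilterParams())
        attribution = attribute_variants(filtered)
        founder, progression = partition_founder_progression(filtered, attribution)
        phylo = build_sample_phylogeny(filtered)
        vafs = filtered.vaf_matrix()
        founder_vafs = vafs.loc[sorted(founder), "marrow"]
        report["phylo"] = {
            "n_retained": int(audit["retained"].sum()),
            "n_founder": len(founder),
            "n_progression": len(progression),
            "n_conflicts": len(phylo.conflicts),
            "founder_vaf_cv": compute_vaf_dispersion(founder_vafs),
        }
        counts["retained_variants"] = int(audit["retained"].sum())
        table = filtered

    if "signatures" in stages:
        sig_report = {}
        for s in table.sample_order:
            spec96 = build_spectrum(table, s)
            contrib = refit_contributions(spec96, catalogue)
            m = uv_metrics(table, s)
            sig_report[s] = {
                "n_snvs": spec96.n_snvs,
                "uv_contribution": contrib.uv_contribution(UV_SIGNATURE),
                "tc_tt_fraction": m.tc_tt_fraction,
                "cc_ct_fraction": m.cc_ct_fraction,
                "n_cc_tt_dinucleotides": m.n_cc_tt_dinucleotides,
            }
        strand = strand_asymmetry(table)
        sig_report["strand"] = {
            k: {"nontemplate_fraction": v.nontemplate_fraction, "p": v.p_value}
            for k, v in strand.items()
        }
        sig_report["shared_tc_tt_skin1_skin2"] = _shared_tc_tt_fraction(table, "skin1", "skin2")
        report["signatures"] = sig_report

    adata = genotype_df = None
    if {"genotype", "celltype", "malignancy"} & set(stages):
        # assign single cells to clones: pDCs in the involved sample are
        # malignant (skin1 lineage), some marrow pDCs carry founder-only clones
        sc_plan = SingleCellPlan(cells_per_type=config["n_sc_cells_per_type"])
        cells_per_type = sc_plan.cells_per_type
        n_cells = sum(cells_per_type.values())
        rng = np.random.default_rng(rng_seeds["sc"])
        barcodes = [f"CELL{i:05d}" for i in range(n_cells)]
        types = [t for t in sorted(cells_per_type) for _ in range(cells_per_type[t])]
        clone_of_cell = {}
        for b, t in zip(barcodes, types):
            if t == "pDC":
                clone_of_cell[b] = "skin1" if rng.random() < 0.6 else "f4"
            else:
                clone_of_cell[b] = "f1" if rng.random() < 0.3 else ""
        # genotype two loci: one founder, one progression mutation
        founder_mut = mut_catalogue.index[mut_catalogue["clone"] == "f1"][0]
        prog_mut = mut_catalogue.index[mut_catalogue["clone"] == "shared_skin"][0]
        carriers = {
            founder_mut: tree.descendants("f1"),
            prog_mut: tree.descendants("shared_skin"),
        }
        adata, read_table = simulate_sc_data(
            sc_plan, rng_seeds["sc"], [founder_mut, prog_mut], clone_of_cell, carriers
        )
        adata.obs["sample_id"] = "patient_marrow"
        counts["sc_cells"] = adata.n_obs

    if "genotype" in stages and adata is not None:
        genos = {}
        for locus in read_table["locus"].unique():
            spec = LocusSpec(locus_id=locus, wt_sequence="ACGT", mut_sequence="ACTT")
            genos[locus] = genotype_cells(read_table, spec)
        genotype_df = pd.DataFrame(index=adata.obs_names)
        genotype_df["has_progression_mutation"] = (
            genos.get(prog_mut, pd.DataFrame())
            .reindex(adata.obs_names)["call"]
            .eq("MUT")
            .fillna(False)
            if prog_mut in genos
            else False
        )
        report["genotype"] = {
            locus: dict(g["call"].value_counts()) for locus, g in genos.items()
        }
        for locus in report["genotype"]:
            report["genotype"][locus] = {k: int(v) for k, v in report["genotype"][locus].items()}

    if "celltype" in stages and adata is not None:
        qc_adata, qc_report = qc_filter(adata)
        even = np.arange(qc_adata.n_obs) % 2 == 0  # stratified-ish split by interleaving
        ref = qc_adata[even].copy()
        ref.obs["cell_type"] = ref.obs["true_type"].to_numpy()
        query = qc_adata[~even].copy()
        markers = find_markers(ref)
        clf = train_classifier(ref, markers, seed=rng_seeds["classifier"] % (2**31))
        scores = predict_cells(clf, query)
        acc = float((scores["predicted_type"] == query.obs["true_type"]).mean())
        report["celltype"] = {
            "n_qc_pass": int(qc_report["retained"].sum()),
            "cv_accuracy": clf.cv_accuracy,
            "query_accuracy": acc,
        }
        adata_scored = query
        annotations = scores[["predicted_type"]].copy()
        annotations["sample_id"] = adata_scored.obs["sample_id"].to_numpy()

    if "malignancy" in stages:
        # dedicated mini-cohort: healthy-like pDCs vs malignant pDCs with a
        # planted up-regulated programme, spread over pseudo-samples so the
        # per-sample downsampling cap leaves both groups well powered
        mal_plan = SingleCellPlan(
            cells_per_type={"pDC": 300, "pDC_malignant": 300},
            n_markers_per_type=45,
            marker_log_effect=2.0,
        )
        mal_adata, _ = simulate_sc_data(mal_plan, rng_seeds["signature"])
        n_pseudo = 10
        mal_adata.obs["sample_id"] = [
            f"{'inv' if t == 'pDC_malignant' else 'uninv'}{i % n_pseudo}"
            for i, t in enumerate(mal_adata.obs["true_type"])
        ]
        ref_cells = list(mal_adata.obs_names[mal_adata.obs["true_type"] == "pDC"])
        mal_cells = list(mal_adata.obs_names[mal_adata.obs["true_type"] == "pDC_malignant"])
        groups = GroupSpec(reference_cells=ref_cells, involved_cells=mal_cells)
        sig = derive_signature(mal_adata, groups, seed=rng_seeds["signature"] % (2**31))
        planted = set(mal_adata.uns["markers"]["pDC_malignant"])
        score = module_score(mal_adata, sig.genes or sorted(planted),
                             seed=rng_seeds["score"] % (2**31))
        annotations_mal = pd.DataFrame(
            {"predicted_type": "pDC", "sample_id": mal_adata.obs["sample_id"]},
            index=mal_adata.obs_names,
        )
        involvement = {s: s.startswith("inv") for s in mal_adata.obs["sample_id"].unique()}
        calls = classify_malignancy(annotations_mal, score, involvement)
        recovered = len(planted & set(sig.genes))
        report["malignancy"] = {
            "n_signature_genes": len(sig.genes),
            "n_planted_recovered": recovered,
            "n_false_positive_genes": len(set(sig.genes) - planted),
            "mean_score_malignant": float(score[mal_cells].mean()),
            "mean_score_reference": float(score[ref_cells].mean()),
            "labels": {k: int(v) for k, v in calls["label"].value_counts().items()},
        }

    if "chimerism" in stages:
        chim_cfg = config.get("chimera", {})
        plan = ChimeraPlan(**chim_cfg)
        sim = simulate_chimera(plan, rng_seeds["chimera"])
        panel = select_informative_snvs(sim["bulk"], cna_mask=[])
        agg = aggregate_cell_alleles(sim["pileup"], panel)
        labelled, summary = classify_cells(agg)
        truth = sim["cells"]["true_origin"]
        joined = labelled.join(truth, how="left")
        assigned = joined[joined["label"].isin(["host", "donor"])]
        acc = float((assigned["label"] == assigned["true_origin"]).mean()) if len(assigned) else float("nan")
        report["chimerism"] = {**summary, "accuracy_vs_truth": acc,
                               "n_panel_sites": len(panel)}
        counts["panel_sites"] = len(panel)

    report["manifest"] = {
        "uvclone_version": __version__,
        "seed": seed,
        "derived_seeds": rng_seeds,
        "config": {k: v for k, v in config.items()},
        "row_counts": counts,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
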