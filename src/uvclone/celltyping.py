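"""QC filtering, reference-based cell-type classification and projection.

The reference is a labelled healthy-marrow atlas. Marker genes are found by
one-vs-rest rank-sum testing, a probabilistic bagged-tree classifier is
trained on marker-gene expression with stratified five-fold cross-validation,
patient cells receive per-type probability vectors (argmax call, doublet
exclusion), and each patient cell is projected onto the 2-D coordinates of
the reference cell whose prediction-score vector it correlates with best.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

DOUBLET_LABEL = "Doublet"


@dataclass
class QCParams:
    min_umis: float = 2000.0    # strict >
    min_genes: float = 1000.0   # strict >
    max_mito_fraction: float = 0.20  # strict <
    rrna_genes: set = field(default_factory=set)


def qc_filter(adata: ad.AnnData, params: QCParams | None = None) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells on UMI/gene/mitochondrial thresholds (strict inequalities).

    The mitochondrial fraction is computed before mitochondrial (``MT-*``)
    and rRNA genes are removed from the matrix; X/Y genes are retained.
    Returns the filtered copy plus a per-cell QC report.
    """
    params = params or QCParams()
    X = adata.X
    counts = np.asarray(X.sum(axis=1)).ravel()
    genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith("MT-")
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    mito_frac = np.divide(mito, counts, out=np.zeros_like(mito, dtype=float), where=counts > 0)
    report = pd.DataFrame(
        {
            "n_umis": counts,
            "n_genes": genes,
            "mito_fraction": mito_frac,
            "pass_umis": counts > params.min_umis,
            "pass_genes": genes > params.min_genes,
            "pass_mito": mito_frac < params.max_mito_fraction,
        },
        index=adata.obs_names,
    )
    report["retained"] = report[["pass_umis", "pass_genes", "pass_mito"]].all(axis=1)
    drop_genes = mito_mask | adata.var_names.isin(params.rrna_genes)
    out = adata[report["retained"].to_numpy(), ~drop_genes].copy()
    out.obs["n_umis"] = report.loc[out.obs_names, "n_umis"].to_numpy()
    out.obs["mito_fraction"] = report.loc[out.obs_names, "mito_fraction"].to_numpy()
    return out, report


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Per-cell scaling to a fixed total followed by log1p (in a copy)."""
    out = adata.copy()
    out.X = out.X.astype(float)
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def find_markers(
    reference: ad.AnnData,
    label_key: str = "cell_type",
    n_top: int = 50,
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    """One-vs-rest rank-sum marker genes per reference type.

    Genes passing a Benjamini-Hochberg-corrected rank-sum screen are ranked
    by log fold change; the top ``n_top`` per type are returned.
    """
    if reference.obs[label_key].nunique() < 2:
        raise ValueError("need at least two reference types")
    norm = normalize_log(reference)
    sc.tl.rank_genes_groups(norm, groupby=label_key, method="wilcoxon", n_genes=norm.n_vars)
    res = norm.uns["rank_genes_groups"]
    markers: dict[str, list[str]] = {}
    for grp in res["names"].dtype.names:
        names = np.asarray(res["names"][grp])
        lfc = np.asarray(res["logfoldchanges"][grp])
        padj = np.asarray(res["pvals_adj"][grp])
        keep = (padj < alpha) & (lfc > 0)
        ranked = names[keep][np.argsort(-lfc[keep], kind="stable")]
        markers[grp] = list(ranked[:n_top])
    return markers


@dataclass
class TrainedClassifier:
    model: RandomForestClassifier
    marker_genes: list[str]
    classes: list[str]
    cv_accuracy: float
    reference_scores: pd.DataFrame  # out-of-fold probability vectors per reference cell


def train_classifier(
    reference: ad.AnnData,
    markers: dict[str, list[str]],
    label_key: str = "cell_type",
    n_estimators: int = 300,
    n_folds: int = 5,
    seed: int = 0,
) -> TrainedClassifier:
    """Train the reference classifier and report stratified CV accuracy.

    The default realisation is a bagged-tree ensemble (random forest) on
    normalised marker-gene expression; out-of-fold probability vectors per
    reference cell are stored for prediction-score-correlation projection.
    """
    genes = sorted({g for gs in markers.values() for g in gs})
    genes = [g for g in genes if g in reference.var_names]
    if not genes:
        raise ValueError("no marker genes present in the reference matrix")
    norm = normalize_log(reference)
    Xm = np.asarray(norm[:, genes].X)
    y = norm.obs[label_key].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two reference types")
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    proba = cross_val_predict(model, Xm, y, cv=cv, method="predict_proba", n_jobs=1)
    classes = sorted(np.unique(y))
    pred = np.array(classes)[proba.argmax(axis=1)]
    acc = float((pred == y).mean())
    model.fit(Xm, y)
    ref_scores = pd.DataFrame(proba, index=reference.obs_names, columns=classes)
    return TrainedClassifier(
        model=model,
        marker_genes=genes,
        classes=list(model.classes_),
        cv_accuracy=acc,
        reference_scores=ref_scores,
    )


def predict_cells(clf: TrainedClassifier, patient: ad.AnnData) -> pd.DataFrame:
    """Per-cell probability vectors, argmax calls and doublet flags.

    Marker genes absent from the patient matrix are imputed as zero (their
    names are recorded in the returned frame's ``attrs['imputed_genes']``).
    Argmax ties break lexicographically by type name.
    """
    norm = normalize_log(patient)
    present = [g for g in clf.marker_genes if g in norm.var_names]
    missing = [g for g in clf.marker_genes if g not in norm.var_names]
    X = np.zeros((norm.n_obs, len(clf.marker_genes)))
    if present:
        sub = np.asarray(norm[:, present].X)
        for j, g in enumerate(clf.marker_genes):
            if g in present:
                X[:, j] = sub[:, present.index(g)]
    proba = clf.model.predict_proba(X)
    classes = list(clf.model.classes_)
    # lexicographic tie-break: numpy argmax takes the first maximum and the
    # forest's classes_ are already sorted
    calls = np.array(classes)[proba.argmax(axis=1)]
    out = pd.DataFrame(proba, index=patient.obs_names, columns=classes)
    out["predicted_type"] = calls
    out["is_doublet"] = calls == DOUBLET_LABEL
    out["max_score"] = proba.max(axis=1)
    out.attrs["imputed_genes"] = missing
    return out


def project_to_reference(
    scores: pd.DataFrame,
    reference_scores: pd.DataFrame,
    reference_coords: pd.DataFrame,
) -> pd.DataFrame:
    """Place each patient cell at the coordinates of the best-correlated reference cell.

    Pearson correlation between the patient cell's probability vector and
    every reference cell's out-of-fold vector; ties break at the first
    reference index. Constant probability vectors have undefined correlation
    and receive no coordinates (flagged).
    """
    classes = [c for c in reference_scores.columns]
    P = scores[classes].to_numpy(dtype=float)
    R = reference_scores[classes].to_numpy(dtype=float)
    Pc = P - P.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    p_norm = np.linalg.norm(Pc, axis=1)
    r_norm = np.linalg.norm(Rc, axis=1)
    rows = []
    degenerate_ref = r_norm == 0
    for i, cell in enumerate(scores.index):
        if p_norm[i] == 0:
            rows.append({"ref_cell": None, "x": np.nan, "y": np.nan, "flagged": True})
            continue
        corr = (Rc @ Pc[i]) / (r_norm * p_norm[i] + 1e-300)
        corr[degenerate_ref] = -np.inf
        j = int(np.argmax(corr))
        ref_cell = reference_scores.index[j]
        rows.append(
            {
                "ref_cell": ref_cell,
                "x": float(reference_coords.loc[ref_cell].iloc[0]),
                "y": float(reference_coords.loc[ref_cell].iloc[1]),
                "flagged": False,
            }
        )
    return pd.DataFrame(rows, index=scores.index)
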