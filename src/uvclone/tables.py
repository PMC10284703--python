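"""Tabular containers shared across pipeline stages.

The central object is :class:`VariantTable`: a per-patient catalogue of
somatic variants with per-sample VAF/depth observations and per-sample
metadata. It is a thin wrapper over three :class:`pandas.DataFrame` objects
rather than a new format — everything round-trips through a single TSV whose
header comments carry the sample metadata.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "gene_strand", "context"]


@dataclass
class VariantTable:
    """Somatic variant catalogue for one patient.

    Attributes
    ----------
    variants
        One row per variant, indexed by ``variant_id``; columns include
        ``chrom, pos (1-based), ref, alt, gene, gene_strand, context``
        (3-base reference context) plus any annotation columns.
    calls
        Long table with columns ``variant_id, sample_id, vaf, depth``.
    samples
        One row per sample, indexed by ``sample_id``; columns
        ``tissue`` (marrow|skin|other), ``order`` (chronological rank) and
        ``sample_type`` (cryopreserved|FFPE).
    """

    variants: pd.DataFrame
    calls: pd.DataFrame
    samples: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants table lacks columns: {missing}")
        for c in ("variant_id", "sample_id", "vaf", "depth"):
            if c not in self.calls.columns:
                raise ValueError(f"calls table lacks column: {c}")
        vafs = self.calls["vaf"].to_numpy(dtype=float)
        if np.nanmin(vafs, initial=0.0) < 0 or np.nanmax(vafs, initial=0.0) > 1:
            raise ValueError("VAFs must lie in [0, 1]")
        if (self.calls["depth"].to_numpy(dtype=float) < 0).any():
            raise ValueError("depths must be non-negative")
        unknown = set(self.calls["sample_id"]) - set(self.samples.index)
        if unknown:
            raise ValueError(f"calls reference unknown samples: {sorted(unknown)}")

    # ------------------------------------------------------------------ views
    @property
    def sample_order(self) -> list[str]:
        """Sample ids sorted by their chronological/anatomical ``order``."""
        return list(self.samples.sort_values("order").index)

    def vaf_matrix(self) -> pd.DataFrame:
        """Variants x samples VAF matrix (absent observations become 0)."""
        m = self.calls.pivot_table(index="variant_id", columns="sample_id", values="vaf", fill_value=0.0)
        m = m.reindex(index=self.variants.index, columns=self.sample_order, fill_value=0.0)
        return m

    def depth_matrix(self) -> pd.DataFrame:
        m = self.calls.pivot_table(index="variant_id", columns="sample_id", values="depth", fill_value=0.0)
        return m.reindex(index=self.variants.index, columns=self.sample_order, fill_value=0.0)

    def subset(self, variant_ids) -> "VariantTable":
        ids = pd.Index(variant_ids)
        return VariantTable(
            variants=self.variants.loc[ids].copy(),
            calls=self.calls[self.calls["variant_id"].isin(ids)].copy(),
            samples=self.samples.copy(),
            meta=dict(self.meta),
        )

    # -------------------------------------------------------------------- IO
    def to_tsv(self, path) -> None:
        """Write the wide single-file TSV (sample metadata in ``#sample`` header lines)."""
        wide = self.variants.copy()
        vafs = self.vaf_matrix()
        depths = self.depth_matrix()
        for s in self.sample_order:
            wide[f"vaf:{s}"] = vafs[s]
            wide[f"depth:{s}"] = depths[s]
        buf = _io.StringIO()
        for s, row in self.samples.iterrows():
            buf.write(
                f"#sample\t{s}\ttissue={row['tissue']}\torder={row['order']}\t"
                f"sample_type={row['sample_type']}\n"
            )
        wide.to_csv(buf, sep="\t", index_label="variant_id")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_tsv(cls, path) -> "VariantTable":
        sample_rows = []
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#sample\t"):
                parts = line.rstrip("\n").split("\t")
                rec = {"sample_id": parts[1]}
                for kv in parts[2:]:
                    k, v = kv.split("=", 1)
                    rec[k] = v
                sample_rows.append(rec)
            elif not line.startswith("#"):
                body.append(line)
        wide = pd.read_csv(_io.StringIO("".join(body)), sep="\t", index_col="variant_id")
        samples = pd.DataFrame(sample_rows).set_index("sample_id")
        samples["order"] = samples["order"].astype(int)
        vaf_cols = [c for c in wide.columns if c.startswith("vaf:")]
        sample_ids = [c.split(":", 1)[1] for c in vaf_cols]
        records = []
        for s in sample_ids:
            records.append(
                pd.DataFrame(
                    {
                        "variant_id": wide.index,
                        "sample_id": s,
                        "vaf": wide[f"vaf:{s}"].to_numpy(dtype=float),
                        "depth": wide[f"depth:{s}"].to_numpy(dtype=float),
                    }
                )
            )
        calls = pd.concat(records, ignore_index=True)
        variants = wide[[c for c in wide.columns if ":" not in c]].copy()
        return cls(variants=variants, calls=calls, samples=samples)


def make_sample_frame(specs) -> pd.DataFrame:
    """Build the ``samples`` frame from ``(sample_id, tissue, sample_type)`` tuples in order."""
    return pd.DataFrame(
        [
            {"sample_id": sid, "tissue": tissue, "order": i, "sample_type": stype}
            for i, (sid, tissue, stype) in enumerate(specs)
        ]
    ).set_index("sample_id")
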