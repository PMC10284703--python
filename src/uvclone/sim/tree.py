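"""Clonal-tree mutation simulator.

Emulates the evolution of a skin-tropic leukaemia: a founder clone acquires
clock-like mutations in the marrow (TET2/ASXL1/ZRSR2-like events), and
progression clones acquire UV-dominated mutations in the skin (RAS-like SNVs,
CDKN2A-loss-like copy events are layered on by the bulk simulator). Each
clone draws its new mutations' trinucleotide contexts from its own mixture of
signature-catalogue columns; UV branches additionally emit CC>TT dinucleotide
pairs and transcriptional strand bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..catalogue import synthetic_catalogue, validate_catalogue
from ..contexts import COMPLEMENT, CONTEXT_LABELS, revcomp

_CHROMS = [f"chr{i}" for i in range(1, 23)]
_CHROM_LEN = 100_000_000


@dataclass
class ClonalTreeSpec:
    """Ground-truth clonal tree and per-clone mutational processes.

    Parameters
    ----------
    nodes
        Clone identifiers; exactly one must have no parent (the root).
    parent_of
        Mapping child -> parent; acyclic.
    n_new_mutations
        New SNV events per clone (a CC>TT pair counts as one event but
        produces two SNV records sharing a ``dinuc_id``).
    signature_mix
        Per clone, a probability vector over catalogue columns (sums to 1).
    uv_dinucleotide_rate
        Per clone, the fraction of new C>T events emitted as adjacent CC>TT
        dinucleotide pairs.
    nontemplate_bias
        Per clone, the probability that a genic UV-category mutation
        (dipyrimidine C>T) lies on the non-template strand of its gene.
    genic_fraction
        Probability any mutation falls inside an annotated gene.
    """

    nodes: list[str]
    parent_of: dict[str, str]
    n_new_mutations: dict[str, int]
    signature_mix: dict[str, np.ndarray]
    uv_dinucleotide_rate: dict[str, float] = field(default_factory=dict)
    nontemplate_bias: dict[str, float] = field(default_factory=dict)
    genic_fraction: float = 0.5

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes if n not in self.parent_of]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        # acyclicity: walking up from every node must terminate at the root
        for n in self.nodes:
            seen = set()
            cur = n
            while cur in self.parent_of:
                if cur in seen:
                    raise ValueError(f"cycle in parent_of at clone {cur!r}")
                seen.add(cur)
                cur = self.parent_of[cur]
        for clone, mix in self.signature_mix.items():
            mix = np.asarray(mix, dtype=float)
            if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
                raise ValueError(f"signature_mix of clone {clone!r} is not a probability vector")
            self.signature_mix[clone] = mix
        for name, rates in (("uv_dinucleotide_rate", self.uv_dinucleotide_rate),
                            ("nontemplate_bias", self.nontemplate_bias)):
            for clone, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"{name} of clone {clone!r} must be in [0, 1]")

    @property
    def root(self) -> str:
        return next(n for n in self.nodes if n not in self.parent_of)

    def descendants(self, clone: str) -> set[str]:
        """Clone plus all clones below it (carriers of its mutations)."""
        out = {clone}
        changed = True
        while changed:
            changed = False
            for child, parent in self.parent_of.items():
                if parent in out and child not in out:
                    out.add(child)
                    changed = True
        return out


def _random_context(label: str, rng: np.random.Generator) -> tuple[str, str, str, str]:
    """Place a pyrimidine-strand class on a random reference orientation.

    Returns ``(ref, alt, context, pyrimidine_strand)`` where ``context`` is
    the plus-strand reference 3-mer and ``pyrimidine_strand`` is '+' or '-'.
    """
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    ctx = five + ref + three
    if rng.random() < 0.5:
        return ref, alt, ctx, "+"
    return COMPLEMENT[ref], COMPLEMENT[alt], revcomp(ctx), "-"


def simulate_clonal_tree(
    spec: ClonalTreeSpec,
    seed: int,
    catalogue: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw the ground-truth mutation catalogue for a clonal tree.

    Returns a DataFrame indexed by ``variant_id`` with one row per SNV record:
    clone of origin, genomic placement, plus-strand ``ref``/``alt``/``context``,
    pyrimidine-strand class label, genic annotation (``gene``, ``gene_strand``),
    the truth strand class (template/nontemplate) for genic UV mutations, and
    ``dinuc_id`` linking the two members of each CC>TT pair.
    """
    if catalogue is None:
        catalogue = synthetic_catalogue()
    validate_catalogue(catalogue)
    rng = np.random.default_rng(seed)
    labels = np.array(CONTEXT_LABELS)
    rows: list[dict] = []
    gene_counter = 0
    for clone in spec.nodes:
        n = int(spec.n_new_mutations.get(clone, 0))
        if n == 0:
            continue
        mix = spec.signature_mix[clone]
        if mix.shape[0] != catalogue.shape[1]:
            raise ValueError(
                f"signature_mix of clone {clone!r} has length {mix.shape[0]}, "
                f"catalogue has {catalogue.shape[1]} signatures"
            )
        p96 = catalogue.values @ mix
        p96 = p96 / p96.sum()
        dinuc_rate = spec.uv_dinucleotide_rate.get(clone, 0.0)
        nt_bias = spec.nontemplate_bias.get(clone, 0.5)
        drawn = rng.choice(96, size=n, p=p96)
        for j, ci in enumerate(drawn):
            label = labels[ci]
            is_ct = label[2:5] == "C>T"
            as_pair = is_ct and rng.random() < dinuc_rate
            chrom = _CHROMS[rng.integers(len(_CHROMS))]
            pos = int(rng.integers(1000, _CHROM_LEN))
            genic = rng.random() < spec.genic_fraction
            gene = ""
            if genic:
                gene_counter += 1
                gene = f"G{gene_counter:05d}"
            if as_pair:
                # CC>TT pair on the pyrimidine strand: contexts N[C>T]C / C[C>T]N
                left = f"{label[0]}[C>T]C"
                right = f"C[C>T]{label[6]}"
                pair_id = f"{clone}.dn{j}"
                members = [(left, pos), (right, pos + 1)]
            else:
                pair_id = ""
                members = [(label, pos)]
            # one orientation and one gene strand per event (shared by pair members)
            orient = "+" if rng.random() < 0.5 else "-"
            uv_class = label[2:5] == "C>T" and label[0] in "TC"
            if genic and uv_class:
                nontemplate = rng.random() < nt_bias
            elif genic:
                nontemplate = rng.random() < 0.5
            else:
                nontemplate = False
            gene_strand = ""
            if genic:
                # non-template <=> pyrimidine strand is the coding strand
                gene_strand = orient if nontemplate else ("-" if orient == "+" else "+")
            for lab, p in members:
                five, ref, alt, three = lab[0], lab[2], lab[4], lab[6]
                ctx = five + ref + three
                if orient == "-":
                    ref, alt, ctx = COMPLEMENT[ref], COMPLEMENT[alt], revcomp(ctx)
                rows.append(
                    {
                        "clone": clone,
                        "chrom": chrom,
                        "pos": p,
                        "ref": ref,
                        "alt": alt,
                        "context": ctx,
                        "context_label": lab,
                        "gene": gene,
                        "gene_strand": gene_strand,
                        "is_genic": genic,
                        "is_uv_class": lab[2:5] == "C>T" and lab[0] in "TC",
                        "strand_class": (
                            ("nontemplate" if nontemplate else "template") if genic else ""
                        ),
                        "dinuc_id": pair_id,
                    }
                )
    cat = pd.DataFrame(rows)
    if len(cat):
        cat.index = pd.Index([f"m{i:05d}" for i in range(len(cat))], name="variant_id")
    return cat


def patient10_like_tree(catalogue: pd.DataFrame | None = None) -> ClonalTreeSpec:
    """Default study-condition tree: a marrow founder lineage, a shared
    UV-exposed transformed precursor, and two skin progression clones.

    The founder lineage is a chain of four subclones (f1..f4) carrying 16
    clock-like mutations in total, emulating gradual acquisition in the
    marrow (and hence a wide founder VAF range). A transformed precursor
    shared by both skin tumours carries 60 UV-dominated mutations and each
    skin clone adds 26 private UV-dominated progression mutations, so that
    roughly half of the UV-class TC>TT events are shared between the two
    skin tumours.
    """
    if catalogue is None:
        catalogue = synthetic_catalogue()
    k = catalogue.shape[1]
    names = list(catalogue.columns)
    clock = np.zeros(k)
    clock[names.index("Signature.1")] = 0.7
    clock[names.index("Signature.5")] = 0.3
    uv = np.zeros(k)
    uv[names.index("Signature.7")] = 0.85
    uv[names.index("Signature.5")] = 0.15
    founders = ["f1", "f2", "f3", "f4"]
    parent = {"f2": "f1", "f3": "f2", "f4": "f3",
              "shared_skin": "f4", "skin1": "shared_skin", "skin2": "shared_skin"}
    return ClonalTreeSpec(
        nodes=founders + ["shared_skin", "skin1", "skin2"],
        parent_of=parent,
        n_new_mutations={"f1": 4, "f2": 4, "f3": 4, "f4": 4,
                         "shared_skin": 60, "skin1": 26, "skin2": 26},
        signature_mix={
            **{f: clock for f in founders},
            "shared_skin": uv,
            "skin1": uv,
            "skin2": uv,
        },
        uv_dinucleotide_rate={**{f: 0.0 for f in founders},
                              "shared_skin": 0.05, "skin1": 0.05, "skin2": 0.05},
        nontemplate_bias={**{f: 0.5 for f in founders},
                          "shared_skin": 0.6, "skin1": 0.6, "skin2": 0.6},
    )
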