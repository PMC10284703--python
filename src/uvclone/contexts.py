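"""Trinucleotide substitution classes on the pyrimidine-strand convention.

Single-base substitutions are folded onto the strand whose reference base is a
pyrimidine (C or T), giving six substitution types (C>A, C>G, C>T, T>A, T>C,
T>G) times sixteen flanking-base combinations: the standard 96 classes used by
mutational-signature analysis.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: The 96 class labels in canonical order, e.g. ``"A[C>A]A"``.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

LABEL_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


class ContextError(ValueError):
    """Raised when a record's context is inconsistent with its alleles."""


def classify_snv(ref: str, alt: str, context: str) -> str:
    """Return the 96-class label for a single-base substitution.

    ``context`` is the 3-base reference sequence centred on the variant, on
    either strand; purine-centred records are reverse-complemented onto the
    pyrimidine strand. Raises :class:`ContextError` when the centre of the
    context does not match ``ref``, when ``ref == alt``, or when the record is
    not a single-base substitution.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ContextError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3:
        raise ContextError(f"context must be 3 bases, got {context!r}")
    if context[1] != ref:
        raise ContextError(f"context {context!r} centre does not match ref {ref!r}")
    if ref in ("G", "A"):
        context = revcomp(context)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    sub = f"{ref}>{alt}"
    if sub not in SUBSTITUTIONS:
        raise ContextError(f"invalid substitution {sub}")
    label = f"{context[0]}[{sub}]{context[2]}"
    if label not in LABEL_INDEX:
        raise ContextError(f"malformed context {context!r}")
    return label


def pyrimidine_context(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Return (context, ref, alt) folded onto the pyrimidine strand."""
    label = classify_snv(ref, alt, context)
    return label[0] + label[2] + label[6], label[2], label[4]


def is_tc_to_tt(label: str) -> bool:
    """UV-associated TC>TT class: C>T with a 5' T on the pyrimidine strand."""
    return label[2:5] == "C>T" and label[0] == "T"


def is_cc_to_ct(label: str) -> bool:
    """UV-associated CC>CT class: C>T with a 5' C on the pyrimidine strand."""
    return label[2:5] == "C>T" and label[0] == "C"


def is_dipyrimidine_ct(label: str) -> bool:
    """C>T at a dipyrimidine (5' T or C), the UV-damage substrate."""
    return label[2:5] == "C>T" and label[0] in ("T", "C")


def labels_to_indices(labels) -> np.ndarray:
    """Vectorised lookup of class labels to positions 0..95."""
    return np.array([LABEL_INDEX[l] for l in labels], dtype=np.intp)
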