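"""Reference mutational-signature catalogue handling.

A catalogue is a 96 x K matrix of per-context probabilities (columns sum to
one) with signature names, held as a :class:`pandas.DataFrame` indexed by the
96 class labels.

Because the canonical reference catalogue is an external download, this module
also provides :func:`synthetic_catalogue`, a deterministic SYNTHETIC stand-in
with the same shape and the qualitative structure the analysis relies on:
column 7 is a UV-like signature (C>T concentrated at dipyrimidines, TpC > CpC),
column 1 is a clock-like deamination signature (C>T at NpCpG) and column 5 is
flat. The remaining columns are fixed random compositions. Numeric values are
not those of any published catalogue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contexts import CONTEXT_LABELS

#: conventional column count of the legacy reference catalogue
N_SIGNATURES = 30

UV_SIGNATURE = "Signature.7"
CLOCK_SIGNATURE = "Signature.1"
FLAT_SIGNATURE = "Signature.5"

_CATALOGUE_SEED = 20230601  # fixed: the synthetic catalogue is a constant


def _uv_column() -> np.ndarray:
    w = np.full(96, 1e-4)
    for i, lab in enumerate(CONTEXT_LABELS):
        if lab[2:5] == "C>T":
            if lab[0] == "T":
                w[i] = 1.0  # TpC>T, the dominant UV class
            elif lab[0] == "C":
                w[i] = 0.55  # CpC>T
            else:
                w[i] = 0.05
    return w / w.sum()


def _clock_column() -> np.ndarray:
    w = np.full(96, 5e-4)
    for i, lab in enumerate(CONTEXT_LABELS):
        if lab[2:5] == "C>T" and lab[6] == "G":
            w[i] = 1.0  # NpCpG deamination
    return w / w.sum()


def synthetic_catalogue(n_signatures: int = N_SIGNATURES) -> pd.DataFrame:
    """Deterministic synthetic 96 x ``n_signatures`` signature catalogue."""
    rng = np.random.default_rng(_CATALOGUE_SEED)
    cols = {}
    for k in range(1, n_signatures + 1):
        name = f"Signature.{k}"
        if name == UV_SIGNATURE:
            col = _uv_column()
        elif name == CLOCK_SIGNATURE:
            col = _clock_column()
        elif name == FLAT_SIGNATURE:
            col = np.full(96, 1.0 / 96)
        else:
            col = rng.dirichlet(np.full(96, 0.3))
        cols[name] = col
    cat = pd.DataFrame(cols, index=list(CONTEXT_LABELS))
    validate_catalogue(cat)
    return cat


def validate_catalogue(cat: pd.DataFrame, atol: float = 1e-6) -> None:
    """Check shape, non-negativity and column normalisation."""
    if list(cat.index) != list(CONTEXT_LABELS):
        raise ValueError("catalogue must be indexed by the 96 context labels in canonical order")
    if (cat.values < 0).any():
        raise ValueError("catalogue probabilities must be non-negative")
    sums = cat.values.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=atol):
        bad = cat.columns[np.abs(sums - 1.0) > atol].tolist()
        raise ValueError(f"catalogue columns do not sum to 1: {bad}")


def read_catalogue(path) -> pd.DataFrame:
    """Read a catalogue TSV (96 rows labelled like ``A[C>T]A``, one column per signature)."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    cat = cat.reindex(list(CONTEXT_LABELS))
    if cat.isna().any().any():
        raise ValueError("catalogue TSV is missing context rows")
    validate_catalogue(cat)
    return cat


def write_catalogue(cat: pd.DataFrame, path) -> None:
    validate_catalogue(cat)
    cat.to_csv(path, sep="\t", index_label="context")
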