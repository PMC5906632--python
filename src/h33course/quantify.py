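"""Normalization and matrix construction.

Signal matrices are pandas DataFrames indexed by gene_id with one column per
sample label.  Counts are library-normalized to a fixed tag total (default
1e7, the common ChIP tag-directory convention), expression is FPKM, and
boolean presence calls come from fold-over-input with a density floor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_io import ValidationError


def _check_axes(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    if not a.index.equals(b.index) or not a.columns.equals(b.columns):
        raise ValidationError(f"{what}: matrices do not share axes")


def normalize_library(
    counts: pd.DataFrame,
    library_sizes: pd.Series | dict,
    scale: float = 1e7,
) -> pd.DataFrame:
    """Scale raw tag counts to a common library size.

    value' = value * scale / library_size(sample).  Library sizes must be
    positive for every sample column.
    """
    sizes = pd.Series(library_sizes, dtype=float)
    missing = [c for c in counts.columns if c not in sizes.index]
    if missing:
        raise ValidationError(f"no library size for samples {missing}")
    sizes = sizes.reindex(counts.columns)
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise ValidationError(f"non-positive library size for {bad}")
    return counts * (scale / sizes)


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | dict,
) -> pd.DataFrame:
    """FPKM = counts / ((gene_length/1e3) * (library_size/1e6))."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValidationError("gene length missing for some genes")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValidationError("library sizes must be positive for all samples")
    return counts.div(lengths / 1e3, axis=0).div(sizes / 1e6, axis=1)


def call_enrichment(
    ip: pd.DataFrame,
    input_: pd.DataFrame,
    gene_lengths: pd.Series | None = None,
    fold: float = 2.0,
    min_density: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Boolean presence calls from library-normalized IP vs input.

    A gene/sample is called present when
    ``(ip + pseudocount) / (input + pseudocount) >= fold`` and the IP density
    (normalized tags per kb of genebody) is at least ``min_density``.  Set
    ``min_density=0`` (or pass no lengths) to apply the fold rule alone.
    """
    _check_axes(ip, input_, "call_enrichment")
    ratio = (ip + pseudocount) / (input_ + pseudocount)
    present = ratio >= fold
    if min_density > 0 and gene_lengths is not None:
        lengths = gene_lengths.reindex(ip.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise ValidationError("gene lengths must be positive for density floor")
        density = ip.div(lengths / 1e3, axis=0)
        present &= density >= min_density
    return present.astype(bool)


def row_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row min-max scaling into [0, 1]; constant rows map to all zeros."""
    lo = matrix.min(axis=1)
    span = matrix.max(axis=1) - lo
    out = matrix.sub(lo, axis=0)
    nonconst = span != 0
    out.loc[nonconst] = out.loc[nonconst].div(span[nonconst], axis=0)
    out.loc[~nonconst] = 0.0
    return out
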