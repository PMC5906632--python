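"""Binned average-enrichment profiles and gene-set trajectory curves.

A profile averages per-bp coverage in equal-width bins across a set of
anchors (TSSs or arbitrary loci); minus-strand windows are reversed so that
upstream always plots left of the anchor.  A trajectory curve is the mean
(+/- standard error) of a signal matrix over a gene set, time-point by
time-point along one route of the course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import SampleSheet, StepCoverage, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ProfileTable:
    """Average per-bp signal in contiguous equal-width bins around anchors."""

    bin_centers: np.ndarray          # bp offset of bin center relative to anchor
    mean_signal: np.ndarray          # mean per-bp signal per bin (over covered bp)
    n_anchors: int
    bin_width: int
    n_clamped: int = 0
    bin_sums: np.ndarray = field(default=None, repr=False)       # total signal per bin
    covered_bp: np.ndarray = field(default=None, repr=False)     # total covered bases per bin

    @property
    def total_signal(self) -> float:
        return float(np.sum(self.bin_sums))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers.astype(int),
                "mean_signal": self.mean_signal,
                "n_anchors": self.n_anchors,
            }
        )


def bin_signal(
    coverage: StepCoverage,
    anchors: Sequence[tuple[str, int, str]],
    flank: int,
    n_bins: int,
) -> ProfileTable:
    """Average coverage in ``n_bins`` equal bins over ``[pos-flank, pos+flank)``.

    Windows running past the chromosome start are clamped: clipped bins are
    averaged over their covered bases only (a count of clamped anchors is
    kept and logged).  Minus-strand windows are reversed.
    """
    if flank <= 0:
        raise ValidationError("flank must be positive")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if (2 * flank) % n_bins != 0:
        raise ValidationError("2*flank must be divisible by n_bins")
    width = (2 * flank) // n_bins
    sums = np.zeros(n_bins)
    covered = np.zeros(n_bins)
    n_clamped = 0
    for chrom, pos, strand in anchors:
        w0 = pos - flank
        clamped = w0 < 0
        n_clamped += clamped
        for b in range(n_bins):
            s = w0 + b * width
            e = s + width
            if e <= 0:
                continue
            cs = max(0, s)
            out_b = (n_bins - 1 - b) if strand == "-" else b
            sums[out_b] += coverage.interval_sum(chrom, cs, e)
            covered[out_b] += e - cs
    if n_clamped:
        log.warning("%d/%d anchor windows clamped at chromosome start", n_clamped, len(anchors))
    mean = np.divide(sums, covered, out=np.zeros_like(sums), where=covered > 0)
    centers = np.arange(n_bins) * width - flank + width // 2
    return ProfileTable(
        bin_centers=centers,
        mean_signal=mean,
        n_anchors=len(anchors),
        bin_width=width,
        n_clamped=n_clamped,
        bin_sums=sums,
        covered_bp=covered,
    )


@dataclass
class TrajectoryCurve:
    geneset_name: str
    sample_labels: list[str]
    mean: np.ndarray
    sem: np.ndarray        # standard error of the mean per time-point
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_labels,
                "mean": self.mean,
                "sem": self.sem,
                "geneset": self.geneset_name,
            }
        )


def geneset_trajectory(
    matrix: pd.DataFrame,
    geneset: Sequence[str],
    sheet: SampleSheet,
    assay: str,
    route: str = "successful",
    name: str = "geneset",
) -> TrajectoryCurve:
    """Mean +/- SEM of ``matrix`` over ``geneset``, ordered along ``route``.

    The successful route includes the shared (unsorted) early time-points.
    """
    genes = list(geneset)
    if not genes:
        raise ValidationError("empty geneset")
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    labels = sheet.route_labels(assay, route)
    absent = [l for l in labels if l not in matrix.columns]
    if absent:
        raise ValidationError(f"route samples absent from matrix: {absent}")
    sub = matrix.loc[genes, labels]
    mean = sub.mean(axis=0).to_numpy()
    if len(genes) > 1:
        sem = (sub.std(axis=0, ddof=1) / np.sqrt(len(genes))).to_numpy()
    else:
        sem = np.zeros(len(labels))
    return TrajectoryCurve(name, labels, mean, sem, len(genes))
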