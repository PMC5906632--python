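"""Domain types and plain-text I/O for the H3.3 time-course pipeline.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Gene catalogs come from BED6, peak calls from BED, genome-wide coverage from
bedGraph, and all matrices travel as UTF-8 TSV with '.' decimal separators.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

ROUTES = ("shared", "successful", "unsuccessful")
ASSAYS = ("chip_ip", "chip_input", "rna", "atac")


class ParseError(ValueError):
    """A text input failed to parse; the message names the offending line."""


class ValidationError(ValueError):
    """An input parsed but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Gene models and peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene interval.

    The transcription start site (TSS) sits at ``start`` for + genes and at
    ``end`` for − genes; the transcription termination site (TTS) is the
    opposite terminus.  Promoter and genebody windows derive from these.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: need 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def promoter_window(self, promoter_bp: int = 3000) -> tuple[int, int]:
        """Promoter interval: the ``promoter_bp`` bases strictly upstream of
        the TSS, strand-aware, clamped at coordinate 0."""
        if promoter_bp <= 0:
            raise ValidationError("promoter_bp must be positive")
        if self.strand == "+":
            return max(0, self.start - promoter_bp), self.start
        return self.end, self.end + promoter_bp


@dataclass(frozen=True)
class Peak:
    """A called enrichment region; score is fold-enrichment (dimensionless)."""

    chrom: str
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"peak: need 0 <= start < end, got [{self.start}, {self.end})")
        if self.score < 0:
            raise ValidationError("peak score must be >= 0")


@dataclass(frozen=True)
class RegionAssignment:
    peak: Peak
    category: str  # promoter | genebody | intergenic
    gene_id: str | None

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.category == "intergenic"):
            raise ValidationError("gene_id must be None iff category is intergenic")


class GeneCatalog:
    """Unique-id collection of :class:`GeneModel` with fast interval lookup."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g
        self._trees: dict[int, dict[str, IntervalTree]] = {}

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self):
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self}, name="length")

    def chroms(self) -> set[str]:
        return {g.chrom for g in self}

    def _tree_for(self, promoter_bp: int) -> dict[str, IntervalTree]:
        # cache per promoter width; entries are (kind, gene)
        if promoter_bp not in self._trees:
            trees: dict[str, IntervalTree] = {}
            for g in self:
                t = trees.setdefault(g.chrom, IntervalTree())
                p0, p1 = g.promoter_window(promoter_bp)
                if p0 < p1:
                    t.addi(p0, p1, ("promoter", g))
                t.addi(g.start, g.end, ("genebody", g))
            self._trees[promoter_bp] = trees
        return self._trees[promoter_bp]


def read_gene_models(path: str | Path) -> GeneCatalog:
    """Read a BED6 gene catalog (chrom, start, end, name, score, strand)."""
    genes: list[GeneModel] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 BED fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            try:
                genes.append(GeneModel(fields[3], fields[0], start, end, fields[5]))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return GeneCatalog(genes)


def write_gene_models(catalog: GeneCatalog, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for g in catalog:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peaks from BED; column 5 (score), when present, is fold-enrichment."""
    peaks: list[Peak] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad numeric field") from exc
            peaks.append(Peak(fields[0], start, end, score))
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{p.score:.10g}\n")


def _peak_tss_distance(peak: Peak, gene: GeneModel) -> int:
    p = gene.tss
    return max(0, peak.start - p, p - (peak.end - 1))


def assign_region(
    peak: Peak,
    catalog: GeneCatalog,
    promoter_bp: int = 3000,
) -> RegionAssignment:
    """Assign a peak to promoter / genebody / intergenic.

    The promoter is the ``promoter_bp`` bases strictly upstream of the TSS
    (strand-aware, clamped at 0).  Category precedence on >=1 bp overlap is
    promoter > genebody > intergenic; ties across genes are broken by the
    smallest peak-to-TSS distance, then lexicographic gene_id.  Peaks on
    chromosomes absent from the catalog are intergenic (a warning is logged).
    """
    if promoter_bp <= 0:
        raise ValidationError("promoter_bp must be positive")
    trees = catalog._tree_for(promoter_bp)
    if peak.chrom not in trees:
        log.warning("peak on unknown chromosome %s: assigned intergenic", peak.chrom)
        return RegionAssignment(peak, "intergenic", None)
    hits = trees[peak.chrom].overlap(peak.start, peak.end)
    for category in ("promoter", "genebody"):
        genes = [iv.data[1] for iv in hits if iv.data[0] == category]
        if genes:
            best = min(genes, key=lambda g: (_peak_tss_distance(peak, g), g.gene_id))
            return RegionAssignment(peak, category, best.gene_id)
    return RegionAssignment(peak, "intergenic", None)


def assign_regions(
    peaks: Sequence[Peak], catalog: GeneCatalog, promoter_bp: int = 3000
) -> pd.DataFrame:
    """Vector form of :func:`assign_region`; one row per peak."""
    rows = []
    for p in peaks:
        a = assign_region(p, catalog, promoter_bp)
        rows.append((p.chrom, p.start, p.end, p.score, a.category, a.gene_id or ""))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score", "category", "gene_id"]
    )


# ---------------------------------------------------------------------------
# Stepwise coverage (bedGraph)
# ---------------------------------------------------------------------------

class StepCoverage:
    """Piecewise-constant genome coverage; value 0 outside listed intervals."""

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # segments[chrom] = (starts, ends, values), sorted, non-overlapping
        self._seg = segments

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "StepCoverage":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if not (0 <= start < end):
                raise ValidationError(f"bad interval [{start}, {end}) on {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        seg = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([i[0] for i in ivs], dtype=np.int64)
            ends = np.array([i[1] for i in ivs], dtype=np.int64)
            values = np.array([i[2] for i in ivs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping bedGraph intervals on {chrom}")
            seg[chrom] = (starts, ends, values)
        return cls(seg)

    @property
    def chroms(self) -> list[str]:
        return list(self._seg)

    def records(self):
        for chrom in sorted(self._seg):
            starts, ends, values = self._seg[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._seg:
            return 0.0
        starts, ends, values = self._seg[chrom]
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over ``[start, end)`` (clamped below at 0)."""
        start = max(0, start)
        if chrom not in self._seg or end <= start:
            return 0.0
        starts, ends, values = self._seg[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))


def read_bedgraph(path: str | Path) -> StepCoverage:
    """Read 4-column bedGraph into stepwise coverage.

    Overlapping intervals on a chromosome are a validation error; queries
    outside all listed intervals return 0.
    """
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad numeric field") from exc
    return StepCoverage.from_records(records)


def write_bedgraph(coverage: StepCoverage, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, s, e, v in coverage.records():
            fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    label: str
    day: int
    route: str
    assay: str

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"sample {self.label}: day must be >= 0")
        if self.route not in ROUTES:
            raise ValidationError(f"sample {self.label}: bad route {self.route!r}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"sample {self.label}: bad assay {self.assay!r}")


class SampleSheet:
    """Ordered description of the time-course design.

    Samples are time-points tagged with a day number, a route (``shared`` for
    unsorted early points, ``successful`` for Thy-1−/SSEA-1+ sorted cells and
    the endpoint, ``unsuccessful`` for Thy-1+/SSEA-1− cells) and an assay.
    """

    def __init__(self, samples: Sequence[Sample]):
        self.samples = list(samples)
        self._validate()

    def _validate(self) -> None:
        seen = set()
        for s in self.samples:
            key = (s.label, s.assay)
            if key in seen:
                raise ValidationError(f"duplicate sample {s.label!r} for assay {s.assay}")
            seen.add(key)
        for assay in {s.assay for s in self.samples}:
            rows = [s for s in self.samples if s.assay == assay]
            day0 = [s for s in rows if s.day == 0 and s.route == "shared"]
            if len(day0) != 1:
                raise ValidationError(
                    f"assay {assay}: need exactly one day-0 shared sample, got {len(day0)}"
                )
            for route in ROUTES:
                days = [s.day for s in rows if s.route == route]
                if any(a > b for a, b in zip(days, days[1:])):
                    raise ValidationError(f"assay {assay}: days not sorted within route {route}")

    def __len__(self) -> int:
        return len(self.samples)

    def assays(self) -> list[str]:
        out = []
        for s in self.samples:
            if s.assay not in out:
                out.append(s.assay)
        return out

    def for_assay(self, assay: str) -> list[Sample]:
        return [s for s in self.samples if s.assay == assay]

    def labels(self, assay: str) -> list[str]:
        return [s.label for s in self.for_assay(assay)]

    def day0_label(self, assay: str) -> str:
        return next(s.label for s in self.for_assay(assay) if s.day == 0 and s.route == "shared")

    def successful_route(self, assay: str) -> list[str]:
        """Sample labels along the successful trajectory: shared time-points
        followed by sorted successful ones, in day order (stable)."""
        rows = [s for s in self.for_assay(assay) if s.route in ("shared", "successful")]
        rows.sort(key=lambda s: s.day)
        return [s.label for s in rows]

    def unsuccessful_route(self, assay: str) -> list[str]:
        rows = [s for s in self.for_assay(assay) if s.route == "unsuccessful"]
        rows.sort(key=lambda s: s.day)
        return [s.label for s in rows]

    def route_labels(self, assay: str, route: str) -> list[str]:
        if route == "successful":
            return self.successful_route(assay)
        if route == "unsuccessful":
            return self.unsuccessful_route(assay)
        raise ValidationError(f"unknown route {route!r}")

    # Canonical designs ----------------------------------------------------

    @classmethod
    def reprogramming_7pt(cls, assays: Sequence[str] = ASSAYS) -> "SampleSheet":
        """The bifurcating fibroblast→iPSC design: D0/D3 unsorted, Thy-1
        sorting at days 6/9, SSEA-1 sorting at days 12/16, iPSC endpoint."""
        spec = [
            ("D0", 0, "shared"),
            ("D3", 3, "shared"),
            ("D6T-", 6, "successful"),
            ("D6T+", 6, "unsuccessful"),
            ("D9T-", 9, "successful"),
            ("D9T+", 9, "unsuccessful"),
            ("D12S+", 12, "successful"),
            ("D12S-", 12, "unsuccessful"),
            ("D16S+", 16, "successful"),
            ("D16S-", 16, "unsuccessful"),
            ("iPSC", 18, "successful"),
        ]
        return cls([Sample(l, d, r, a) for a in assays for (l, d, r) in spec])

    @classmethod
    def transdiff_3pt(cls, assays: Sequence[str] = ASSAYS) -> "SampleSheet":
        """Three-point fibroblast→hematopoietic-progenitor transdifferentiation
        design (day 0, day 4, iHP endpoint); no unsuccessful branch."""
        spec = [("D0", 0, "shared"), ("D4", 4, "successful"), ("iHP", 8, "successful")]
        return cls([Sample(l, d, r, a) for a in assays for (l, d, r) in spec])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str})
    required = {"label", "day", "route", "assay"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {sorted(required)}")
    return SampleSheet(
        [Sample(r.label, int(r.day), r.route, r.assay) for r in df.itertuples()]
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path, header: str | None = None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("label\tday\troute\tassay\n")
        for s in sheet.samples:
            fh.write(f"{s.label}\t{s.day}\t{s.route}\t{s.assay}\n")


# ---------------------------------------------------------------------------
# Gene x sample matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Read a gene × sample TSV matrix (first column gene_id, header = labels).

    If a sample sheet is given, every column label must appear in it.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if sheet is not None:
        known = {s.label for s in sheet.samples}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise ValidationError(f"{path}: sample labels not in sheet: {unknown}")
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        raise ValidationError(f"{path}: non-numeric values in columns {list(bad)}")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing/non-numeric cells present")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a matrix as TSV with full round-trip precision (repr floats)."""
    integral = all(
        pd.api.types.is_bool_dtype(t) or pd.api.types.is_integer_dtype(t)
        for t in matrix.dtypes
    )
    fmt = (lambda v: str(int(v))) if integral else (lambda v: repr(float(v)))
    with open(path, "wt", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("gene_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gid, row in matrix.iterrows():
            fh.write(str(gid) + "\t" + "\t".join(fmt(v) for v in row) + "\n")
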