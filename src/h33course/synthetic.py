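"""Synthetic bifurcating reprogramming time-course with planted ground truth.

The generator emulates the structure of a sorted reprogramming ChIP/RNA/ATAC
time-course: unsorted day-0/day-3 samples, Thy-1-sorted intermediate and
SSEA-1-sorted late time-points on a successful and an unsuccessful branch,
and an iPSC endpoint (a three-point transdifferentiation design is produced
by the same machinery).  Every gene carries a class with a piecewise-constant
trajectory template:

* ``fibroblast`` / ``mesenchymal`` — somatic-identity genes: H3.3-marked and
  expressed at day 0, losing both along the successful route only
  (expression loss on both routes for planted Cluster I, successful-only for
  Cluster II; H3.3 is retained throughout the unsuccessful branch).
* ``pluripotency`` / ``epithelial`` — genes of the target fate: H3.3 deposited
  from a planted onset time-point onward, expression switching on at the
  same point or later (deposition leading transcription for a configurable
  fraction of genes); planted Cluster III/IV by unsuccessful-route behavior.
* ``housekeeping`` — constitutively H3.3-marked and expressed everywhere.
* ``neutral`` — never enriched, never expressed above threshold.

Counts are negative-binomially dispersed around their expectations
(dispersion 0 gives the expectation exactly); FPKM and accessibility carry
multiplicative lognormal noise; boolean presence states can be flipped with
probability ε before count generation.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import write_gmt
from .genome_io import (
    GeneCatalog,
    GeneModel,
    Peak,
    SampleSheet,
    StepCoverage,
    ValidationError,
    read_bedgraph,
    read_gene_models,
    read_matrix,
    read_sample_sheet,
    write_bedgraph,
    write_gene_models,
    write_matrix,
    write_peaks,
    write_sample_sheet,
)

CLASSES = ("fibroblast", "mesenchymal", "pluripotency", "epithelial", "housekeeping", "neutral")

# trajectory template levels (FPKM / accessibility score / ChIP parameters)
FPKM_HIGH_DOWN = 20.0    # somatic genes at day 0
FPKM_LOW_DOWN = 4.25     # somatic genes after silencing: pseudocounted lfc exactly -2
FPKM_LOW_UP = 0.8        # target-fate genes before activation (below the FPKM>1 gate)
FPKM_HIGH_UP = 6.2       # after activation: pseudocounted lfc exactly +2
FPKM_HOUSEKEEPING = 50.0
FPKM_NEUTRAL = 0.5
ACC_OPEN = 8.0
ACC_CLOSED = 0.2
CHIP_FOLD = 6.0          # planted IP/input fold where enriched (>= the calling threshold 2)
INPUT_DENSITY_PER_KB = 20.0
NOMINAL_DEPTH = 1e7      # mapped tags per library (depth-equalized libraries)

DEFAULT_FRACTIONS = {
    "fibroblast": 0.15,
    "mesenchymal": 0.10,
    "pluripotency": 0.20,
    "epithelial": 0.10,
    "housekeeping": 0.15,
    "neutral": 0.30,
}
DEFAULT_CHROM_LENGTHS = {"chr1": 40_000_000, "chr2": 35_000_000, "chr3": 25_000_000}


@dataclass
class SimulationConfig:
    seed: int
    n_genes: int = 1000
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    fpkm_log_sd: float = 0.25       # lognormal sd (natural log) on FPKM/accessibility
    count_dispersion: float = 0.05  # NB dispersion: var = mu + d*mu^2; 0 = exact
    presence_flip: float = 0.0      # per gene x sample boolean flip probability
    deposition_lead_fraction: float = 0.9
    design: str = "reprogramming-7pt"
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("class fractions must sum to 1")
        if not (0 <= self.presence_flip < 0.5):
            raise ValidationError("presence_flip must lie in [0, 0.5)")
        if not (0 <= self.deposition_lead_fraction <= 1):
            raise ValidationError("deposition_lead_fraction must lie in [0, 1]")
        if self.design not in ("reprogramming-7pt", "transdiff-3pt"):
            raise ValidationError(f"unknown design {self.design!r}")

    def sheet(self) -> SampleSheet:
        if self.design == "reprogramming-7pt":
            return SampleSheet.reprogramming_7pt()
        return SampleSheet.transdiff_3pt()


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(
    n_genes: int,
    chrom_lengths: dict | None = None,
    seed: int = 0,
) -> GeneCatalog:
    """Random non-overlapping gene catalog; lengths log-uniform in 1-50 kb.

    Genes are packed chromosome by chromosome with random intergenic gaps;
    an error is raised when the total footprint cannot fit.
    """
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    rng = _rng(seed, 0)
    if n_genes == 0:
        return GeneCatalog([])
    lengths = np.round(
        10 ** rng.uniform(math.log10(1_000), math.log10(50_000), size=n_genes)
    ).astype(np.int64)
    if lengths.sum() > sum(chrom_lengths.values()):
        raise ValidationError("total gene footprint exceeds genome size")
    strands = rng.choice(["+", "-"], size=n_genes)
    # capacity-proportional split of genes across chromosomes
    chroms = sorted(chrom_lengths)
    capacity = {c: chrom_lengths[c] for c in chroms}
    assignment: dict[str, list[int]] = {c: [] for c in chroms}
    used = {c: 0 for c in chroms}
    for i in range(n_genes):
        free = {c: capacity[c] - used[c] - lengths[i] for c in chroms}
        c = max(chroms, key=lambda ch: free[ch])
        if free[c] < 0:
            raise ValidationError("cannot pack genes into chromosomes")
        assignment[c].append(i)
        used[c] += lengths[i]
    genes: list[GeneModel] = []
    for c in chroms:
        idx = assignment[c]
        if not idx:
            continue
        slack = capacity[c] - used[c]
        # random gap before each gene plus a tail gap
        gaps = rng.multinomial(slack, np.full(len(idx) + 1, 1.0 / (len(idx) + 1)))
        pos = 0
        for k, i in enumerate(idx):
            pos += int(gaps[k])
            genes.append(GeneModel(f"g{i:05d}", c, pos, pos + int(lengths[i]), str(strands[i])))
            pos += int(lengths[i])
    genes.sort(key=lambda g: g.gene_id)
    return GeneCatalog(genes)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def generate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Planted per-gene ground truth table.

    Columns: class, planted_cluster, planted_h33_status, planted_h33_onset,
    planted_expr_onset, planted_loss_index, h33_unsuccessful (all|none),
    lead (time-point steps), is_activator, is_repressor.
    """
    rng = _rng(config.seed, 1)
    sheet = config.sheet()
    succ = sheet.successful_route("chip_ip")
    has_unsucc = bool(sheet.unsuccessful_route("chip_ip"))
    n = config.n_genes
    # deterministic class counts matching the fractions to rounding
    counts = {c: int(math.floor(config.class_fractions.get(c, 0.0) * n)) for c in CLASSES}
    rema = sorted(
        CLASSES,
        key=lambda c: (config.class_fractions.get(c, 0.0) * n) - counts[c],
        reverse=True,
    )
    for c in rema[: n - sum(counts.values())]:
        counts[c] += 1
    classes = np.repeat([c for c in CLASSES], [counts[c] for c in CLASSES])
    rng.shuffle(classes)

    if config.design == "reprogramming-7pt":
        up_onset_choices = [1, 2, 3, 4]        # D3 .. D12S+
        down_loss_choices = [1, 2, 3]
    else:
        up_onset_choices = [1]
        down_loss_choices = [1, 2]

    rows = []
    for i, cls in enumerate(classes):
        gid = f"g{i:05d}"
        cluster, h33_status, h33_onset, expr_onset = "none", "never", "none", "none"
        loss_index, unsucc_state, lead = -1, "none", -1
        activator = repressor = False
        if cls in ("fibroblast", "mesenchymal"):
            h33_status = "constitutive"
            loss_index = int(rng.choice(down_loss_choices))
            unsucc_state = "all"
            if has_unsucc:
                cluster = "I" if rng.random() < 0.5 else "II"
                repressor = cluster == "II"
        elif cls in ("pluripotency", "epithelial"):
            h33_status = "onset"
            o = int(rng.choice(up_onset_choices))
            h33_onset = succ[o]
            lead = 0  # allocated exactly across onset genes below
            expr_onset = succ[o]
            if cls == "pluripotency":
                unsucc_state = "all" if rng.random() < 0.5 else "none"
            else:
                unsucc_state = "all"  # epithelial genes stay enriched off-route
            if has_unsucc:
                cluster = "III" if unsucc_state == "all" else "IV"
                activator = (
                    cls == "pluripotency"
                    and unsucc_state == "none"
                    and h33_onset in ("D6T-", "D9T-", "D12S+")
                )
        elif cls == "housekeeping":
            h33_status = "constitutive"
            unsucc_state = "all"
        rows.append(
            (gid, cls, cluster, h33_status, h33_onset, expr_onset,
             loss_index, unsucc_state, lead, activator, repressor)
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "class", "planted_cluster", "planted_h33_status",
            "planted_h33_onset", "planted_expr_onset", "planted_loss_index",
            "h33_unsuccessful", "lead", "is_activator", "is_repressor",
        ],
    ).set_index("gene_id")
    # exact allocation of the deposition-lead fraction: with Bernoulli draws
    # the realized fraction would only approximate the configured one
    onset_ids = list(truth.index[truth["planted_h33_status"] == "onset"])
    k = int(round(config.deposition_lead_fraction * len(onset_ids)))
    lead_ids = [onset_ids[i] for i in rng.permutation(len(onset_ids))[:k]]
    for gid in lead_ids:
        o = succ.index(truth.at[gid, "planted_h33_onset"])
        truth.at[gid, "lead"] = 1
        truth.at[gid, "planted_expr_onset"] = succ[o + 1]
    return truth


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    sheet: SampleSheet
    catalog: GeneCatalog
    truth: pd.DataFrame
    h33_ip_counts: pd.DataFrame
    h33_input_counts: pd.DataFrame
    fpkm: pd.DataFrame
    accessibility: pd.DataFrame
    library_sizes: pd.Series            # per chip sample label (tags, depth-equalized)
    peaks: dict                         # chip_ip label -> list[Peak]
    coverage: StepCoverage              # per-bp normalized IP density, endpoint sample
    marker_sets: dict                   # set name -> set of gene ids

    def write(self, outdir: str | Path, header: str | None = None) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gene_models(self.catalog, out / "genes.bed")
        write_sample_sheet(self.sheet, out / "sample_sheet.tsv", header=header)
        truth = self.truth.copy()
        truth[["is_activator", "is_repressor"]] = truth[["is_activator", "is_repressor"]].astype(int)
        truth.to_csv(out / "truth.tsv", sep="\t")
        write_matrix(self.h33_ip_counts, out / "h33_ip_counts.tsv", header=header)
        write_matrix(self.h33_input_counts, out / "h33_input_counts.tsv", header=header)
        write_matrix(self.fpkm, out / "fpkm.tsv", header=header)
        write_matrix(self.accessibility, out / "accessibility.tsv", header=header)
        self.library_sizes.rename("library_size").to_frame().to_csv(
            out / "library_sizes.tsv", sep="\t", index_label="label"
        )
        for label, peaks in sorted(self.peaks.items()):
            write_peaks(peaks, out / f"peaks_{label}.bed")
        write_bedgraph(self.coverage, out / "coverage.bedGraph")
        write_gmt(self.marker_sets, out / "markers.gmt")


def _planted_presence(truth: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Boolean H3.3 enrichment state per gene over every chip time-point."""
    succ = sheet.successful_route("chip_ip")
    unsucc = sheet.unsuccessful_route("chip_ip")
    labels = sheet.labels("chip_ip")
    n_succ = len(succ)
    states = {}
    for gid, row in truth.iterrows():
        vec = {}
        cls = row["class"]
        if cls in ("fibroblast", "mesenchymal"):
            svec = [i < row["planted_loss_index"] for i in range(n_succ)]
        elif cls in ("pluripotency", "epithelial"):
            o = succ.index(row["planted_h33_onset"])
            svec = [i >= o for i in range(n_succ)]
        elif cls == "housekeeping":
            svec = [True] * n_succ
        else:
            svec = [False] * n_succ
        vec.update(zip(succ, svec))
        on_unsucc = row["h33_unsuccessful"] == "all"
        vec.update({l: on_unsucc for l in unsucc})
        states[gid] = [vec[l] for l in labels]
    return pd.DataFrame.from_dict(states, orient="index", columns=labels).loc[truth.index]


def _fpkm_template(truth: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    succ = sheet.successful_route("rna")
    unsucc = sheet.unsuccessful_route("rna")
    labels = sheet.labels("rna")
    out = {}
    for gid, row in truth.iterrows():
        cls = row["class"]
        vec = {}
        if cls in ("fibroblast", "mesenchymal"):
            li = row["planted_loss_index"]
            vec.update(
                {l: (FPKM_HIGH_DOWN if i < li else FPKM_LOW_DOWN) for i, l in enumerate(succ)}
            )
            down_on_unsucc = row["planted_cluster"] == "I"
            vec.update({l: (FPKM_LOW_DOWN if down_on_unsucc else FPKM_HIGH_DOWN) for l in unsucc})
        elif cls in ("pluripotency", "epithelial"):
            e = succ.index(row["planted_expr_onset"])
            vec.update(
                {l: (FPKM_HIGH_UP if i >= e else FPKM_LOW_UP) for i, l in enumerate(succ)}
            )
            up_on_unsucc = row["planted_cluster"] == "III"
            vec.update({l: (FPKM_HIGH_UP if up_on_unsucc else FPKM_LOW_UP) for l in unsucc})
        elif cls == "housekeeping":
            vec.update({l: FPKM_HOUSEKEEPING for l in labels})
        else:
            vec.update({l: FPKM_NEUTRAL for l in labels})
        out[gid] = [vec[l] for l in labels]
    return pd.DataFrame.from_dict(out, orient="index", columns=labels).loc[truth.index]


def simulate_matrices(
    truth: pd.DataFrame,
    config: SimulationConfig,
    catalog: GeneCatalog | None = None,
) -> SyntheticBundle:
    """Generate count/FPKM/accessibility matrices plus peaks and coverage.

    IP tag expectations are ``CHIP_FOLD x`` the input expectation wherever
    the (possibly ε-flipped) planted state is enriched; libraries are
    depth-equalized to ``NOMINAL_DEPTH`` mapped tags (gene-region tags are a
    small fraction of each library), so per-library normalization preserves
    the planted fold.  Deterministic given the config seed.
    """
    if catalog is None:
        catalog = generate_genome(config.n_genes, config.chrom_lengths, config.seed)
    if len(catalog) != config.n_genes or len(truth) != config.n_genes:
        raise ValidationError("truth, catalog and config disagree on n_genes")
    rng = _rng(config.seed, 2)
    sheet = config.sheet()
    labels = sheet.labels("chip_ip")
    lengths = catalog.lengths().loc[truth.index]

    presence = _planted_presence(truth, sheet)
    if config.presence_flip > 0:
        flips = rng.random(presence.shape) < config.presence_flip
        presence = presence ^ flips

    input_mu = np.tile(
        (lengths.to_numpy() / 1e3) * INPUT_DENSITY_PER_KB, (len(labels), 1)
    ).T
    ip_mu = np.where(presence.to_numpy(), CHIP_FOLD, 1.0) * input_mu

    def draw(mu: np.ndarray) -> np.ndarray:
        if config.count_dispersion <= 0:
            return mu.copy()
        r = 1.0 / config.count_dispersion
        return rng.negative_binomial(r, r / (r + mu)).astype(float)

    ip_counts = pd.DataFrame(draw(ip_mu), index=truth.index, columns=labels)
    input_counts = pd.DataFrame(draw(input_mu), index=truth.index, columns=labels)
    library_sizes = pd.Series(NOMINAL_DEPTH, index=pd.Index(labels, name="label"))

    fpkm_t = _fpkm_template(truth, sheet)
    acc_t = fpkm_t.where(fpkm_t <= 1.0, ACC_OPEN).where(fpkm_t > 1.0, ACC_CLOSED)
    hk = truth["class"] == "housekeeping"
    acc_t.loc[hk] = ACC_OPEN
    if config.fpkm_log_sd > 0:
        fpkm = fpkm_t * np.exp(rng.normal(0.0, config.fpkm_log_sd, fpkm_t.shape))
        acc = acc_t * np.exp(rng.normal(0.0, config.fpkm_log_sd, acc_t.shape))
    else:
        fpkm, acc = fpkm_t.copy(), acc_t.copy()

    # peaks over enriched genebodies, per IP sample
    peaks = {}
    for label in labels:
        plist = [
            Peak(catalog[g].chrom, catalog[g].start, catalog[g].end, CHIP_FOLD)
            for g in truth.index
            if presence.loc[g, label]
        ]
        peaks[label] = sorted(plist, key=lambda p: (p.chrom, p.start))

    # per-bp normalized IP density for the endpoint sample
    end_label = sheet.successful_route("chip_ip")[-1]
    scale = NOMINAL_DEPTH / library_sizes[end_label]
    records = []
    for g in truth.index:
        gene = catalog[g]
        density = float(ip_counts.loc[g, end_label]) * scale / gene.length
        if density > 0:
            records.append((gene.chrom, gene.start, gene.end, density))
    coverage = StepCoverage.from_records(records)

    marker_sets = {
        "fibroblast": set(truth.index[truth["class"] == "fibroblast"]),
        "mesenchymal": set(truth.index[truth["class"] == "mesenchymal"]),
        "mESC": set(truth.index[truth["class"] == "pluripotency"]),
        "epithelial": set(truth.index[truth["class"] == "epithelial"]),
    }
    return SyntheticBundle(
        config=config,
        sheet=sheet,
        catalog=catalog,
        truth=truth,
        h33_ip_counts=ip_counts,
        h33_input_counts=input_counts,
        fpkm=fpkm,
        accessibility=acc,
        library_sizes=library_sizes,
        peaks=peaks,
        coverage=coverage,
        marker_sets=marker_sets,
    )


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Genome + truth + matrices in one call (deterministic given seed)."""
    catalog = generate_genome(config.n_genes, config.chrom_lengths, config.seed)
    truth = generate_truth(config)
    return simulate_matrices(truth, config, catalog)


def load_bundle(indir: str | Path):
    """Re-read an on-disk synthetic bundle's pipeline-facing files."""
    indir = Path(indir)
    sheet = read_sample_sheet(indir / "sample_sheet.tsv")
    catalog = read_gene_models(indir / "genes.bed")
    lib = pd.read_csv(indir / "library_sizes.tsv", sep="\t", index_col=0)["library_size"]
    data = {
        "sheet": sheet,
        "catalog": catalog,
        "library_sizes": lib,
        "h33_ip_counts": read_matrix(indir / "h33_ip_counts.tsv", sheet),
        "h33_input_counts": read_matrix(indir / "h33_input_counts.tsv", sheet),
        "fpkm": read_matrix(indir / "fpkm.tsv", sheet),
        "accessibility": read_matrix(indir / "accessibility.tsv", sheet),
    }
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        data["truth"] = pd.read_csv(truth_path, sep="\t", index_col=0)
    cov = indir / "coverage.bedGraph"
    if cov.exists():
        data["coverage"] = read_bedgraph(cov)
    return data
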