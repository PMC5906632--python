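"""End-to-end orchestration of the analysis stages.

Each stage reads the plain-text inputs the previous stage (or the synthetic
generator) produced, and writes TSV outputs stamped with the config hash.
``run_all`` is exactly the stages composed in order, so subcommand-by-
subcommand execution reproduces its bundle bit for bit.  A JSON manifest
records the effective configuration, tool version, warning counts and
output list — and nothing time-dependent, so identical configs yield
byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import discovery, dynamics, onset, profiles, quantify
from .config import RunConfig
from .genome_io import (
    ValidationError,
    assign_regions,
    read_matrix,
    read_peaks,
    write_matrix,
)
from .synthetic import SimulationConfig, load_bundle, simulate_bundle

log = logging.getLogger(__name__)

STAGES = ("annotate", "quantify", "profiles", "clusters", "onset", "discover")


def _stamp(config: RunConfig) -> str:
    return f"config_hash={config.config_hash()} version={__version__}"


def _write_df(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = True) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# {_stamp(config)}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _load_inputs(config: RunConfig) -> dict:
    indir = Path(config.input_dir)
    if not indir.is_dir():
        raise ValidationError(f"input directory not found: {indir}")
    if not (indir / "sample_sheet.tsv").exists():
        raise ValidationError(f"sample sheet missing from {indir}")
    return load_bundle(indir)


def stage_simulate(config: RunConfig, sim: SimulationConfig | None = None) -> Path:
    """Generate a synthetic bundle into the input directory."""
    sim = sim or SimulationConfig(seed=config.seed)
    bundle = simulate_bundle(sim)
    bundle.write(config.input_dir, header=_stamp(config))
    return Path(config.input_dir)


def stage_annotate(config: RunConfig) -> None:
    """Assign every called peak to promoter/genebody/intergenic, per sample."""
    data = _load_inputs(config)
    out = _outdir(config)
    frames = []
    for bed in sorted(Path(config.input_dir).glob("peaks_*.bed")):
        label = bed.stem[len("peaks_"):]
        peaks = read_peaks(bed)
        df = assign_regions(peaks, data["catalog"], promoter_bp=config.promoter_bp)
        df.insert(0, "sample", label)
        frames.append(df)
    if not frames:
        raise ValidationError(f"no peaks_*.bed files in {config.input_dir}")
    ann = pd.concat(frames, ignore_index=True)
    _write_df(ann, out / "annotations.tsv", config, index=False)
    dist = (
        ann.groupby(["sample", "category"]).size().unstack(fill_value=0)
        .reindex(columns=["promoter", "genebody", "intergenic"], fill_value=0)
    )
    dist["total"] = dist.sum(axis=1)
    _write_df(dist, out / "region_distribution.tsv", config)


def stage_quantify(config: RunConfig) -> None:
    """Library-normalize ChIP tags and call fold-over-input presence."""
    data = _load_inputs(config)
    out = _outdir(config)
    lengths = data["catalog"].lengths()
    ip = quantify.normalize_library(data["h33_ip_counts"], data["library_sizes"], scale=config.scale)
    inp = quantify.normalize_library(
        data["h33_input_counts"], data["library_sizes"], scale=config.scale
    )
    presence = quantify.call_enrichment(
        ip, inp, lengths,
        fold=config.fold, min_density=config.min_density, pseudocount=config.pseudocount,
    )
    _write_df(ip, out / "h33_normalized.tsv", config)
    write_matrix(presence.astype(int), out / "presence.tsv", header=_stamp(config))


def stage_profiles(config: RunConfig) -> None:
    """TSS meta-profile of endpoint coverage and per-class trajectories."""
    data = _load_inputs(config)
    out = _outdir(config)
    if "coverage" in data:
        anchors = [(g.chrom, g.tss, g.strand) for g in data["catalog"]]
        table = profiles.bin_signal(data["coverage"], anchors, config.flank, config.n_bins)
        _write_df(table.to_frame(), out / "profile_tss.tsv", config, index=False)
    ip = read_matrix(out / "h33_normalized.tsv")
    truth = data.get("truth")
    curves = []
    if truth is not None:
        for cls in sorted(truth["class"].unique()):
            genes = list(truth.index[truth["class"] == cls])
            curve = profiles.geneset_trajectory(
                ip, genes, data["sheet"], assay="chip_ip", route="successful", name=cls
            )
            curves.append(curve.to_frame())
    if curves:
        _write_df(pd.concat(curves, ignore_index=True), out / "trajectories.tsv", config, index=False)


def stage_clusters(config: RunConfig) -> None:
    """Endpoint DE gate and route-dependent cluster labels."""
    data = _load_inputs(config)
    out = _outdir(config)
    de = dynamics.endpoint_de(
        data["fpkm"], data["sheet"], assay="rna",
        lfc_min=config.lfc_min, pseudocount=config.pseudocount,
    )
    clusters = dynamics.assign_cluster(de, lfc_min=config.lfc_min)
    _write_df(de.join(clusters), out / "clusters.tsv", config)
    rownorm = quantify.row_normalize(data["fpkm"])
    _write_df(rownorm, out / "fpkm_rownorm.tsv", config)
    order = dynamics.order_rows_for_heatmap(rownorm, clusters)
    (out / "heatmap_order.txt").write_text(
        f"# {_stamp(config)}\n" + "".join(f"{g}\n" for g in order), encoding="utf-8"
    )


def stage_onset(config: RunConfig) -> None:
    """D-onwards calls for deposition, expression and accessibility."""
    data = _load_inputs(config)
    out = _outdir(config)
    presence = read_matrix(out / "presence.tsv").astype(bool)
    sheet = data["sheet"]
    h33_calls = onset.classify_onsets(presence, sheet, assay="chip_ip", modality="h33")
    expr_calls = onset.expression_onsets(
        data["fpkm"], sheet, assay="rna",
        threshold=config.fpkm_threshold, sustained=config.sustained_expression,
    )
    atac_calls = onset.expression_onsets(
        data["accessibility"], sheet, assay="atac",
        threshold=config.fpkm_threshold, sustained=config.sustained_expression,
        modality="accessibility",
    )
    prec = onset.precedence_table(h33_calls, expr_calls)
    _write_df(h33_calls, out / "onset_h33.tsv", config)
    _write_df(expr_calls, out / "onset_expression.tsv", config)
    _write_df(atac_calls, out / "onset_accessibility.tsv", config)
    _write_df(prec, out / "precedence.tsv", config)


def stage_discover(config: RunConfig) -> None:
    """Loss ranking, activators, target intersection, marker enrichment."""
    data = _load_inputs(config)
    out = _outdir(config)
    sheet = data["sheet"]
    ip = read_matrix(out / "h33_normalized.tsv")
    succ = sheet.successful_route("chip_ip")
    top = discovery.rank_h33_loss(ip[succ], n=config.top_n)
    _write_df(top, out / "top_h33_loss.tsv", config)

    h33_calls = pd.read_csv(out / "onset_h33.tsv", sep="\t", comment="#", index_col=0).fillna("")
    activators = discovery.identify_activators(
        h33_calls, data["fpkm"], sheet, assay="rna",
        lfc_min=config.lfc_min, pseudocount=config.pseudocount,
    )
    (out / "activators.txt").write_text(
        f"# {_stamp(config)}\n" + "".join(f"{g}\n" for g in sorted(activators)),
        encoding="utf-8",
    )

    clusters = pd.read_csv(out / "clusters.tsv", sep="\t", comment="#", index_col=0)
    down = set(clusters.index[clusters["cluster"].isin(["I", "II"])])
    targets, venn = discovery.functional_targets(down, set(top.index))
    venn_df = pd.DataFrame(sorted(venn.items()), columns=["region", "size"])
    _write_df(venn_df, out / "venn.tsv", config, index=False)
    (out / "functional_targets.txt").write_text(
        f"# {_stamp(config)}\n" + "".join(f"{g}\n" for g in sorted(targets)),
        encoding="utf-8",
    )

    gmt = Path(config.input_dir) / "markers.gmt"
    if gmt.exists() and activators:
        sets = discovery.read_gmt(gmt)
        universe = set(data["fpkm"].index)
        enr = discovery.marker_enrichment(
            activators, sets, universe, significance_score=config.significance_score
        )
        _write_df(enr, out / "marker_enrichment.tsv", config)


def write_manifest(config: RunConfig) -> Path:
    """Record config, version and outputs; nothing time-dependent, so the
    manifest (like every output) is reproducible byte for byte."""
    out = _outdir(config)
    outputs = sorted(
        p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "tool": "h33course",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": dict(config.items()),
        "outputs": outputs,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def run_all(config: RunConfig) -> Path:
    """Run every analysis stage in order and write the manifest.

    Identical config (and inputs) ⇒ byte-identical output bundle.
    """
    stage_fns = {
        "annotate": stage_annotate,
        "quantify": stage_quantify,
        "clusters": stage_clusters,
        "onset": stage_onset,
        "profiles": stage_profiles,
        "discover": stage_discover,
    }
    # quantify before profiles/onset/discover (they read its outputs)
    for name in ("annotate", "quantify", "clusters", "onset", "profiles", "discover"):
        t0 = time.perf_counter()
        try:
            stage_fns[name](config)
        except Exception:
            log.error("stage %s failed", name)
            raise
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    return write_manifest(config)
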