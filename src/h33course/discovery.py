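"""Downstream discovery: H3.3-loss ranking, target intersection,
route-exclusive activator identification, and marker-set enrichment.

Marker-set enrichment re-implements the cell-type enrichment protocol as an
upper-tail hypergeometric test per marker set with Benjamini–Hochberg
adjustment; the enrichment score is −log10(adjusted p) and scores of 2 and
above are called significant.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dynamics import endpoint_de
from .genome_io import SampleSheet, ValidationError
from .onset import route_exclusive

DEFAULT_ONSET_WINDOW = ("D6T-", "D9T-", "D12S+")


def rank_h33_loss(h33: pd.DataFrame, n: int = 250) -> pd.DataFrame:
    """Rank genes by their sharpest loss of H3.3 along the successful route.

    The loss score is the maximum decrease between consecutive time-points
    (floored at 0); ties break by total loss (sum of all consecutive
    decreases) and then gene_id.  Columns of ``h33`` must already be ordered
    along the successful route.  Returns the top ``n`` genes.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if h33.shape[1] < 2:
        raise ValidationError("need at least two successful-route samples")
    vals = h33.to_numpy(dtype=float)
    drops = vals[:, :-1] - vals[:, 1:]
    loss = np.maximum(drops, 0.0).max(axis=1)
    total = np.maximum(drops, 0.0).sum(axis=1)
    table = pd.DataFrame(
        {"gene_id": h33.index, "loss_score": loss, "total_loss": total}
    ).sort_values(
        ["loss_score", "total_loss", "gene_id"], ascending=[False, False, True]
    ).head(n)
    table["rank"] = np.arange(1, len(table) + 1)
    return table.set_index("gene_id")


def functional_targets(
    down_on_knockdown: Iterable[str], losing_h33: Iterable[str]
) -> tuple[set, dict]:
    """Intersect knockdown-sensitive genes with H3.3-losing genes.

    Returns the intersection and the three Venn region sizes
    (``only_knockdown``, ``only_loss``, ``both``).
    """
    a, b = set(down_on_knockdown), set(losing_h33)
    both = a & b
    venn = {"only_knockdown": len(a - b), "only_loss": len(b - a), "both": len(both)}
    return both, venn


def identify_activators(
    h33_calls: pd.DataFrame,
    expr: pd.DataFrame,
    sheet: SampleSheet,
    assay: str = "rna",
    onset_window: Sequence[str] = DEFAULT_ONSET_WINDOW,
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
) -> set:
    """Route-exclusive H3.3-dependent activators of reprogramming.

    A gene qualifies when (1) its H3.3 call is an onset inside
    ``onset_window`` (intermediate time-points, D6–D12 by default), (2) it
    is never enriched on the unsuccessful route, and (3) its expression
    rises along the successful route (endpoint log2FC >= lfc_min) but not
    along the unsuccessful one (|log2FC| < lfc_min).

    ``h33_calls`` is the table from :func:`h33course.onset.classify_onsets`
    (must carry the ``route_exclusive`` column).
    """
    for col in ("status", "onset_label", "route_exclusive"):
        if col not in h33_calls.columns:
            raise ValidationError(f"h33_calls missing column {col!r}")
    de = endpoint_de(expr, sheet, assay=assay, lfc_min=lfc_min, pseudocount=pseudocount)
    window = set(onset_window)
    out = set()
    for gid, row in h33_calls.iterrows():
        if row["status"] != "onset" or row["onset_label"] not in window:
            continue
        if str(row["route_exclusive"]) != "True":
            continue
        if gid not in de.index:
            continue
        lfc_s = de.loc[gid, "log2fc_successful"]
        lfc_u = de.loc[gid, "log2fc_unsuccessful"]
        if np.isnan(lfc_u):
            continue
        if lfc_s >= lfc_min and abs(lfc_u) < lfc_min:
            out.add(gid)
    return out


def marker_enrichment(
    query: Iterable[str],
    marker_sets: Mapping[str, Set[str]],
    universe: Iterable[str],
    significance_score: float = 2.0,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list in named marker sets.

    For each set, p = P(X >= overlap) with X hypergeometric(universe, set,
    query); BH adjustment runs across sets; score = −log10(adjusted p).
    """
    uni = set(universe)
    q = set(query)
    if not q <= uni:
        raise ValidationError("query genes must all belong to the universe")
    names, pvals, rows = [], [], []
    for name in sorted(marker_sets):
        s = set(marker_sets[name]) & uni
        k = len(q & s)
        # upper tail at the observed overlap
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, k, len(s), len(q), len(uni)))
    if not names:
        return pd.DataFrame(
            columns=["set_name", "overlap", "set_size", "query_size",
                     "universe_size", "p", "adjusted_p", "score", "significant"]
        ).set_index("set_name")
    adj = multipletests(pvals, method="fdr_bh")[1]
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size"])
    df["p"] = pvals
    df["adjusted_p"] = adj
    with np.errstate(divide="ignore"):
        df["score"] = np.maximum(np.where(adj > 0, -np.log10(adj), np.inf), 0.0)
    df["significant"] = df["score"] >= significance_score
    return df.set_index("set_name")


# ---------------------------------------------------------------------------
# GMT-style marker-set text format
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set]:
    """Read marker sets from GMT text (name, description, genes...)."""
    sets: dict[str, set] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: line {lineno}: GMT needs name, description, genes")
            if fields[0] in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate set {fields[0]!r}")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(marker_sets: Mapping[str, Set[str]], path, description: str = "synthetic") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for name in sorted(marker_sets):
            genes = "\t".join(sorted(marker_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")
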