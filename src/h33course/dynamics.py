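"""Differential-expression gate and route-dependent trajectory clusters.

Genes differentially expressed between the start of the course (D0) and the
successful endpoint (iPSC) fall into four route-dependent classes:

* Cluster I   — expression decreases along both routes,
* Cluster II  — decreases exclusively along the successful route,
* Cluster III — increases along both routes,
* Cluster IV  — increases exclusively along the successful route.

Direction of change is measured by a pseudocounted endpoint log2 fold
change; no replicate-based testing is attempted (the cluster semantics
depend only on direction of change).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genome_io import SampleSheet, ValidationError

CLUSTERS = ("I", "II", "III", "IV")


def endpoint_de(
    expr: pd.DataFrame,
    sheet: SampleSheet,
    assay: str = "rna",
    lfc_min: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Endpoint log2 fold changes vs day 0 on both routes.

    Returns a frame indexed by gene_id with columns ``log2fc_successful``
    (successful endpoint vs D0), ``log2fc_unsuccessful`` (last
    unsuccessful-route sample vs D0; NaN when that route is absent) and
    ``is_de`` (|log2fc_successful| >= lfc_min).
    """
    d0 = sheet.day0_label(assay)
    succ = sheet.successful_route(assay)
    if len(succ) < 2:
        raise ValidationError("successful route needs an endpoint beyond day 0")
    succ_end = succ[-1]
    for label in (d0, succ_end):
        if label not in expr.columns:
            raise ValidationError(f"sample {label!r} missing from expression matrix")
    base = expr[d0] + pseudocount
    lfc_s = np.log2((expr[succ_end] + pseudocount) / base)
    unsucc = sheet.unsuccessful_route(assay)
    if unsucc:
        unsucc_end = unsucc[-1]
        if unsucc_end not in expr.columns:
            raise ValidationError(f"sample {unsucc_end!r} missing from expression matrix")
        lfc_u = np.log2((expr[unsucc_end] + pseudocount) / base)
    else:
        lfc_u = pd.Series(np.nan, index=expr.index)
    return pd.DataFrame(
        {
            "log2fc_successful": lfc_s,
            "log2fc_unsuccessful": lfc_u,
            "is_de": lfc_s.abs() >= lfc_min,
        }
    )


def assign_cluster(de: pd.DataFrame, lfc_min: float = 1.0) -> pd.Series:
    """Route-dependent cluster labels (I-IV) per gene; 'unassigned' otherwise.

    Non-DE genes and genes with no unsuccessful-route measurement stay
    unassigned — never guessed.
    """
    s = de["log2fc_successful"]
    u = de["log2fc_unsuccessful"]
    s_down, s_up = s <= -lfc_min, s >= lfc_min
    u_down, u_up = u <= -lfc_min, u >= lfc_min
    u_flat = u.abs() < lfc_min
    labels = pd.Series("unassigned", index=de.index, name="cluster")
    defined = de["is_de"] & u.notna()
    labels[defined & s_down & u_down] = "I"
    labels[defined & s_down & (u_flat | u_up)] = "II"
    labels[defined & s_up & u_up] = "III"
    labels[defined & s_up & (u_flat | u_down)] = "IV"
    return labels


def order_rows_for_heatmap(matrix: pd.DataFrame, clusters: pd.Series) -> list[str]:
    """Deterministic row ordering for per-row-normalized heatmaps.

    Rows are grouped by cluster label (I, II, III, IV, then unassigned);
    within each group, average-linkage hierarchical clustering (Euclidean)
    fixes the leaf order.  Ties and the pre-linkage order are broken by
    gene_id, making the result invariant to row permutation of the input.
    """
    order: list[str] = []
    for label in (*CLUSTERS, "unassigned"):
        ids = sorted(clusters.index[clusters == label])
        ids = [g for g in ids if g in matrix.index]
        if len(ids) <= 2:
            order.extend(ids)
            continue
        rows = matrix.loc[ids].to_numpy(dtype=float)
        d = pdist(rows)
        if d.max() == 0:  # all rows identical: leaf order is arbitrary, keep id order
            order.extend(ids)
            continue
        link = hierarchy.linkage(d, method="average")
        order.extend(ids[i] for i in hierarchy.leaves_list(link))
    return order
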