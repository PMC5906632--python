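"""Onset classification of presence trajectories and precedence analysis.

The core rule ("D-onwards"): a gene is an onset gene for time-point *t* when
its enrichment is absent at day 0 and every point before *t*, and present at
*t* and every later point through the end of the course.  Genes already
enriched at day 0 are *constitutive*; genes never enriched are *never*;
anything else (gained then lost, or gapped) is *unsustained*.

Expression onset uses an FPKM threshold (>1 by default).  Two readings of
"above threshold at any time-point after day 0 till the end" are exposed:
the existential default (first crossing after day 0) and a sustained variant
(earliest point from which expression stays above threshold through the
end).  Neither is silently preferred; the default is documented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import SampleSheet, ValidationError

STATUSES = ("onset", "constitutive", "never", "unsustained")


@dataclass(frozen=True)
class OnsetCall:
    gene_id: str
    modality: str                 # h33 | expression | accessibility
    status: str                   # onset | constitutive | never | unsustained
    onset_label: str | None       # sample label, set iff status == "onset"
    onset_index: int | None       # position along the route, iff onset
    route_exclusive: bool | None = None

    def __post_init__(self) -> None:
        if (self.status == "onset") != (self.onset_label is not None):
            raise ValidationError("onset_label must be set iff status is 'onset'")


@dataclass(frozen=True)
class PrecedenceCall:
    gene_id: str
    relation: str                 # deposition_first | simultaneous | expression_first | undefined
    lead: int | None              # time-point steps, expr index - h3.3 index


def classify_onset(
    presence: Sequence[bool],
    labels: Sequence[str],
    gene_id: str = "",
    modality: str = "h33",
) -> OnsetCall:
    """Apply the D-onwards rule to one boolean trajectory.

    ``presence[0]`` must correspond to the day-0 sample; at least two
    time-points are required.
    """
    p = [bool(x) for x in presence]
    if len(p) == 0:
        raise ValidationError("empty presence vector")
    if len(p) != len(labels):
        raise ValidationError("presence vector and labels differ in length")
    if len(p) < 2:
        raise ValidationError("need at least two time-points")
    if p[0]:
        return OnsetCall(gene_id, modality, "constitutive", None, None)
    if not any(p):
        return OnsetCall(gene_id, modality, "never", None, None)
    t = p.index(True)
    if all(p[t:]):
        return OnsetCall(gene_id, modality, "onset", labels[t], t)
    return OnsetCall(gene_id, modality, "unsustained", None, None)


def expression_onset(
    fpkm: Sequence[float],
    labels: Sequence[str],
    threshold: float = 1.0,
    sustained: bool = False,
    gene_id: str = "",
    modality: str = "expression",
) -> OnsetCall:
    """Onset of expression at FPKM > threshold.

    Day-0 expression above threshold makes the gene constitutive.  With
    ``sustained=False`` (default) the onset is the first time-point after
    day 0 exceeding the threshold; with ``sustained=True`` it is the
    earliest time-point from which every later value exceeds it, earlier
    transient crossings notwithstanding.
    """
    v = np.asarray(list(fpkm), dtype=float)
    if v.size == 0:
        raise ValidationError("empty FPKM vector")
    if v.size != len(labels):
        raise ValidationError("FPKM vector and labels differ in length")
    if v.size < 2:
        raise ValidationError("need at least two time-points")
    above = v > threshold
    if above[0]:
        return OnsetCall(gene_id, modality, "constitutive", None, None)
    if not above.any():
        return OnsetCall(gene_id, modality, "never", None, None)
    if not sustained:
        t = int(np.argmax(above))
        return OnsetCall(gene_id, modality, "onset", labels[t], t)
    # sustained: earliest suffix entirely above threshold
    for t in range(1, v.size):
        if above[t:].all():
            return OnsetCall(gene_id, modality, "onset", labels[t], int(t))
    return OnsetCall(gene_id, modality, "unsustained", None, None)


def route_exclusive(
    presence_successful: Sequence[bool] | None,
    presence_unsuccessful: Sequence[bool],
) -> bool | None:
    """True iff enrichment is absent at every sorted unsuccessful time-point.

    Only the unsuccessful-route samples (post-sorting) enter the check;
    shared day-0/day-3 samples cannot discriminate routes by construction.
    An empty unsuccessful vector yields None (undefined), never True.
    """
    u = [bool(x) for x in presence_unsuccessful]
    if not u:
        return None
    return not any(u)


def precedence(h33: OnsetCall, expr: OnsetCall) -> PrecedenceCall:
    """Deposition-vs-expression order for one gene.

    lead = (expression onset index) − (deposition onset index); positive
    means deposition precedes transcription.  Undefined when either call is
    not an onset.
    """
    gene_id = h33.gene_id or expr.gene_id
    if h33.status != "onset" or expr.status != "onset":
        return PrecedenceCall(gene_id, "undefined", None)
    lead = expr.onset_index - h33.onset_index
    if lead > 0:
        relation = "deposition_first"
    elif lead < 0:
        relation = "expression_first"
    else:
        relation = "simultaneous"
    return PrecedenceCall(gene_id, relation, lead)


# ---------------------------------------------------------------------------
# Matrix-level drivers
# ---------------------------------------------------------------------------

def classify_onsets(
    presence: pd.DataFrame,
    sheet: SampleSheet,
    assay: str = "chip_ip",
    modality: str = "h33",
) -> pd.DataFrame:
    """D-onwards calls for every gene along the successful route, plus
    route-exclusivity against the unsuccessful samples (when present)."""
    succ = sheet.successful_route(assay)
    unsucc = sheet.unsuccessful_route(assay)
    missing = [l for l in succ if l not in presence.columns]
    if missing:
        raise ValidationError(f"successful-route samples missing: {missing}")
    unsucc = [l for l in unsucc if l in presence.columns]
    rows = []
    for gid in presence.index:
        svec = presence.loc[gid, succ].tolist()
        call = classify_onset(svec, succ, gene_id=gid, modality=modality)
        excl = route_exclusive(svec, presence.loc[gid, unsucc].tolist()) if unsucc else None
        rows.append(
            (gid, modality, call.status, call.onset_label or "",
             -1 if call.onset_index is None else call.onset_index,
             "" if excl is None else str(bool(excl)))
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "modality", "status", "onset_label", "onset_index", "route_exclusive"],
    ).set_index("gene_id")


def expression_onsets(
    fpkm: pd.DataFrame,
    sheet: SampleSheet,
    assay: str = "rna",
    threshold: float = 1.0,
    sustained: bool = False,
    modality: str = "expression",
) -> pd.DataFrame:
    succ = sheet.successful_route(assay)
    missing = [l for l in succ if l not in fpkm.columns]
    if missing:
        raise ValidationError(f"successful-route samples missing: {missing}")
    rows = []
    for gid in fpkm.index:
        call = expression_onset(
            fpkm.loc[gid, succ].tolist(), succ, threshold=threshold,
            sustained=sustained, gene_id=gid, modality=modality,
        )
        rows.append(
            (gid, modality, call.status, call.onset_label or "",
             -1 if call.onset_index is None else call.onset_index)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "modality", "status", "onset_label", "onset_index"]
    ).set_index("gene_id")


def precedence_table(h33_calls: pd.DataFrame, expr_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene deposition-vs-expression precedence from two call tables."""
    genes = h33_calls.index.intersection(expr_calls.index)
    rows = []
    for gid in genes:
        h = h33_calls.loc[gid]
        e = expr_calls.loc[gid]
        if h["status"] != "onset" or e["status"] != "onset":
            rows.append((gid, "undefined", ""))
            continue
        lead = int(e["onset_index"]) - int(h["onset_index"])
        relation = (
            "deposition_first" if lead > 0
            else "expression_first" if lead < 0
            else "simultaneous"
        )
        rows.append((gid, relation, lead))
    return pd.DataFrame(rows, columns=["gene_id", "relation", "lead"]).set_index("gene_id")
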