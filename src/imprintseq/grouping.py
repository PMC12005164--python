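"""Temporal-consistency classification of imprinted genes.

Genes called MEG or PEG at one or more time points are sorted into four
groups describing how consistent their parent-of-origin expression is
across endosperm development, after a global mean-1-RPM expression filter:

* **Group 1** — expressed (>= 1 RPM) at every time point and imprinted in
  the same direction at every time point.
* **Group 2** — imprinted in the same direction at every time point at
  which the gene is expressed (not expressed everywhere).
* **Group 3** — parentally biased in the imprint's direction at every time
  point at which the gene is not imprinted.
* **Group 4** — clearly expressed (>= 5 RPM at every time point) genes that
  gain or lose imprinting: at least one time point is neither imprinted nor
  same-direction biased.

Rules are applied hierarchically (first match wins) so the groups are
disjoint; anything left is ``unassigned``. A gene imprinted in both
directions at different time points ("mixed"; not expected in practice)
skips Groups 1-3 and is evaluated for Group 4 with "biased in either
direction" as the bias notion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imprinting import (
    STATUS_BIPARENTAL,
    STATUS_MATERNAL_BIAS,
    STATUS_MEG,
    STATUS_NOT_EXPRESSED,
    STATUS_PATERNAL_BIAS,
    STATUS_PEG,
    ImprintThresholds,
)

__all__ = [
    "GROUP_1",
    "GROUP_2",
    "GROUP_3",
    "GROUP_4",
    "GROUP_UNASSIGNED",
    "GROUP_FILTERED",
    "GeneTemporalProfile",
    "GroupAssignment",
    "assign_group",
    "assign_groups",
    "build_profiles",
    "bias_consistency_counts",
    "group_summary",
]

GROUP_1 = "1"
GROUP_2 = "2"
GROUP_3 = "3"
GROUP_4 = "4"
GROUP_UNASSIGNED = "unassigned"
GROUP_FILTERED = "filtered_low_expression"

_IMPRINTED = (STATUS_MEG, STATUS_PEG)
_BIAS_OF = {STATUS_MEG: STATUS_MATERNAL_BIAS, STATUS_PEG: STATUS_PATERNAL_BIAS}


@dataclass(frozen=True)
class GeneTemporalProfile:
    """Per-time-point status and expression of one gene allele."""

    gene_allele_id: str
    daps: tuple[int, ...]
    rpm: tuple[float, ...]  # replicate-mean RPM per time point
    status: tuple[str, ...]  # imprinting status per time point
    rer: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (len(self.daps) == len(self.rpm) == len(self.status)):
            raise ValueError("daps, rpm and status must have equal length")


@dataclass(frozen=True)
class GroupAssignment:
    gene_allele_id: str
    group: str
    direction: str  # MEG, PEG or mixed
    rationale: str


def assign_group(
    p: GeneTemporalProfile,
    expr_min: float = 1.0,
    strong_min: float = 5.0,
) -> GroupAssignment:
    """Assign one gene allele to a temporal-consistency group.

    Precondition: the gene is imprinted (MEG or PEG) at >= 1 time point;
    profiles without any imprinted time point raise ``ValueError``.
    """
    status = list(p.status)
    rpm = np.asarray(p.rpm, dtype=float)
    imprinted = [s in _IMPRINTED for s in status]
    if not any(imprinted):
        raise ValueError(
            f"{p.gene_allele_id}: no imprinted time point; pre-filter callers "
            "must only submit imprinted genes"
        )
    dirs = sorted({s for s in status if s in _IMPRINTED})
    direction = dirs[0] if len(dirs) == 1 else "mixed"

    if rpm.mean() < expr_min:
        return GroupAssignment(
            p.gene_allele_id, GROUP_FILTERED, direction,
            f"mean RPM {rpm.mean():.3g} < {expr_min}",
        )

    if direction != "mixed":
        bias = _BIAS_OF[direction]
        expressed = rpm >= expr_min
        if expressed.all() and all(s == direction for s in status):
            return GroupAssignment(
                p.gene_allele_id, GROUP_1, direction,
                "expressed and imprinted in the same direction at every time point",
            )
        if all(s == direction for s, e in zip(status, expressed) if e):
            return GroupAssignment(
                p.gene_allele_id, GROUP_2, direction,
                "imprinted in the same direction at every expressed time point",
            )
        if all(s == bias for s, imp in zip(status, imprinted) if not imp):
            return GroupAssignment(
                p.gene_allele_id, GROUP_3, direction,
                "parentally biased in the same direction when not imprinted",
            )
        biased_or_imprinted = [s == direction or s == bias for s in status]
    else:
        biased_or_imprinted = [
            s in _IMPRINTED or s in _BIAS_OF.values() for s in status
        ]

    if (rpm >= strong_min).all() and not all(biased_or_imprinted):
        return GroupAssignment(
            p.gene_allele_id, GROUP_4, direction,
            f">= {strong_min} RPM throughout with gain/loss of imprinting",
        )
    return GroupAssignment(p.gene_allele_id, GROUP_UNASSIGNED, direction, "no rule matched")


def build_profiles(calls: pd.DataFrame) -> list[GeneTemporalProfile]:
    """Build temporal profiles from the long per-time-point call table."""
    profiles = []
    for gid, sub in calls.groupby(level="gene_allele_id", sort=False):
        sub = sub.sort_index(level="dap")
        profiles.append(
            GeneTemporalProfile(
                gene_allele_id=str(gid),
                daps=tuple(int(d) for d in sub.index.get_level_values("dap")),
                rpm=tuple(sub["mean_rpm"].astype(float)),
                status=tuple(sub["status"]),
                rer=tuple(sub["rer"].astype(float)),
            )
        )
    return profiles


def assign_groups(
    calls: pd.DataFrame, expr_min: float = 1.0, strong_min: float = 5.0
) -> pd.DataFrame:
    """Group every gene allele with >= 1 imprinted time point."""
    rows = []
    for p in build_profiles(calls):
        if not any(s in _IMPRINTED for s in p.status):
            continue
        a = assign_group(p, expr_min=expr_min, strong_min=strong_min)
        rows.append(
            {
                "gene_allele_id": a.gene_allele_id,
                "group": a.group,
                "direction": a.direction,
                "rationale": a.rationale,
            }
        )
    out = pd.DataFrame(rows, columns=["gene_allele_id", "group", "direction", "rationale"])
    return out.set_index("gene_allele_id")


def bias_consistency_counts(
    calls: pd.DataFrame, thr: ImprintThresholds = ImprintThresholds()
) -> pd.DataFrame:
    """Cross-tabulate imprinting recurrence against parental-bias recurrence.

    For MEGs and PEGs separately, genes are split into those imprinted at a
    single time point versus multiple time points, and binned by the number
    of time points (1..n) at which the RER meets the direction's lenient
    parental-bias threshold (> 0.8 maternal / < 0.4 paternal). Fractions
    are within each (direction, recurrence) stratum.
    """
    n_dap = calls.index.get_level_values("dap").nunique()
    rows = []
    for gid, sub in calls.groupby(level="gene_allele_id", sort=False):
        status = sub["status"].to_numpy()
        rer = sub["rer"].to_numpy(dtype=float)
        n_meg = int((status == STATUS_MEG).sum())
        n_peg = int((status == STATUS_PEG).sum())
        if (n_meg > 0) == (n_peg > 0):  # none imprinted, or mixed direction
            continue
        direction = STATUS_MEG if n_meg else STATUS_PEG
        n_imp = n_meg + n_peg
        with np.errstate(invalid="ignore"):
            if direction == STATUS_MEG:
                n_bias = int((rer > thr.maternal_bias_rer).sum())
            else:
                n_bias = int((rer < thr.paternal_bias_rer).sum())
        rows.append((direction, "single" if n_imp == 1 else "multiple", n_bias))
    tidy = pd.DataFrame(rows, columns=["direction", "imprint_recurrence", "n_bias_daps"])
    grid = pd.MultiIndex.from_product(
        [[STATUS_MEG, STATUS_PEG], ["single", "multiple"], range(0, n_dap + 1)],
        names=["direction", "imprint_recurrence", "n_bias_daps"],
    )
    counts = (
        tidy.groupby(["direction", "imprint_recurrence", "n_bias_daps"])
        .size()
        .reindex(grid, fill_value=0)
        .rename("count")
        .reset_index()
    )
    stratum = counts.groupby(["direction", "imprint_recurrence"])["count"].transform("sum")
    counts["fraction"] = np.where(stratum > 0, counts["count"] / stratum, 0.0)
    return counts


def group_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per (group x direction).

    Percentages are within direction, over the genes passing the 1 RPM
    expression filter (i.e. excluding ``filtered_low_expression``).
    """
    groups = [GROUP_1, GROUP_2, GROUP_3, GROUP_4, GROUP_UNASSIGNED, GROUP_FILTERED]
    directions = [STATUS_MEG, STATUS_PEG, "mixed"]
    grid = pd.MultiIndex.from_product([directions, groups], names=["direction", "group"])
    counts = (
        assignments.groupby(["direction", "group"]).size().reindex(grid, fill_value=0)
    )
    out = counts.rename("count").reset_index()
    passing = (
        out[out["group"] != GROUP_FILTERED].groupby("direction")["count"].transform("sum")
    )
    out["percent"] = 0.0
    mask = out["group"] != GROUP_FILTERED
    denom = passing.reindex(out.index[mask])
    out.loc[mask, "percent"] = np.where(
        denom > 0, 100.0 * out.loc[mask, "count"] / denom, 0.0
    )
    return out
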