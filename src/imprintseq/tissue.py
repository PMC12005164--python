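"""Endosperm-preferred versus multitissue expression classification.

Using a 10-tissue expression atlas, a gene is *endosperm preferred* when
more than 65% of its summed RPM across all tissue replicates originates in
the endosperm columns, and *multitissue* otherwise; genes with no atlas
expression are *not expressed*. Tissue classes are then cross-tabulated
against the temporal imprinting groups and a mutant-vs-wild-type DE gene
list (e.g. a DNA glycosylase mutant), with a "not detected" bin for genes
absent from that study's detection universe.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .io_tables import TissueAtlas

__all__ = [
    "TISSUE_ENDOSPERM_PREFERRED",
    "TISSUE_MULTI",
    "TISSUE_NOT_EXPRESSED",
    "classify_tissue",
    "crosstab_groups_tissue",
]

TISSUE_ENDOSPERM_PREFERRED = "endosperm_preferred"
TISSUE_MULTI = "multitissue"
TISSUE_NOT_EXPRESSED = "not_expressed_in_atlas"

MDR1_DE = "mdr1_DE"
MDR1_NOT_DE = "not_DE"
MDR1_NOT_DETECTED = "not_detected"


def classify_tissue(
    atlas: TissueAtlas, threshold: float = 0.65
) -> pd.DataFrame:
    """Per-gene endosperm expression fraction and tissue class.

    The endosperm fraction is the sum of the endosperm replicate columns
    over the sum of all tissue columns; classification requires the
    fraction to be strictly greater than ``threshold`` (default 65%).
    Classification is invariant to global rescaling of the atlas.
    """
    total = atlas.values.sum(axis=1)
    endo = atlas.values[list(atlas.endosperm_columns)].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fraction = np.where(total > 0, endo / total.replace(0, 1.0), np.nan)
    cls = np.select(
        [total <= 0, fraction > threshold],
        [TISSUE_NOT_EXPRESSED, TISSUE_ENDOSPERM_PREFERRED],
        default=TISSUE_MULTI,
    )
    return pd.DataFrame(
        {"endosperm_fraction": fraction, "tissue_class": cls}, index=atlas.values.index
    )


def crosstab_groups_tissue(
    groups: pd.DataFrame,
    tissue_calls: pd.DataFrame,
    mdr1_degs: Iterable[str],
    mdr1_universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Contingency of temporal group x tissue class x mutant-DE status.

    ``groups`` is indexed by gene id with ``group`` (and optionally
    ``direction``) columns; genes missing from the atlas fall into the
    "not expressed in atlas" tissue class; genes outside ``mdr1_universe``
    (when given) count as "not detected" in the mutant study.
    """
    degs = set(mdr1_degs)
    universe = set(mdr1_universe) if mdr1_universe is not None else None
    df = groups.copy()
    df["tissue_class"] = (
        tissue_calls["tissue_class"].reindex(df.index).fillna(TISSUE_NOT_EXPRESSED)
    )

    def mdr1_status(gene: str) -> str:
        if gene in degs:
            return MDR1_DE
        if universe is None or gene in universe:
            return MDR1_NOT_DE
        return MDR1_NOT_DETECTED

    df["mdr1_status"] = [mdr1_status(g) for g in df.index]
    out = (
        df.groupby(["group", "tissue_class", "mdr1_status"])
        .size()
        .rename("count")
        .reset_index()
    )
    return out
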