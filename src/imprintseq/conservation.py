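"""Cross-genotype conservation of parent-of-origin expression bias.

A panel of reciprocal crosses between a reference line (B73) and several
alternate genotypes, each profiled at a single time point, is reduced to a
per-(gene, genotype) table of RER and status through single-copy syntelogs.
The conservation statistic is *percent same imprint*: the number of
genotypes in which the gene meets the lenient parental-bias RER threshold
in its reference direction, divided by the number of genotypes in which an
informative syntelog is expressed. Conservation is assessed on bias, not on
significance-gated imprinting calls, so modest panel sequencing depth does
not masquerade as lost imprinting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import AlleleCountMatrix, SyntelogMap, split_gene_allele
from .imprinting import (
    STATUS_MEG,
    STATUS_PEG,
    ImprintThresholds,
    run_imprinting,
)

__all__ = [
    "ConservationScore",
    "build_genotype_table",
    "percent_same_imprint",
    "conservation_scores",
    "conservation_by_group",
    "panel_counts",
]


@dataclass(frozen=True)
class ConservationScore:
    b73_gene_id: str
    direction: str  # MEG or PEG, from the reference time-series call
    n_genotypes_expressed: int
    n_genotypes_same_bias: int

    @property
    def percent_same_imprint(self) -> float:
        if self.n_genotypes_expressed == 0:
            raise ValueError(
                f"{self.b73_gene_id}: no expressed syntelog in any genotype"
            )
        return self.n_genotypes_same_bias / self.n_genotypes_expressed


def build_genotype_table(
    panel: Mapping[str, AlleleCountMatrix],
    syntelogs: SyntelogMap,
    thr: ImprintThresholds = ImprintThresholds(),
    dap: int | None = None,
    expr_min: float = 1.0,
) -> pd.DataFrame:
    """Per-genotype RER/status for the alternate-genome allele of each gene.

    ``panel`` maps each alternate genotype to its reciprocal-cross count
    matrix (with the reference line). For every genotype, imprinting is
    called on the alternate-genome gene-allele rows and joined back to
    reference ids through single-copy syntelogs; alleles without an
    informative syntelog are excluded. ``expressed`` requires a combined
    (maternal + paternal) replicate-mean RPM of at least ``expr_min``.
    """
    syn = syntelogs.single_copy()
    frames = []
    for genotype, acm in panel.items():
        directions = acm.directions
        genomes_in_meta = {g for d in directions for g in d}
        if genotype not in genomes_in_meta:
            raise ValueError(f"panel matrix for {genotype!r} lacks that genotype")
        mats = {d[0] for d in directions}
        if len(directions) < 2 or genotype not in mats:
            raise ValueError(
                f"genotype {genotype!r} is missing a reciprocal direction"
            )
        use = acm
        if dap is not None:
            cols = use.samples_where(dap=dap)
            if not cols:
                raise ValueError(f"genotype {genotype!r} has no samples at {dap} DAP")
            use = use.subset_samples(cols)
        calls, _ = run_imprinting(use, thr=thr, expr_min=expr_min)
        # one time point expected for a panel snapshot
        calls = calls.reset_index()
        mapping = syn.alt_to_b73(genotype)
        rows = []
        for _, row in calls.iterrows():
            genome, gene = split_gene_allele(row["gene_allele_id"])
            if genome != genotype or gene not in mapping.index:
                continue
            combined = row["maternal_rpm"] + row["paternal_rpm"]
            rows.append(
                {
                    "b73_gene_id": mapping[gene],
                    "genotype": genotype,
                    "dap": row["dap"],
                    "rer": row["rer"],
                    "status": row["status"],
                    "expressed": bool(combined >= expr_min),
                    "maternal_rpm": row["maternal_rpm"],
                    "paternal_rpm": row["paternal_rpm"],
                }
            )
        frames.append(pd.DataFrame(rows))
    if not frames:
        raise ValueError("empty panel")
    return pd.concat(frames, ignore_index=True)


def _bias_met(table: pd.DataFrame, direction: str, thr: ImprintThresholds) -> pd.Series:
    rer = table["rer"].astype(float)
    with np.errstate(invalid="ignore"):
        if direction == STATUS_MEG:
            return rer > thr.maternal_bias_rer
        if direction == STATUS_PEG:
            return rer < thr.paternal_bias_rer
    raise ValueError(f"reference direction must be MEG or PEG, got {direction!r}")


def percent_same_imprint(
    table: pd.DataFrame,
    gene: str,
    reference_direction: str,
    thr: ImprintThresholds = ImprintThresholds(),
) -> ConservationScore:
    """Conservation score of one gene across the genotype panel."""
    sub = table[table["b73_gene_id"] == gene]
    expressed = sub[sub["expressed"]]
    if len(expressed) == 0:
        raise ValueError(f"{gene!r}: no expressed syntelog in the panel")
    same = _bias_met(expressed, reference_direction, thr)
    return ConservationScore(
        b73_gene_id=gene,
        direction=reference_direction,
        n_genotypes_expressed=int(len(expressed)),
        n_genotypes_same_bias=int(same.sum()),
    )


def conservation_scores(
    table: pd.DataFrame,
    reference_directions: pd.Series,
    thr: ImprintThresholds = ImprintThresholds(),
) -> pd.DataFrame:
    """Vectorized percent-same-imprint for every gene with a reference call.

    ``reference_directions`` maps reference gene id -> MEG/PEG from the
    time-series analysis. Genes without any expressed syntelog are dropped.
    """
    sub = table[table["b73_gene_id"].isin(reference_directions.index)].copy()
    sub["direction"] = reference_directions.reindex(sub["b73_gene_id"]).to_numpy()
    rows = []
    for (gene, direction), grp in sub.groupby(["b73_gene_id", "direction"]):
        expressed = grp[grp["expressed"]]
        if len(expressed) == 0:
            continue
        same = int(_bias_met(expressed, direction, thr).sum())
        rows.append(
            {
                "b73_gene_id": gene,
                "direction": direction,
                "n_genotypes_expressed": int(len(expressed)),
                "n_genotypes_same_bias": same,
                "percent_same_imprint": same / len(expressed),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "b73_gene_id",
            "direction",
            "n_genotypes_expressed",
            "n_genotypes_same_bias",
            "percent_same_imprint",
        ],
    ).set_index("b73_gene_id")


def conservation_by_group(
    scores: pd.DataFrame,
    assignments: pd.DataFrame,
    min_genotypes: int = 4,
) -> pd.DataFrame:
    """Mean and spread of percent-same-imprint per (temporal group, direction).

    ``assignments`` is indexed by reference gene id with ``group`` and
    ``direction`` columns. Genes expressed in fewer than ``min_genotypes``
    genotypes are excluded.
    """
    joined = scores.join(assignments[["group"]], how="inner")
    joined = joined[joined["n_genotypes_expressed"] >= min_genotypes]
    out = (
        joined.groupby(["group", "direction"])["percent_same_imprint"]
        .agg(["count", "mean", "median", "std"])
        .reset_index()
        .rename(columns={"count": "n_genes"})
    )
    return out


def panel_counts(
    table: pd.DataFrame, thr: ImprintThresholds = ImprintThresholds()
) -> pd.DataFrame:
    """Per-genotype tallies of imprinted and parentally biased genes."""
    rows = []
    with np.errstate(invalid="ignore"):
        for genotype, grp in table.groupby("genotype"):
            rer = grp["rer"].astype(float)
            rows.append(
                {
                    "genotype": genotype,
                    "n_meg": int((grp["status"] == STATUS_MEG).sum()),
                    "n_peg": int((grp["status"] == STATUS_PEG).sum()),
                    "n_maternal_bias": int((rer > thr.maternal_bias_rer).sum()),
                    "n_paternal_bias": int((rer < thr.paternal_bias_rer).sum()),
                }
            )
    return pd.DataFrame(rows).set_index("genotype")
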