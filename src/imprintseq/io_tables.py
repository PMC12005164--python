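"""Tabular data model and IO for allele-resolved reciprocal-cross experiments.

Count tables come from RNA-seq reads aligned to *concatenated* parental
genome assemblies, so every row is a gene **allele**: one parental genome's
copy of a gene model. Rows are namespaced ``"<genotype>:<gene_id>"`` to keep
the two genomes' feature spaces unambiguous. Sample metadata records the
cross direction (maternal and paternal genotype), the developmental time
point in days after pollination (DAP), and the replicate number.

The module also owns RPM (reads-per-million) normalization, the pan-gene
syntelog table reader with its single-copy filter, and the 10-tissue
expression atlas container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ("maternal_genotype", "paternal_genotype", "dap", "replicate")

__all__ = [
    "META_COLUMNS",
    "SampleMeta",
    "AlleleCountMatrix",
    "ExpressionMatrix",
    "SyntelogMap",
    "TissueAtlas",
    "split_gene_allele",
    "read_counts",
    "write_counts",
    "rpm_normalize",
    "read_syntelog_table",
    "write_pangene_table",
    "read_tissue_atlas",
    "write_tissue_atlas",
    "collapse_alleles",
]


def split_gene_allele(gene_allele_id: str) -> tuple[str, str]:
    """Split ``"<genotype>:<gene_id>"`` into its genome and gene parts."""
    genome, sep, gene = gene_allele_id.partition(":")
    if not sep or not genome or not gene:
        raise ValueError(
            f"gene-allele id {gene_allele_id!r} is not namespaced as "
            "'<genotype>:<gene_id>'"
        )
    return genome, gene


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library."""

    sample_id: str
    maternal_genotype: str
    paternal_genotype: str
    dap: int
    replicate: int

    def __post_init__(self) -> None:
        if self.maternal_genotype == self.paternal_genotype:
            raise ValueError(
                f"sample {self.sample_id!r}: maternal and paternal genotype "
                f"are both {self.maternal_genotype!r}; reciprocal-cross "
                "samples must be hybrids"
            )
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id!r}: replicate must be >= 1")


def _meta_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "maternal_genotype": s.maternal_genotype,
            "paternal_genotype": s.paternal_genotype,
            "dap": s.dap,
            "replicate": s.replicate,
        }
        for s in samples
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _validate_meta(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample metadata is missing columns: {missing}")
    samples = samples.copy()
    samples["dap"] = samples["dap"].astype(int)
    samples["replicate"] = samples["replicate"].astype(int)
    same = samples["maternal_genotype"] == samples["paternal_genotype"]
    if same.any():
        bad = samples.index[same][0]
        raise ValueError(
            f"sample {bad!r} has identical maternal and paternal genotype"
        )
    key = samples[list(META_COLUMNS)]
    if key.duplicated().any():
        bad = samples.index[key.duplicated()][0]
        raise ValueError(
            f"duplicate (maternal, paternal, dap, replicate) combination at "
            f"sample {bad!r}"
        )
    return samples


@dataclass
class AlleleCountMatrix:
    """Raw uniquely-assigned read counts per gene allele per sample.

    Parameters
    ----------
    counts
        Integer DataFrame, gene-allele ids (``"<genotype>:<gene_id>"``) as
        index, sample ids as columns.
    samples
        DataFrame indexed by sample id with the :data:`META_COLUMNS`.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene-allele id {dup!r} in count table")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count table contains non-numeric values")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count {values[g, s]} at gene "
                f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise ValueError(
                    f"non-integer count {values[g, s]} at gene "
                    f"{self.counts.index[g]!r}, sample "
                    f"{self.counts.columns[s]!r}"
                )
            self.counts = self.counts.round().astype(np.int64)
        self.samples = _validate_meta(self.samples)
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"no metadata for sample column(s): {missing}")
        # align metadata to count columns, dropping unused metadata rows
        self.samples = self.samples.loc[list(self.counts.columns)]
        for gid in self.counts.index:
            split_gene_allele(gid)

    # -- convenience views ------------------------------------------------
    @property
    def gene_allele_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def dap_set(self) -> tuple[int, ...]:
        return tuple(sorted(self.samples["dap"].unique()))

    @property
    def genomes(self) -> pd.Series:
        """Source genome of every gene-allele row."""
        return pd.Series(
            [split_gene_allele(g)[0] for g in self.counts.index],
            index=self.counts.index,
            name="genome",
        )

    @property
    def directions(self) -> list[tuple[str, str]]:
        pairs = self.samples[["maternal_genotype", "paternal_genotype"]]
        return sorted(set(map(tuple, pairs.itertuples(index=False))))

    def subset_samples(self, sample_ids: Sequence[str]) -> "AlleleCountMatrix":
        return AlleleCountMatrix(
            counts=self.counts[list(sample_ids)].copy(),
            samples=self.samples.loc[list(sample_ids)].copy(),
        )

    def samples_where(self, *, maternal: str | None = None, dap: int | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if maternal is not None:
            mask &= self.samples["maternal_genotype"] == maternal
        if dap is not None:
            mask &= self.samples["dap"] == dap
        return list(self.samples.index[mask])


@dataclass
class ExpressionMatrix:
    """RPM-normalized expression on the same axes as the count matrix."""

    values: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series

    @property
    def gene_allele_ids(self) -> pd.Index:
        return self.values.index

    @property
    def dap_set(self) -> tuple[int, ...]:
        return tuple(sorted(self.samples["dap"].unique()))

    @property
    def genomes(self) -> pd.Series:
        return pd.Series(
            [split_gene_allele(g)[0] for g in self.values.index],
            index=self.values.index,
            name="genome",
        )

    def direction_mean(self, maternal: str, dap: int | None = None) -> pd.Series:
        """Replicate-mean RPM over samples with the given maternal parent."""
        mask = self.samples["maternal_genotype"] == maternal
        if dap is not None:
            mask &= self.samples["dap"] == dap
        cols = self.samples.index[mask]
        if len(cols) == 0:
            raise ValueError(
                f"no samples with maternal genotype {maternal!r}"
                + (f" at {dap} DAP" if dap is not None else "")
            )
        return self.values[cols].mean(axis=1)

    def dap_means(self, maternal: str) -> pd.DataFrame:
        """Gene x DAP replicate-mean RPM for one cross direction."""
        out = {}
        for dap in self.dap_set:
            out[dap] = self.direction_mean(maternal, dap)
        return pd.DataFrame(out)


def rpm_normalize(m: AlleleCountMatrix) -> ExpressionMatrix:
    """Normalize counts to reads per million of the per-sample library total.

    The library total is the sum over *all* gene-allele rows of the
    concatenated-genome table, mirroring per-library total-read
    normalization.
    """
    totals = m.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"sample {totals.index[zero][0]!r} has zero total counts; "
            "cannot RPM-normalize"
        )
    values = m.counts.div(totals, axis=1) * 1e6
    return ExpressionMatrix(
        values=values, samples=m.samples.copy(), library_sizes=totals.astype(float)
    )


# ---------------------------------------------------------------------------
# count table IO
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, meta_path: str | Path) -> AlleleCountMatrix:
    """Read a gene-allele x sample count TSV plus its sample-metadata TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.isna().any().any():
        raise ValueError(f"count table {path} contains missing values")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return AlleleCountMatrix(counts=counts, samples=meta)


def write_counts(m: AlleleCountMatrix, path: str | Path, meta_path: str | Path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="gene_allele_id")
    m.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def write_expression(e: ExpressionMatrix, path: str | Path) -> None:
    e.values.to_csv(path, sep="\t", index_label="gene_allele_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# syntelogs
# ---------------------------------------------------------------------------

@dataclass
class SyntelogMap:
    """Single-copy syntelog correspondences between B73 and alternate genomes.

    ``records`` has columns ``b73_gene_id``, ``genotype``, ``alt_gene_id``.
    After single-copy filtering each (b73_gene_id, genotype) pair appears at
    most once.
    """

    records: pd.DataFrame
    reference: str = "B73"

    COLUMNS = ("b73_gene_id", "genotype", "alt_gene_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"syntelog records missing columns: {missing}")
        self.records = self.records.reset_index(drop=True)

    def single_copy(self) -> "SyntelogMap":
        """Drop any (gene, genotype) pair appearing more than once. Idempotent."""
        key = self.records[["b73_gene_id", "genotype"]]
        keep = ~key.duplicated(keep=False)
        return SyntelogMap(self.records[keep].reset_index(drop=True), self.reference)

    def genotypes(self) -> list[str]:
        return sorted(self.records["genotype"].unique())

    def for_genotype(self, genotype: str) -> pd.DataFrame:
        return self.records[self.records["genotype"] == genotype]

    def alt_to_b73(self, genotype: str) -> pd.Series:
        sub = self.for_genotype(genotype)
        return pd.Series(sub["b73_gene_id"].values, index=sub["alt_gene_id"].values)


def read_syntelog_table(
    path: str | Path,
    genotypes: Iterable[str],
    reference: str = "B73",
) -> SyntelogMap:
    """Read a pan-gene TSV and keep single-copy reference/alternate pairs.

    Dialect: tab-separated; first column the pan-gene group id; one column
    per genome listing comma-separated member gene ids; empty cell = gene
    absent from that genome. Only pairs that are single copy in *both* the
    reference and the alternate genotype are retained.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genotypes = sorted(set(genotypes) - {reference})
    absent = [g for g in [reference, *genotypes] if g not in table.columns]
    if absent:
        raise ValueError(f"genotype column(s) {absent} absent from pan-gene table header")

    def members(cell: object) -> list[str]:
        if isinstance(cell, str) and cell.strip():
            return [m.strip() for m in cell.split(",") if m.strip()]
        return []

    rows = []
    for _, row in table.iterrows():
        ref_members = members(row[reference])
        if len(ref_members) != 1:
            continue
        for g in genotypes:
            alt_members = members(row[g])
            if len(alt_members) == 1:
                rows.append((ref_members[0], g, alt_members[0]))
    records = pd.DataFrame(rows, columns=list(SyntelogMap.COLUMNS))
    return SyntelogMap(records, reference).single_copy()


def write_pangene_table(
    syn: SyntelogMap, path: str | Path, genotypes: Iterable[str] | None = None
) -> None:
    """Write a SyntelogMap back out in the pan-gene TSV dialect."""
    genotypes = sorted(genotypes) if genotypes is not None else syn.genotypes()
    wide = syn.records.pivot_table(
        index="b73_gene_id",
        columns="genotype",
        values="alt_gene_id",
        aggfunc=lambda x: ",".join(x),
    ).reindex(columns=genotypes)
    wide.insert(0, syn.reference, wide.index)
    wide.index = [f"pan_{i:06d}" for i in range(len(wide))]
    wide.fillna("").to_csv(path, sep="\t", index_label="pan_gene_id")


# ---------------------------------------------------------------------------
# tissue atlas
# ---------------------------------------------------------------------------

@dataclass
class TissueAtlas:
    """RPM expression of genes across a panel of tissues.

    ``values`` is a gene x tissue-replicate-column DataFrame; the columns in
    ``endosperm_columns`` are the designated endosperm replicates.
    """

    values: pd.DataFrame
    endosperm_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.endosperm_columns) == 0:
            raise ValueError("tissue atlas needs at least one endosperm column")
        missing = [c for c in self.endosperm_columns if c not in self.values.columns]
        if missing:
            raise ValueError(f"endosperm column(s) {missing} absent from atlas")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("tissue atlas contains negative expression values")


def read_tissue_atlas(
    path: str | Path, endosperm_prefix: str = "endosperm"
) -> TissueAtlas:
    values = pd.read_csv(path, sep="\t", index_col=0)
    endo = tuple(c for c in values.columns if c.startswith(endosperm_prefix))
    return TissueAtlas(values=values, endosperm_columns=endo)


def write_tissue_atlas(atlas: TissueAtlas, path: str | Path) -> None:
    atlas.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# allele -> gene-model collapsing
# ---------------------------------------------------------------------------

def collapse_alleles(
    m: AlleleCountMatrix, mapping: Mapping[str, str]
) -> AlleleCountMatrix:
    """Sum gene-allele rows into gene-model rows.

    ``mapping`` sends gene-allele ids to gene-model ids (for example both
    parental alleles of one gene to its reference id, emulating a
    single-reference alignment). Rows absent from the mapping are dropped.
    """
    keep = [g for g in m.counts.index if g in mapping]
    grouped = m.counts.loc[keep].groupby([mapping[g] for g in keep]).sum()
    # gene-model rows keep a pseudo-namespace so downstream code can reuse them
    grouped.index = [f"gene:{g}" if ":" not in g else g for g in grouped.index]
    return AlleleCountMatrix(counts=grouped, samples=m.samples.copy())
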