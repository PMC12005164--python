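"""Synthetic reciprocal-cross experiments with known per-gene imprinting truth.

The generator emulates the count structure of allele-specific endosperm
RNA-seq: two reciprocal cross directions, several days-after-pollination
(DAP) time points, replicated libraries, negative-binomial counts, and a
2 maternal : 1 paternal genome dosage (triploid endosperm), so that a gene
with equal per-genome-copy expression contributes 2/3 of its transcripts
from the maternal alleles.

Every simulated gene carries a truth class:

``MEG_constitutive`` / ``PEG_constitutive``
    maternal transcript fraction 0.97 / 0.03 at every time point.
``MEG_transient`` / ``PEG_transient``
    imprinted fraction at a proper, non-empty subset of time points,
    dosage-proportional (2/3) elsewhere; clearly expressed so that the
    variable-imprinting group is recoverable.
``maternal_bias`` / ``paternal_bias``
    one imprinted time point plus sub-imprinting parental bias (fractions
    0.86 / 0.30) at the remaining time points.
``biparental``
    dosage-proportional 2/3 everywhere; includes a small "edge" subpopulation
    whose expression straddles the 1-5 RPM filter thresholds.
``zein_like``
    dosage-proportional but 100-1000x more highly expressed than the median
    gene, peaking at 17 DAP, stress-testing RPM normalization the way seed
    storage prolamins dominate real endosperm libraries.
``silent``
    no expression.

Because each gene model appears as two gene-allele rows (one per parental
genome), the per-gene total count is split binomially between the two rows
with probability equal to the maternal fraction in that cross direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import AlleleCountMatrix, SyntelogMap, TissueAtlas

DOSAGE_NULL_FRACTION = 2.0 / 3.0  # 2 maternal : 1 paternal genome copies

CLASS_NAMES = (
    "MEG_constitutive",
    "PEG_constitutive",
    "MEG_transient",
    "PEG_transient",
    "maternal_bias",
    "paternal_bias",
    "biparental",
    "zein_like",
    "silent",
)

DEFAULT_N_GENES: dict[str, int] = {
    "MEG_constitutive": 400,
    "PEG_constitutive": 100,
    "MEG_transient": 100,
    "PEG_transient": 100,
    "maternal_bias": 200,
    "paternal_bias": 200,
    "biparental": 1850,
    "zein_like": 10,
    "silent": 40,
}

# probability that an alternate (non-reference-pair) genotype retains the
# class's parental bias; drives the cross-genotype conservation gradient
DEFAULT_BIAS_CONSERVATION: dict[str, float] = {
    "MEG_constitutive": 0.85,
    "PEG_constitutive": 0.85,
    "MEG_transient": 0.30,
    "PEG_transient": 0.30,
    "maternal_bias": 0.60,
    "paternal_bias": 0.60,
}

# probability that a gene's class makes it endosperm-preferred in the atlas
ENDOSPERM_PREFERRED_RATE: dict[str, float] = {
    "MEG_constitutive": 0.70,
    "PEG_constitutive": 0.40,
    "MEG_transient": 0.30,
    "PEG_transient": 0.30,
    "maternal_bias": 0.40,
    "paternal_bias": 0.40,
    "biparental": 0.15,
    "zein_like": 1.00,
    "silent": 0.00,
}


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one simulated gene model."""

    gene_id: str
    gene_class: str
    maternal_fraction: tuple[float, ...]  # per time point
    base_rpm: tuple[float, ...]  # expected nominal RPM trajectory
    present_in_genotypes: frozenset[str]
    biased_in_genotypes: frozenset[str]
    endosperm_preferred: bool


@dataclass
class SimConfig:
    """Configuration of a simulated reciprocal-cross experiment."""

    n_genes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_GENES))
    genotype_pairs: tuple[tuple[str, str], ...] = (("B73", "W22"),)
    dap_set: tuple[int, ...] = (11, 14, 17, 21)
    replicates: int = 3
    library_size_mean: float = 5e6
    library_size_cv: float = 0.15
    nb_dispersion: float = 0.05
    imprint_fraction: float = 0.97  # maternal fraction of an imprinted MEG dap
    maternal_bias_fraction: float = 0.86
    paternal_bias_fraction: float = 0.30
    presence_rate: float = 0.90  # P(gene present in a non-reference genotype)
    bias_conservation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIAS_CONSERVATION)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        unknown = set(self.n_genes) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown gene classes in n_genes: {sorted(unknown)}")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per direction are required")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.presence_rate <= 1:
            raise ValueError("presence_rate must be in [0, 1]")

    @property
    def reference_pair(self) -> tuple[str, str]:
        return self.genotype_pairs[0]

    @property
    def alt_genotypes(self) -> list[str]:
        ref = self.reference_pair[0]
        return [b for a, b in self.genotype_pairs if a == ref] + [
            a for a, b in self.genotype_pairs if a != ref
        ]

    def n_total(self) -> int:
        return int(sum(self.n_genes.values()))


def _require_seed(cfg: SimConfig) -> int:
    if cfg.seed is None:
        raise ValueError("SimConfig.seed is required for reproducible simulation")
    return int(cfg.seed)


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

def _trajectory(rng: np.random.Generator, cls: str, n_dap: int, dap_set) -> np.ndarray:
    """Nominal expected-RPM trajectory for one gene."""
    if cls == "silent":
        return np.zeros(n_dap)
    if cls == "zein_like":
        peak = rng.uniform(1e4, 5e4)
        # prolamin-style ramp peaking near 17 DAP
        template = {11: 0.05, 14: 0.30, 17: 1.00, 21: 0.50}
        shape = np.array([template.get(d, 0.3) for d in dap_set])
        shape = shape * rng.lognormal(0.0, 0.15, n_dap)
        return peak * shape / shape.max()
    if cls in ("MEG_transient", "PEG_transient"):
        peak = rng.lognormal(np.log(100.0), 0.6)
        sigma = 0.2
    elif cls == "biparental":
        if rng.uniform() < 0.07:  # edge genes straddling the 1-5 RPM filters
            peak = rng.lognormal(np.log(2.0), 0.8)
        else:
            peak = rng.lognormal(np.log(250.0), 1.0)
        sigma = 0.5
    else:  # constitutive imprints and bias classes
        peak = rng.lognormal(np.log(50.0), 0.75)
        sigma = 0.2
    shape = rng.lognormal(0.0, sigma, n_dap)
    return peak * shape / shape.max()


def _fractions(rng: np.random.Generator, cls: str, cfg: SimConfig, n_dap: int) -> np.ndarray:
    meg, peg = cfg.imprint_fraction, 1.0 - cfg.imprint_fraction
    f = np.full(n_dap, DOSAGE_NULL_FRACTION)
    if cls == "MEG_constitutive":
        f[:] = meg
    elif cls == "PEG_constitutive":
        f[:] = peg
    elif cls in ("MEG_transient", "PEG_transient"):
        k = int(rng.integers(1, n_dap))  # imprinted at 1 .. n_dap-1 time points
        idx = rng.choice(n_dap, size=k, replace=False)
        f[idx] = meg if cls == "MEG_transient" else peg
    elif cls == "maternal_bias":
        f[:] = cfg.maternal_bias_fraction
        f[rng.integers(n_dap)] = meg
    elif cls == "paternal_bias":
        f[:] = cfg.paternal_bias_fraction
        f[rng.integers(n_dap)] = peg
    return f


def generate_truth(cfg: SimConfig) -> list[GeneTruth]:
    """Draw the per-gene truth table for an experiment (seeded by the config)."""
    seed = _require_seed(cfg)
    rng = np.random.default_rng([seed, 101])
    n_dap = len(cfg.dap_set)
    ref_alt = cfg.reference_pair[1]
    other_genotypes = [g for g in cfg.alt_genotypes if g != ref_alt]
    truth: list[GeneTruth] = []
    i = 0
    for cls in CLASS_NAMES:
        for _ in range(int(cfg.n_genes.get(cls, 0))):
            gid = f"g{i:06d}"
            i += 1
            present = {ref_alt} | {
                g for g in other_genotypes if rng.uniform() < cfg.presence_rate
            }
            rate = cfg.bias_conservation.get(cls, 1.0)
            biased = {ref_alt} | {
                g for g in other_genotypes if g in present and rng.uniform() < rate
            }
            truth.append(
                GeneTruth(
                    gene_id=gid,
                    gene_class=cls,
                    maternal_fraction=tuple(_fractions(rng, cls, cfg, n_dap)),
                    base_rpm=tuple(_trajectory(rng, cls, n_dap, cfg.dap_set)),
                    present_in_genotypes=frozenset(present),
                    biased_in_genotypes=frozenset(biased),
                    endosperm_preferred=bool(
                        rng.uniform() < ENDOSPERM_PREFERRED_RATE.get(cls, 0.0)
                    ),
                )
            )
    return truth


def truth_frame(truth: Sequence[GeneTruth]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {
                "gene_id": t.gene_id,
                "gene_class": t.gene_class,
                "maternal_fraction": ",".join(f"{x:.17g}" for x in t.maternal_fraction),
                "base_rpm": ",".join(f"{x:.17g}" for x in t.base_rpm),
                "present_in_genotypes": ",".join(sorted(t.present_in_genotypes)),
                "biased_in_genotypes": ",".join(sorted(t.biased_in_genotypes)),
                "endosperm_preferred": t.endosperm_preferred,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def alt_gene_id(genotype: str, gene_id: str) -> str:
    """Gene-model id of a reference gene in an alternate genome assembly."""
    return f"{genotype}_{gene_id}"


def reference_gene_id(gene_allele_id: str) -> str:
    """Recover the reference (truth-table) gene id behind any gene-allele row."""
    from .io_tables import split_gene_allele

    genome, gene = split_gene_allele(gene_allele_id)
    prefix = f"{genome}_"
    return gene[len(prefix):] if gene.startswith(prefix) else gene


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 0.0))
    return rng.negative_binomial(n, p)


def simulate_experiment(
    cfg: SimConfig,
    truth: Sequence[GeneTruth] | None = None,
    pair: tuple[str, str] | None = None,
) -> tuple[AlleleCountMatrix, list[GeneTruth]]:
    """Simulate one reciprocal-cross experiment.

    Returns the allele-resolved count matrix (two gene-allele rows per gene
    model present in both genomes) and the truth table. When ``pair`` is an
    alternate genotype pair, genes keep their class fractions only in
    genotypes listed in their ``biased_in_genotypes``; elsewhere they revert
    to the 2/3 dosage null. Reads from an allele whose genome lacks the gene
    are discarded (presence/absence variation).
    """
    seed = _require_seed(cfg)
    if truth is None:
        truth = generate_truth(cfg)
    if pair is None:
        pair = cfg.reference_pair
    if pair not in cfg.genotype_pairs:
        raise ValueError(f"pair {pair} not in cfg.genotype_pairs")
    ref, alt = pair
    pair_idx = cfg.genotype_pairs.index(pair)
    rng = np.random.default_rng([seed, 7919, pair_idx])

    dap_set = cfg.dap_set
    n_dap = len(dap_set)
    n_genes = len(truth)

    # sample sheet: 2 directions x daps x replicates
    sample_rows = []
    for mat, pat in ((ref, alt), (alt, ref)):
        for dap in dap_set:
            for rep in range(1, cfg.replicates + 1):
                sample_rows.append(
                    {
                        "sample_id": f"{mat}x{pat}_{dap}DAP_r{rep}",
                        "maternal_genotype": mat,
                        "paternal_genotype": pat,
                        "dap": dap,
                        "replicate": rep,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(samples)
    sigma = np.sqrt(np.log1p(cfg.library_size_cv**2))
    lib = rng.lognormal(np.log(cfg.library_size_mean) - sigma**2 / 2, sigma, n_samples)

    dap_idx = np.array([dap_set.index(d) for d in samples["dap"]])
    ref_is_maternal = (samples["maternal_genotype"] == ref).to_numpy()

    base = np.array([t.base_rpm for t in truth])  # genes x daps
    frac = np.array(
        [
            t.maternal_fraction
            if alt in t.biased_in_genotypes
            else np.full(n_dap, DOSAGE_NULL_FRACTION)
            for t in truth
        ]
    )
    present_alt = np.array([alt in t.present_in_genotypes for t in truth])

    mu = base[:, dap_idx] * (lib[None, :] / 1e6)  # genes x samples
    total = _nb_draw(rng, mu, cfg.nb_dispersion)
    p_mat = frac[:, dap_idx]
    maternal = rng.binomial(total, p_mat)
    paternal = total - maternal

    # allele of the reference genome: maternal reads when ref is the mother
    ref_counts = np.where(ref_is_maternal[None, :], maternal, paternal)
    alt_counts = total - ref_counts

    gene_ids = [t.gene_id for t in truth]
    ref_rows = pd.DataFrame(
        ref_counts, index=[f"{ref}:{g}" for g in gene_ids], columns=samples.index
    )
    alt_rows = pd.DataFrame(
        alt_counts[present_alt],
        index=[f"{alt}:{alt_gene_id(alt, g)}" for g, keep in zip(gene_ids, present_alt) if keep],
        columns=samples.index,
    )
    counts = pd.concat([ref_rows, alt_rows])
    return AlleleCountMatrix(counts=counts, samples=samples), list(truth)


def simulate_panel(
    cfg: SimConfig, truth: Sequence[GeneTruth] | None = None
) -> tuple[dict[str, AlleleCountMatrix], list[GeneTruth]]:
    """Simulate every genotype pair of the config against one shared truth."""
    if truth is None:
        truth = generate_truth(cfg)
    panel: dict[str, AlleleCountMatrix] = {}
    for pair in cfg.genotype_pairs:
        acm, _ = simulate_experiment(cfg, truth=truth, pair=pair)
        alt = pair[1] if pair[0] == cfg.reference_pair[0] else pair[0]
        panel[alt] = acm
    return panel, list(truth)


# ---------------------------------------------------------------------------
# companion resources
# ---------------------------------------------------------------------------

TISSUE_NAMES = (
    "endosperm",
    "embryo",
    "leaf",
    "root",
    "tassel",
    "ear",
    "anther",
    "silk",
    "seedling",
    "internode",
)


def simulate_tissue_atlas(
    truth: Sequence[GeneTruth],
    cfg: SimConfig,
    noise_sd: float = 0.0,
    endosperm_replicates: int = 2,
) -> TissueAtlas:
    """Build a 10-tissue RPM atlas consistent with the genes' truth flags.

    Endosperm-preferred genes receive a 0.70-0.95 share of their expression
    in the endosperm replicate columns; multitissue genes 0.05-0.55. With
    ``noise_sd`` = 0 the atlas classifies perfectly against truth.
    """
    if not truth:
        raise ValueError("truth list is empty")
    seed = _require_seed(cfg)
    rng = np.random.default_rng([seed, 131])
    columns = [f"endosperm_{i + 1}" for i in range(endosperm_replicates)]
    for t_name in TISSUE_NAMES[1:]:
        columns.append(f"{t_name}_1")
    n_other = len(TISSUE_NAMES) - 1

    rows = np.zeros((len(truth), len(columns)))
    for i, t in enumerate(truth):
        level = float(np.mean(t.base_rpm))
        if level <= 0:
            continue
        share = rng.uniform(0.70, 0.95) if t.endosperm_preferred else rng.uniform(0.05, 0.55)
        endo = level * share * rng.dirichlet(np.full(endosperm_replicates, 5.0))
        other = level * (1 - share) * rng.dirichlet(np.full(n_other, 2.0))
        row = np.concatenate([endo, other])
        if noise_sd > 0:
            row = row * rng.lognormal(0.0, noise_sd, row.size)
        rows[i] = row
    values = pd.DataFrame(rows, index=[t.gene_id for t in truth], columns=columns)
    return TissueAtlas(values=values, endosperm_columns=tuple(columns[:endosperm_replicates]))


def simulate_syntelogs(
    truth: Sequence[GeneTruth],
    genotypes: Iterable[str],
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> SyntelogMap:
    """Single-copy syntelog pairs for each gene present in each genotype.

    ``dropout_rate`` thins pairs at random, emulating genes whose sequence
    is identical between assemblies (no informative variants) or whose
    syntelog was not called.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng([int(seed), 151])
    rows = []
    for t in truth:
        for g in sorted(genotypes):
            if g in t.present_in_genotypes and rng.uniform() >= dropout_rate:
                rows.append((t.gene_id, g, alt_gene_id(g, t.gene_id)))
    records = pd.DataFrame(rows, columns=list(SyntelogMap.COLUMNS))
    return SyntelogMap(records).single_copy()


def simulate_mdr1_degs(
    truth: Sequence[GeneTruth],
    seed: int = 0,
    detect_rate: float = 0.9,
    target_rate: float = 0.7,
    background_rate: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Synthetic mutant-vs-WT DE gene list plus its detection universe.

    Emulates a published DNA-glycosylase-mutant comparison in which
    endosperm-preferred maternally expressed genes are enriched among the
    differentially expressed genes. Returns ``(degs, universe)``; genes
    outside the universe were "not detected" in the emulated study.
    """
    rng = np.random.default_rng([int(seed), 173])
    universe: set[str] = set()
    degs: set[str] = set()
    for t in truth:
        if rng.uniform() > detect_rate or t.gene_class == "silent":
            continue
        universe.add(t.gene_id)
        is_target = t.endosperm_preferred and t.gene_class.startswith(
            ("MEG", "maternal")
        )
        rate = target_rate if is_target else background_rate
        if rng.uniform() < rate:
            degs.add(t.gene_id)
    return degs, universe


def write_truth(truth: Sequence[GeneTruth], path: str | Path) -> None:
    truth_frame(truth).to_csv(path, sep="\t")


def read_truth(path: str | Path) -> list[GeneTruth]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    out = []
    for gid, row in df.iterrows():
        out.append(
            GeneTruth(
                gene_id=str(gid),
                gene_class=row["gene_class"],
                maternal_fraction=tuple(
                    float(x) for x in str(row["maternal_fraction"]).split(",")
                ),
                base_rpm=tuple(float(x) for x in str(row["base_rpm"]).split(",")),
                present_in_genotypes=frozenset(
                    x for x in str(row["present_in_genotypes"]).split(",") if x
                ),
                biased_in_genotypes=frozenset(
                    x for x in str(row["biased_in_genotypes"]).split(",") if x
                ),
                endosperm_preferred=str(row["endosperm_preferred"]) == "True",
            )
        )
    return out
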