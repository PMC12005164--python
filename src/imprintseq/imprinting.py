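"""Reciprocal expression ratio (RER) and per-time-point imprinting calls.

RER for a gene allele is the replicate-mean RPM when inherited maternally
divided by the sum of the maternal and paternal replicate-mean RPM, so it
ranges from 0 (all paternal transcripts) to 1 (all maternal). Under the
2 maternal : 1 paternal genome dosage of triploid endosperm, a gene with
equal per-genome-copy expression sits at RER = 2/3; deviation from 2/3
indicates parent-of-origin bias.

Status calls distinguish statistically supported imprinting from lenient
expression-ratio bias:

* ``MEG`` — RER >= 0.9 *and* a significant greater-abs fold-change test;
* ``PEG`` — RER <= 0.3 and significance;
* ``maternal_bias`` / ``paternal_bias`` — RER > 0.8 / < 0.4 without the
  significance gate;
* ``biparental`` — everything else that is expressed;
* ``not_expressed`` — mean RPM below the expression floor (1 RPM).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import AlleleCountMatrix, ExpressionMatrix, rpm_normalize
from .allele_stats import TestSpec, imprint_tests

__all__ = [
    "STATUS_MEG",
    "STATUS_PEG",
    "STATUS_MATERNAL_BIAS",
    "STATUS_PATERNAL_BIAS",
    "STATUS_BIPARENTAL",
    "STATUS_NOT_EXPRESSED",
    "STATUSES",
    "ImprintThresholds",
    "compute_rer",
    "call_status",
    "imprint_profile",
    "run_imprinting",
]

STATUS_MEG = "MEG"
STATUS_PEG = "PEG"
STATUS_MATERNAL_BIAS = "maternal_bias"
STATUS_PATERNAL_BIAS = "paternal_bias"
STATUS_BIPARENTAL = "biparental"
STATUS_NOT_EXPRESSED = "not_expressed"
STATUSES = (
    STATUS_MEG,
    STATUS_PEG,
    STATUS_MATERNAL_BIAS,
    STATUS_PATERNAL_BIAS,
    STATUS_BIPARENTAL,
    STATUS_NOT_EXPRESSED,
)


@dataclass(frozen=True)
class ImprintThresholds:
    """RER cutoffs and significance settings for imprinting/bias calls."""

    meg_rer: float = 0.9
    peg_rer: float = 0.3
    maternal_bias_rer: float = 0.8
    paternal_bias_rer: float = 0.4
    alpha: float = 0.05
    lfc: float = 1.0

    def __post_init__(self) -> None:
        if not (
            self.peg_rer
            < self.paternal_bias_rer
            < 2 / 3
            < self.maternal_bias_rer
            < self.meg_rer
        ):
            raise ValueError(
                "thresholds must satisfy peg < paternal_bias < 2/3 < "
                "maternal_bias < meg"
            )

    def test_spec(self) -> TestSpec:
        return TestSpec(lfc_threshold=self.lfc, alternative="greater_abs", alpha=self.alpha)


def compute_rer(maternal_rpm, paternal_rpm):
    """RER = maternal / (maternal + paternal); NaN when both are zero.

    Scale-invariant: multiplying both inputs by the same positive constant
    leaves the ratio unchanged. Accepts scalars or arrays.
    """
    m = np.asarray(maternal_rpm, dtype=float)
    p = np.asarray(paternal_rpm, dtype=float)
    if (m < 0).any() or (p < 0).any():
        raise ValueError("RPM inputs to compute_rer must be nonnegative")
    total = m + p
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(maternal_rpm) and np.isscalar(paternal_rpm):
        return float(rer)
    return rer


def call_status(
    rer,
    padj,
    mean_rpm,
    thr: ImprintThresholds = ImprintThresholds(),
    expr_min: float = 1.0,
):
    """Classify one or many (RER, padj, mean RPM) combinations.

    The decision ladder is total and mutually exclusive: not expressed
    (mean RPM < ``expr_min``), MEG (RER >= 0.9 with significance), PEG
    (RER <= 0.3 with significance), maternal bias (RER > 0.8), paternal
    bias (RER < 0.4), else biparental. Imprinting thresholds are closed,
    bias thresholds strict.
    """
    rer_a = np.atleast_1d(np.asarray(rer, dtype=float))
    padj_a = np.atleast_1d(np.asarray(padj, dtype=float))
    rpm_a = np.atleast_1d(np.asarray(mean_rpm, dtype=float))
    expressed = rpm_a >= expr_min
    if (expressed & np.isnan(rer_a)).any():
        raise ValueError("RER undefined for an expressed gene")
    sig = padj_a < thr.alpha
    with np.errstate(invalid="ignore"):
        out = np.select(
            [
                ~expressed,
                (rer_a >= thr.meg_rer) & sig,
                (rer_a <= thr.peg_rer) & sig,
                rer_a > thr.maternal_bias_rer,
                rer_a < thr.paternal_bias_rer,
            ],
            [
                STATUS_NOT_EXPRESSED,
                STATUS_MEG,
                STATUS_PEG,
                STATUS_MATERNAL_BIAS,
                STATUS_PATERNAL_BIAS,
            ],
            default=STATUS_BIPARENTAL,
        )
    if np.isscalar(rer) or (isinstance(rer, float) and np.isnan(rer)):
        return str(out[0])
    return out


def imprint_profile(
    expr: ExpressionMatrix,
    de: pd.DataFrame,
    thr: ImprintThresholds = ImprintThresholds(),
    expr_min: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene-allele, per-time-point imprinting calls plus per-gene summary.

    ``de`` is the long result of :func:`imprint_tests` (indexed by
    gene_allele_id and dap); its time points must cover the expression
    matrix. The per-gene summary reports the imprint direction, the number
    of imprinted time points and the number of time points at which the RER
    meets the direction's parental-bias threshold.
    """
    de_daps = set(de.index.get_level_values("dap"))
    missing = [d for d in expr.dap_set if d not in de_daps]
    if missing:
        raise ValueError(f"DE results missing time point(s) {missing}")

    genome = expr.genomes
    frames = []
    for dap in expr.dap_set:
        maternal = pd.Series(np.nan, index=expr.gene_allele_ids)
        paternal = pd.Series(np.nan, index=expr.gene_allele_ids)
        for gnm in sorted(genome.unique()):
            rows = genome.index[genome == gnm]
            maternal.loc[rows] = expr.direction_mean(gnm, dap).loc[rows]
            pat_dir = expr.samples.loc[
                expr.samples["paternal_genotype"] == gnm, "maternal_genotype"
            ].unique()
            if len(pat_dir) != 1:
                raise ValueError(
                    f"genome {gnm!r} must appear as the paternal parent of "
                    "exactly one cross direction"
                )
            paternal.loc[rows] = expr.direction_mean(pat_dir[0], dap).loc[rows]
        padj = de.xs(dap, level="dap")["padj"].reindex(expr.gene_allele_ids).fillna(1.0)
        rer = compute_rer(maternal.to_numpy(), paternal.to_numpy())
        mean_rpm = (maternal.to_numpy() + paternal.to_numpy()) / 2.0
        status = call_status(rer, padj.to_numpy(), mean_rpm, thr, expr_min)
        frames.append(
            pd.DataFrame(
                {
                    "gene_allele_id": expr.gene_allele_ids,
                    "dap": dap,
                    "maternal_rpm": maternal.to_numpy(),
                    "paternal_rpm": paternal.to_numpy(),
                    "mean_rpm": mean_rpm,
                    "rer": rer,
                    "padj": padj.to_numpy(),
                    "status": status,
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True).set_index(["gene_allele_id", "dap"])
    summary = summarize_calls(calls, thr)
    return calls, summary


def summarize_calls(
    calls: pd.DataFrame, thr: ImprintThresholds = ImprintThresholds()
) -> pd.DataFrame:
    """Per-gene-allele imprint direction, imprinted-dap and bias-dap counts."""
    rows = []
    for gid, sub in calls.groupby(level="gene_allele_id", sort=False):
        status = sub["status"].to_numpy()
        rer = sub["rer"].to_numpy()
        n_meg = int((status == STATUS_MEG).sum())
        n_peg = int((status == STATUS_PEG).sum())
        if n_meg and n_peg:
            direction = "mixed"
        elif n_meg:
            direction = STATUS_MEG
        elif n_peg:
            direction = STATUS_PEG
        else:
            direction = "none"
        if direction == STATUS_MEG:
            n_bias = int(np.nansum(rer > thr.maternal_bias_rer))
        elif direction == STATUS_PEG:
            n_bias = int(np.nansum(rer < thr.paternal_bias_rer))
        else:
            n_bias = 0
        rows.append(
            {
                "gene_allele_id": gid,
                "direction": direction,
                "n_imprinted_daps": n_meg + n_peg,
                "n_bias_daps": n_bias,
                "statuses": ";".join(status),
            }
        )
    return pd.DataFrame(rows).set_index("gene_allele_id")


def run_imprinting(
    m: AlleleCountMatrix,
    thr: ImprintThresholds = ImprintThresholds(),
    expr_min: float = 1.0,
    daps: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> RPM -> greater-abs tests -> per-time-point imprinting calls."""
    expr = rpm_normalize(m)
    de = imprint_tests(m, spec=thr.test_spec(), daps=daps)
    return imprint_profile(expr, de, thr, expr_min)
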