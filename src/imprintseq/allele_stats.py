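"""Count-based tests for allele-specific and time-course differential expression.

The centerpiece is a negative-binomial Wald test of a *fold-change-threshold*
composite null: H0 |log2FC| <= theta vs H1 |log2FC| > theta ("greater-abs"
alternative). Requiring significantly more than a 2-fold maternal/paternal
difference (theta = 1) absorbs the 2:1 maternal:paternal genome dosage of
triploid endosperm, so that a dosage-proportional biparental gene sits at
the null boundary rather than in the alternative.

Dispersion is estimated per gene by the method of moments on size-factor
normalized counts and shrunk toward a fitted mean-dispersion trend; the
greater-abs p-value is the capped doubling of two one-sided Wald tests at
+/- theta. Multiple testing is controlled with Benjamini-Hochberg FDR.
No outlier replacement or independent filtering is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io_tables import AlleleCountMatrix

__all__ = [
    "TestSpec",
    "bh_adjust",
    "dispersion_mom",
    "fit_dispersion_trend",
    "shrink_dispersion",
    "test_fold_change",
    "imprint_tests",
    "de_vs_baseline",
]

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class TestSpec:
    """Parameters of a differential-expression call."""

    lfc_threshold: float = 1.0
    alternative: str = "greater_abs"  # or "two_sided"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.alternative not in ("greater_abs", "two_sided"):
            raise ValueError(f"unknown alternative {self.alternative!r}")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def dispersion_mom(*norm_count_groups: np.ndarray) -> np.ndarray:
    """Raw method-of-moments NB dispersion per gene, pooled across groups.

    Each argument is a genes x replicates array of size-factor normalized
    counts. For each group, ``alpha = (var - mean) / mean^2``; group
    estimates are pooled weighted by degrees of freedom. Genes with zero
    mean in every group get NaN (untestable); negative estimates (Poisson
    or underdispersed genes) are clipped to 0 downstream.
    """
    num = None
    den = None
    for grp in norm_count_groups:
        grp = np.asarray(grp, dtype=float)
        n = grp.shape[1]
        if n < 2:
            continue
        m = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        w = np.where(m > 0, float(n - 1), 0.0)
        a = np.where(m > 0, a, 0.0)
        num = a * w if num is None else num + a * w
        den = w if den is None else den + w
    if num is None:
        raise ValueError("at least one group needs >= 2 replicates")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def fit_dispersion_trend(mean: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Fit the mean-dispersion trend ``alpha(mu) = a0/mu + a1`` (a0, a1 >= 0).

    Returns the trend evaluated at every gene's mean. Falls back to the
    median positive raw dispersion when too few genes inform the fit.
    """
    mean = np.asarray(mean, dtype=float)
    alpha_raw = np.asarray(alpha_raw, dtype=float)
    ok = np.isfinite(alpha_raw) & (alpha_raw > 0) & (mean > 0)
    fallback = float(np.median(alpha_raw[ok])) if ok.sum() else 0.1
    if ok.sum() >= 10:
        X = np.column_stack([1.0 / mean[ok], np.ones(ok.sum())])
        coef, _ = optimize.nnls(X, alpha_raw[ok])
        a0, a1 = coef
        if a0 == 0 and a1 == 0:
            a1 = fallback
    else:
        a0, a1 = 0.0, fallback
    with np.errstate(divide="ignore"):
        trend = a0 / np.maximum(mean, 1e-12) + a1
    return np.maximum(trend, _DISPERSION_FLOOR)


def shrink_dispersion(
    alpha_raw: np.ndarray,
    alpha_trend: np.ndarray,
    residual_df: float,
    prior_df: float = 6.0,
) -> np.ndarray:
    """Shrink raw dispersions toward the trend, weighting by residual df."""
    a = np.clip(np.nan_to_num(np.asarray(alpha_raw, dtype=float), nan=0.0), 0.0, None)
    shrunk = (residual_df * a + prior_df * np.asarray(alpha_trend)) / (
        residual_df + prior_df
    )
    return np.maximum(shrunk, _DISPERSION_FLOOR)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def test_fold_change(
    counts_a: np.ndarray | pd.DataFrame,
    counts_b: np.ndarray | pd.DataFrame,
    size_factors_a: np.ndarray,
    size_factors_b: np.ndarray,
    spec: TestSpec = TestSpec(),
    index: pd.Index | None = None,
    dispersion: np.ndarray | None = None,
) -> pd.DataFrame:
    """NB Wald test of group A vs group B expression per gene.

    log2FC is estimated from size-factor-corrected group means (A over B);
    with ``alternative="greater_abs"`` the composite null |log2FC| <= theta
    is tested by doubling the smaller of two one-sided Wald p-values at
    +/- theta. Genes with zero counts in both groups are flagged untestable
    (p = 1 by convention) and excluded from the BH denominator. Significance
    (``significant`` column) additionally requires the point estimate to
    exceed the threshold.
    """
    A = np.atleast_2d(np.asarray(counts_a, dtype=float))
    B = np.atleast_2d(np.asarray(counts_b, dtype=float))
    sfa = np.asarray(size_factors_a, dtype=float)
    sfb = np.asarray(size_factors_b, dtype=float)
    if A.shape[1] == 0 or B.shape[1] == 0:
        raise ValueError("both contrast groups must contain samples")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("both contrast groups need >= 2 replicates")
    if (sfa <= 0).any() or (sfb <= 0).any():
        raise ValueError("size factors must be positive")

    ya = A / sfa  # normalized counts
    yb = B / sfb
    qa = ya.mean(axis=1)
    qb = yb.mean(axis=1)
    testable = (A.sum(axis=1) + B.sum(axis=1)) > 0

    if dispersion is None:
        mean_all = np.concatenate([ya, yb], axis=1).mean(axis=1)
        raw = dispersion_mom(ya, yb)
        trend = fit_dispersion_trend(mean_all, raw)
        residual_df = float(A.shape[1] + B.shape[1] - 2)
        disp = shrink_dispersion(raw, trend, residual_df)
    else:
        disp = np.maximum(np.asarray(dispersion, dtype=float), _DISPERSION_FLOOR)

    # half-a-read pseudo-level keeps the estimate finite for one-sided zeros
    eps_a = 0.5 / sfa.mean()
    eps_b = 0.5 / sfb.mean()
    qa0 = np.where(qa > 0, qa, eps_a)
    qb0 = np.where(qb > 0, qb, eps_b)
    lfc = np.log2(qa0 / qb0)

    var_qa = (qa0[:, None] / sfa[None, :] + disp[:, None] * qa0[:, None] ** 2).sum(
        axis=1
    ) / A.shape[1] ** 2
    var_qb = (qb0[:, None] / sfb[None, :] + disp[:, None] * qb0[:, None] ** 2).sum(
        axis=1
    ) / B.shape[1] ** 2
    se = np.sqrt(var_qa / qa0**2 + var_qb / qb0**2) / _LN2

    theta = spec.lfc_threshold
    if spec.alternative == "greater_abs":
        p_plus = stats.norm.sf((lfc - theta) / se)
        p_minus = stats.norm.cdf((lfc + theta) / se)
        pvalue = np.minimum(1.0, 2.0 * np.minimum(p_plus, p_minus))
        exceeds = np.abs(lfc) > theta
    else:
        pvalue = 2.0 * stats.norm.sf(np.abs(lfc - 0.0) / se)
        exceeds = np.ones_like(lfc, dtype=bool)
    pvalue = np.where(testable, pvalue, 1.0)

    padj = np.ones_like(pvalue)
    if testable.any():
        padj[testable] = bh_adjust(pvalue[testable])

    out = pd.DataFrame(
        {
            "mean_expression": np.concatenate([ya, yb], axis=1).mean(axis=1),
            "log2fc": lfc,
            "se": se,
            "dispersion": disp,
            "pvalue": pvalue,
            "padj": padj,
            "testable": testable,
            "significant": testable & exceeds & (padj < spec.alpha),
        }
    )
    if index is not None:
        out.index = index
    elif isinstance(counts_a, pd.DataFrame):
        out.index = counts_a.index
    return out


# ---------------------------------------------------------------------------
# imprinting contrast: maternal vs paternal inheritance
# ---------------------------------------------------------------------------

def imprint_tests(
    m: AlleleCountMatrix,
    spec: TestSpec = TestSpec(),
    daps: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Maternal-vs-paternal greater-abs test per gene allele per time point.

    For every gene-allele row, the "maternal" group pools the samples in
    which that allele's genome is the maternal parent, and the "paternal"
    group is the reciprocal direction — so both reciprocal directions enter
    every test. Tests are run, and BH-adjusted, separately per time point.
    Returns a long DataFrame indexed by (gene_allele_id, dap).
    """
    if daps is None:
        daps = m.dap_set
    totals = m.counts.sum(axis=0)
    size_factors = totals / 1e6  # total-count scaling, consistent with RPM
    genome = m.genomes
    frames = []
    for dap in daps:
        dap_samples = m.samples.index[m.samples["dap"] == dap]
        if len(dap_samples) == 0:
            raise ValueError(f"no samples at {dap} DAP")
        sub_meta = m.samples.loc[dap_samples]
        results = []
        for gnm in sorted(genome.unique()):
            rows = genome.index[genome == gnm]
            a_cols = sub_meta.index[sub_meta["maternal_genotype"] == gnm]
            b_cols = sub_meta.index[sub_meta["paternal_genotype"] == gnm]
            if len(a_cols) == 0 or len(b_cols) == 0:
                raise ValueError(
                    f"genome {gnm!r} lacks a reciprocal direction at {dap} DAP"
                )
            res = test_fold_change(
                m.counts.loc[rows, a_cols],
                m.counts.loc[rows, b_cols],
                size_factors[a_cols].to_numpy(),
                size_factors[b_cols].to_numpy(),
                spec=spec,
                index=rows,
            )
            results.append(res)
        res = pd.concat(results)
        # re-adjust across the full gene-allele set for this time point
        mask = res["testable"].to_numpy()
        padj = np.ones(len(res))
        if mask.any():
            padj[mask] = bh_adjust(res["pvalue"].to_numpy()[mask])
        res["padj"] = padj
        res["significant"] = (
            res["testable"]
            & (np.abs(res["log2fc"]) > spec.lfc_threshold)
            & (res["padj"] < spec.alpha)
        )
        res["dap"] = dap
        frames.append(res)
    out = pd.concat(frames)
    out.index.name = "gene_allele_id"
    return out.reset_index().set_index(["gene_allele_id", "dap"])


# ---------------------------------------------------------------------------
# time-course DE versus the earliest time point
# ---------------------------------------------------------------------------

@dataclass
class BaselineDE:
    """Per-time-point DE results against the baseline plus the overlap bins."""

    results: pd.DataFrame  # long, indexed by (gene_id, dap)
    up_sets: dict[int, set[str]]
    down_sets: dict[int, set[str]]
    overlap: pd.DataFrame  # rows: direction, columns: in exactly 1/2/3 comparisons


def de_vs_baseline(
    m: AlleleCountMatrix,
    baseline_dap: int = 11,
    spec: TestSpec = TestSpec(lfc_threshold=0.0, alternative="two_sided"),
    lfc_call: float = 1.0,
) -> BaselineDE:
    """Differential expression of each later time point versus the baseline.

    The matrix must be restricted to a single cross direction. A gene is
    called up (down) at a time point when padj < alpha and log2FC > lfc_call
    (< -lfc_call). The overlap summary counts genes that are DE in exactly
    1, 2, or all of the later-time-point comparisons, separately for up- and
    downregulation.
    """
    directions = m.directions
    if len(directions) != 1:
        raise ValueError(
            f"de_vs_baseline expects one cross direction, got {directions}"
        )
    if baseline_dap not in m.dap_set:
        raise ValueError(f"baseline time point {baseline_dap} DAP absent")
    later = [d for d in m.dap_set if d != baseline_dap]
    if not later:
        raise ValueError("need at least one non-baseline time point")
    totals = m.counts.sum(axis=0)
    size_factors = totals / 1e6
    base_cols = m.samples_where(dap=baseline_dap)

    frames, up_sets, down_sets = [], {}, {}
    for dap in later:
        cols = m.samples_where(dap=dap)
        res = test_fold_change(
            m.counts[cols],
            m.counts[base_cols],
            size_factors[cols].to_numpy(),
            size_factors[base_cols].to_numpy(),
            spec=spec,
        )
        called = res["testable"] & (res["padj"] < spec.alpha)
        up_sets[dap] = set(res.index[called & (res["log2fc"] > lfc_call)])
        down_sets[dap] = set(res.index[called & (res["log2fc"] < -lfc_call)])
        res["dap"] = dap
        frames.append(res)

    def bins(sets: Mapping[int, set[str]]) -> list[int]:
        tally = pd.Series(
            [g for s in sets.values() for g in s], dtype=object
        ).value_counts()
        return [int((tally == k).sum()) for k in range(1, len(later) + 1)]

    overlap = pd.DataFrame(
        [bins(up_sets), bins(down_sets)],
        index=["up", "down"],
        columns=[f"in_{k}_comparisons" for k in range(1, len(later) + 1)],
    )
    results = pd.concat(frames)
    results.index.name = "gene_id"
    results = results.reset_index().set_index(["gene_id", "dap"])
    return BaselineDE(results=results, up_sets=up_sets, down_sets=down_sets, overlap=overlap)
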