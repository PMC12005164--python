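import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintseq.allele_stats import (
    bh_adjust,
    de_vs_baseline,
    dispersion_mom,
    fit_dispersion_trend,
    shrink_dispersion,
)
from imprintseq.allele_stats import test_fold_change as nb_fold_change_test
from imprintseq.io_tables import AlleleCountMatrix


def bh_brute_force(p):
    """Independent step-up oracle: p_(i) * n / i, cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_hand_computed_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    def test_matches_brute_force(self, p):
        assert bh_adjust(p) == pytest.approx(bh_brute_force(p))


class TestDispersion:
    def test_poisson_limit_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(100.0, size=(300, 1000)).astype(float)
        a = dispersion_mom(y)
        assert abs(np.median(a)) < 0.01

    def test_moment_identity_recovers_alpha_two(self):
        rng = np.random.default_rng(1)
        mu, alpha = 50.0, 2.0
        n = 1.0 / alpha
        y = rng.negative_binomial(n, n / (n + mu), size=(200, 1000)).astype(float)
        a = dispersion_mom(y)
        assert np.median(a) == pytest.approx(2.0, rel=0.1)

    def test_constant_counts_floor(self):
        y = np.full((5, 4), 7.0)
        raw = dispersion_mom(y)
        assert (raw <= 0).all()
        shrunk = shrink_dispersion(raw, np.full(5, 1e-8), residual_df=3, prior_df=0.1)
        assert (shrunk >= 1e-8).all()

    def test_trend_tracks_common_dispersion(self):
        rng = np.random.default_rng(2)
        mu = rng.lognormal(np.log(200), 1, 500)
        alpha = 0.05
        n = 1.0 / alpha
        y = rng.negative_binomial(n, n / (n + mu[:, None]), size=(500, 6)).astype(float)
        raw = dispersion_mom(y)
        trend = fit_dispersion_trend(y.mean(axis=1), raw)
        assert np.median(trend) == pytest.approx(alpha, rel=0.5)


def _nb(rng, mu, alpha, size):
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu), size=size).astype(float)


class TestFoldChangeTest:
    def test_identical_groups_are_null(self):
        counts = np.tile([100.0, 40.0, 7.0], (3, 1)).T
        res = nb_fold_change_test(counts, counts, np.ones(3), np.ones(3))
        assert res["log2fc"].to_numpy() == pytest.approx([0.0, 0.0, 0.0])
        assert not res["significant"].any()

    def test_eightfold_change_is_detected(self):
        """Monte-Carlo power >= 0.9 for an 8x effect with tight dispersion."""
        rng = np.random.default_rng(3)
        n_genes = 300
        a = _nb(rng, 800.0, 0.01, (n_genes, 3))
        b = _nb(rng, 100.0, 0.01, (n_genes, 3))
        res = nb_fold_change_test(a, b, np.ones(3), np.ones(3))
        assert res["significant"].mean() >= 0.9
        assert np.median(res["log2fc"]) == pytest.approx(3.0, abs=0.2)

    def test_type_i_error_under_threshold_null(self):
        """True log2FC = 0 against a greater-abs threshold of 1: deep null."""
        rng = np.random.default_rng(4)
        a = _nb(rng, 500.0, 0.05, (5000, 3))
        b = _nb(rng, 500.0, 0.05, (5000, 3))
        res = nb_fold_change_test(a, b, np.ones(3), np.ones(3))
        frac = (res["pvalue"] < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 5000)

    def test_boundary_null_calibration(self):
        """At the composite-null boundary (true FC exactly 2x) the test stays
        at or below the nominal level."""
        rng = np.random.default_rng(5)
        a = _nb(rng, 1000.0, 0.02, (4000, 3))
        b = _nb(rng, 500.0, 0.02, (4000, 3))
        res = nb_fold_change_test(a, b, np.ones(3), np.ones(3))
        frac = (res["pvalue"] < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 4000)

    def test_power_monotone_in_effect_and_replicates(self):
        rng = np.random.default_rng(6)
        power = {}
        for fc in (2.5, 4.0, 8.0):
            a = _nb(rng, 200.0 * fc, 0.05, (600, 3))
            b = _nb(rng, 200.0, 0.05, (600, 3))
            res = nb_fold_change_test(a, b, np.ones(3), np.ones(3))
            power[fc] = res["significant"].mean()
        assert power[2.5] <= power[4.0] <= power[8.0]
        a6 = _nb(rng, 200.0 * 2.5, 0.05, (600, 6))
        b6 = _nb(rng, 200.0, 0.05, (600, 6))
        res6 = nb_fold_change_test(a6, b6, np.ones(6), np.ones(6))
        assert res6["significant"].mean() >= power[2.5]

    def test_label_swap_negates_lfc_keeps_pvalues(self):
        rng = np.random.default_rng(7)
        a = _nb(rng, 400.0, 0.05, (100, 3))
        b = _nb(rng, 150.0, 0.05, (100, 3))
        fwd = nb_fold_change_test(a, b, np.ones(3), np.ones(3))
        rev = nb_fold_change_test(b, a, np.ones(3), np.ones(3))
        assert rev["log2fc"].to_numpy() == pytest.approx(-fwd["log2fc"].to_numpy())
        assert rev["pvalue"].to_numpy() == pytest.approx(fwd["pvalue"].to_numpy())

    def test_all_zero_gene_untestable(self):
        a = np.array([[0.0, 0.0, 0.0], [5.0, 6.0, 7.0]])
        b = np.array([[0.0, 0.0, 0.0], [5.0, 6.0, 7.0]])
        res = nb_fold_change_test(a, b, np.ones(3), np.ones(3))
        assert not res["testable"][0]
        assert res["pvalue"][0] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            nb_fold_change_test(np.zeros((3, 0)), np.ones((3, 3)), np.ones(0), np.ones(3))

    def test_matches_reference_nb_framework_on_clear_calls(self):
        """Qualitative agreement with an established NB greater-abs test."""
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(8)
        n = 60
        mu_b = rng.lognormal(np.log(300), 0.6, n)
        fc = np.ones(n)
        fc[:15] = 10.0
        a = _nb(rng, np.outer(mu_b * fc, np.ones(3)), 0.02, (n, 3))
        b = _nb(rng, np.outer(mu_b, np.ones(3)), 0.02, (n, 3))
        mine = nb_fold_change_test(a, b, np.ones(3), np.ones(3))

        cdf = pd.DataFrame(
            np.vstack([a.T, b.T]).astype(int),
            index=[f"s{i}" for i in range(6)],
            columns=[f"g{i}" for i in range(n)],
        )
        meta = pd.DataFrame({"condition": ["A"] * 3 + ["B"] * 3}, index=cdf.index)
        dds = DeseqDataSet(counts=cdf, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        ds = DeseqStats(
            dds, contrast=["condition", "A", "B"], lfc_null=1.0,
            alt_hypothesis="greaterAbs", quiet=True,
        )
        ds.summary()
        ref = ds.results_df
        assert np.corrcoef(mine["log2fc"], ref["log2FoldChange"])[0, 1] > 0.95
        assert mine["significant"][:15].all() and (ref["padj"][:15] < 0.05).all()
        assert not mine["significant"][15:].any()
        assert not (ref["padj"][15:] < 0.05).any()


@pytest.fixture(scope="module")
def timecourse():
    rng = np.random.default_rng(9)
    daps = (11, 14, 17, 21)
    rows = []
    ids = []
    profiles = {}
    for i in range(25):  # flat
        ids.append(f"B73:flat{i}")
        profiles[ids[-1]] = [300.0] * 4
    for i in range(60):  # stable high-expression ballast keeps the
        ids.append(f"B73:ballast{i}")  # library composition steady
        profiles[ids[-1]] = [2000.0] * 4
    for i in range(10):  # induced 4x at every later time point
        ids.append(f"B73:up{i}")
        profiles[ids[-1]] = [200.0, 800.0, 800.0, 800.0]
    for i in range(10):  # induced only at 17 DAP
        ids.append(f"B73:late{i}")
        profiles[ids[-1]] = [200.0, 200.0, 800.0, 200.0]
    samples = []
    for dap in daps:
        for rep in (1, 2, 3):
            samples.append((f"s_{dap}_{rep}", dap, rep))
    counts = {}
    for sid, dap, rep in samples:
        di = daps.index(dap)
        mu = np.array([profiles[g][di] for g in ids])
        counts[sid] = _nb(rng, mu, 0.01, len(ids))
    meta = pd.DataFrame(
        {
            "maternal_genotype": "B73",
            "paternal_genotype": "W22",
            "dap": [d for _, d, _ in samples],
            "replicate": [r for _, _, r in samples],
        },
        index=pd.Index([s for s, _, _ in samples], name="sample_id"),
    )
    return AlleleCountMatrix(pd.DataFrame(counts, index=ids), meta)


class TestDeVsBaseline:

    def test_flat_genes_never_de(self, timecourse):
        de = de_vs_baseline(timecourse, baseline_dap=11)
        flat = {g for g in timecourse.gene_allele_ids if "flat" in g}
        for s in list(de.up_sets.values()) + list(de.down_sets.values()):
            assert not (s & flat)

    def test_consistent_induction_in_all_three_sets(self, timecourse):
        de = de_vs_baseline(timecourse, baseline_dap=11)
        up = {g for g in timecourse.gene_allele_ids if "up" in g}
        in_all = de.up_sets[14] & de.up_sets[17] & de.up_sets[21]
        assert up <= in_all
        assert de.overlap.loc["up", "in_3_comparisons"] >= len(up)

    def test_single_timepoint_induction_binned_once(self, timecourse):
        de = de_vs_baseline(timecourse, baseline_dap=11)
        late = {g for g in timecourse.gene_allele_ids if "late" in g}
        assert late <= de.up_sets[17]
        assert not (late & (de.up_sets[14] | de.up_sets[21]))
        assert de.overlap.loc["up", "in_1_comparisons"] >= len(late)

    def test_two_directions_rejected(self, tiny_acm):
        with pytest.raises(ValueError, match="direction"):
            de_vs_baseline(tiny_acm, baseline_dap=14)

    def test_missing_baseline_rejected(self, timecourse):
        with pytest.raises(ValueError):
            de_vs_baseline(timecourse, baseline_dap=12)
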