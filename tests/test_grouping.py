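import itertools

import numpy as np
import pandas as pd
import pytest

from imprintseq.grouping import (
    GROUP_1,
    GROUP_2,
    GROUP_3,
    GROUP_4,
    GROUP_FILTERED,
    GROUP_UNASSIGNED,
    GeneTemporalProfile,
    assign_group,
    bias_consistency_counts,
    group_summary,
)
from imprintseq.imprinting import (
    STATUS_BIPARENTAL,
    STATUS_MATERNAL_BIAS,
    STATUS_MEG,
    STATUS_NOT_EXPRESSED,
    STATUS_PATERNAL_BIAS,
    STATUS_PEG,
    STATUSES,
)

DAPS = (11, 14, 17, 21)


def group_oracle(status, rpm, expr_min=1.0, strong_min=5.0):
    """Brute-force re-derivation of the grouping rule ladder.

    Written flat and independently of the package implementation; returns
    None when the precondition (>= 1 imprinted time point) is violated.
    """
    imprinted_daps = [i for i, s in enumerate(status) if s in (STATUS_MEG, STATUS_PEG)]
    if not imprinted_daps:
        return None
    if sum(rpm) / len(rpm) < expr_min:
        return GROUP_FILTERED
    kinds = set(status[i] for i in imprinted_daps)
    if kinds == {STATUS_MEG}:
        d, bias = STATUS_MEG, STATUS_MATERNAL_BIAS
    elif kinds == {STATUS_PEG}:
        d, bias = STATUS_PEG, STATUS_PATERNAL_BIAS
    else:
        d = bias = None  # mixed-direction gene
    if d is not None:
        if all(r >= expr_min for r in rpm) and all(s == d for s in status):
            return GROUP_1
        if all(s == d for s, r in zip(status, rpm) if r >= expr_min):
            return GROUP_2
        if all(
            s == bias
            for i, s in enumerate(status)
            if i not in imprinted_daps
        ):
            return GROUP_3
        ok = [s == d or s == bias for s in status]
    else:
        ok = [
            s in (STATUS_MEG, STATUS_PEG, STATUS_MATERNAL_BIAS, STATUS_PATERNAL_BIAS)
            for s in status
        ]
    if all(r >= strong_min for r in rpm) and not all(ok):
        return GROUP_4
    return GROUP_UNASSIGNED


def make_profile(status, rpm, rer=None, gid="g"):
    return GeneTemporalProfile(
        gene_allele_id=gid, daps=DAPS, rpm=tuple(rpm), status=tuple(status), rer=rer
    )


class TestAssignGroupExamples:
    def test_group1_constitutive(self):
        p = make_profile([STATUS_MEG] * 4, (5, 8, 9, 4))
        assert assign_group(p).group == GROUP_1

    def test_group2_imprinted_whenever_expressed(self):
        p = make_profile(
            [STATUS_NOT_EXPRESSED, STATUS_MEG, STATUS_MEG, STATUS_NOT_EXPRESSED],
            (0.2, 6, 7, 0.3),
        )
        assert assign_group(p).group == GROUP_2

    def test_group3_biased_when_not_imprinted(self):
        p = make_profile(
            [STATUS_MEG, STATUS_MATERNAL_BIAS, STATUS_MATERNAL_BIAS, STATUS_MATERNAL_BIAS],
            (3, 4, 5, 2),
        )
        assert assign_group(p).group == GROUP_3

    def test_group4_needs_strong_expression(self):
        status = [STATUS_MEG, STATUS_MEG, STATUS_BIPARENTAL, STATUS_BIPARENTAL]
        assert assign_group(make_profile(status, (6, 9, 12, 8))).group == GROUP_4
        assert assign_group(make_profile(status, (2, 3, 4, 3))).group == GROUP_UNASSIGNED

    def test_low_mean_expression_filtered(self):
        p = make_profile([STATUS_MEG] + [STATUS_NOT_EXPRESSED] * 3, (2, 0.1, 0.2, 0.1))
        assert assign_group(p).group == GROUP_FILTERED

    def test_unimprinted_profile_is_an_error(self):
        p = make_profile([STATUS_BIPARENTAL] * 4, (5, 5, 5, 5))
        with pytest.raises(ValueError):
            assign_group(p)

    def test_opposite_bias_breaks_group3(self):
        p = make_profile(
            [STATUS_MEG, STATUS_PATERNAL_BIAS, STATUS_MATERNAL_BIAS, STATUS_MATERNAL_BIAS],
            (6, 6, 6, 6),
        )
        assert assign_group(p).group == GROUP_4

    def test_groups_one_and_four_disjoint_by_construction(self):
        # a gene imprinted at every dap can never satisfy the gain/loss rule
        p = make_profile([STATUS_PEG] * 4, (9, 9, 9, 9))
        assert assign_group(p).group == GROUP_1


class TestExhaustiveOracle:
    def test_sampled_rule_table_equivalence(self):
        """Dense random sample of the status x RPM-regime space (the full
        enumeration runs in the acceptance suite)."""
        rng = np.random.default_rng(12)
        rpm_levels = (0.5, 2.0, 10.0)
        for _ in range(3000):
            status = tuple(rng.choice(STATUSES, 4))
            rpm = tuple(rng.choice(rpm_levels, 4))
            expected = group_oracle(status, rpm)
            p = make_profile(status, rpm)
            if expected is None:
                with pytest.raises(ValueError):
                    assign_group(p)
            else:
                assert assign_group(p).group == expected


class TestBiasConsistency:
    def _calls(self, records):
        rows = []
        for gid, daps_status in records.items():
            for dap, (status, rer, rpm) in zip(DAPS, daps_status):
                rows.append(
                    {
                        "gene_allele_id": gid,
                        "dap": dap,
                        "status": status,
                        "rer": rer,
                        "mean_rpm": rpm,
                        "maternal_rpm": rpm,
                        "paternal_rpm": rpm,
                        "padj": 1.0,
                    }
                )
        return pd.DataFrame(rows).set_index(["gene_allele_id", "dap"])

    def test_single_dap_meg_with_one_bias_dap(self):
        calls = self._calls(
            {
                "B73:g1": [
                    (STATUS_MEG, 0.95, 10),
                    (STATUS_BIPARENTAL, 0.7, 10),
                    (STATUS_BIPARENTAL, 0.6, 10),
                    (STATUS_BIPARENTAL, 0.5, 10),
                ]
            }
        )
        tab = bias_consistency_counts(calls)
        row = tab[
            (tab["direction"] == STATUS_MEG)
            & (tab["imprint_recurrence"] == "single")
            & (tab["n_bias_daps"] == 1)
        ]
        assert row["count"].item() == 1
        assert row["fraction"].item() == 1.0

    def test_saturated_multi_dap_megs(self):
        records = {
            f"B73:g{i}": [(STATUS_MEG, 0.95, 10)] * 2
            + [(STATUS_MATERNAL_BIAS, 0.85, 10)] * 2
            for i in range(5)
        }
        tab = bias_consistency_counts(self._calls(records))
        row = tab[
            (tab["direction"] == STATUS_MEG)
            & (tab["imprint_recurrence"] == "multiple")
            & (tab["n_bias_daps"] == 4)
        ]
        assert row["count"].item() == 5
        assert row["fraction"].item() == 1.0

    def test_random_cohort_matches_recount(self):
        rng = np.random.default_rng(3)
        records = {}
        for i in range(200):
            profile = []
            for _ in DAPS:
                rer = rng.uniform()
                padj = rng.choice([0.01, 0.5])
                rpm = 10.0
                from imprintseq.imprinting import call_status

                profile.append((call_status(rer, padj, rpm), rer, rpm))
            records[f"B73:r{i}"] = profile
        calls = self._calls(records)
        tab = bias_consistency_counts(calls)
        # independent recount
        for direction, lo, hi in ((STATUS_MEG, 0.8, None), (STATUS_PEG, None, 0.4)):
            expect = {}
            for gid, profile in records.items():
                statuses = [s for s, _, _ in profile]
                n_imp_meg = statuses.count(STATUS_MEG)
                n_imp_peg = statuses.count(STATUS_PEG)
                if direction == STATUS_MEG and not (n_imp_meg and not n_imp_peg):
                    continue
                if direction == STATUS_PEG and not (n_imp_peg and not n_imp_meg):
                    continue
                if lo is not None:
                    nb = sum(r > lo for _, r, _ in profile)
                else:
                    nb = sum(r < hi for _, r, _ in profile)
                key = ("single" if (n_imp_meg + n_imp_peg) == 1 else "multiple", nb)
                expect[key] = expect.get(key, 0) + 1
            for (rec, nb), n in expect.items():
                row = tab[
                    (tab["direction"] == direction)
                    & (tab["imprint_recurrence"] == rec)
                    & (tab["n_bias_daps"] == nb)
                ]
                assert row["count"].item() == n


class TestGroupSummary:
    def test_pure_group1_cohort(self):
        assignments = pd.DataFrame(
            {
                "group": [GROUP_1] * 10,
                "direction": [STATUS_MEG] * 10,
                "rationale": [""] * 10,
            },
            index=[f"B73:g{i}" for i in range(10)],
        )
        out = group_summary(assignments)
        row = out[(out["direction"] == STATUS_MEG) & (out["group"] == GROUP_1)]
        assert row["count"].item() == 10
        assert row["percent"].item() == 100.0

    def test_empty_cohort_no_division_by_zero(self):
        assignments = pd.DataFrame(columns=["group", "direction", "rationale"])
        out = group_summary(assignments)
        assert (out["count"] == 0).all()
        assert (out["percent"] == 0.0).all()

    def test_mixed_cohort_matches_tally(self):
        rng = np.random.default_rng(5)
        groups = rng.choice([GROUP_1, GROUP_2, GROUP_3, GROUP_4, GROUP_UNASSIGNED, GROUP_FILTERED], 300)
        dirs = rng.choice([STATUS_MEG, STATUS_PEG], 300)
        assignments = pd.DataFrame(
            {"group": groups, "direction": dirs, "rationale": ""},
            index=[f"B73:m{i}" for i in range(300)],
        )
        out = group_summary(assignments)
        for d in (STATUS_MEG, STATUS_PEG):
            denom = ((dirs == d) & (groups != GROUP_FILTERED)).sum()
            for g in (GROUP_1, GROUP_2, GROUP_3, GROUP_4):
                n = ((groups == g) & (dirs == d)).sum()
                row = out[(out["direction"] == d) & (out["group"] == g)]
                assert row["count"].item() == n
                assert row["percent"].item() == pytest.approx(100.0 * n / denom)
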