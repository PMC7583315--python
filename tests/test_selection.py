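"""Exact binomial selection-pressure statistics and marker tallies."""

import math

import numpy as np
import pytest

from tatascan import (
    AnnotationRecord,
    CountsRegime,
    SelectionCounts,
    SimSpec,
    binom_tail,
    gen_counts_table,
    selection_report,
    tally,
)
from tatascan.fixtures import load_marker_counts
from tatascan.zscore import MarkerCall


def brute_force_tail(n, k, p0, tail):
    """Independent oracle: direct summation of the binomial pmf."""
    def pmf(i):
        if n <= 100:
            return math.comb(n, i) * p0 ** i * (1 - p0) ** (n - i)
        return math.exp(
            math.lgamma(n + 1) - math.lgamma(i + 1) - math.lgamma(n - i + 1)
            + i * math.log(p0) + (n - i) * math.log(1 - p0)
        )

    if tail == "ge":
        return sum(pmf(i) for i in range(k, n + 1))
    if tail == "le":
        return sum(pmf(i) for i in range(0, k + 1))
    # two-sided by the minimum-likelihood rule
    pk = pmf(k)
    return sum(pmf(i) for i in range(n + 1) if pmf(i) <= pk * (1 + 1e-12))


class TestBinomTail:
    def test_exhaustive_against_pmf_summation(self):
        for n in range(0, 31):
            for p0 in (0.2, 0.5, 0.7):
                for k in range(n + 1):
                    for tail in ("ge", "le", "two_sided"):
                        if n == 0 and tail == "two_sided":
                            continue
                        assert binom_tail(n, k, p0, tail) == pytest.approx(
                            brute_force_tail(n, k, p0, tail), abs=1e-12
                        ), (n, k, p0, tail)

    def test_spot_checks_large_n(self, rng):
        # log-space oracle for n where naive summation still works
        for _ in range(5):
            n = int(rng.integers(500, 2000))
            k = int(rng.integers(0, n + 1))
            assert binom_tail(n, k, 0.2, "ge") == pytest.approx(
                brute_force_tail(n, k, 0.2, "ge"), rel=1e-6, abs=1e-300
            )

    def test_documented_values(self):
        assert binom_tail(12, 6, 0.2, "ge") == pytest.approx(
            0.019405279232, abs=1e-10
        )
        assert binom_tail(1, 0, 0.5, "two_sided") == 1.0
        assert binom_tail(261, 176, 0.2, "ge") < 1e-6

    def test_two_sided_symmetry(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            k = int(rng.integers(0, n + 1))
            assert binom_tail(n, k, 0.5, "two_sided") == pytest.approx(
                binom_tail(n, n - k, 0.5, "two_sided")
            )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binom_tail(10, 11, 0.2)
        with pytest.raises(ValueError):
            binom_tail(10, 5, 0.0)
        with pytest.raises(ValueError):
            binom_tail(10, 5, 0.2, "weird")


def make_call(gene, delta, alpha=0.01):
    from tatascan.zscore import DECISION_DEFICIENCY, DECISION_EXCESS
    decision = DECISION_EXCESS if delta > 0 else DECISION_DEFICIENCY
    return MarkerCall(
        rsid=f"rs_{gene}_{delta:+.2f}", gene_id=gene,
        neglog_kd_wt=18.0, se_wt=0.2, neglog_kd_min=18.0 + delta, se_min=0.2,
        delta_ln_kd=delta, z=delta / (0.2 * math.sqrt(2)), alpha=alpha,
        decision=decision, rank_rho="D", expression_ratio=math.exp(delta),
        kd_wt_nM=1.0, kd_min_nM=1.0,
    )


class TestTally:
    ANNOTATIONS = [
        AnnotationRecord("G1", "over", "increase"),
        AnnotationRecord("G1", "under", "decrease"),
        AnnotationRecord("G2", "over", "decrease"),
        AnnotationRecord("G2", "under", "increase"),
    ]
    CLASSES = {"G1": "PAR1", "G2": "PAR1", "G3": "unique"}

    def test_counts_and_annotations(self):
        calls = [make_call("G1", +0.8), make_call("G1", -0.8),
                 make_call("G2", +0.8)]
        rows = tally(calls, self.ANNOTATIONS, self.CLASSES)
        assert len(rows) == 1
        row = rows[0]
        assert (row.n_res, row.n_gt, row.n_lt) == (3, 2, 1)
        assert (row.n_up, row.n_dn) == (1, 2)
        assert row.n_unclassified == 0

    def test_missing_annotation_counted_unclassified(self):
        rows = tally([make_call("G3", +0.6)], self.ANNOTATIONS, self.CLASSES)
        assert rows[0].n_unclassified == 1
        assert rows[0].n_up == rows[0].n_dn == 0

    def test_missing_class_raises(self):
        with pytest.raises(KeyError):
            tally([make_call("G9", 0.6)], self.ANNOTATIONS, self.CLASSES)

    def test_insignificant_calls_excluded(self):
        call = make_call("G1", 0.1, alpha=0.3)
        call.decision = "insignificant"
        assert tally([call], self.ANNOTATIONS, self.CLASSES) == []

    def test_conservation_property(self, rng):
        # n_gt + n_lt == n_res for random call sets
        for _ in range(20):
            deltas = rng.normal(0, 1, size=rng.integers(1, 40))
            calls = [make_call("G1", d if d != 0 else 0.1) for d in deltas]
            rows = tally(calls, self.ANNOTATIONS, self.CLASSES)
            row = rows[0]
            assert row.n_gt + row.n_lt == row.n_res == len(calls)
            assert row.n_up + row.n_dn + row.n_unclassified == row.n_res


class TestSelectionReport:
    def test_total_row_probabilities(self):
        rows = [r for r in load_marker_counts() if r.class_label == "TOTAL"]
        (row,) = selection_report(rows)
        assert row.p_norm_null < 1e-6
        assert row.p_norm_null_tail == "ge"
        assert row.p_equal_null > 0.06

    def test_unique_and_paralogous_rows(self):
        rows = {r.class_label: r for r in
                selection_report(load_marker_counts())}
        assert rows["unique"].p_norm_null == pytest.approx(0.0194053, abs=1e-6)
        assert rows["unique"].p_norm_null <= 0.025
        assert rows["paralogous"].p_norm_null <= 0.01

    def test_null_centred_row(self):
        (row,) = selection_report(
            [SelectionCounts("null", n_res=100, n_gt=20, n_lt=80)]
        )
        assert 0.4 < row.p_norm_null < 0.7

    def test_below_norm_row_reports_left_tail(self):
        (row,) = selection_report(
            [SelectionCounts("low", n_res=100, n_gt=5, n_lt=95)]
        )
        assert row.p_norm_null_tail == "le"
        assert row.p_norm_null == binom_tail(100, 5, 0.2, "le")

    def test_empty_row(self):
        (row,) = selection_report(
            [SelectionCounts("empty", n_res=0, n_gt=0, n_lt=0)]
        )
        assert row.p_norm_null == 1.0
        assert row.p_equal_null == 1.0


class TestRegimeRecovery:
    def test_genome_norm_regime_is_not_rejected(self):
        # tables drawn at the 1:4 improve:damage norm should usually
        # be compatible with the null
        ps = []
        for seed in range(200):
            spec = SimSpec(seed=seed, counts_regime=CountsRegime(
                n_res=1000, improve_fraction=0.2, up_fraction=0.5))
            (row,) = selection_report([gen_counts_table(spec)])
            ps.append(row.p_norm_null)
        assert np.median(ps) >= 0.05

    def test_two_to_one_regime_is_rejected(self):
        # the observed ~2:1 excess of affinity-increasing markers at
        # n_res = 261 must be detected essentially always
        rejected = 0
        for seed in range(200):
            spec = SimSpec(seed=seed, counts_regime=CountsRegime(
                n_res=261, improve_fraction=176 / 261, up_fraction=0.5))
            (row,) = selection_report([gen_counts_table(spec)])
            if row.p_norm_null_tail == "ge" and row.p_norm_null < 1e-6:
                rejected += 1
        assert rejected >= 190
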