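"""Diagnostic statistics, Youden optimisation, fold partitioning and
cross-validation mechanics."""

import numpy as np
import pytest

from strokemap.errors import CohortError, UndefinedStatisticError
from strokemap.stats import (
    CaseFeatures,
    ContingencyCounts,
    cross_validate,
    diagnostic_stats,
    evaluate_cases,
    independent_validate,
    optimize_cutoffs,
    partition_folds,
    youden,
)
from strokemap.territories import TERRITORIES


class TestDiagnosticStats:
    def test_standard_formulas_on_a_mixed_table(self):
        s = diagnostic_stats(ContingencyCounts(TP=11, FP=4, TN=28, FN=2))
        assert s.sensitivity == pytest.approx(11 / 13)
        assert s.specificity == pytest.approx(28 / 32)
        assert s.ppv == pytest.approx(11 / 15)
        assert s.npv == pytest.approx(28 / 30)
        assert s.plr == pytest.approx((11 / 13) / (1 - 28 / 32))
        assert s.nlr == pytest.approx((1 - 11 / 13) / (28 / 32))

    def test_perfect_classifier(self):
        s = diagnostic_stats(ContingencyCounts(TP=5, FP=0, TN=5, FN=0), plr_mode="zero")
        assert s.sensitivity == 1.0 and s.specificity == 1.0 and s.youden == 1.0

    def test_plr_at_perfect_specificity_modes(self):
        c = ContingencyCounts(TP=11, FP=0, TN=31, FN=3)
        assert np.isnan(diagnostic_stats(c).plr)
        assert diagnostic_stats(c, plr_mode="zero").plr == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            diagnostic_stats(ContingencyCounts(TP=0, FP=3, TN=5, FN=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            ContingencyCounts(TP=-1, FP=0, TN=1, FN=0)


class TestYouden:
    def test_perfect_counts_give_one(self):
        assert youden(ContingencyCounts(TP=10, FP=0, TN=10, FN=0)) == 1.0

    def test_published_group_counts(self):
        assert youden(ContingencyCounts(TP=11, FP=4, TN=28, FN=2)) == pytest.approx(
            11 / 13 + 28 / 32 - 1
        )

    def test_random_decisions_center_on_zero(self, rng):
        # decisions independent of truth: E[Y] = 0; simulate 10^4 tables
        n_pos, n_neg, p = 40, 60, 0.3
        tp = rng.binomial(n_pos, p, size=10_000)
        fp = rng.binomial(n_neg, p, size=10_000)
        ys = tp / n_pos + (n_neg - fp) / n_neg - 1
        assert abs(ys.mean()) < 0.01

    def test_youden_equals_sens_plus_spec_minus_one(self, rng):
        for _ in range(50):
            c = ContingencyCounts(*(int(v) for v in rng.integers(1, 50, size=4)))
            s = diagnostic_stats(c, plr_mode="zero")
            assert s.youden == pytest.approx(youden(c))


def _case(cid, cov, blk, labels):
    return CaseFeatures(
        case_id=cid,
        coverage={t: cov.get(t, 0.0) for t in TERRITORIES},
        bulk={t: blk.get(t, 0.0) for t in TERRITORIES},
        labels=frozenset(labels),
    )


def _separable_cases(n=20, cov_pos=0.4, cov_neg=0.05):
    """Alternating PICA/ACA cases whose true territory carries high
    coverage and the other territory only noise-level coverage."""
    cases = []
    for i in range(n):
        pica = i % 2 == 0
        cov = {"PICA": cov_pos if pica else cov_neg,
               "ACA": cov_neg if pica else cov_pos}
        cases.append(_case(f"c{i}", cov, {}, ["PICA" if pica else "ACA"]))
    return cases


class TestOptimizeCutoffs:
    def test_single_pair_grid_returned_verbatim(self):
        cases = _separable_cases()
        cfg = optimize_cutoffs(cases, grid=[0.25])
        assert all(cfg.area_cutoff[t] == 0.25 for t in TERRITORIES)
        assert all(cfg.bulk_cutoff[t] == 0.25 for t in TERRITORIES)

    def test_perfectly_separable_territory_gets_perfect_youden_pair(self):
        cases = _separable_cases(cov_pos=0.4, cov_neg=0.05)
        cfg, traces = optimize_cutoffs(cases, return_traces=True)
        t = traces["PICA"].rows
        best = t.loc[t.youden.idxmax()]
        assert best.youden == 1.0
        assert 0.05 <= cfg.area_cutoff["PICA"] < 0.4

    def test_ties_break_toward_largest_cutoffs(self):
        # any cut-off in [0.1, 0.3] separates: the largest area cut-off wins
        cases = _separable_cases(cov_pos=0.35, cov_neg=0.05)
        cfg = optimize_cutoffs(cases, grid=[0.10, 0.20, 0.30])
        assert cfg.area_cutoff["PICA"] == 0.30
        assert cfg.bulk_cutoff["PICA"] == 0.30

    def test_territory_without_positives_defaults_to_grid_maximum(self, caplog):
        cases = [_case(f"c{i}", {"PICA": 0.5}, {}, ["PICA"]) for i in range(4)]
        with caplog.at_level("WARNING"):
            cfg = optimize_cutoffs(cases)
        assert cfg.area_cutoff["ACA"] == 1.0
        assert "ACA" in caplog.text

    def test_empty_training_rejected(self):
        with pytest.raises(CohortError):
            optimize_cutoffs([])


class TestPartitionFolds:
    def test_91_cases_in_10_folds_gives_nine_nines_and_one_ten(self):
        ids = [f"p{i}" for i in range(91)]
        folds = partition_folds(ids, 10, seed=3)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [9] * 9 + [10]
        flat = [cid for f in folds for cid in f]
        assert sorted(flat) == sorted(ids)  # disjoint cover

    def test_partition_is_seeded(self):
        ids = [f"p{i}" for i in range(30)]
        assert partition_folds(ids, 5, seed=1) == partition_folds(ids, 5, seed=1)
        assert partition_folds(ids, 5, seed=1) != partition_folds(ids, 5, seed=2)

    def test_too_few_cases_rejected(self):
        with pytest.raises(CohortError):
            partition_folds(["a", "b"], 3, seed=0)


class TestCrossValidate:
    def test_fold_decision_totals_are_five_per_case(self):
        cases = _separable_cases(n=30)
        report = cross_validate(cases, n_folds=5, seed=4)
        for fold in report.folds:
            assert fold.counts.total == 5 * len(fold.case_ids)

    def test_every_case_in_exactly_one_validation_fold(self):
        cases = _separable_cases(n=30)
        report = cross_validate(cases, n_folds=5, seed=4)
        seen = [cid for f in report.folds for cid in f.case_ids]
        assert sorted(seen) == sorted(c.case_id for c in cases)

    def test_separable_cohort_reaches_perfect_fold_stats(self):
        cases = _separable_cases(n=40)
        report = cross_validate(cases, n_folds=4, seed=0)
        assert report.mean["sensitivity"] == 1.0
        assert report.mean["specificity"] == 1.0

    def test_summary_renders_mean_and_sd_rows(self):
        report = cross_validate(_separable_cases(n=20), n_folds=4, seed=0)
        text = report.summary()
        assert "Mean" in text and "SD" in text


class TestIndependentValidate:
    def test_twenty_cases_give_hundred_decisions(self):
        train = _separable_cases(n=20)
        cfg = optimize_cutoffs(train)
        holdout = [
            _case(f"h{i}", {"PICA": 0.5 if i % 2 else 0.0}, {},
                  ["PICA"] if i % 2 else ["ACA"])
            for i in range(20)
        ]
        stats, counts = independent_validate(holdout, cfg, [c.case_id for c in train])
        assert counts.total == 100

    def test_identifier_overlap_rejected(self):
        train = _separable_cases(n=10)
        cfg = optimize_cutoffs(train)
        with pytest.raises(CohortError):
            independent_validate(train[:2], cfg, [c.case_id for c in train])

    def test_empty_holdout_rejected(self):
        cfg = optimize_cutoffs(_separable_cases(n=10))
        with pytest.raises(CohortError):
            independent_validate([], cfg, ["x"])


class TestEvaluateCases:
    def test_bulk_criterion_can_fire_alone(self):
        from strokemap.classify import CutoffConfig

        case = _case("c0", {}, {"PCA": 0.95}, ["PCA"])
        cfg = CutoffConfig(
            area_cutoff={t: 1.0 for t in TERRITORIES},
            bulk_cutoff={t: (0.9 if t == "PCA" else 0.0) for t in TERRITORIES},
        )
        counts = evaluate_cases([case], cfg)
        assert counts.TP == 1 and counts.TN == 4
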