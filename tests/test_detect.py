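import numpy as np
import pytest
from hypothesis import given, strategies as st

from breakoff import (
    BreakoffClassifier,
    CohortConfig,
    MissingFlagMatrix,
    brute_force_threshold,
    classify_cohort,
    fit_respondent_classifier,
    naive_cutoff_classifier,
    simulate_cohort,
)
from conftest import survey_rows


class TestBruteForceOracle:
    @pytest.mark.parametrize(
        "row, expect_t, expect_acc",
        [
            ([1, 1, 1], 0, 1.0),
            ([0, 0, 0, 0], 4, 1.0),
            ([0, 0, 1, 0, 1, 1], 4, 5 / 6),  # tie at t in {2,4}; largest wins
            ([0, 1, 0, 0, 1, 1, 1, 1], 4, 7 / 8),
        ],
    )
    def test_hand_enumerated_examples(self, row, expect_t, expect_acc):
        t, acc = brute_force_threshold(row)
        assert t == expect_t
        assert acc == pytest.approx(expect_acc)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            brute_force_threshold([])


class TestRespondentClassifier:
    def test_all_answered_is_completer(self):
        c = fit_respondent_classifier([0, 0, 0, 0])
        assert not c.is_noncompleter
        assert c.quit_index == 4
        assert c.accuracy == 1.0

    def test_clean_breakoff_marks_first_missing_item(self):
        # answered the first two items, then nothing
        c = fit_respondent_classifier([0, 0, 1, 1, 1, 1, 1, 1])
        assert c.is_noncompleter
        assert c.quit_index == 2
        assert c.accuracy == 1.0

    def test_pre_quit_skip_lowers_accuracy(self):
        c = fit_respondent_classifier([0, 1, 0, 0, 1, 1, 1, 1])
        assert c.quit_index == 4
        assert c.accuracy == pytest.approx(7 / 8)
        assert c.is_noncompleter

    def test_all_missing_is_immediate_quit(self):
        c = fit_respondent_classifier([1, 1, 1])
        assert c.is_noncompleter and c.quit_index == 0 and c.accuracy == 1.0

    def test_boundary_lies_between_answers_and_terminal_run(self):
        c = fit_respondent_classifier([0, 0, 0, 1, 1, 1])
        assert 2 < c.boundary <= 3.5
        assert c.slope > 0

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            fit_respondent_classifier([])

    def test_single_item_rows(self):
        assert fit_respondent_classifier([0]).quit_index == 1
        assert fit_respondent_classifier([1]).quit_index == 0

    def test_oracle_equivalence_on_survey_rows(self):
        rng = np.random.default_rng(77)
        for row in survey_rows(rng, 400):
            c = fit_respondent_classifier(row)
            t_star, acc_star = brute_force_threshold(row)
            n = len(row)
            assert c.accuracy >= acc_star - 1 / n - 1e-12

    def test_matches_oracle_at_unique_maximizer(self):
        rng = np.random.default_rng(78)
        checked = 0
        for row in survey_rows(rng, 300):
            n = len(row)
            accs = [((np.arange(n) >= t).astype(int) == row).mean() for t in range(n + 1)]
            if sum(abs(a - max(accs)) < 1e-12 for a in accs) != 1:
                continue
            checked += 1
            t_star, _ = brute_force_threshold(row)
            assert fit_respondent_classifier(row).quit_index == t_star
        assert checked > 100

    @given(
        row=st.lists(st.integers(0, 1), min_size=1, max_size=15),
        extra=st.integers(1, 5),
    )
    def test_appending_answers_never_creates_noncompleter(self, row, extra):
        base = fit_respondent_classifier(row)
        if base.is_noncompleter:
            return
        longer = fit_respondent_classifier(list(row) + [0] * extra)
        assert not longer.is_noncompleter


class TestClassifyCohort:
    def test_all_zero_matrix_rate_zero(self):
        m = MissingFlagMatrix(
            tuple(f"r{i}" for i in range(5)), np.zeros((5, 8), dtype=np.int8)
        )
        cls, summary = classify_cohort(m)
        assert summary.n_noncompleters == 0
        assert summary.noncompletion_rate == 0.0
        assert np.isnan(summary.quit_location_mean)

    def test_recovery_without_skips_is_exact(self):
        cfg = CohortConfig(n_respondents=800, mar_skip_prob=0.0, seed=21)
        matrix, _, truth = simulate_cohort(cfg)
        cls, _ = classify_cohort(matrix)
        assert np.array_equal(cls["quit_index"].to_numpy(), truth.quit_index)
        assert np.array_equal(
            cls["is_noncompleter"].to_numpy(), truth.is_noncompleter
        )

    def test_quit_recovered_for_skip_free_respondents(self, small_cohort):
        _, matrix, _, truth = small_cohort
        cls, _ = classify_cohort(matrix)
        clean = ~truth.skips.any(axis=1)
        assert np.array_equal(
            cls.loc[clean, "quit_index"].to_numpy(), truth.quit_index[clean]
        )

    def test_deterministic(self, small_cohort):
        _, matrix, _, _ = small_cohort
        cls1, s1 = classify_cohort(matrix)
        cls2, s2 = classify_cohort(matrix)
        assert cls1.equals(cls2) and s1 == s2

    def test_summary_moments_consistent(self, small_cohort):
        _, matrix, _, _ = small_cohort
        cls, s = classify_cohort(matrix)
        nc = cls["is_noncompleter"]
        assert s.n_noncompleters == nc.sum()
        assert s.noncompletion_rate == pytest.approx(100 * nc.mean())
        assert s.accuracy_mean == pytest.approx(cls["accuracy"].mean())
        quits = cls.loc[nc, "quit_index"]
        assert s.quit_location_mean == pytest.approx(quits.mean())

    def test_chunking_does_not_change_results(self, small_cohort):
        _, matrix, _, _ = small_cohort
        a = BreakoffClassifier(chunk_size=37).fit(matrix)
        b = BreakoffClassifier(chunk_size=100000).fit(matrix)
        for col in ("quit_index", "is_noncompleter", "accuracy"):
            assert (a.classifications_[col] == b.classifications_[col]).all()
        for col in ("intercept", "slope", "boundary"):
            assert np.allclose(
                a.classifications_[col], b.classifications_[col],
                atol=1e-8, equal_nan=True,
            )

    def test_sklearn_interface(self, small_cohort):
        _, matrix, _, truth = small_cohort
        clf = BreakoffClassifier()
        assert clf.get_params()["ridge"] == 1e-3
        labels = clf.fit_predict(matrix)
        assert labels.dtype == bool
        # predict on a fresh matrix is row-wise independent of the fit data
        sub = matrix.flags[:10]
        assert np.array_equal(clf.predict(sub), labels[:10])


class TestNaiveCutoff:
    def test_no_missing_is_completer(self):
        assert not naive_cutoff_classifier(np.zeros((1, 10), dtype=np.int8))[0]

    def test_sub_threshold_terminal_run_misses(self):
        # 37/250 = 14.8% missing as a terminal run: under the 15% rule this
        # respondent is called a completer even though they plainly quit
        row = np.zeros((1, 250), dtype=np.int8)
        row[0, -37:] = 1
        assert not naive_cutoff_classifier(row, 0.15)[0]
        cls, _ = classify_cohort(row)
        assert cls["is_noncompleter"].iloc[0]

    def test_underestimates_rate_with_late_quitters(self):
        rng = np.random.default_rng(5)
        n = 250
        rows = []
        for _ in range(300):
            q = int(rng.integers(int(0.87 * n), n))  # all quit past 85% of items
            r = np.zeros(n, dtype=np.int8)
            r[q:] = 1
            rows.append(r)
        m = np.array(rows)
        naive_rate = naive_cutoff_classifier(m, 0.15).mean()
        _, summary = classify_cohort(m)
        assert naive_rate < summary.noncompletion_rate / 100
        assert summary.noncompletion_rate == 100.0

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            naive_cutoff_classifier(np.zeros((1, 4), dtype=np.int8), 1.5)
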