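import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from breakoff import (
    FormatError,
    MissingFlagMatrix,
    TemplateValidationError,
    classify_cohort,
    generate_template,
    load_responses,
    load_template,
    summarize_sections,
    write_responses,
)
from breakoff.survey import write_flags


def _write_template(path, rows):
    pd.DataFrame(rows, columns=["item_id", "index", "section", "sensitivity"]).to_csv(
        path, index=False
    )
    return path


class TestLoadTemplate:
    def test_minimal_valid_file(self, tmp_path):
        p = _write_template(
            tmp_path / "t.csv",
            [("a", 0, "s", 0), ("b", 1, "s", 1), ("c", 2, "s", 2)],
        )
        tpl = load_template(p)
        assert tpl.n_items == 3
        assert tpl.sections == ("s",)

    def test_index_gap_rejected(self, tmp_path):
        p = _write_template(tmp_path / "t.csv", [("a", 0, "s", 0), ("b", 2, "s", 0)])
        with pytest.raises(TemplateValidationError, match="0..1|gap"):
            load_template(p)

    def test_duplicate_index_rejected(self, tmp_path):
        p = _write_template(tmp_path / "t.csv", [("a", 0, "s", 0), ("b", 0, "s", 0)])
        with pytest.raises(TemplateValidationError):
            load_template(p)

    def test_bad_sensitivity_rejected(self, tmp_path):
        p = _write_template(tmp_path / "t.csv", [("a", 0, "s", 3)])
        with pytest.raises(TemplateValidationError, match="sensitivity"):
            load_template(p)

    def test_noncontiguous_section_rejected(self, tmp_path):
        p = _write_template(
            tmp_path / "t.csv",
            [("a", 0, "s1", 0), ("b", 1, "s2", 0), ("c", 2, "s1", 0)],
        )
        with pytest.raises(TemplateValidationError, match="contiguous"):
            load_template(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        pd.DataFrame({"item_id": ["a"], "index": [0]}).to_csv(p, index=False)
        with pytest.raises(FormatError, match="missing columns"):
            load_template(p)

    def test_full_instrument_round_trips_with_stated_moments(self, tmp_path):
        tpl = generate_template(250, 39, seed=7)
        tpl.save(tmp_path / "full.csv")
        loaded = load_template(tmp_path / "full.csv")
        assert loaded.n_items == 250
        assert len(loaded.sections) == 39
        sizes = [sl.stop - sl.start for sl in loaded.section_slices.values()]
        assert sum(sizes) == 250
        assert abs(np.mean(sizes) - 6.44) < 0.5


class TestLoadResponses:
    def test_filled_row_has_zero_flags(self, tmp_path, tiny_template):
        p = tmp_path / "r.csv"
        row = {"respondent_id": "r0", **{q: "5" for q in tiny_template.item_ids}}
        pd.DataFrame([row]).to_csv(p, index=False)
        m = load_responses(p, tiny_template)
        assert m.flags.sum() == 0

    def test_terminal_blank_run_flags_suffix(self, tmp_path):
        tpl = generate_template(6, 1, seed=0)
        p = tmp_path / "r.csv"
        vals = ["x", "x", "x", "", "", ""]
        pd.DataFrame([{"respondent_id": "r0", **dict(zip(tpl.item_ids, vals))}]).to_csv(
            p, index=False
        )
        m = load_responses(p, tpl)
        assert m.flags.tolist() == [[0, 0, 0, 1, 1, 1]]

    def test_sentinels_and_blanks_counted(self, tmp_path):
        tpl = generate_template(10, 2, seed=1)
        rng = np.random.default_rng(4)
        cells = np.array([["v"] * 10 for _ in range(5)], dtype=object)
        blanks = [(0, 1), (1, 5), (2, 0), (2, 9), (3, 3), (4, 4), (4, 8)]
        for k, (i, j) in enumerate(blanks):
            cells[i, j] = ["", "NA", "nan", "Na "][k % 4]
        df = pd.DataFrame(cells, columns=list(tpl.item_ids))
        df.insert(0, "respondent_id", [f"r{i}" for i in range(5)])
        p = tmp_path / "r.csv"
        df.to_csv(p, index=False)
        assert load_responses(p, tpl).grand_total == 7

    def test_column_mismatch_is_format_error(self, tmp_path, tiny_template):
        p = tmp_path / "r.csv"
        pd.DataFrame([{"respondent_id": "r0", "wrong": "1"}]).to_csv(p, index=False)
        with pytest.raises(FormatError):
            load_responses(p, tiny_template)

    @given(
        flags=st.lists(
            st.lists(st.integers(0, 1), min_size=10, max_size=10),
            min_size=1,
            max_size=8,
        )
    )
    def test_write_load_round_trip_is_bit_exact(self, flags, tmp_path_factory):
        tpl = generate_template(10, 3, seed=2)
        arr = np.array(flags, dtype=np.int8)
        m = MissingFlagMatrix(tuple(f"r{i}" for i in range(arr.shape[0])), arr)
        d = tmp_path_factory.mktemp("rt")
        write_responses(m, tpl, d / "r.csv")
        back = load_responses(d / "r.csv", tpl)
        assert np.array_equal(back.flags, m.flags)
        assert back.respondent_ids == m.respondent_ids

    def test_flag_matrix_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0 and 1"):
            MissingFlagMatrix(("r0",), np.array([[0, 2]]))


class TestSummarizeSections:
    def test_single_section_aggregates(self):
        tpl = generate_template(4, 1, seed=0)
        # force known sensitivities 0,0,1,1
        from breakoff import Item, SurveyTemplate

        tpl = SurveyTemplate(
            tuple(
                Item(i, f"q{i}", "s0", s) for i, s in enumerate([0, 0, 1, 1])
            )
        )
        m = MissingFlagMatrix(("r0",), np.zeros((1, 4), dtype=np.int8))
        cls, _ = classify_cohort(m)
        out = summarize_sections(tpl, m, cls)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_location"] == 1.5
        assert row["mean_sensitivity"] == 0.5
        assert row["question_count"] == 4
        assert row["quit_count"] == 0

    def test_no_noncompleters_means_zero_quit_counts(self, tiny_template):
        m = MissingFlagMatrix(
            tuple(f"r{i}" for i in range(3)), np.zeros((3, 10), dtype=np.int8)
        )
        cls, _ = classify_cohort(m)
        out = summarize_sections(tiny_template, m, cls)
        assert (out["quit_count"] == 0).all()

    def test_conservation_against_cohort_classification(self, small_cohort):
        cfg, matrix, _, truth = small_cohort
        cls, summary = classify_cohort(matrix)
        from breakoff import generate_template

        tpl = generate_template(cfg.n_items, cfg.n_sections, seed=cfg.seed)
        out = summarize_sections(tpl, matrix, cls)
        assert out["question_count"].sum() == tpl.n_items
        assert out["quit_count"].sum() == summary.n_noncompleters
        assert out["missing_count"].sum() == matrix.grand_total

    def test_flag_writer_round_trip(self, tmp_path, tiny_template):
        arr = np.array([[0, 1] * 5, [1, 0] * 5], dtype=np.int8)
        m = MissingFlagMatrix(("a", "b"), arr)
        p = write_flags(m, tiny_template, tmp_path / "f.csv")
        df = pd.read_csv(p)
        assert np.array_equal(df[list(tiny_template.item_ids)].to_numpy(), arr)
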