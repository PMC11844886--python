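"""Prompt templates, filename detection, file-header addenda, and the
correction instruction."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from execbench.prompts import (
    DATA_EXTENSIONS,
    build_correction_prompt,
    build_file_header_addendum,
    build_prompt_bundle,
    build_system_prompt,
    extract_filenames,
)

# The canonical system prompts for the default (R) code language, frozen as
# golden strings.
GOLDEN_SIMPLE = (
    "Provide R code for the following tasks. "
    "Provide the code in triple backticks (``` and ```). "
    "Provide the code as a single block at the end of your response. "
    "Do not provide code output."
)
GOLDEN_ACTAS = (
    "Act as an expert bioinformatician and R programmer. "
    "You also have a lot of knowledge about biology. "
    "Complete the following tasks, using your expertise and always provide "
    "relevant code. "
    "When providing the code in triple backticks (``` and ```). "
    "Provide the code as a single block at the end of your response."
)
GOLDEN_COT = (
    "Act as an expert bioinformatician and R programmer. "
    "You also have a lot of knowledge about biology. "
    "Answer questions using your expertise and always provide code. "
    "When providing code, provide the code in triple backticks (``` and ```). "
    "Provide the code as a single block at the end of your response. "
    "Let's work this out in a step by step way to be sure we have the right "
    "answer."
)


class TestSystemPrompts:
    @pytest.mark.parametrize(
        "strategy,golden",
        [("simple", GOLDEN_SIMPLE), ("actAs", GOLDEN_ACTAS), ("cot", GOLDEN_COT)],
    )
    def test_template_fidelity(self, strategy, golden):
        """Default-language templates byte-match the canonical strings."""
        assert build_system_prompt(strategy) == golden

    def test_language_substitution_at_sole_slot(self):
        text = build_system_prompt("simple", "Python")
        assert text.startswith("Provide Python code for the following tasks.")
        assert "R code" not in text
        actas = build_system_prompt("actAs", "Python")
        assert "Python programmer" in actas and " R " not in actas

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            build_system_prompt("few_shot")

    def test_empty_language_rejected(self):
        with pytest.raises(ValueError):
            build_system_prompt("simple", "")


class TestExtractFilenames:
    def test_single_file_in_sentence(self):
        text = (
            "I have a file called leukemiaExp.txt, which holds information "
            "about gene expression data."
        )
        assert extract_filenames(text) == ["leukemiaExp.txt"]

    def test_no_filename(self):
        assert extract_filenames("Cluster the samples using k-means.") == []

    def test_dedup_in_order_of_first_appearance(self):
        text = (
            "Read subjects.txt and leukemiaExp.txt, then merge with "
            "subjects.txt again."
        )
        assert extract_filenames(text) == ["subjects.txt", "leukemiaExp.txt"]

    def test_sentence_final_period_excluded(self):
        assert extract_filenames("Please read subjects.txt.") == ["subjects.txt"]

    def test_unrecognized_extension_ignored(self):
        assert extract_filenames("Do not touch archive.txt.gz or notes.docx") == []

    def test_quoted_names_and_case_insensitive_extension(self):
        assert extract_filenames('Open "Counts.TSV" now') == ["Counts.TSV"]

    @given(
        names=st.lists(
            st.builds(
                lambda stem, ext: f"{stem}.{ext}",
                st.from_regex(r"[A-Za-z][A-Za-z0-9_-]{0,8}", fullmatch=True),
                st.sampled_from(DATA_EXTENSIONS),
            ),
            min_size=0,
            max_size=5,
            unique=True,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent_over_own_output(self, names):
        """Re-rendering extracted names into text re-extracts exactly them."""
        text = "Files: " + " and ".join(names) + "."
        first = extract_filenames(text)
        assert first == [n for n in names if n in first]  # subset, in order
        again = extract_filenames("Use " + ", ".join(first) + ".")
        assert again == first


class TestFileHeaderAddendum:
    def test_canonical_two_line_wording(self, tmp_path):
        (tmp_path / "f.txt").write_text("a\tb\n1\t2\n3\t4\n")
        text = build_file_header_addendum(["f.txt"], tmp_path, 2)
        assert "Here are the first two lines of the file f.txt:" in text
        assert "a\tb\n1\t2" in text
        assert "3\t4" not in text

    def test_empty_file_list(self, tmp_path):
        assert build_file_header_addendum([], tmp_path, 2) == ""

    def test_missing_file_named_in_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="ghost.txt"):
            build_file_header_addendum(["ghost.txt"], tmp_path, 2)

    def test_nonpositive_n_lines_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_file_header_addendum([], tmp_path, 0)

    @pytest.mark.parametrize("n_lines", [1, 2, 3])
    def test_line_budget_per_file(self, tmp_path, n_lines):
        """An addendum built with n lines contains exactly n content lines
        per file, and says 'two' only when n = 2."""
        for name in ("a.txt", "b.txt"):
            (tmp_path / name).write_text("".join(f"row{i}\n" for i in range(5)))
        text = build_file_header_addendum(["a.txt", "b.txt"], tmp_path, n_lines)
        content = [ln for ln in text.splitlines() if ln.startswith("row")]
        assert len(content) == 2 * n_lines
        spelled = "two" if n_lines == 2 else str(n_lines)
        assert f"first {spelled} lines" in text

    def test_long_lines_clipped_with_marker(self, tmp_path):
        (tmp_path / "wide.txt").write_text("x" * 5000 + "\nsecond\n")
        text = build_file_header_addendum(["wide.txt"], tmp_path, 2, line_clip=100)
        clipped = text.splitlines()[1]
        assert clipped == "x" * 100 + "..."

    def test_spreadsheet_first_sheet_rendered_tab_separated(self, tmp_path):
        openpyxl = pytest.importorskip("openpyxl")
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.append(["gene", "s1", "s2"])
        ws.append(["g1", 1.5, 2.5])
        ws.append(["g2", 3.5, 4.5])
        wb.save(tmp_path / "data.xlsx")
        text = build_file_header_addendum(["data.xlsx"], tmp_path, 2)
        assert "gene\ts1\ts2" in text
        assert "g1\t1.5\t2.5" in text
        assert "g2" not in text


class TestCorrectionPrompt:
    def test_canonical_wording(self):
        text = build_correction_prompt("could not find function foo")
        assert text.startswith(
            "The previous code above returned the following errors and/or warnings:"
        )
        assert text.endswith("delimited in triple backticks.")
        assert "could not find function foo" in text

    def test_multiline_traceback_embedded_verbatim(self):
        tb = "Traceback (most recent call last):\n  File x\nNameError: nope"
        assert tb in build_correction_prompt(tb)

    def test_empty_error_rejected(self):
        with pytest.raises(ValueError):
            build_correction_prompt("")


class TestPromptBundle:
    def test_headers_appended_at_end_of_user_text(self, tmp_path):
        (tmp_path / "d.txt").write_text("h1\th2\n1\t2\n")
        bundle = build_prompt_bundle(
            "simple", "Read d.txt and summarize it.",
            data_dir=tmp_path, include_file_headers=True,
        )
        assert bundle.user_text.startswith("Read d.txt and summarize it.")
        assert bundle.user_text.endswith("h1\th2\n1\t2")
        assert bundle.injected_files == (("d.txt", 2),)

    def test_no_injection_when_disabled_or_no_files(self, tmp_path):
        bundle = build_prompt_bundle("simple", "No files here.", data_dir=tmp_path,
                                     include_file_headers=True)
        assert bundle.injected_files == ()
        assert bundle.user_text == "No files here."
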