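"""Prompt construction: strategy system prompts, filename detection,
file-header addenda, and the error-correction instruction.

The three system-prompt templates are fixed strings; the code language (R by
default) is substituted at its single occurrence so the same machinery drives
a Python-generating agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import re

DEFAULT_LANGUAGE = "R"

#: Extensions recognised as data files when scanning task text.
DATA_EXTENSIONS = (
    "txt", "tsv", "csv", "xls", "xlsx", "json",
    "bed", "gff", "gtf", "fasta", "fa", "fastq", "vcf",
)

_SYSTEM_TEMPLATES = {
    "simple": (
        "Provide {language} code for the following tasks. "
        "Provide the code in triple backticks (``` and ```). "
        "Provide the code as a single block at the end of your response. "
        "Do not provide code output."
    ),
    "actAs": (
        "Act as an expert bioinformatician and {language} programmer. "
        "You also have a lot of knowledge about biology. "
        "Complete the following tasks, using your expertise and always provide "
        "relevant code. "
        "When providing the code in triple backticks (``` and ```). "
        "Provide the code as a single block at the end of your response."
    ),
    "cot": (
        "Act as an expert bioinformatician and {language} programmer. "
        "You also have a lot of knowledge about biology. "
        "Answer questions using your expertise and always provide code. "
        "When providing code, provide the code in triple backticks (``` and ```). "
        "Provide the code as a single block at the end of your response. "
        "Let's work this out in a step by step way to be sure we have the right "
        "answer."
    ),
}

#: The three base prompting strategies.  The composed benchmark strategies
#: fileCont (simple + file headers) and selfCorrect (fileCont + error loop)
#: live in the benchmark layer.
STRATEGIES = tuple(_SYSTEM_TEMPLATES)

CORRECTION_HEADER = (
    "The previous code above returned the following errors and/or warnings:"
)
CORRECTION_FOOTER = (
    "Fix the error and return the fixed code in one block, "
    "delimited in triple backticks."
)

# Token: maximal run of word chars/dots/hyphens ending in a recognised data
# extension.  The trailing lookahead rejects longer runs ("file.txt.gz") while
# still matching before a sentence-final period.
_FILENAME_RE = re.compile(
    r"(?<![\w.-])[\w][\w.-]*\.(?:%s)(?!\.?[\w-])" % "|".join(DATA_EXTENSIONS),
    re.IGNORECASE,
)

#: Cap on characters injected per header line, to keep wide matrices from
#: blowing up the prompt (and the provider's context window).
DEFAULT_LINE_CLIP = 2000


@dataclass(frozen=True)
class PromptBundle:
    """A ready-to-send (system, user) prompt pair.

    ``injected_files`` records which data files contributed a header addendum
    to ``user_text`` and how many lines each one supplied.
    """

    system_text: str
    user_text: str
    injected_files: tuple[tuple[str, int], ...] = field(default=())


def build_system_prompt(strategy: str, target_code_language: str = DEFAULT_LANGUAGE) -> str:
    """Return the system prompt for one strategy.

    With the default code language the result is the canonical template
    verbatim; any other language name is substituted at the template's sole
    language slot.
    """
    if strategy not in _SYSTEM_TEMPLATES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    if not target_code_language:
        raise ValueError("target_code_language must be non-empty")
    return _SYSTEM_TEMPLATES[strategy].format(language=target_code_language)


def extract_filenames(task_text: str) -> list[str]:
    """Detect data-file names mentioned in task text.

    Returns them deduplicated, in order of first appearance.  A token counts
    as a filename when it ends in one of :data:`DATA_EXTENSIONS`
    (case-insensitive on the extension only).
    """
    seen: dict[str, None] = {}
    for match in _FILENAME_RE.finditer(task_text):
        seen.setdefault(match.group(0))
    return list(seen)


def _spell_count(n: int) -> str:
    # The canonical addendum says "two"; other counts are spelled as digits.
    return "two" if n == 2 else str(n)


def _read_head(path: Path, n_lines: int, line_clip: int) -> list[str]:
    """First ``n_lines`` raw lines of a file; spreadsheet workbooks are
    rendered from their first sheet as tab-separated rows."""
    if path.suffix.lower() in (".xls", ".xlsx"):
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        sheet = wb.worksheets[0]
        lines = []
        for i, row in enumerate(sheet.iter_rows(values_only=True)):
            if i >= n_lines:
                break
            lines.append("\t".join("" if v is None else str(v) for v in row))
        wb.close()
    else:
        lines = []
        with open(path, "r", errors="replace") as fh:
            for i, line in enumerate(fh):
                if i >= n_lines:
                    break
                lines.append(line.rstrip("\n"))
    return [
        line if len(line) <= line_clip else line[:line_clip] + "..." for line in lines
    ]


def build_file_header_addendum(
    filenames: list[str],
    data_dir: str | Path,
    n_lines: int = 2,
    line_clip: int = DEFAULT_LINE_CLIP,
) -> str:
    """Build the "Here are the first two lines of the file ..." addendum.

    One block per file: the introduction sentence followed by the file's first
    ``n_lines`` raw lines.  Empty string for an empty file list.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    data_dir = Path(data_dir)
    blocks = []
    for name in filenames:
        path = data_dir / name
        if not path.is_file():
            raise FileNotFoundError(f"data file {name!r} not found under {data_dir}")
        head = _read_head(path, n_lines, line_clip)
        blocks.append(
            f"Here are the first {_spell_count(n_lines)} lines of the file {name}:\n"
            + "\n".join(head)
        )
    return "\n".join(blocks)


def build_correction_prompt(error_text: str) -> str:
    """The fixed self-correction instruction wrapping an execution error.

    The error text is embedded byte-for-byte between the instruction header
    and the fix-request footer.
    """
    if not error_text:
        raise ValueError("error_text must be non-empty")
    return f"{CORRECTION_HEADER}\n{error_text}\n{CORRECTION_FOOTER}"


def build_prompt_bundle(
    strategy: str,
    task_text: str,
    data_dir: str | Path | None = None,
    include_file_headers: bool = False,
    n_lines: int = 2,
    target_code_language: str = DEFAULT_LANGUAGE,
) -> PromptBundle:
    """Compose the full (system, user) bundle for one task.

    When ``include_file_headers`` is set, filenames detected in the task text
    are read from ``data_dir`` and their headers appended at the end of the
    user prompt.
    """
    system_text = build_system_prompt(strategy, target_code_language)
    user_text = task_text
    injected: list[tuple[str, int]] = []
    if include_file_headers and data_dir is not None:
        names = extract_filenames(task_text)
        if names:
            addendum = build_file_header_addendum(names, data_dir, n_lines=n_lines)
            user_text = f"{task_text}\n{addendum}"
            injected = [(name, n_lines) for name in names]
    return PromptBundle(system_text, user_text, tuple(injected))
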