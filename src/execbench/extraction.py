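"""Cleaning model replies, pulling fenced code blocks, and resolving the
packages the generated code depends on."""

from __future__ import annotations

import importlib.util
import re
import subprocess
import sys
from dataclasses import dataclass, field

# Typographic characters that chat models (and copy-pasted notebooks) emit in
# place of the ASCII the interpreter needs.  Chosen as a harmless superset:
# quotes and backtick look-alikes map to their ASCII equivalent, zero-width
# characters vanish, non-breaking spaces become plain spaces.
_CHAR_MAP = {
    "“": '"', "”": '"', "„": '"', "«": '"', "»": '"',
    "‘": "'", "’": "'", "‚": "'",
    "´": "'", "ʼ": "'",
    "–": "-", "—": "-", "−": "-",
    " ": " ", " ": " ", " ": " ",
    "​": "", "‌": "", "‍": "", "﻿": "",
}
_CLEAN_TABLE = str.maketrans(_CHAR_MAP)

_FENCE_RE = re.compile(r"^\s*```(.*)$")


@dataclass(frozen=True)
class CodeBlock:
    """One fenced code block from a reply, fence lines excluded."""

    code: str
    fence_label: str = ""
    position: int = 0
    unterminated: bool = False


@dataclass(frozen=True)
class DependencySet:
    """Packages a code string depends on, with where each was detected."""

    names: frozenset[str]
    detected_from: tuple[tuple[str, int], ...] = field(default=())

    def __bool__(self) -> bool:
        return bool(self.names)


def clean_response(reply: str) -> str:
    """Normalize a raw model reply to plain ASCII punctuation.

    Curly quotes become straight quotes, zero-width and non-breaking spaces
    are stripped, CRLF/CR line endings become LF, and trailing whitespace is
    trimmed per line.  Idempotent; fenced content is otherwise untouched.
    """
    text = reply.replace("\r\n", "\n").replace("\r", "\n")
    text = text.translate(_CLEAN_TABLE)
    return "\n".join(line.rstrip() for line in text.split("\n"))


def find_code_blocks(reply: str) -> list[CodeBlock]:
    """All fenced blocks in order.  An unclosed fence extends to the end of
    the reply and is flagged ``unterminated``."""
    blocks: list[CodeBlock] = []
    label = ""
    buf: list[str] = []
    in_fence = False
    for line in reply.split("\n"):
        m = _FENCE_RE.match(line)
        if m and not in_fence:
            in_fence = True
            label = m.group(1).strip()
            buf = []
        elif m and in_fence:
            blocks.append(CodeBlock("\n".join(buf), label, len(blocks)))
            in_fence = False
        elif in_fence:
            buf.append(line)
    if in_fence:
        blocks.append(CodeBlock("\n".join(buf), label, len(blocks), unterminated=True))
    return blocks


def extract_code(reply: str, policy: str = "last_block") -> CodeBlock | None:
    """Extract runnable code from a cleaned reply.

    ``last_block`` (default) returns the final fenced block — the system
    prompts instruct the model to put a single block at the end of its
    response.  ``concatenate_all`` joins every block in order.  Returns
    ``None`` when the reply contains no fence.
    """
    if policy not in ("last_block", "concatenate_all"):
        raise ValueError(f"unknown extraction policy {policy!r}")
    blocks = find_code_blocks(reply)
    if not blocks:
        return None
    if policy == "last_block":
        return blocks[-1]
    return CodeBlock(
        "\n".join(b.code for b in blocks),
        blocks[0].fence_label,
        0,
        unterminated=any(b.unterminated for b in blocks),
    )


_R_PATTERNS = (
    ("library", re.compile(r"\b(?:library|require)\s*\(\s*[\"']?([A-Za-z][\w.]*)[\"']?\s*[,)]")),
    ("namespace", re.compile(r"\b([A-Za-z][\w.]*)\s*::")),
    ("install.packages", re.compile(r"\binstall\.packages\s*\(\s*[\"']([A-Za-z][\w.]*)[\"']")),
)

_PY_PATTERNS = (
    ("import", re.compile(r"^\s*import\s+([A-Za-z_][\w]*(?:\s*,\s*[A-Za-z_][\w]*)*)")),
    ("from-import", re.compile(r"^\s*from\s+([A-Za-z_][\w.]*)\s+import\b")),
)


def extract_dependencies(
    code: str, fence_label: str = "", default_language: str = "r"
) -> DependencySet:
    """Scan code line-wise for package dependencies.

    The pattern set is chosen by the fence label (``r``/``python``); an
    unlabeled fence is assumed to be in the configured generated-code
    language.  R patterns: ``library(NAME)``, ``require(NAME)``, ``NAME::``
    qualifiers, ``install.packages("NAME")``.  Python patterns: ``import
    NAME`` and ``from NAME import``.
    """
    language = (fence_label or default_language).lower()
    names: dict[str, None] = {}
    found: list[tuple[str, int]] = []
    if language in ("python", "py", "python3"):
        for lineno, line in enumerate(code.split("\n"), start=1):
            for kind, pat in _PY_PATTERNS:
                m = pat.match(line)
                if not m:
                    continue
                for part in m.group(1).split(","):
                    top = part.strip().split(".")[0]
                    if top:
                        names.setdefault(top)
                        found.append((kind, lineno))
    else:
        for lineno, line in enumerate(code.split("\n"), start=1):
            for kind, pat in _R_PATTERNS:
                for m in pat.finditer(line):
                    names.setdefault(m.group(1))
                    found.append((kind, lineno))
    return DependencySet(frozenset(names), tuple(found))


#: Packages the ``install_allowlisted`` policy may install, per language.
#: Common analysis packages only — installing arbitrary names suggested by a
#: language model is a supply-chain hazard.
INSTALL_ALLOWLIST = {
    "r": frozenset(
        "ggplot2 dplyr tidyr readr data.table pheatmap cluster stats utils "
        "matrixStats readxl".split()
    ),
    "python": frozenset(
        "numpy pandas scipy matplotlib seaborn sklearn scikit-learn "
        "statsmodels openpyxl".split()
    ),
}


def _is_available(name: str, language: str) -> bool:
    if language in ("python", "py", "python3"):
        try:
            return importlib.util.find_spec(name) is not None
        except (ImportError, ValueError):
            return False
    probe = subprocess.run(
        ["Rscript", "--vanilla", "-e",
         f"cat(requireNamespace('{name}', quietly=TRUE))"],
        capture_output=True, text=True,
    )
    return probe.stdout.strip().endswith("TRUE")


def _install(name: str, language: str) -> bool:
    if language in ("python", "py", "python3"):
        proc = subprocess.run(
            [sys.executable, "-m", "pip", "install", name], capture_output=True
        )
        return proc.returncode == 0
    proc = subprocess.run(
        ["Rscript", "--vanilla", "-e",
         f"install.packages('{name}', repos='https://cloud.r-project.org')"],
        capture_output=True,
    )
    return proc.returncode == 0 and _is_available(name, language)


def ensure_dependencies(
    deps: DependencySet, policy: str = "report_only", language: str = "r"
) -> list[tuple[str, str]]:
    """Check (and per policy install) each dependency in the executor
    environment.

    Policies: ``forbid`` checks availability but refuses installs (missing
    packages are ``blocked``); ``report_only`` reports present/missing;
    ``install_allowlisted``
    installs missing packages on :data:`INSTALL_ALLOWLIST`, marking others
    ``blocked``; ``install_all`` installs anything missing.  Installation
    failure is a recorded ``failed`` status, never an exception.
    """
    if policy not in ("forbid", "report_only", "install_allowlisted", "install_all"):
        raise ValueError(f"unknown dependency policy {policy!r}")
    lang_key = "python" if language in ("python", "py", "python3") else "r"
    report: list[tuple[str, str]] = []
    for name in sorted(deps.names):
        if _is_available(name, language):
            report.append((name, "present"))
            continue
        if policy == "forbid":
            report.append((name, "blocked"))
        elif policy == "report_only":
            report.append((name, "missing"))
        elif policy == "install_allowlisted" and name not in INSTALL_ALLOWLIST[lang_key]:
            report.append((name, "blocked"))
        else:
            report.append((name, "installed" if _install(name, language) else "failed"))
    return report
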