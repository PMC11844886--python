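"""Isolated execution of generated code.

Each run gets a brand-new interpreter process with the workspace root as its
working directory, so no state leaks between attempts or cycles and every
file the code writes is captured as an artifact.  OS-level containment is a
deployment concern, not implemented here; do not point this at untrusted code
outside a disposable environment.
"""

from __future__ import annotations

import html
import os
import shutil
import signal
import subprocess
import sys
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path


class BackendUnavailableError(Exception):
    """The requested interpreter is not on PATH (distinct from code failure)."""


@dataclass(frozen=True)
class ExecutionResult:
    """Outcome of running one code string."""

    status: str  # success | error | timeout
    error_text: str = ""
    warning_texts: tuple[str, ...] = ()
    stdout_text: str = ""
    artifacts: tuple[str, ...] = ()
    elapsed_seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in ("success", "error", "timeout"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "error" and not self.error_text:
            raise ValueError("error status requires non-empty error_text")

    @property
    def executable(self) -> bool:
        return self.status == "success"


@dataclass
class Workspace:
    """A working directory for one session; inputs are staged as copies."""

    root: Path
    staged_inputs: list[str] = field(default_factory=list)
    retain: bool = False

    @classmethod
    def create(cls, root: str | Path | None = None, retain: bool = False) -> "Workspace":
        if root is None:
            root = tempfile.mkdtemp(prefix="execbench-ws-")
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        return cls(root=root, retain=retain)

    def stage(self, *paths: str | Path) -> None:
        """Copy input files into the workspace root (copies, never links)."""
        for p in paths:
            p = Path(p)
            shutil.copyfile(p, self.root / p.name)
            self.staged_inputs.append(p.name)

    def cleanup(self) -> None:
        if not self.retain and self.root.exists():
            shutil.rmtree(self.root, ignore_errors=True)


@dataclass(frozen=True)
class ExecutorBackend:
    """Subprocess adapter for one code language."""

    name: str
    script_suffix: str
    argv_template: tuple[str, ...]  # "{script}" is replaced by the script path
    env_overrides: tuple[tuple[str, str], ...] = ()

    def argv(self, script: str) -> list[str]:
        return [a.replace("{script}", script) for a in self.argv_template]

    def available(self) -> bool:
        return shutil.which(self.argv_template[0]) is not None


#: Shipped adapters, keyed by code-fence label.  Both run headless: the
#: Python backend forces the Agg matplotlib backend, the R one relies on
#: Rscript's file-device defaults (no interactive display).
BACKENDS: dict[str, ExecutorBackend] = {}
for _b in (
    ExecutorBackend(
        "python",
        ".py",
        (sys.executable, "{script}"),
        (("MPLBACKEND", "Agg"),),
    ),
    ExecutorBackend("r", ".R", ("Rscript", "--vanilla", "{script}")),
):
    BACKENDS[_b.name] = _b
BACKENDS["py"] = BACKENDS["python"]
BACKENDS["R"] = BACKENDS["r"]


def get_backend(language: str) -> ExecutorBackend:
    try:
        backend = BACKENDS[language]
    except KeyError:
        raise BackendUnavailableError(f"no executor backend for {language!r}") from None
    if not backend.available():
        raise BackendUnavailableError(
            f"interpreter {backend.argv_template[0]!r} not found on PATH"
        )
    return backend


def _snapshot(root: Path) -> set[str]:
    return {
        str(p.relative_to(root))
        for p in root.rglob("*")
        if p.is_file()
    }


def _split_warnings(stderr_text: str) -> tuple[str, ...]:
    """Heuristic warning capture: stderr lines around 'warning' markers."""
    warnings = [
        line
        for line in stderr_text.splitlines()
        if "warning" in line.lower()
    ]
    return tuple(warnings)


DEFAULT_TIMEOUT = 300.0


def execute_code(
    code: str,
    workspace: Workspace,
    language_backend: str = "python",
    timeout_seconds: float = DEFAULT_TIMEOUT,
    strict_warnings: bool = False,
) -> ExecutionResult:
    """Run one code string in a fresh interpreter process.

    Nonzero exit (or an uncaught error) yields status ``error`` with the
    error stream captured; exceeding the timeout terminates the whole process
    tree and yields ``timeout``.  Files newly present under the workspace
    root afterwards are reported as artifacts.  Runs that only emit warnings
    count as successful unless ``strict_warnings`` is set.
    """
    if timeout_seconds <= 0:
        raise ValueError("timeout_seconds must be positive")
    backend = get_backend(language_backend)
    script = workspace.root / f".execbench-snippet{backend.script_suffix}"
    script.write_text(code if code.endswith("\n") else code + "\n")
    before = _snapshot(workspace.root)

    env = dict(os.environ)
    env.update(dict(backend.env_overrides))
    start = time.monotonic()
    proc = subprocess.Popen(
        backend.argv(str(script)),
        cwd=workspace.root,
        stdout=subprocess.PIPE,
        stderr=subprocess.PIPE,
        text=True,
        env=env,
        start_new_session=True,
    )
    try:
        stdout, stderr = proc.communicate(timeout=timeout_seconds)
        timed_out = False
    except subprocess.TimeoutExpired:
        try:
            os.killpg(proc.pid, signal.SIGKILL)
        except (ProcessLookupError, PermissionError):
            proc.kill()
        stdout, stderr = proc.communicate()
        timed_out = True
    elapsed = time.monotonic() - start

    script.unlink(missing_ok=True)
    artifacts = tuple(sorted(_snapshot(workspace.root) - before))
    warnings = _split_warnings(stderr or "")

    if timed_out:
        return ExecutionResult(
            status="timeout",
            error_text="execution exceeded the time limit",
            warning_texts=warnings,
            stdout_text=stdout or "",
            artifacts=artifacts,
            elapsed_seconds=elapsed,
        )
    failed = proc.returncode != 0 or (strict_warnings and bool(warnings))
    if failed:
        error_text = (stderr or "").strip() or f"process exited with status {proc.returncode}"
        return ExecutionResult(
            status="error",
            error_text=error_text,
            warning_texts=warnings,
            stdout_text=stdout or "",
            artifacts=artifacts,
            elapsed_seconds=elapsed,
        )
    return ExecutionResult(
        status="success",
        warning_texts=warnings,
        stdout_text=stdout or "",
        artifacts=artifacts,
        elapsed_seconds=elapsed,
    )


_REPORT_CSS = (
    "body{font-family:sans-serif;max-width:60em;margin:2em auto;}"
    "pre{background:#f6f6f6;padding:1em;overflow-x:auto;}"
    ".error{color:#a00;}.status-success{color:#070;}.status-error,"
    ".status-timeout{color:#a00;}"
)


def render_html_report(
    session: list[tuple[str, str, "object", ExecutionResult | None]],
    out_path: str | Path,
    title: str = "execbench session report",
) -> Path:
    """Write a standalone HTML report of a session.

    ``session`` is a list of (user prompt, full reply, extracted CodeBlock or
    None, ExecutionResult or None) rounds.
    """
    out_path = Path(out_path)
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{html.escape(title)}</title><style>{_REPORT_CSS}</style></head><body>",
        f"<h1>{html.escape(title)}</h1>",
    ]
    if not session:
        parts.append("<p><em>no rounds</em></p>")
    for i, (prompt, reply, block, result) in enumerate(session, start=1):
        parts.append(f"<h2>Round {i}</h2>")
        parts.append(f"<h3>Prompt</h3><pre>{html.escape(prompt)}</pre>")
        parts.append(f"<h3>Reply</h3><pre>{html.escape(reply)}</pre>")
        if block is not None:
            parts.append(
                f"<h3>Extracted code</h3><pre>{html.escape(block.code)}</pre>"
            )
        if result is not None:
            parts.append(
                f"<h3>Execution</h3><p class='status-{result.status}'>"
                f"status: {result.status} "
                f"({result.elapsed_seconds:.2f}s)</p>"
            )
            if result.error_text:
                parts.append(
                    f"<pre class='error'>{html.escape(result.error_text)}</pre>"
                )
            for w in result.warning_texts:
                parts.append(f"<p class='error'>warning: {html.escape(w)}</p>")
            if result.stdout_text:
                parts.append(f"<h4>Output</h4><pre>{html.escape(result.stdout_text)}</pre>")
            if result.artifacts:
                links = "".join(
                    f"<li><a href='{html.escape(a)}'>{html.escape(a)}</a></li>"
                    for a in result.artifacts
                )
                parts.append(f"<h4>Artifacts</h4><ul>{links}</ul>")
    parts.append("</body></html>")
    out_path.write_text("\n".join(parts))
    return out_path
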