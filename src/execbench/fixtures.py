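"""Synthetic data and scripted-reply generators.

Everything the benchmark needs — tabular data files shaped like real
gene-expression and sample-annotation tables, canned model replies, and a
20-task suite (4 tasks per complexity level) — is generated deterministically
from a seed, so the whole package is testable with no download and no API
key.  The expression fixtures are log-normal with a heavy-tailed per-gene
variance spread, which keeps "most variable genes" style tasks well-posed on
tiny matrices; they do not emulate any real leukemia biology.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .agents import AgentHandle, AgentSpec, MockAgent, MockScript
from .bench import TaskSpec

# ---------------------------------------------------------------------------
# tabular fixtures


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic expression table."""

    seed: int
    n_genes: int = 50
    n_samples: int = 6
    variable_fraction: float = 0.2  # genes given inflated variance
    base_sigma: float = 0.3
    high_sigma: float = 1.5


def gen_expression_table(spec: FixtureSpec, out_path: str | Path) -> Path:
    """Write a tab-separated expression matrix: gene names in the first
    column, one column per sample.

    A ``variable_fraction`` subset of genes draws its log-scale spread from
    ``high_sigma`` instead of ``base_sigma``, producing the heavy-tailed
    variance distribution that variability-filtering tasks need.  Same spec
    ⇒ byte-identical file.
    """
    rng = np.random.default_rng(spec.seed)
    n_var = int(round(spec.variable_fraction * spec.n_genes))
    sigmas = np.full(spec.n_genes, spec.base_sigma)
    if n_var:
        sigmas[rng.choice(spec.n_genes, size=n_var, replace=False)] = spec.high_sigma
    mus = rng.uniform(1.0, 4.0, size=spec.n_genes)
    values = rng.lognormal(
        mean=mus[:, None], sigma=sigmas[:, None], size=(spec.n_genes, spec.n_samples)
    )
    frame = pd.DataFrame(
        np.round(values, 3),
        index=[f"gene_{i + 1:04d}" for i in range(spec.n_genes)],
        columns=[f"sample_{j + 1}" for j in range(spec.n_samples)],
    )
    out_path = Path(out_path)
    frame.to_csv(out_path, sep="\t", index_label="gene")
    return out_path


_CATEGORY_LABELS = ("groupA", "groupB", "groupC")


def gen_subjects_table(
    seed: int,
    n_rows: int,
    columns: Sequence[tuple[str, str]] = (
        ("subject", "categorical"),
        ("age", "numeric"),
        ("treatment", "categorical"),
    ),
    out_path: str | Path = "subjects.txt",
) -> Path:
    """Write a tab-separated sample/subject annotation table.

    Column kinds: ``categorical`` draws from a fixed label set, ``numeric``
    draws rounded values from a normal distribution.  Deterministic under a
    fixed seed.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if not columns:
        raise ValueError("at least one column is required")
    rng = np.random.default_rng(seed)
    data = {}
    for name, kind in columns:
        if kind == "categorical":
            data[name] = rng.choice(_CATEGORY_LABELS, size=n_rows)
        elif kind == "numeric":
            data[name] = np.round(rng.normal(50, 12, size=n_rows), 1)
        else:
            raise ValueError(f"unknown column kind {kind!r}")
    out_path = Path(out_path)
    pd.DataFrame(data).to_csv(out_path, sep="\t", index=False)
    return out_path


# ---------------------------------------------------------------------------
# scripted model replies

_SNIPPETS = {
    "python": {
        "clean": "values = [1, 2, 3, 4]\nprint(sum(values) / len(values))",
        "fail": "print(undefined_variable_xyz)",
    },
    "r": {
        "clean": 'values <- c(1, 2, 3, 4)\ncat(mean(values), "\\n")',
        "fail": "print(undefined_variable_xyz)",
    },
}

_PROSE_ONLY = (
    "To carry out this analysis you would load the table, inspect its "
    "columns and then summarise it; I cannot say more without seeing the "
    "data layout."
)


def _wrap(code: str, language_tag: str, note: str) -> str:
    return f"{note}\n\n```{language_tag}\n{code}\n```"


def make_mock_script(kind: str, target_language_tag: str = "python") -> MockScript:
    """Canned reply scripts covering the model behaviours the loop must
    handle.

    ``clean``: one reply whose fenced code runs; ``fail_then_fix``: an
    undefined-name error then a working fix; ``always_fail``: every reply
    errors (cycling); ``no_code``: prose with no fence (cycling).
    """
    lang = "python" if target_language_tag in ("python", "py") else "r"
    snip = _SNIPPETS[lang]
    clean = _wrap(snip["clean"], target_language_tag, "Here is the code for the task.")
    fail = _wrap(snip["fail"], target_language_tag, "This code performs the analysis.")
    fixed = _wrap(
        snip["clean"], target_language_tag,
        "Apologies for the error; here is the corrected code.",
    )
    if kind == "clean":
        return MockScript((clean,))
    if kind == "fail_then_fix":
        return MockScript((fail, fixed))
    if kind == "always_fail":
        return MockScript((fail,), replay_policy="cycle")
    if kind == "no_code":
        return MockScript((_PROSE_ONLY,), replay_policy="cycle")
    raise ValueError(f"unknown mock kind {kind!r}")


def mock_agent_from_script(
    script: MockScript, model_name: str = "scripted-mock"
) -> MockAgent:
    """Wrap an in-memory MockScript in a ready agent handle."""
    spec = AgentSpec(
        backend_kind="mock", model_name=model_name, mock_script_ref="<in-memory>"
    )
    return MockAgent(spec, script)


#: Per-complexity per-attempt success probabilities of the synthetic model.
#: Monotone-decreasing with complexity: easy read-a-file tasks almost always
#: yield runnable code, five-component tasks rarely do on the first try.
DEFAULT_SUCCESS_PROBABILITIES = {1: 0.95, 2: 0.85, 3: 0.60, 4: 0.45, 5: 0.30}


def make_bernoulli_agent_factory(
    seed: int,
    p_by_complexity: dict[int, float] | None = None,
    max_attempts: int = 3,
    target_language_tag: str = "python",
) -> Callable[[TaskSpec, str, int], AgentHandle]:
    """Factory of per-trial mock agents with complexity-dependent success.

    Each trial gets a fresh script of ``max_attempts`` replies; every reply's
    code independently runs with probability ``p_by_complexity[complexity]``.
    The per-trial randomness is a pure function of (seed, task id, strategy,
    cycle), so re-running a benchmark reproduces it exactly.
    """
    probs = DEFAULT_SUCCESS_PROBABILITIES if p_by_complexity is None else p_by_complexity
    lang = "python" if target_language_tag in ("python", "py") else "r"
    snip = _SNIPPETS[lang]
    clean = _wrap(snip["clean"], target_language_tag, "Here is the code for the task.")
    fail = _wrap(snip["fail"], target_language_tag, "This code performs the analysis.")

    def factory(task: TaskSpec, strategy: str, cycle: int) -> AgentHandle:
        entropy = (
            seed,
            zlib.crc32(task.id.encode()),
            zlib.crc32(strategy.encode()),
            cycle,
        )
        rng = np.random.default_rng(np.random.SeedSequence(entropy))
        p = probs[task.complexity]
        replies = tuple(
            clean if rng.random() < p else fail for _ in range(max_attempts)
        )
        return mock_agent_from_script(replies_script(replies), model_name="bernoulli-mock")

    return factory


def replies_script(replies: tuple[str, ...]) -> MockScript:
    return MockScript(replies, replay_policy="strict")


# ---------------------------------------------------------------------------
# the shipped task suite

#: Generator (seed offsets keep the four files distinct but reproducible).
_SUITE_FILES: dict[str, Callable[[int, Path], Path]] = {
    "subjects.txt": lambda seed, path: gen_subjects_table(seed + 1, 24, out_path=path),
    "samplesheet.txt": lambda seed, path: gen_subjects_table(
        seed + 2,
        12,
        columns=(
            ("sample", "categorical"),
            ("condition", "categorical"),
            ("batch", "categorical"),
            ("rin_score", "numeric"),
        ),
        out_path=path,
    ),
    "leukemiaExp.txt": lambda seed, path: gen_expression_table(
        FixtureSpec(seed + 3, n_genes=60, n_samples=8), path
    ),
    "expressionB.txt": lambda seed, path: gen_expression_table(
        FixtureSpec(seed + 4, n_genes=40, n_samples=6), path
    ),
}


def packaged_task_suite() -> list[TaskSpec]:
    """The shipped 20-task synthetic suite: 4 tasks per complexity 1-5."""
    text = resources.files("execbench.data").joinpath("task_suite.json").read_text()
    docs = json.loads(text)
    return [
        TaskSpec(
            id=d["id"],
            prompt_text=d["prompt_text"],
            data_files=tuple(d["data_files"]),
            components=tuple(d["components"]),
        )
        for d in docs
    ]


def materialize_suite(data_dir: str | Path, seed: int = 0) -> list[TaskSpec]:
    """Write every data file the shipped suite references into ``data_dir``
    and return the task list."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    tasks = packaged_task_suite()
    needed = {name for t in tasks for name in t.data_files}
    for name in sorted(needed):
        _SUITE_FILES[name](seed, data_dir / name)
    return tasks
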