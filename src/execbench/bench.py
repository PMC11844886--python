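"""Task suite, complexity scoring, trial runner, and aggregation.

A task's complexity is the number of components it involves, out of five:
reading data from files, data wrangling, visualization, a machine-learning or
statistics application, and handling more than one dataset.  A task that only
reads a file has complexity 1; one with all five components has complexity 5.

Benchmark strategies stack as follows: ``simple``/``actAs``/``cot`` are the
three system-prompt regimes; ``fileCont`` is the simple prompt with the first
lines of each referenced data file appended; ``selfCorrect`` is ``fileCont``
plus the bounded error-feedback loop.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .agents import AgentHandle, TransportError
from .prompts import build_prompt_bundle, extract_filenames
from .sandbox import Workspace
from .selfcorrect import SelfCorrectConfig, run_attempt, self_correct

logger = logging.getLogger(__name__)

COMPONENTS = ("read_file", "wrangle", "visualize", "ml_stats", "multi_dataset")

BENCH_STRATEGIES = ("simple", "actAs", "cot", "fileCont", "selfCorrect")

#: Which base system prompt each benchmark strategy uses.
_SYSTEM_STRATEGY = {
    "simple": "simple",
    "actAs": "actAs",
    "cot": "cot",
    "fileCont": "simple",
    "selfCorrect": "simple",
}


def score_complexity(components: Iterable[str]) -> int:
    """Complexity of a task = number of distinct components it involves."""
    comps = set(components)
    if not comps:
        raise ValueError("a task must have at least one component")
    unknown = comps - set(COMPONENTS)
    if unknown:
        raise ValueError(f"unrecognized components: {sorted(unknown)}")
    return len(comps)


@dataclass(frozen=True)
class TaskSpec:
    """One benchmark task."""

    id: str
    prompt_text: str
    data_files: tuple[str, ...] = ()
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        score_complexity(self.components)  # validates
        for name in self.data_files:
            if name not in self.prompt_text:
                raise ValueError(
                    f"task {self.id}: data file {name!r} not mentioned in prompt"
                )

    @property
    def complexity(self) -> int:
        return score_complexity(self.components)


def load_task_suite(path: str | Path) -> list[TaskSpec]:
    """Load a task-suite config file (JSON: list of task documents)."""
    docs = json.loads(Path(path).read_text())
    return [
        TaskSpec(
            id=d["id"],
            prompt_text=d["prompt_text"],
            data_files=tuple(d.get("data_files", ())),
            components=tuple(d["components"]),
        )
        for d in docs
    ]


def save_task_suite(tasks: Sequence[TaskSpec], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            [
                {
                    "id": t.id,
                    "prompt_text": t.prompt_text,
                    "data_files": list(t.data_files),
                    "components": list(t.components),
                    "complexity": t.complexity,
                }
                for t in tasks
            ],
            indent=2,
        )
    )
    return path


@dataclass(frozen=True)
class TrialRecord:
    """One (task, strategy, model, cycle) evaluation."""

    task_id: str
    complexity: int
    strategy: str
    model_name: str
    cycle: int
    response_chars: int
    executable: bool
    attempts_used: int
    correctness: str = "unassessed"  # manual annotation only
    decoding: dict = field(default_factory=dict)
    infrastructure_error: bool = False

    def __post_init__(self) -> None:
        if self.strategy not in BENCH_STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy != "selfCorrect" and self.attempts_used not in (0, 1):
            raise ValueError("attempts_used must be 1 unless strategy is selfCorrect")
        if self.correctness not in ("unassessed", "correct", "incorrect"):
            raise ValueError(f"invalid correctness {self.correctness!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def load_trial_records(path: str | Path) -> list[TrialRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            records.append(TrialRecord(**json.loads(line)))
    return records


AgentFactory = Callable[[TaskSpec, str, int], AgentHandle]


def run_trials(
    tasks: Sequence[TaskSpec],
    strategies: Sequence[str],
    agent: AgentHandle | AgentFactory,
    cycles: int,
    config: SelfCorrectConfig = SelfCorrectConfig(),
    data_dir: str | Path | None = None,
    records_path: str | Path | None = None,
    workspace_root: str | Path | None = None,
) -> list[TrialRecord]:
    """Evaluate every task under every strategy for ``cycles`` repeats.

    ``agent`` is either a single handle or a factory called with
    (task, strategy, cycle) — the latter lets scripted mocks vary per trial.
    Each trial runs in a freshly staged workspace.  Records are appended to
    ``records_path`` (line-delimited JSON) as they complete, so a crash loses
    at most the in-flight trial.  An agent transport failure marks the trial
    ``infrastructure_error`` (excluded from aggregation) rather than
    non-executable.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    unknown = set(strategies) - set(BENCH_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")

    records: list[TrialRecord] = []
    records_fh = open(records_path, "a") if records_path is not None else None
    try:
        for strategy in strategies:
            for task in tasks:
                for cycle in range(1, cycles + 1):
                    handle = agent(task, strategy, cycle) if callable(agent) else agent
                    record = _run_one_trial(
                        task, strategy, cycle, handle, config, data_dir, workspace_root
                    )
                    records.append(record)
                    if records_fh is not None:
                        records_fh.write(record.to_json() + "\n")
                        records_fh.flush()
                    logger.info(
                        "trial %s/%s cycle %d: executable=%s attempts=%d",
                        task.id, strategy, cycle, record.executable,
                        record.attempts_used,
                    )
    finally:
        if records_fh is not None:
            records_fh.close()
    return records


def _run_one_trial(
    task: TaskSpec,
    strategy: str,
    cycle: int,
    agent: AgentHandle,
    config: SelfCorrectConfig,
    data_dir: str | Path | None,
    workspace_root: str | Path | None,
) -> TrialRecord:
    include_headers = strategy in ("fileCont", "selfCorrect") and config.include_file_headers
    bundle = build_prompt_bundle(
        _SYSTEM_STRATEGY[strategy],
        task.prompt_text,
        data_dir=data_dir,
        include_file_headers=include_headers,
    )
    ws_root = (
        Path(workspace_root) / f"{task.id}-{strategy}-{cycle}"
        if workspace_root is not None
        else None
    )
    workspace = Workspace.create(ws_root)
    try:
        if data_dir is not None:
            present = [
                Path(data_dir) / name
                for name in extract_filenames(task.prompt_text)
                if (Path(data_dir) / name).is_file()
            ]
            workspace.stage(*present)

        common = dict(
            task_id=task.id,
            complexity=task.complexity,
            strategy=strategy,
            model_name=agent.spec.model_name,
            cycle=cycle,
            decoding=agent.spec.decoding(),
        )
        if strategy == "selfCorrect":
            outcome = self_correct(agent, bundle, workspace, config)
            if outcome.aborted:
                return TrialRecord(
                    response_chars=0, executable=False,
                    attempts_used=outcome.attempts_used,
                    infrastructure_error=True, **common,
                )
            final_reply = outcome.per_attempt[-1].reply
            return TrialRecord(
                response_chars=len(final_reply),
                executable=outcome.success,
                attempts_used=outcome.attempts_used,
                **common,
            )
        # single-shot strategies: one send, one execution
        from .agents import make_transcript, send_chat

        transcript = make_transcript(bundle.system_text, bundle.user_text)
        try:
            reply = send_chat(agent, transcript)
        except TransportError:
            return TrialRecord(
                response_chars=0, executable=False, attempts_used=0,
                infrastructure_error=True, **common,
            )
        attempt = run_attempt(reply, workspace, config)
        return TrialRecord(
            response_chars=len(attempt.reply),
            executable=attempt.succeeded,
            attempts_used=1,
            **common,
        )
    finally:
        workspace.cleanup()


@dataclass(frozen=True)
class AggregateCell:
    """Executability summary for one (strategy, complexity) stratum."""

    strategy: str
    complexity: int
    n_trials: int
    n_executable: int
    mean_chars_executable: float | None
    mean_chars_non_executable: float | None

    @property
    def fraction_executable(self) -> float:
        return self.n_executable / self.n_trials


def aggregate_trials(records: Sequence[TrialRecord]) -> list[AggregateCell]:
    """One cell per (strategy, complexity) stratum present in the records.

    Trials flagged as infrastructure errors are excluded from the counts.
    """
    if not records:
        raise ValueError("no trial records to aggregate")
    usable = [r for r in records if not r.infrastructure_error]
    cells = []
    keys = sorted({(r.strategy, r.complexity) for r in usable})
    for strategy, complexity in keys:
        group = [r for r in usable if (r.strategy, r.complexity) == (strategy, complexity)]
        exe = [r.response_chars for r in group if r.executable]
        non = [r.response_chars for r in group if not r.executable]
        cells.append(
            AggregateCell(
                strategy=strategy,
                complexity=complexity,
                n_trials=len(group),
                n_executable=len(exe),
                mean_chars_executable=sum(exe) / len(exe) if exe else None,
                mean_chars_non_executable=sum(non) / len(non) if non else None,
            )
        )
    return cells


def aggregate_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Aggregate cells as a tidy DataFrame (one row per stratum)."""
    cells = aggregate_trials(records)
    return pd.DataFrame(
        {
            "strategy": [c.strategy for c in cells],
            "complexity": [c.complexity for c in cells],
            "n_trials": [c.n_trials for c in cells],
            "n_executable": [c.n_executable for c in cells],
            "fraction_executable": [c.fraction_executable for c in cells],
            "mean_chars_executable": [c.mean_chars_executable for c in cells],
            "mean_chars_non_executable": [c.mean_chars_non_executable for c in cells],
        }
    )
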