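"""The error-feedback loop: execute the model's code, feed any error back
with the fixed correction instruction, repeat up to ``max_attempts``.

Failed assistant replies stay in the transcript — the correction instruction
("The previous code above ...") only makes sense when the model can still see
its own prior code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .agents import AgentHandle, ChatTranscript, TransportError, make_transcript, send_chat
from .extraction import (
    CodeBlock,
    clean_response,
    ensure_dependencies,
    extract_code,
    extract_dependencies,
)
from .prompts import PromptBundle, build_correction_prompt
from .sandbox import DEFAULT_TIMEOUT, ExecutionResult, Workspace, execute_code

NO_CODE_ERROR = "no code block found in the response"


@dataclass(frozen=True)
class SelfCorrectConfig:
    max_attempts: int = 3
    include_file_headers: bool = True
    extraction_policy: str = "last_block"
    timeout_seconds: float = DEFAULT_TIMEOUT
    dependency_policy: str = "report_only"
    language_backend: str = "python"
    strict_warnings: bool = False

    def __post_init__(self) -> None:
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass(frozen=True)
class Attempt:
    """One round of the loop: reply, extracted code, dependency report,
    execution outcome (None when no code could be extracted)."""

    reply: str
    code_block: CodeBlock | None
    dependency_report: tuple[tuple[str, str], ...]
    result: ExecutionResult | None

    @property
    def error_text(self) -> str:
        if self.code_block is None:
            return NO_CODE_ERROR
        failed = [name for name, status in self.dependency_report if status == "failed"]
        if failed:
            return "failed to install dependencies: " + ", ".join(failed)
        assert self.result is not None
        return self.result.error_text

    @property
    def succeeded(self) -> bool:
        return (
            self.code_block is not None
            and self.result is not None
            and self.result.status == "success"
            and not any(s == "failed" for _, s in self.dependency_report)
        )


@dataclass
class SelfCorrectResult:
    success: bool
    attempts_used: int
    per_attempt: list[Attempt]
    final_code: str
    transcript: ChatTranscript
    aborted: bool = False  # transport failure mid-loop; partial result preserved


def run_attempt(
    reply: str, workspace: Workspace, config: SelfCorrectConfig
) -> Attempt:
    """Clean one reply, extract code, resolve dependencies, execute."""
    cleaned = clean_response(reply)
    block = extract_code(cleaned, policy=config.extraction_policy)
    if block is None:
        return Attempt(cleaned, None, (), None)
    deps = extract_dependencies(
        block.code, block.fence_label, default_language=config.language_backend
    )
    report = tuple(
        ensure_dependencies(deps, config.dependency_policy, config.language_backend)
    )
    if any(status == "failed" for _, status in report):
        return Attempt(cleaned, block, report, None)
    result = execute_code(
        block.code,
        workspace,
        language_backend=config.language_backend,
        timeout_seconds=config.timeout_seconds,
        strict_warnings=config.strict_warnings,
    )
    return Attempt(cleaned, block, report, result)


def self_correct(
    agent: AgentHandle,
    bundle: PromptBundle,
    workspace: Workspace,
    config: SelfCorrectConfig = SelfCorrectConfig(),
) -> SelfCorrectResult:
    """Run the prompt through the agent with up to ``max_attempts`` rounds of
    error feedback.

    Attempt 1 sends the bundle's system+user prompt.  After a failed attempt
    the next user turn is the correction instruction embedding that attempt's
    error text verbatim, appended to the same transcript.  The loop stops at
    the first success or when the attempt budget is spent; exactly
    ``attempts_used`` agent calls are made.
    """
    transcript = make_transcript(bundle.system_text, bundle.user_text)
    attempts: list[Attempt] = []
    final_code = ""
    for attempt_no in range(1, config.max_attempts + 1):
        try:
            reply = send_chat(agent, transcript)
        except TransportError:
            return SelfCorrectResult(
                success=False,
                attempts_used=len(attempts),
                per_attempt=attempts,
                final_code=final_code,
                transcript=transcript,
                aborted=True,
            )
        transcript.append("assistant", reply)
        attempt = run_attempt(reply, workspace, config)
        attempts.append(attempt)
        if attempt.code_block is not None:
            final_code = attempt.code_block.code
        if attempt.succeeded:
            break
        if attempt_no < config.max_attempts:
            transcript.append("user", build_correction_prompt(attempt.error_text))
    return SelfCorrectResult(
        success=attempts[-1].succeeded,
        attempts_used=len(attempts),
        per_attempt=attempts,
        final_code=final_code,
        transcript=transcript,
    )
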