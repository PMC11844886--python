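"""Chat-completion backends: a remote OpenAI-compatible client and a scripted mock.

Every other layer of the package talks to a model through :func:`setup_agent` /
:func:`send_chat`, so the benchmark can run identically against a live endpoint
or a fully deterministic scripted stand-in.
"""

from __future__ import annotations

import json
import logging
import os
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

logger = logging.getLogger(__name__)

ROLES = ("system", "user", "assistant")


class AgentError(Exception):
    """Base class for agent-layer failures."""


class CredentialError(AgentError):
    """The configured credential reference could not be resolved."""


class TransportError(AgentError):
    """The remote endpoint could not be reached after bounded retries."""


class MockExhaustedError(AgentError):
    """A strict mock script was asked for more replies than it holds."""


@dataclass(frozen=True)
class ChatMessage:
    """One role-tagged message in a conversation."""

    role: str
    content: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role in ("user", "assistant") and not self.content:
            raise ValueError(f"{self.role} message content must be non-empty")


@dataclass
class ChatTranscript:
    """Ordered messages of one session: at most one leading system message,
    then strictly alternating user/assistant turns."""

    messages: list[ChatMessage] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        body = list(self.messages)
        if body and body[0].role == "system":
            body = body[1:]
        for i, msg in enumerate(body):
            if msg.role == "system":
                raise ValueError("system message allowed only in leading position")
            expected = "user" if i % 2 == 0 else "assistant"
            if msg.role != expected:
                raise ValueError(
                    f"message {i} after the system prompt has role {msg.role!r}, "
                    f"expected {expected!r} (user/assistant must alternate)"
                )

    def append(self, role: str, content: str) -> None:
        self.messages.append(ChatMessage(role, content))
        self.validate()

    def ends_with_user(self) -> bool:
        return bool(self.messages) and self.messages[-1].role == "user"

    def to_jsonl(self) -> str:
        """Serialize as line-delimited JSON records, one message per line."""
        return "\n".join(
            json.dumps({"role": m.role, "content": m.content}) for m in self.messages
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_jsonl() + "\n")
        return path

    @classmethod
    def from_jsonl(cls, text: str) -> "ChatTranscript":
        msgs = [
            ChatMessage(**json.loads(line)) for line in text.splitlines() if line.strip()
        ]
        return cls(msgs)


@dataclass(frozen=True)
class MockScript:
    """A fixed ordered list of canned assistant replies.

    ``strict`` replay errors when the script is exhausted; ``cycle`` wraps
    around.  Replay is a pure function of the turn index, so identical
    (script, send sequence) pairs always produce identical replies.
    """

    replies: tuple[str, ...]
    replay_policy: str = "strict"

    def __post_init__(self) -> None:
        if not self.replies:
            raise ValueError("mock script needs at least one reply")
        if self.replay_policy not in ("strict", "cycle"):
            raise ValueError(f"unknown replay_policy {self.replay_policy!r}")

    def reply_at(self, turn_index: int) -> str:
        if turn_index < len(self.replies):
            return self.replies[turn_index]
        if self.replay_policy == "cycle":
            return self.replies[turn_index % len(self.replies)]
        raise MockExhaustedError(
            f"strict mock script of length {len(self.replies)} exhausted "
            f"at turn {turn_index}"
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {"replay_policy": self.replay_policy, "replies": list(self.replies)},
                indent=2,
            )
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MockScript":
        try:
            doc = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise AgentError(f"unreadable mock script {path}: {exc}") from exc
        return cls(tuple(doc["replies"]), doc.get("replay_policy", "strict"))


@dataclass(frozen=True)
class AgentSpec:
    """Configuration for one chat backend.

    ``credential_ref`` names an environment variable (or, prefixed with
    ``file:``, a file path) holding the API key — never the secret itself.
    """

    backend_kind: str
    model_name: str = "mock"
    endpoint_url: str = ""
    credential_ref: str = ""
    temperature: float | str = 0.0
    max_reply_tokens: int | None = None
    mock_script_ref: str = ""

    def __post_init__(self) -> None:
        if self.backend_kind not in ("remote", "mock"):
            raise ValueError(f"unknown backend_kind {self.backend_kind!r}")
        if self.backend_kind == "remote":
            if not self.endpoint_url or not self.credential_ref:
                raise ValueError("remote spec requires endpoint_url and credential_ref")
        elif not self.mock_script_ref:
            raise ValueError("mock spec requires mock_script_ref")
        if self.temperature != "provider-default" and float(self.temperature) < 0:
            raise ValueError("temperature must be >= 0 or 'provider-default'")

    def decoding(self) -> dict:
        """The effective decoding settings, recorded on every trial."""
        return {
            "temperature": self.temperature,
            "max_reply_tokens": self.max_reply_tokens,
        }


def _resolve_credential(ref: str) -> str:
    if ref.startswith("file:"):
        path = Path(ref[len("file:") :])
        try:
            return path.read_text().strip()
        except OSError as exc:
            raise CredentialError(f"credential file {path} unreadable") from exc
    value = os.environ.get(ref)
    if not value:
        raise CredentialError(f"environment variable {ref!r} is unset or empty")
    return value


class AgentHandle:
    """Opaque handle over one backend; created by :func:`setup_agent`."""

    def __init__(self, spec: AgentSpec):
        self.spec = spec

    def send(self, transcript: ChatTranscript) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


class MockAgent(AgentHandle):
    def __init__(self, spec: AgentSpec, script: MockScript):
        super().__init__(spec)
        self.script = script
        self.turns_consumed = 0

    def send(self, transcript: ChatTranscript) -> str:
        reply = self.script.reply_at(self.turns_consumed)
        self.turns_consumed += 1
        return reply


class RemoteAgent(AgentHandle):
    """Speaks the de-facto chat-completions JSON wire format over HTTPS.

    ``transport`` is injectable for testing: a callable taking
    (url, payload dict, headers dict) and returning the parsed response dict.
    """

    max_retries = 3

    def __init__(
        self,
        spec: AgentSpec,
        transport: Callable[[str, dict, dict], dict] | None = None,
        backoff_base: float = 1.0,
    ):
        super().__init__(spec)
        self._credential = _resolve_credential(spec.credential_ref)
        self._transport = transport or _http_transport
        self._backoff_base = backoff_base

    def send(self, transcript: ChatTranscript) -> str:
        payload: dict = {
            "model": self.spec.model_name,
            "messages": [
                {"role": m.role, "content": m.content} for m in transcript.messages
            ],
        }
        if self.spec.temperature != "provider-default":
            payload["temperature"] = float(self.spec.temperature)
        if self.spec.max_reply_tokens is not None:
            payload["max_tokens"] = self.spec.max_reply_tokens
        headers = {
            "Authorization": f"Bearer {self._credential}",
            "Content-Type": "application/json",
        }
        last_exc: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                doc = self._transport(self.spec.endpoint_url, payload, headers)
                return doc["choices"][0]["message"]["content"]
            except (urllib.error.URLError, OSError, KeyError, json.JSONDecodeError) as exc:
                last_exc = exc
                wait = self._backoff_base * 2**attempt
                logger.warning(
                    "remote send failed (attempt %d/%d): %s; backing off %.1fs",
                    attempt + 1,
                    self.max_retries,
                    exc,
                    wait,
                )
                if attempt + 1 < self.max_retries:
                    time.sleep(wait)
        raise TransportError(
            f"remote endpoint failed after {self.max_retries} attempts"
        ) from last_exc


def _http_transport(url: str, payload: dict, headers: dict) -> dict:
    req = urllib.request.Request(
        url, data=json.dumps(payload).encode(), headers=headers, method="POST"
    )
    with urllib.request.urlopen(req, timeout=120) as resp:
        return json.loads(resp.read().decode())


def setup_agent(
    spec: AgentSpec,
    transport: Callable[[str, dict, dict], dict] | None = None,
    backoff_base: float = 1.0,
) -> AgentHandle:
    """Create a ready-to-use agent handle from a validated spec.

    Mock agents make no network connection at any point; remote agents
    resolve their credential here (so a misconfiguration fails fast) but do
    not contact the endpoint until the first send.
    """
    if spec.backend_kind == "mock":
        return MockAgent(spec, MockScript.load(spec.mock_script_ref))
    return RemoteAgent(spec, transport=transport, backoff_base=backoff_base)


def send_chat(handle: AgentHandle, transcript: ChatTranscript) -> str:
    """Send a transcript ending in a user message; return the assistant reply.

    The caller appends the reply to the transcript — this function does not
    mutate it.
    """
    transcript.validate()
    if not transcript.ends_with_user():
        raise ValueError("transcript must end with a user message before sending")
    return handle.send(transcript)


def make_transcript(system_text: str, user_text: str) -> ChatTranscript:
    msgs: list[ChatMessage] = []
    if system_text:
        msgs.append(ChatMessage("system", system_text))
    msgs.append(ChatMessage("user", user_text))
    return ChatTranscript(msgs)
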