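"""Shared fixtures: a network tripwire (the suite must run fully offline)
and common workspaces/mock agents."""

from __future__ import annotations

import socket

import pytest

from execbench.fixtures import make_mock_script, mock_agent_from_script
from execbench.sandbox import Workspace

_real_connect = socket.socket.connect


class NetworkAccessAttempted(AssertionError):
    pass


def _tripwire_connect(self, address):
    if self.family in (socket.AF_INET, socket.AF_INET6):
        raise NetworkAccessAttempted(
            f"test attempted a network connection to {address!r}"
        )
    return _real_connect(self, address)


@pytest.fixture(autouse=True, scope="session")
def no_network():
    """Fail any test that tries to open an internet socket."""
    socket.socket.connect = _tripwire_connect
    yield
    socket.socket.connect = _real_connect


@pytest.fixture
def workspace(tmp_path):
    ws = Workspace.create(tmp_path / "ws")
    yield ws
    ws.cleanup()


@pytest.fixture
def clean_agent():
    return mock_agent_from_script(make_mock_script("clean"))
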