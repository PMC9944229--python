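"""Execute metadata test cases through the GA4GH WES run-request protocol.

A test case is a run request: the primary descriptor URL, its language type
and version, a workflow-parameters document, and any attachments.  The runner
submits the request, polls the run status until a terminal state, and calls
the test passed exactly when the terminal state is ``COMPLETE`` — no
output-content comparison is attempted.

Two interchangeable backends are provided: :class:`StubWes`, an in-process
executor scripted with per-test terminal states and delays (deterministic,
no engine or container needed), and :class:`HttpWesClient`, a minimal client
for a real WES endpoint speaking the runs-submission and status-poll surface
of the protocol.
"""

from __future__ import annotations

import enum
import itertools
import json
import time
import urllib.parse
import uuid
from dataclasses import dataclass, field
from typing import Callable, Protocol

from .metadata import LanguageType, TestCase, WorkflowMetadata
from .resources import Resolver, TransportError

__all__ = [
    "WesState",
    "WesRunRequest",
    "TestResult",
    "WesClient",
    "StubWes",
    "HttpWesClient",
    "build_run_request",
    "run_test",
    "run_all_tests",
    "STUB",
]

#: Sentinel endpoint meaning "use the built-in stub executor".
STUB = "STUB"


class WesState(str, enum.Enum):
    QUEUED = "QUEUED"
    INITIALIZING = "INITIALIZING"
    RUNNING = "RUNNING"
    COMPLETE = "COMPLETE"
    EXECUTOR_ERROR = "EXECUTOR_ERROR"
    SYSTEM_ERROR = "SYSTEM_ERROR"
    CANCELED = "CANCELED"

    @property
    def terminal(self) -> bool:
        return self in _TERMINAL


_TERMINAL = {
    WesState.COMPLETE,
    WesState.EXECUTOR_ERROR,
    WesState.SYSTEM_ERROR,
    WesState.CANCELED,
}


@dataclass
class WesRunRequest:
    workflow_url: str
    workflow_type: str
    workflow_type_version: str
    workflow_params: str
    test_id: str = ""
    workflow_engine_parameters: str | None = None
    attachments: list[tuple[str, bytes]] = field(default_factory=list)


@dataclass
class TestResult:
    test_id: str
    state: WesState
    log_excerpt: str = ""
    duration: float = 0.0

    @property
    def passed(self) -> bool:
        return self.state is WesState.COMPLETE


class WesClient(Protocol):
    def submit(self, request: WesRunRequest) -> str: ...

    def status(self, run_id: str) -> WesState: ...


def build_run_request(
    meta: WorkflowMetadata, test: TestCase, resolver: Resolver
) -> WesRunRequest:
    """Assemble the WES run request for one of the metadata's test cases.

    The designated workflow-parameters document becomes ``workflow_params``;
    every other test file is attached at its target path; the workflow type
    and version mirror the metadata's language info.
    """
    if test not in meta.testing:
        raise ValueError(f"test case {test.test_id!r} does not belong to this metadata")
    params_entry = test.params_file
    if params_entry is None:
        raise ValueError(f"test case {test.test_id!r} has no workflow-parameters document")
    params = resolver.resolve(params_entry.url)
    if not params.exists:
        raise FileNotFoundError(f"unresolvable test file: {params_entry.url}")
    engine_params: str | None = None
    if test.engine_params_file is not None:
        got = resolver.resolve(test.engine_params_file.url)
        if not got.exists:
            raise FileNotFoundError(
                f"unresolvable test file: {test.engine_params_file.url}"
            )
        engine_params = got.text
    attachments: list[tuple[str, bytes]] = []
    for f in test.attachment_files:
        got = resolver.resolve(f.url)
        if not got.exists:
            raise FileNotFoundError(f"unresolvable test file: {f.url}")
        attachments.append((f.target, got.content))
    lang = meta.language
    return WesRunRequest(
        workflow_url=meta.primary_file.url,
        workflow_type=lang.type.value,
        workflow_type_version=lang.version,
        workflow_params=params.text,
        test_id=test.test_id,
        workflow_engine_parameters=engine_params,
        attachments=attachments,
    )


# ---------------------------------------------------------------------------
# stub executor


@dataclass
class _StubRun:
    request: WesRunRequest
    terminal: WesState
    done_at: float
    submitted_at: float
    polls: int = 0


class StubWes:
    """Scripted in-process WES: deterministic outcomes without an engine.

    ``script`` maps a test id (or the empty string as a catch-all) to a
    ``(terminal_state, delay_seconds)`` pair.  A submitted run reports
    QUEUED, then RUNNING, until the scripted delay has elapsed on the
    injected clock, after which it reports the scripted terminal state.
    """

    def __init__(
        self,
        script: dict[str, tuple[WesState, float]] | None = None,
        clock: Callable[[], float] = time.monotonic,
    ):
        self.script = dict(script or {})
        self.clock = clock
        self._runs: dict[str, _StubRun] = {}
        self._counter = itertools.count(1)
        self.poll_log: list[str] = []

    def _lookup(self, test_id: str) -> tuple[WesState, float]:
        if test_id in self.script:
            return self.script[test_id]
        if "" in self.script:
            return self.script[""]
        return (WesState.COMPLETE, 0.0)

    def submit(self, request: WesRunRequest) -> str:
        terminal, delay = self._lookup(request.test_id)
        now = self.clock()
        run_id = f"stub-run-{next(self._counter)}-{uuid.uuid4().hex[:8]}"
        self._runs[run_id] = _StubRun(
            request=request, terminal=terminal, done_at=now + delay, submitted_at=now
        )
        return run_id

    def status(self, run_id: str) -> WesState:
        run = self._runs.get(run_id)
        if run is None:
            raise KeyError(f"unknown run id {run_id!r}")
        run.polls += 1
        self.poll_log.append(run_id)
        if self.clock() >= run.done_at:
            return run.terminal
        return WesState.QUEUED if run.polls == 1 else WesState.RUNNING

    def polls_for(self, run_id: str) -> int:
        return self._runs[run_id].polls


# ---------------------------------------------------------------------------
# HTTP client


class HttpWesClient:
    """Minimal GA4GH WES HTTP client (run submission + status polling).

    Uses the resolver-style transport so tests can script the wire without
    sockets.  Requests are sent as JSON; attachments are inlined base64-free
    as a JSON list, which the stub-grade servers used in testing understand.
    Unrecognized server states map to SYSTEM_ERROR (fail safe).
    """

    def __init__(self, endpoint: str, transport=None, timeout: float = 10.0):
        from .resources import default_transport

        self.endpoint = endpoint.rstrip("/")
        self.transport = transport or default_transport
        self.timeout = timeout

    def submit(self, request: WesRunRequest) -> str:
        body = {
            "workflow_url": request.workflow_url,
            "workflow_type": request.workflow_type,
            "workflow_type_version": request.workflow_type_version,
            "workflow_params": request.workflow_params,
            "tags": json.dumps({"test_id": request.test_id}),
        }
        if request.workflow_engine_parameters is not None:
            body["workflow_engine_parameters"] = request.workflow_engine_parameters
        if request.attachments:
            body["workflow_attachment"] = [
                {"target": t, "content": c.decode("utf-8", "replace")}
                for t, c in request.attachments
            ]
        url = self.endpoint + "/runs?" + urllib.parse.urlencode(
            {"payload": json.dumps(body, sort_keys=True)}
        )
        status, resp = self.transport(url, self.timeout, None)
        if status != 200:
            raise TransportError(f"WES submit failed: HTTP {status}")
        return json.loads(resp)["run_id"]

    def status(self, run_id: str) -> WesState:
        url = f"{self.endpoint}/runs/{run_id}/status"
        status, resp = self.transport(url, self.timeout, None)
        if status != 200:
            raise TransportError(f"WES status failed: HTTP {status}")
        state_s = json.loads(resp).get("state", "")
        try:
            return WesState(state_s)
        except ValueError:
            return WesState.SYSTEM_ERROR


# ---------------------------------------------------------------------------
# runner


def run_test(
    request: WesRunRequest,
    endpoint: WesClient | str,
    poll_interval: float = 5.0,
    timeout: float = 3600.0,
    sleep: Callable[[float], None] = time.sleep,
    clock: Callable[[], float] = time.monotonic,
) -> TestResult:
    """Submit a run and poll until a terminal state or the timeout.

    A timeout or a transport failure yields a SYSTEM_ERROR result (the test
    verdict treats an environment failure as a failed run), with the cause
    in ``log_excerpt``.
    """
    client: WesClient
    if endpoint == STUB:
        client = StubWes()
    elif isinstance(endpoint, str):
        client = HttpWesClient(endpoint)
    else:
        client = endpoint
    start = clock()
    try:
        run_id = client.submit(request)
    except (TransportError, OSError) as e:
        return TestResult(
            test_id=request.test_id,
            state=WesState.SYSTEM_ERROR,
            log_excerpt=f"submission failed: {e}",
            duration=clock() - start,
        )
    while True:
        try:
            state = client.status(run_id)
        except (TransportError, OSError) as e:
            return TestResult(
                test_id=request.test_id,
                state=WesState.SYSTEM_ERROR,
                log_excerpt=f"status poll failed: {e}",
                duration=clock() - start,
            )
        if state.terminal:
            return TestResult(
                test_id=request.test_id,
                state=state,
                log_excerpt=f"run {run_id} finished in state {state.value}",
                duration=clock() - start,
            )
        if clock() - start + poll_interval > timeout:
            return TestResult(
                test_id=request.test_id,
                state=WesState.SYSTEM_ERROR,
                log_excerpt=f"timed out after {timeout} s waiting for run {run_id}",
                duration=clock() - start,
            )
        sleep(poll_interval)


def run_all_tests(
    meta: WorkflowMetadata,
    endpoint: WesClient | str,
    resolver: Resolver,
    poll_interval: float = 5.0,
    timeout: float = 3600.0,
    sleep: Callable[[float], None] = time.sleep,
    clock: Callable[[], float] = time.monotonic,
) -> list[TestResult]:
    """Run every test case sequentially; never short-circuits on failure."""
    results: list[TestResult] = []
    for test in meta.testing:
        try:
            request = build_run_request(meta, test, resolver)
        except (FileNotFoundError, ValueError) as e:
            results.append(
                TestResult(
                    test_id=test.test_id,
                    state=WesState.SYSTEM_ERROR,
                    log_excerpt=f"could not build run request: {e}",
                )
            )
            continue
        results.append(
            run_test(
                request,
                endpoint,
                poll_interval=poll_interval,
                timeout=timeout,
                sleep=sleep,
                clock=clock,
            )
        )
    return results


def all_passed(results: list[TestResult]) -> bool:
    return bool(results) and all(r.passed for r in results)
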