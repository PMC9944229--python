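"""Three-phase publication lifecycle: submission → review → publication.

The submission phase validates metadata and runs the test cases; the review
phase is a human gate (approve or reject); the publication phase persists
every workflow file through a pluggable archiver, mints a DOI, rewrites the
metadata's file URLs to their persisted locations, and emits the static TRS
registry.  A failure at any step halts the pipeline in-phase, and nothing is
archived or emitted unless validation and all tests passed (publication
atomicity).

The bundled :class:`LocalArchiver` stores content under a local directory
and mints deterministic DOIs in the reserved test prefix ``10.5072``, so the
whole lifecycle runs offline; a networked archiver (e.g. a research-data
repository client) plugs in behind the same two-method contract.
"""

from __future__ import annotations

import datetime
import enum
import os
import shutil
import tempfile
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

from .metadata import WorkflowMetadata
from .resources import Resolver, file_url
from .trs import to_trs, write_registry
from .validator import ValidationReport, validate
from .wes import TestResult, WesClient, all_passed, run_all_tests

__all__ = [
    "Phase",
    "LifecycleRecord",
    "ArchiveReceipt",
    "Archiver",
    "LocalArchiver",
    "ArchiverError",
    "persist_files",
    "rewrite_urls",
    "submit",
    "approve_and_publish",
    "publish",
]


class Phase(str, enum.Enum):
    SUBMISSION = "submission"
    REVIEW = "review"
    PUBLICATION = "publication"


_ORDER = [Phase.SUBMISSION, Phase.REVIEW, Phase.PUBLICATION]


@dataclass
class LifecycleEvent:
    timestamp: str
    phase: Phase
    action: str
    outcome: str
    ok: bool


@dataclass
class LifecycleRecord:
    phase: Phase = Phase.SUBMISSION
    events: list[LifecycleEvent] = field(default_factory=list)
    validation: ValidationReport | None = None
    test_results: list[TestResult] = field(default_factory=list)

    def advance(self, phase: Phase) -> None:
        if _ORDER.index(phase) < _ORDER.index(self.phase):
            raise ValueError(f"cannot move backwards from {self.phase.value} to {phase.value}")
        self.phase = phase

    def log(self, action: str, outcome: str, ok: bool = True) -> None:
        self.events.append(
            LifecycleEvent(
                timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
                phase=self.phase,
                action=action,
                outcome=outcome,
                ok=ok,
            )
        )

    @property
    def succeeded(self) -> bool:
        return all(e.ok for e in self.events)

    @property
    def phases_traversed(self) -> list[Phase]:
        seen: list[Phase] = []
        for e in self.events:
            if e.phase not in seen:
                seen.append(e.phase)
        return seen


@dataclass
class ArchiveReceipt:
    doi: str
    persisted_urls: dict[str, str]

    def __post_init__(self):
        if not self.doi:
            raise ValueError("receipt requires a non-empty DOI")


class ArchiverError(Exception):
    """Persistence failed; no partial receipt is produced."""


class Archiver(Protocol):
    def archive(
        self, meta: WorkflowMetadata, contents: dict[str, bytes]
    ) -> ArchiveReceipt: ...


class LocalArchiver:
    """Store files under a local archive directory, minting test-prefix DOIs.

    The DOI is deterministic for a given (id, version):
    ``10.5072/<first 8 id hex chars>.<version>`` — the 10.5072 namespace is
    reserved for testing, so these identifiers are valid-shaped and can
    never collide with production DOIs.
    """

    def __init__(self, archive_dir: str | os.PathLike):
        self.archive_dir = os.fspath(archive_dir)

    def mint_doi(self, meta: WorkflowMetadata) -> str:
        prefix = meta.id.replace("-", "")[:8]
        return f"10.5072/{prefix}.{meta.version}"

    def archive(
        self, meta: WorkflowMetadata, contents: dict[str, bytes]
    ) -> ArchiveReceipt:
        record_dir = os.path.join(self.archive_dir, meta.id, meta.version)
        staging = tempfile.mkdtemp(prefix=".staging-", dir=_ensure(self.archive_dir))
        try:
            url_map: dict[str, str] = {}
            for url, (target, content) in contents.items():
                dest = os.path.join(staging, target)
                os.makedirs(os.path.dirname(dest) or staging, exist_ok=True)
                with open(dest, "wb") as fh:
                    fh.write(content)
                url_map[url] = file_url(os.path.join(record_dir, target))
            if os.path.isdir(record_dir):
                shutil.rmtree(record_dir)
            os.makedirs(os.path.dirname(record_dir), exist_ok=True)
            shutil.move(staging, record_dir)
        except OSError as e:
            shutil.rmtree(staging, ignore_errors=True)
            raise ArchiverError(f"archiving failed: {e}") from e
        return ArchiveReceipt(doi=self.mint_doi(meta), persisted_urls=url_map)


def _ensure(d: str) -> str:
    os.makedirs(d, exist_ok=True)
    return d


def persist_files(
    meta: WorkflowMetadata, archiver: Archiver, resolver: Resolver
) -> ArchiveReceipt:
    """Hand every file's content to the archiver; all-or-nothing."""
    contents: dict[str, tuple[str, bytes]] = {}
    for f in meta.files:
        got = resolver.resolve(f.url)
        if not got.exists:
            raise ArchiverError(f"cannot persist unresolvable file: {f.url}")
        contents[f.url] = (f.target, got.content)
    for t in meta.testing:
        for f in t.files:
            if f.url in contents:
                continue
            got = resolver.resolve(f.url)
            if not got.exists:
                raise ArchiverError(f"cannot persist unresolvable file: {f.url}")
            contents[f.url] = (f.target, got.content)
    return archiver.archive(meta, contents)


def rewrite_urls(meta: WorkflowMetadata, receipt: ArchiveReceipt) -> WorkflowMetadata:
    """A copy with every file URL replaced by its persisted URL and doi set."""
    def mapped(url: str) -> str:
        if url not in receipt.persisted_urls:
            raise KeyError(f"receipt has no persisted URL for {url}")
        return receipt.persisted_urls[url]

    out = meta.copy()
    for f in out.files:
        f.url = mapped(f.url)
    for t in out.testing:
        for f in t.files:
            f.url = mapped(f.url)
    return replace(out, doi=receipt.doi)


# ---------------------------------------------------------------------------
# pipeline


def submit(
    meta: WorkflowMetadata,
    resolver: Resolver,
    wes_endpoint: WesClient | str,
    record: LifecycleRecord | None = None,
    poll_interval: float = 5.0,
    timeout: float = 3600.0,
    sleep: Callable[[float], None] | None = None,
) -> LifecycleRecord:
    """Submission phase: validate, then run all tests; stops on first gate."""
    import time as _time

    record = record or LifecycleRecord()
    report = validate(meta, resolver)
    record.validation = report
    record.log(
        "validate",
        "11/11 requirements satisfied"
        if report.overall
        else "failed: " + ", ".join(r.requirement.value for r in report.failed),
        ok=report.overall,
    )
    if not report.overall:
        return record
    results = run_all_tests(
        meta,
        wes_endpoint,
        resolver,
        poll_interval=poll_interval,
        timeout=timeout,
        sleep=sleep or _time.sleep,
    )
    record.test_results = results
    ok = all_passed(results)
    record.log(
        "test",
        f"{sum(r.passed for r in results)}/{len(results)} test cases passed",
        ok=ok,
    )
    if ok:
        record.log("stage-for-review", "submission complete; awaiting review")
    return record


def approve_and_publish(
    meta: WorkflowMetadata,
    record: LifecycleRecord,
    resolver: Resolver,
    archiver: Archiver,
    out_dir: str | os.PathLike,
    registry_base_url: str = "https://registry.example.org",
    registry_name: str = "wfregistry",
) -> tuple[LifecycleRecord, WorkflowMetadata | None]:
    """Review approval followed by the publication phase.

    Persists files, rewrites URLs, and emits the TRS registry.  The output
    directory is written only after everything upstream succeeded; a failed
    pipeline leaves it untouched.
    """
    if not record.succeeded or not record.test_results:
        record.log("approve", "cannot approve: submission phase incomplete", ok=False)
        return record, None
    record.advance(Phase.REVIEW)
    record.log("approve", "review approved")
    record.advance(Phase.PUBLICATION)
    try:
        receipt = persist_files(meta, archiver, resolver)
        record.log("persist-files", f"archived under DOI {receipt.doi}")
    except ArchiverError as e:
        record.log("persist-files", str(e), ok=False)
        return record, None
    published = rewrite_urls(meta, receipt)
    record.log("rewrite-urls", f"{len(receipt.persisted_urls)} URLs rewritten; doi set")
    tree = to_trs(
        [published],
        registry_base_url,
        resolver=resolver,
        verified={(published.id, published.version)},
        registry_name=registry_name,
    )
    written = write_registry(tree, out_dir)
    record.log("write-registry", f"{len(written)} documents written to {os.fspath(out_dir)}")
    return record, published


def publish(
    meta: WorkflowMetadata,
    resolver: Resolver,
    wes_endpoint: WesClient | str,
    archiver: Archiver,
    out_dir: str | os.PathLike,
    registry_base_url: str = "https://registry.example.org",
    registry_name: str = "wfregistry",
    poll_interval: float = 5.0,
    timeout: float = 3600.0,
    sleep: Callable[[float], None] | None = None,
) -> LifecycleRecord:
    """Full lifecycle in one call (auto-approved review gate).

    Equivalent to :func:`submit` followed by :func:`approve_and_publish`; a
    validation or test failure halts in the submission phase with nothing
    archived or emitted.
    """
    record = submit(
        meta,
        resolver,
        wes_endpoint,
        poll_interval=poll_interval,
        timeout=timeout,
        sleep=sleep,
    )
    if not record.succeeded:
        return record
    record, _ = approve_and_publish(
        meta,
        record,
        resolver,
        archiver,
        out_dir,
        registry_base_url=registry_base_url,
        registry_name=registry_name,
    )
    return record
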