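"""Retrieval of workflow files and repository facts behind a resolver contract.

Every module that needs file content goes through :class:`Resolver`, so a
local fixture tree (``file://``) and a remote host (``http(s)://``) are
interchangeable.  HTTP goes through an injectable *transport* callable, which
lets tests script statuses and bodies without opening sockets.

Two failure modes are kept strictly apart: a definitive not-found is a
*metadata* defect and comes back as ``exists=False``; a transport failure
(timeout, connection refused, repeated 5xx) is an *environment* defect and
raises :class:`TransportError` after retries with exponential backoff.
"""

from __future__ import annotations

import os
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Callable

from .metadata import UNKNOWN

__all__ = [
    "ResourceRef",
    "Resolved",
    "RepoFacts",
    "Resolver",
    "TransportError",
    "UnrecognizedLocator",
    "default_transport",
    "inspect_repository",
    "file_url",
]

#: (url, timeout_seconds, bearer_token|None) -> (status_code, body_bytes).
#: Must raise TransportError (or OSError) on network-layer failure.
Transport = Callable[[str, float, "str | None"], "tuple[int, bytes]"]


class TransportError(Exception):
    """Network-layer failure (timeout, refused, persistent 5xx) — not a verdict."""


class UnrecognizedLocator(Exception):
    """A repository locator that matches no supported hosting pattern."""


@dataclass(frozen=True)
class ResourceRef:
    """An absolute URL with scheme http, https, or file."""

    url: str

    def __post_init__(self):
        parsed = urllib.parse.urlparse(self.url)
        if parsed.scheme not in ("http", "https", "file"):
            raise ValueError(f"unsupported URL scheme {parsed.scheme!r} in {self.url!r}")

    @property
    def scheme(self) -> str:
        return urllib.parse.urlparse(self.url).scheme

    @property
    def path(self) -> str:
        return urllib.parse.urlparse(self.url).path


@dataclass
class Resolved:
    content: bytes
    exists: bool

    @property
    def length(self) -> int:
        return len(self.content)

    @property
    def text(self) -> str:
        return self.content.decode("utf-8")


@dataclass
class RepoFacts:
    owner: str
    repo: str
    default_ref: str = "main"
    license: str = UNKNOWN
    file_listing: list[str] = field(default_factory=list)


def file_url(path: str | os.PathLike) -> str:
    """Absolute ``file://`` URL for a local path."""
    return "file://" + urllib.parse.quote(os.path.abspath(os.fspath(path)))


def default_transport(url: str, timeout: float, token: str | None) -> tuple[int, bytes]:
    req = urllib.request.Request(url)
    if token:
        req.add_header("Authorization", f"Bearer {token}")
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            return resp.status, resp.read()
    except urllib.error.HTTPError as e:
        return e.code, e.read() or b""
    except (urllib.error.URLError, TimeoutError, OSError) as e:
        raise TransportError(f"transport failure for {url}: {e}") from e


class Resolver:
    """Fetch resource content with retries; ``file://`` reads the filesystem.

    Parameters
    ----------
    transport:
        HTTP transport callable; replaceable for testing.
    timeout_seconds, max_retries, backoff_factor:
        Transport retry policy.  Retries apply to transport failures and
        5xx statuses; 404/410 are definitive not-found.
    token:
        Opaque bearer token passed through to the transport (never used for
        availability checks, which must succeed without credentials).
    sleep:
        Injectable sleep for fast tests.
    """

    def __init__(
        self,
        transport: Transport = default_transport,
        timeout_seconds: float = 10.0,
        max_retries: int = 3,
        backoff_factor: float = 2.0,
        token: str | None = None,
        sleep: Callable[[float], None] = time.sleep,
    ):
        self.transport = transport
        self.timeout_seconds = timeout_seconds
        self.max_retries = max_retries
        self.backoff_factor = backoff_factor
        self.token = token
        self._sleep = sleep

    def resolve(self, ref: ResourceRef | str) -> Resolved:
        if isinstance(ref, str):
            ref = ResourceRef(ref)
        if ref.scheme == "file":
            path = urllib.parse.unquote(ref.path)
            if not os.path.isfile(path):
                return Resolved(b"", exists=False)
            with open(path, "rb") as fh:
                return Resolved(fh.read(), exists=True)
        return self._resolve_http(ref.url)

    def _resolve_http(self, url: str) -> Resolved:
        last_error: Exception | None = None
        for attempt in range(self.max_retries + 1):
            if attempt:
                self._sleep(self.backoff_factor ** (attempt - 1))
            try:
                status, body = self.transport(url, self.timeout_seconds, self.token)
            except TransportError as e:
                last_error = e
                continue
            if 200 <= status < 300:
                return Resolved(body, exists=True)
            if status in (404, 410):
                return Resolved(b"", exists=False)
            last_error = TransportError(f"HTTP {status} from {url}")
        raise TransportError(
            f"giving up on {url} after {self.max_retries + 1} attempts: {last_error}"
        )

    def exists(self, ref: ResourceRef | str) -> bool:
        return self.resolve(ref).exists


# ---------------------------------------------------------------------------
# repository inspection

# blob/raw URL shapes of the dominant code-hosting service
_HOSTED_RAW = ("raw.githubusercontent.com",)
_LICENSE_HINTS = [
    ("apache license", "2.0", "Apache-2.0"),
    ("mit license", "", "MIT"),
    ("bsd 3-clause", "", "BSD-3-Clause"),
    ("bsd 2-clause", "", "BSD-2-Clause"),
    ("gnu general public license", "version 3", "GPL-3.0-only"),
    ("gnu general public license", "version 2", "GPL-2.0-only"),
    ("mozilla public license", "2.0", "MPL-2.0"),
]


def _license_from_text(text: str) -> str:
    head = "\n".join(text.splitlines()[:5]).lower()
    # an SPDX identifier line wins outright
    for line in text.splitlines()[:10]:
        line = line.strip()
        if line.lower().startswith("spdx-license-identifier:"):
            return line.split(":", 1)[1].strip()
    for needle, qualifier, spdx in _LICENSE_HINTS:
        if needle in head and (not qualifier or qualifier in head):
            return spdx
    return UNKNOWN


@dataclass(frozen=True)
class HostedFileLocator:
    """Decomposition of a hosted blob/raw file URL."""

    host: str
    owner: str
    repo: str
    ref: str
    path: str

    def raw_url(self, path: str) -> str:
        if self.host in _HOSTED_RAW:
            return f"https://{self.host}/{self.owner}/{self.repo}/{self.ref}/{path}"
        return f"https://{self.host}/{self.owner}/{self.repo}/raw/{self.ref}/{path}"


def parse_hosted_url(url: str) -> HostedFileLocator | None:
    """Decompose a blob/raw hosting URL; None if the shape is unrecognized."""
    parsed = urllib.parse.urlparse(url)
    if parsed.scheme not in ("http", "https"):
        return None
    parts = [p for p in parsed.path.split("/") if p]
    if parsed.netloc in _HOSTED_RAW and len(parts) >= 3:
        owner, repo, ref = parts[0], parts[1], parts[2]
        return HostedFileLocator(parsed.netloc, owner, repo, ref, "/".join(parts[3:]))
    if len(parts) >= 4 and parts[2] in ("blob", "raw"):
        owner, repo, ref = parts[0], parts[1], parts[3]
        return HostedFileLocator(parsed.netloc, owner, repo, ref, "/".join(parts[4:]))
    return None


_LICENSE_NAMES = ("LICENSE", "LICENSE.md", "LICENSE.txt", "COPYING")


def inspect_repository(locator: str, resolver: Resolver | None = None) -> RepoFacts:
    """Collect repository facts from a repo (or in-repo file) locator.

    Local directories (``file://`` or a file within one) are walked directly:
    owner/repo derive from the last two path segments, ``default_ref`` is
    "main", and the license is read from a LICENSE file if present.  Hosted
    blob/raw URLs are decomposed; license and listing facts come from probing
    well-known paths through the resolver.
    """
    parsed = urllib.parse.urlparse(locator)
    if parsed.scheme == "file":
        path = urllib.parse.unquote(parsed.path)
        if os.path.isfile(path):
            path = _repo_root_of(path)
        if not os.path.isdir(path):
            raise UnrecognizedLocator(f"not a readable directory: {path}")
        return _inspect_local(path)
    loc = parse_hosted_url(locator)
    if loc is None:
        raise UnrecognizedLocator(f"unrecognized repository locator: {locator!r}")
    facts = RepoFacts(owner=loc.owner, repo=loc.repo, default_ref=loc.ref)
    if resolver is not None:
        for name in _LICENSE_NAMES:
            got = resolver.resolve(ResourceRef(loc.raw_url(name)))
            if got.exists:
                facts.license = _license_from_text(got.text)
                facts.file_listing.append(name)
                break
        readme = resolver.resolve(ResourceRef(loc.raw_url("README.md")))
        if readme.exists:
            facts.file_listing.append("README.md")
    return facts


def _repo_root_of(file_path: str) -> str:
    """Walk up from a file to the enclosing repo root (marked by LICENSE/README/.git)."""
    d = os.path.dirname(os.path.abspath(file_path))
    cur = d
    while True:
        entries = set(os.listdir(cur)) if os.path.isdir(cur) else set()
        if entries & {*_LICENSE_NAMES, "README.md", ".git"}:
            return cur
        parent = os.path.dirname(cur)
        if parent == cur:
            return d
        cur = parent


def _inspect_local(path: str) -> RepoFacts:
    path = os.path.abspath(path)
    parent, repo = os.path.split(path.rstrip("/"))
    owner = os.path.basename(parent) or "local"
    listing: list[str] = []
    for root, dirs, files in os.walk(path):
        dirs[:] = sorted(d for d in dirs if d != ".git")
        for f in sorted(files):
            listing.append(os.path.relpath(os.path.join(root, f), path))
    listing.sort()
    license_id = UNKNOWN
    for name in _LICENSE_NAMES:
        lic_path = os.path.join(path, name)
        if os.path.isfile(lic_path):
            with open(lic_path, encoding="utf-8", errors="replace") as fh:
                license_id = _license_from_text(fh.read())
            break
    return RepoFacts(
        owner=owner, repo=repo or "repo", default_ref="main",
        license=license_id, file_listing=listing,
    )
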