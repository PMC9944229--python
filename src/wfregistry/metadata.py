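"""Workflow metadata model: the registry record for one workflow version.

A metadata document is a JSON or YAML file naming, entirely by URL, the
primary workflow descriptor, its dependent files, test cases, license, and
authors.  It is the single input that drives template generation,
validation, test execution, and registry publication.

Parsing is strict by default: structural problems raise :class:`SchemaError`
naming the first offending field path, and semantic invariant violations
raise :class:`InvariantError` listing every failure at once.  ``strict=False``
parses structurally but defers invariant enforcement to the validator, so a
defective document can still be loaded and reported on check-by-check.
"""

from __future__ import annotations

import copy
import enum
import json
import random
import re
import uuid
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "LanguageType",
    "FileRole",
    "Author",
    "LanguageInfo",
    "FileEntry",
    "TestCase",
    "WorkflowMetadata",
    "MetadataError",
    "ParseError",
    "SchemaError",
    "InvariantError",
    "parse_metadata",
    "serialize_metadata",
    "new_workflow_id",
    "OPEN_SOURCE_LICENSES",
    "UNKNOWN",
]

#: Sentinel string used for unspecified license / language fields.
UNKNOWN = "UNKNOWN"

#: SPDX-style identifiers accepted as open-source licenses.  A deliberately
#: common subset of the OSI-approved list; anything else is a validation
#: failure (not a parse failure).
OPEN_SOURCE_LICENSES = frozenset(
    {
        "Apache-2.0",
        "MIT",
        "BSD-2-Clause",
        "BSD-3-Clause",
        "BSD-3-Clause-Clear",
        "GPL-2.0-only",
        "GPL-2.0-or-later",
        "GPL-3.0-only",
        "GPL-3.0-or-later",
        "LGPL-2.1-only",
        "LGPL-2.1-or-later",
        "LGPL-3.0-only",
        "LGPL-3.0-or-later",
        "AGPL-3.0-only",
        "AGPL-3.0-or-later",
        "MPL-2.0",
        "EPL-1.0",
        "EPL-2.0",
        "CDDL-1.0",
        "Artistic-2.0",
        "BSL-1.0",
        "Zlib",
        "Unlicense",
        "CC0-1.0",
        "CC-BY-4.0",
        "ISC",
        "EUPL-1.2",
        "OSL-3.0",
        "PostgreSQL",
        "Python-2.0",
    }
)

_ORCID_RE = re.compile(r"^(?:\d{4}-){3}\d{3}[\dX]$")
_VERSION_RE = re.compile(r"^\d+(?:\.\d+)*$")
_UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-4[0-9a-f]{3}-[0-9a-f]{4}-[0-9a-f]{12}$",
    re.IGNORECASE,
)


class MetadataError(Exception):
    """Base class for metadata document failures."""


class ParseError(MetadataError):
    """The document text is not well-formed JSON/YAML."""


class SchemaError(MetadataError):
    """A field is missing or has the wrong shape.

    ``field_path`` names the first violated field (dotted path).
    """

    def __init__(self, field_path: str, message: str):
        self.field_path = field_path
        super().__init__(f"{field_path}: {message}")


class InvariantError(MetadataError):
    """One or more semantic invariants are violated; all are listed."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("; ".join(failures))


class LanguageType(str, enum.Enum):
    CWL = "CWL"
    WDL = "WDL"
    NFL = "NFL"
    SMK = "SMK"
    UNKNOWN = "UNKNOWN"


class FileRole(str, enum.Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    TEST = "test"
    OTHER = "other"


@dataclass
class Author:
    account: str
    name: str = ""
    affiliation: str | None = None
    orcid: str | None = None


@dataclass
class LanguageInfo:
    type: LanguageType = LanguageType.UNKNOWN
    version: str = UNKNOWN


@dataclass
class FileEntry:
    url: str
    target: str
    role: FileRole = FileRole.OTHER


#: Basename (without extension) that designates a test-case file as the
#: workflow-parameters document.
WF_PARAMS_BASENAME = "wf_params"
#: Likewise for the optional engine-parameters document.
WF_ENGINE_PARAMS_BASENAME = "wf_engine_params"


def _stem(target: str) -> str:
    base = target.rsplit("/", 1)[-1]
    return base.rsplit(".", 1)[0] if "." in base else base


@dataclass
class TestCase:
    __test__ = False  # keep pytest from collecting this domain type

    test_id: str
    files: list[FileEntry] = field(default_factory=list)

    @property
    def params_file(self) -> FileEntry | None:
        """The designated workflow-parameters document, if present."""
        for f in self.files:
            if _stem(f.target) == WF_PARAMS_BASENAME:
                return f
        return None

    @property
    def engine_params_file(self) -> FileEntry | None:
        for f in self.files:
            if _stem(f.target) == WF_ENGINE_PARAMS_BASENAME:
                return f
        return None

    @property
    def attachment_files(self) -> list[FileEntry]:
        """Test files other than the (engine-)parameters documents."""
        skip = {WF_PARAMS_BASENAME, WF_ENGINE_PARAMS_BASENAME}
        return [f for f in self.files if _stem(f.target) not in skip]


@dataclass
class WorkflowMetadata:
    """The complete registry record for one workflow version."""

    id: str
    version: str
    license: str
    authors: list[Author]
    name: str
    readme_url: str
    language: LanguageInfo
    files: list[FileEntry]
    testing: list[TestCase]
    doi: str | None = None
    #: Unknown top-level keys, preserved verbatim for round-trip.
    extras: dict = field(default_factory=dict)

    # -- queries ---------------------------------------------------------
    @property
    def primary_file(self) -> FileEntry:
        primaries = [f for f in self.files if f.role is FileRole.PRIMARY]
        if len(primaries) != 1:
            raise InvariantError(
                [f"files: expected exactly one primary entry, found {len(primaries)}"]
            )
        return primaries[0]

    def invariant_failures(self) -> list[str]:
        """Every violated invariant, as human-readable messages."""
        fails: list[str] = []
        if not _UUID_RE.match(self.id):
            fails.append(f"id: not a version-4 UUID: {self.id!r}")
        if not _VERSION_RE.match(self.version):
            fails.append(f"version: not dotted numerics: {self.version!r}")
        if not self.name:
            fails.append("name: must be non-empty")
        n_primary = sum(1 for f in self.files if f.role is FileRole.PRIMARY)
        if n_primary != 1:
            fails.append(f"files: exactly one primary entry required, found {n_primary}")
        targets: set[str] = set()
        for i, f in enumerate(self.files):
            if f.target.startswith("/") or ".." in f.target.split("/"):
                fails.append(f"files[{i}].target: not a normalized relative path: {f.target!r}")
            if f.target in targets:
                fails.append(f"files[{i}].target: duplicate target {f.target!r}")
            targets.add(f.target)
        for i, a in enumerate(self.authors):
            if not a.account:
                fails.append(f"authors[{i}].account: must be non-empty")
            if a.orcid is not None and not _ORCID_RE.match(a.orcid):
                fails.append(f"authors[{i}].orcid: malformed ORCID {a.orcid!r}")
        if not self.testing:
            fails.append("testing: at least one test case required")
        seen_ids: set[str] = set()
        for i, t in enumerate(self.testing):
            if t.test_id in seen_ids:
                fails.append(f"testing[{i}].test_id: duplicate id {t.test_id!r}")
            seen_ids.add(t.test_id)
            for j, f in enumerate(t.files):
                if f.role not in (FileRole.TEST, FileRole.OTHER):
                    fails.append(
                        f"testing[{i}].files[{j}].role: must be test or other, got {f.role.value}"
                    )
            n_params = sum(1 for f in t.files if _stem(f.target) == WF_PARAMS_BASENAME)
            if n_params != 1:
                fails.append(
                    f"testing[{i}]: exactly one workflow-parameters document "
                    f"(target basename {WF_PARAMS_BASENAME!r}) required, found {n_params}"
                )
        return fails

    def check_invariants(self) -> None:
        fails = self.invariant_failures()
        if fails:
            raise InvariantError(fails)

    def copy(self) -> "WorkflowMetadata":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# parsing


def _require(obj: dict, key: str, typ, path: str):
    if key not in obj:
        raise SchemaError(f"{path}{key}", "missing required field")
    val = obj[key]
    if not isinstance(val, typ):
        raise SchemaError(
            f"{path}{key}", f"expected {typ.__name__}, got {type(val).__name__}"
        )
    return val


def _parse_file_entry(obj, path: str) -> FileEntry:
    if not isinstance(obj, dict):
        raise SchemaError(path, "expected a mapping")
    url = _require(obj, "url", str, f"{path}.")
    target = _require(obj, "target", str, f"{path}.")
    role_s = obj.get("role", "other")
    try:
        role = FileRole(role_s)
    except ValueError:
        raise SchemaError(f"{path}.role", f"unknown role {role_s!r}") from None
    return FileEntry(url=url, target=target, role=role)


def _parse_author(obj, path: str) -> Author:
    if not isinstance(obj, dict):
        raise SchemaError(path, "expected a mapping")
    account = _require(obj, "account", str, f"{path}.")
    name = obj.get("name", "")
    if not isinstance(name, str):
        raise SchemaError(f"{path}.name", "expected str")
    affiliation = obj.get("affiliation")
    orcid = obj.get("orcid")
    if affiliation is not None and not isinstance(affiliation, str):
        raise SchemaError(f"{path}.affiliation", "expected str")
    if orcid is not None and not isinstance(orcid, str):
        raise SchemaError(f"{path}.orcid", "expected str")
    return Author(account=account, name=name, affiliation=affiliation, orcid=orcid)


_KNOWN_KEYS = (
    "id",
    "version",
    "license",
    "authors",
    "name",
    "readme_url",
    "language",
    "files",
    "testing",
    "doi",
)


def parse_metadata(
    document_text: str, dialect: str = "auto", strict: bool = True
) -> WorkflowMetadata:
    """Parse a metadata document from JSON or YAML text.

    Parameters
    ----------
    document_text:
        UTF-8 text of the document.
    dialect:
        ``"json"``, ``"yaml"``, or ``"auto"`` (tries JSON then YAML).
    strict:
        When true (default), semantic invariants are enforced and an
        :class:`InvariantError` lists every violation.  When false, only
        the structural schema is enforced, which lets the validator report
        invariant-level defects requirement by requirement.
    """
    if dialect not in ("json", "yaml", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = None
    if dialect in ("json", "auto"):
        try:
            raw = json.loads(document_text)
        except json.JSONDecodeError as e:
            if dialect == "json":
                raise ParseError(f"malformed JSON: {e}") from e
    if raw is None:
        try:
            raw = yaml.safe_load(document_text)
        except yaml.YAMLError as e:
            raise ParseError(f"malformed YAML: {e}") from e
    if not isinstance(raw, dict):
        raise SchemaError("<document>", "top level must be a mapping")

    wid = _require(raw, "id", str, "")
    version = _require(raw, "version", str, "")
    license_ = _require(raw, "license", str, "")
    name = _require(raw, "name", str, "")
    readme_url = _require(raw, "readme_url", str, "")
    if strict and not _UUID_RE.match(wid):
        raise SchemaError("id", f"not a version-4 UUID: {wid!r}")

    lang_obj = _require(raw, "language", dict, "")
    lang_type_s = lang_obj.get("type", UNKNOWN)
    try:
        lang_type = LanguageType(lang_type_s)
    except ValueError:
        raise SchemaError("language.type", f"unknown language {lang_type_s!r}") from None
    lang_version = lang_obj.get("version", UNKNOWN)
    if not isinstance(lang_version, str):
        raise SchemaError("language.version", "expected str")
    language = LanguageInfo(type=lang_type, version=lang_version)

    authors_raw = _require(raw, "authors", list, "")
    authors = [_parse_author(a, f"authors[{i}]") for i, a in enumerate(authors_raw)]

    files_raw = _require(raw, "files", list, "")
    files = [_parse_file_entry(f, f"files[{i}]") for i, f in enumerate(files_raw)]

    testing_raw = _require(raw, "testing", list, "")
    testing = []
    for i, t in enumerate(testing_raw):
        if not isinstance(t, dict):
            raise SchemaError(f"testing[{i}]", "expected a mapping")
        test_id = _require(t, "test_id", str, f"testing[{i}].")
        tfiles_raw = t.get("files", [])
        if not isinstance(tfiles_raw, list):
            raise SchemaError(f"testing[{i}].files", "expected list")
        tfiles = [
            _parse_file_entry(f, f"testing[{i}].files[{j}]")
            for j, f in enumerate(tfiles_raw)
        ]
        testing.append(TestCase(test_id=test_id, files=tfiles))

    doi = raw.get("doi")
    if doi is not None and not isinstance(doi, str):
        raise SchemaError("doi", "expected str")

    extras = {k: raw[k] for k in raw if k not in _KNOWN_KEYS}

    meta = WorkflowMetadata(
        id=wid,
        version=version,
        license=license_,
        authors=authors,
        name=name,
        readme_url=readme_url,
        language=language,
        files=files,
        testing=testing,
        doi=doi,
        extras=extras,
    )
    if strict:
        meta.check_invariants()
    return meta


# ---------------------------------------------------------------------------
# serialization


def _to_plain(meta: WorkflowMetadata) -> dict:
    doc: dict = {
        "id": meta.id,
        "version": meta.version,
        "license": meta.license,
        "authors": [
            {
                "account": a.account,
                "name": a.name,
                **({"affiliation": a.affiliation} if a.affiliation is not None else {}),
                **({"orcid": a.orcid} if a.orcid is not None else {}),
            }
            for a in meta.authors
        ],
        "name": meta.name,
        "readme_url": meta.readme_url,
        "language": {"type": meta.language.type.value, "version": meta.language.version},
        "files": [
            {"url": f.url, "target": f.target, "role": f.role.value} for f in meta.files
        ],
        "testing": [
            {
                "test_id": t.test_id,
                "files": [
                    {"url": f.url, "target": f.target, "role": f.role.value}
                    for f in t.files
                ],
            }
            for t in meta.testing
        ],
    }
    if meta.doi is not None:
        doc["doi"] = meta.doi
    for k in sorted(meta.extras):
        doc[k] = meta.extras[k]
    return doc


def serialize_metadata(meta: WorkflowMetadata, dialect: str = "yaml") -> str:
    """Serialize to JSON or YAML; output is deterministic and re-parses equal."""
    doc = _to_plain(meta)
    if dialect == "json":
        return json.dumps(doc, indent=2, ensure_ascii=False, sort_keys=False) + "\n"
    if dialect == "yaml":
        return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    raise ValueError(f"unknown dialect {dialect!r}")


def new_workflow_id(rng_seed: int | None = None) -> str:
    """A fresh version-4 UUID string; reproducible when seeded."""
    if rng_seed is None:
        return str(uuid.uuid4())
    rng = random.Random(rng_seed)
    return str(uuid.UUID(int=rng.getrandbits(128), version=4))


def with_doi(meta: WorkflowMetadata, doi: str) -> WorkflowMetadata:
    return replace(meta.copy(), doi=doi)
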