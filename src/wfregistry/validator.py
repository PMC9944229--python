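"""Validation of a metadata document against the reusability requirements.

A workflow is considered reusable with confidence when eleven requirements
hold, grouped in three categories:

* **availability** — the main descriptor, dependent materials, and testing
  materials all resolve without credentials, and the license is a known
  open-source identifier;
* **validity** — the workflow language type and version are declared and the
  descriptor passes shallow syntax checks;
* **traceability** — authors with contact identity are listed, documentation
  resolves, and the workflow id and metadata version are well formed.

Every check always runs (no short-circuiting), so a report is complete even
when several requirements fail at once.  Transport failures propagate as
exceptions — a broken network is an environment problem, never a verdict.
"""

from __future__ import annotations

import enum
import re
import urllib.parse
from dataclasses import dataclass, field

from .languages import check_syntax, detect_language, enumerate_dependencies
from .metadata import (
    OPEN_SOURCE_LICENSES,
    UNKNOWN,
    FileRole,
    LanguageType,
    WorkflowMetadata,
)
from .resources import Resolver

__all__ = ["Requirement", "Category", "CheckResult", "ValidationReport", "validate"]

_UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-4[0-9a-f]{3}-[0-9a-f]{4}-[0-9a-f]{12}$", re.IGNORECASE
)
_VERSION_RE = re.compile(r"^\d+(?:\.\d+)*$")


class Category(str, enum.Enum):
    AVAILABILITY = "availability"
    VALIDITY = "validity"
    TRACEABILITY = "traceability"


class Requirement(str, enum.Enum):
    MAIN_WORKFLOW_DESCRIPTION = "Main workflow description"
    DEPENDENT_MATERIALS = "Dependent materials"
    TESTING_MATERIALS = "Testing materials"
    OPEN_SOURCE_LICENSE = "Open-source license"
    LANGUAGE_TYPE = "Language type"
    LANGUAGE_VERSION = "Language version"
    LANGUAGE_SYNTAX = "Language syntax"
    AUTHORS_AND_MAINTAINERS = "Authors and maintainers"
    DOCUMENTATION = "Documentation"
    WORKFLOW_ID = "Workflow ID"
    WORKFLOW_METADATA_VERSION = "Workflow metadata version"


#: Category each requirement belongs to.
REQUIREMENT_CATEGORY: dict[Requirement, Category] = {
    Requirement.MAIN_WORKFLOW_DESCRIPTION: Category.AVAILABILITY,
    Requirement.DEPENDENT_MATERIALS: Category.AVAILABILITY,
    Requirement.TESTING_MATERIALS: Category.AVAILABILITY,
    Requirement.OPEN_SOURCE_LICENSE: Category.AVAILABILITY,
    Requirement.LANGUAGE_TYPE: Category.VALIDITY,
    Requirement.LANGUAGE_VERSION: Category.VALIDITY,
    Requirement.LANGUAGE_SYNTAX: Category.VALIDITY,
    Requirement.AUTHORS_AND_MAINTAINERS: Category.TRACEABILITY,
    Requirement.DOCUMENTATION: Category.TRACEABILITY,
    Requirement.WORKFLOW_ID: Category.TRACEABILITY,
    Requirement.WORKFLOW_METADATA_VERSION: Category.TRACEABILITY,
}


@dataclass
class CheckResult:
    requirement: Requirement
    category: Category
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    results: list[CheckResult] = field(default_factory=list)

    @property
    def categories(self) -> dict[Category, bool]:
        out: dict[Category, bool] = {c: True for c in Category}
        for r in self.results:
            out[r.category] = out[r.category] and r.passed
        return out

    @property
    def overall(self) -> bool:
        return all(r.passed for r in self.results)

    @property
    def failed(self) -> list[CheckResult]:
        return [r for r in self.results if not r.passed]

    def result_for(self, requirement: Requirement) -> CheckResult:
        for r in self.results:
            if r.requirement is requirement:
                return r
        raise KeyError(requirement)

    def to_plain(self) -> dict:
        return {
            "overall": self.overall,
            "categories": {c.value: ok for c, ok in self.categories.items()},
            "results": [
                {
                    "requirement": r.requirement.value,
                    "category": r.category.value,
                    "passed": r.passed,
                    "detail": r.detail,
                }
                for r in self.results
            ],
        }


def _resolves(resolver: Resolver, url: str) -> bool:
    """False for a malformed or empty URL — a metadata defect, not an error."""
    try:
        return resolver.resolve(url).exists
    except ValueError:
        return False


def validate(meta: WorkflowMetadata, resolver: Resolver) -> ValidationReport:
    """Evaluate all eleven requirements; the report is always complete.

    Availability checks invoke the resolver without credentials: "accessible
    without restriction" is operationalized as resolvable anonymously.
    """
    anon = Resolver(
        transport=resolver.transport,
        timeout_seconds=resolver.timeout_seconds,
        max_retries=resolver.max_retries,
        backoff_factor=resolver.backoff_factor,
        token=None,
        sleep=resolver._sleep,
    )
    results: list[CheckResult] = []

    def add(req: Requirement, passed: bool, detail: str) -> None:
        results.append(CheckResult(req, REQUIREMENT_CATEGORY[req], passed, detail))

    # -- availability ----------------------------------------------------
    primaries = [f for f in meta.files if f.role is FileRole.PRIMARY]
    primary = primaries[0] if len(primaries) == 1 else None
    primary_content: str | None = None
    if primary is None:
        add(
            Requirement.MAIN_WORKFLOW_DESCRIPTION,
            False,
            f"expected exactly one primary file entry, found {len(primaries)}",
        )
    else:
        got = anon.resolve(primary.url)
        if got.exists:
            primary_content = got.text
            add(Requirement.MAIN_WORKFLOW_DESCRIPTION, True, primary.url)
        else:
            add(
                Requirement.MAIN_WORKFLOW_DESCRIPTION,
                False,
                f"primary descriptor not found: {primary.url}",
            )

    missing_deps: list[str] = []
    for f in meta.files:
        if f.role is FileRole.PRIMARY:
            continue
        if not _resolves(anon, f.url):
            missing_deps.append(f.url)
    if primary_content is not None:
        lang = meta.language
        if lang.type is LanguageType.UNKNOWN:
            lang = detect_language(primary_content, primary.target)
        if lang.type is not LanguageType.UNKNOWN:
            for dep in enumerate_dependencies(primary_content, lang):
                if dep.remote and not _resolves(anon, dep.path):
                    missing_deps.append(dep.path)
    add(
        Requirement.DEPENDENT_MATERIALS,
        not missing_deps,
        "all dependent materials resolve"
        if not missing_deps
        else "unresolvable: " + ", ".join(missing_deps),
    )

    test_problems: list[str] = []
    for t in meta.testing:
        if t.params_file is None:
            test_problems.append(f"{t.test_id}: no workflow-parameters document")
        for f in t.files:
            if not _resolves(anon, f.url):
                test_problems.append(f"{t.test_id}: not found: {f.url}")
    if not meta.testing:
        test_problems.append("no test cases")
    add(
        Requirement.TESTING_MATERIALS,
        not test_problems,
        "all testing materials resolve"
        if not test_problems
        else "; ".join(test_problems),
    )

    add(
        Requirement.OPEN_SOURCE_LICENSE,
        meta.license in OPEN_SOURCE_LICENSES,
        f"license {meta.license!r}"
        + ("" if meta.license in OPEN_SOURCE_LICENSES else " is not a recognized open-source license"),
    )

    # -- validity --------------------------------------------------------
    add(
        Requirement.LANGUAGE_TYPE,
        meta.language.type is not LanguageType.UNKNOWN,
        f"language type {meta.language.type.value}",
    )
    add(
        Requirement.LANGUAGE_VERSION,
        meta.language.version != UNKNOWN and bool(meta.language.version),
        f"language version {meta.language.version!r}",
    )
    if primary_content is None:
        # not assessable: the missing descriptor is already flagged under
        # the main-workflow-description requirement, and each defect should
        # surface exactly once
        add(
            Requirement.LANGUAGE_SYNTAX,
            True,
            "not assessable: primary descriptor unavailable",
        )
    else:
        # fall back to content-based detection so a mis-declared language
        # type fails only the language-type requirement
        lang = meta.language
        if lang.type is LanguageType.UNKNOWN:
            lang = detect_language(primary_content, primary.target)
        if lang.type is LanguageType.UNKNOWN:
            add(Requirement.LANGUAGE_SYNTAX, False, "language undetectable; cannot check syntax")
        else:
            errors = [i for i in check_syntax(primary_content, lang) if i.is_error]
            add(
                Requirement.LANGUAGE_SYNTAX,
                not errors,
                "syntax valid" if not errors else "; ".join(i.message for i in errors),
            )

    # -- traceability ----------------------------------------------------
    named = [a for a in meta.authors if a.account and a.name]
    add(
        Requirement.AUTHORS_AND_MAINTAINERS,
        bool(named),
        f"{len(named)} author(s) with account and name"
        if named
        else "no author with both account and display name",
    )
    readme = anon.resolve(meta.readme_url) if meta.readme_url else None
    add(
        Requirement.DOCUMENTATION,
        bool(readme and readme.exists),
        meta.readme_url if readme and readme.exists else f"documentation not found: {meta.readme_url!r}",
    )
    add(
        Requirement.WORKFLOW_ID,
        bool(_UUID_RE.match(meta.id)),
        f"id {meta.id!r}",
    )
    add(
        Requirement.WORKFLOW_METADATA_VERSION,
        bool(_VERSION_RE.match(meta.version)),
        f"version {meta.version!r}",
    )

    return ValidationReport(results=results)
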