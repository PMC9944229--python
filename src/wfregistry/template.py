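"""Draft-metadata generation from a primary workflow descriptor URL.

``make_template`` inspects the descriptor and its repository and emits a
schema-valid draft the submitter edits before validation: language detected
from the content, one file entry per resolvable dependency, license and
author account pulled from repository facts, and a stub test case that must
be completed.  A draft is intentionally allowed to *fail validation* (empty
author name, UNKNOWN license, stub test) — those are authoring gaps, not
schema errors.
"""

from __future__ import annotations

import logging
import posixpath
import urllib.parse

from .languages import detect_language, enumerate_dependencies
from .metadata import (
    UNKNOWN,
    Author,
    FileEntry,
    FileRole,
    LanguageType,
    TestCase,
    WorkflowMetadata,
    new_workflow_id,
)
from .resources import (
    Resolver,
    UnrecognizedLocator,
    inspect_repository,
    parse_hosted_url,
)

__all__ = ["make_template"]

logger = logging.getLogger(__name__)

#: Target path of the stub workflow-parameters document the submitter fills in.
STUB_PARAMS_TARGET = "tests/wf_params.json"


def _repo_relative_target(primary_url: str) -> tuple[str, str]:
    """(base url of the primary's directory, primary's repo-relative target)."""
    hosted = parse_hosted_url(primary_url)
    if hosted is not None and hosted.path:
        directory = posixpath.dirname(hosted.path)
        base = primary_url.rsplit("/", 1)[0] + "/"
        return base, hosted.path
    parsed = urllib.parse.urlparse(primary_url)
    base = primary_url.rsplit("/", 1)[0] + "/"
    return base, posixpath.basename(parsed.path)


def make_template(
    primary_url: str,
    resolver: Resolver,
    rng_seed: int | None = None,
) -> WorkflowMetadata:
    """Generate a pre-filled draft metadata document for a primary descriptor.

    Raises ``FileNotFoundError`` if the primary does not resolve.  An
    undetectable language is not an error: the draft carries UNKNOWN fields
    and a warning is logged, leaving the gap to validation.
    """
    got = resolver.resolve(primary_url)
    if not got.exists:
        raise FileNotFoundError(f"primary descriptor not found: {primary_url}")
    content = got.text

    parsed = urllib.parse.urlparse(primary_url)
    filename = posixpath.basename(parsed.path)
    language = detect_language(content, filename)
    if language.type is LanguageType.UNKNOWN:
        logger.warning("could not detect workflow language of %s", primary_url)

    base, primary_target = _repo_relative_target(primary_url)
    prefix = posixpath.dirname(primary_target)
    files = [FileEntry(url=primary_url, target=primary_target, role=FileRole.PRIMARY)]
    if language.type is not LanguageType.UNKNOWN:
        for dep in enumerate_dependencies(content, language):
            if dep.remote:
                dep_url = dep.path
                target = posixpath.basename(urllib.parse.urlparse(dep.path).path)
            else:
                dep_url = urllib.parse.urljoin(base, dep.path)
                target = posixpath.normpath(posixpath.join(prefix, dep.path))
            if not resolver.resolve(dep_url).exists:
                logger.warning("dependency does not resolve: %s", dep_url)
            files.append(FileEntry(url=dep_url, target=target, role=FileRole.SECONDARY))

    license_id = UNKNOWN
    authors = [Author(account="unknown", name="")]
    readme_url = ""
    try:
        facts = inspect_repository(primary_url, resolver)
    except UnrecognizedLocator:
        facts = None
    if facts is not None:
        license_id = facts.license
        authors = [Author(account=facts.owner, name="")]
        readmes = [p for p in facts.file_listing if posixpath.basename(p) == "README.md"]
        if readmes:
            hosted = parse_hosted_url(primary_url)
            if hosted is not None:
                readme_url = hosted.raw_url(readmes[0])
            else:
                root = base
                # local repos: readme path is relative to the repo root
                repo_root_url = primary_url
                for _ in range(len([p for p in primary_target.split("/") if p])):
                    repo_root_url = repo_root_url.rsplit("/", 1)[0]
                readme_url = repo_root_url + "/" + readmes[0]

    stub_test = TestCase(
        test_id="test_1",
        files=[FileEntry(url="", target=STUB_PARAMS_TARGET, role=FileRole.TEST)],
    )
    return WorkflowMetadata(
        id=new_workflow_id(rng_seed),
        version="1.0.0",
        license=license_id,
        authors=authors,
        name=filename or "workflow",
        readme_url=readme_url,
        language=language,
        files=files,
        testing=[stub_test],
    )
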