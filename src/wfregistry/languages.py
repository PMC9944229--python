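"""Workflow-language detection, shallow syntax checks, dependency listing.

Covers the four common workflow languages: CWL, WDL, Nextflow (NFL), and
Snakemake (SMK).  Checks are deliberately structural — enough to catch the
defect classes a registry cares about (missing keys, unbalanced braces,
absent rule/process blocks) without pulling in a full language toolchain.
"""

from __future__ import annotations

import enum
import re
import urllib.parse
from dataclasses import dataclass

import yaml

from .metadata import UNKNOWN, LanguageInfo, LanguageType

__all__ = [
    "Severity",
    "SyntaxIssue",
    "DependencyRef",
    "detect_language",
    "check_syntax",
    "enumerate_dependencies",
]


class Severity(str, enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class SyntaxIssue:
    severity: Severity
    message: str
    location: int | str = UNKNOWN  # line number or UNKNOWN

    @property
    def is_error(self) -> bool:
        return self.severity is Severity.ERROR


@dataclass(frozen=True)
class DependencyRef:
    """A dependency referenced from a descriptor; remote iff it is an absolute URL."""

    path: str
    remote: bool = False


_WDL_VERSION_RE = re.compile(r"^\s*version\s+([\w.\-]+)", re.MULTILINE)
_WDL_WORKFLOW_RE = re.compile(r"^\s*(workflow|task)\s+\w+\s*\{", re.MULTILINE)
_NFL_BLOCK_RE = re.compile(r"^\s*(process\s+\w+|workflow(\s+\w+)?)\s*\{", re.MULTILINE)
_NFL_DSL_RE = re.compile(r"nextflow\.enable\.dsl\s*=\s*(\d+)")
_NFL_IDIOM_RE = re.compile(r"(Channel\s*\.|\.out\b|params\.\w+|nextflow\.enable)")
_SMK_RULE_RE = re.compile(r"^rule\s+\w+\s*:", re.MULTILINE)


def detect_language(content: str, filename: str = "") -> LanguageInfo:
    """Identify the workflow language of a descriptor.

    Detection rules, in priority order: a top-level ``cwlVersion`` key means
    CWL (version taken from its value); a leading ``version X`` statement plus
    a workflow/task block means WDL; process/workflow blocks with Nextflow
    idioms mean NFL (DSL version if declared, else UNKNOWN); ``rule name:``
    blocks or a Snakefile filename mean SMK.  Anything else is UNKNOWN —
    there is no error path.
    """
    cwl_m = re.search(r"^cwlVersion\s*:\s*[\"']?([\w.\-]+)", content, re.MULTILINE)
    if cwl_m:
        return LanguageInfo(LanguageType.CWL, cwl_m.group(1))
    wdl_v = _WDL_VERSION_RE.search(content)
    if wdl_v and _WDL_WORKFLOW_RE.search(content):
        return LanguageInfo(LanguageType.WDL, wdl_v.group(1))
    if _NFL_BLOCK_RE.search(content) and _NFL_IDIOM_RE.search(content):
        dsl = _NFL_DSL_RE.search(content)
        return LanguageInfo(LanguageType.NFL, f"DSL{dsl.group(1)}" if dsl else UNKNOWN)
    base = filename.rsplit("/", 1)[-1]
    if _SMK_RULE_RE.search(content) or base == "Snakefile" or base.endswith(".smk"):
        return LanguageInfo(LanguageType.SMK, UNKNOWN)
    return LanguageInfo(LanguageType.UNKNOWN, UNKNOWN)


# ---------------------------------------------------------------------------
# syntax checks


def _strip_strings_and_comments(content: str, comment_chars: str = "//") -> str:
    """Blank out string literals and line comments so brace counting is honest."""
    out: list[str] = []
    i, n = 0, len(content)
    while i < n:
        c = content[i]
        if c in "\"'":
            quote = c
            out.append(" ")
            i += 1
            while i < n and content[i] != quote:
                out.append("\n" if content[i] == "\n" else " ")
                i += 2 if content[i] == "\\" else 1
            i += 1
        elif comment_chars and content.startswith(comment_chars, i):
            while i < n and content[i] != "\n":
                i += 1
        elif c == "#" and comment_chars == "#":
            while i < n and content[i] != "\n":
                i += 1
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _brace_issues(content: str, comment: str) -> list[SyntaxIssue]:
    stripped = _strip_strings_and_comments(content, comment)
    opens = stripped.count("{")
    closes = stripped.count("}")
    if opens != closes:
        return [
            SyntaxIssue(
                Severity.ERROR,
                f"unbalanced braces: {opens} '{{' vs {closes} '}}'",
            )
        ]
    return []


_CWL_CLASSES = {"Workflow", "CommandLineTool", "ExpressionTool"}


def check_syntax(content: str, language: LanguageInfo) -> list[SyntaxIssue]:
    """Shallow structural validation; an empty list means valid.

    CWL: parses as YAML with ``cwlVersion`` and a recognized ``class``.
    WDL: version statement present, braces balanced.
    NFL: braces balanced, at least one process/workflow block.
    SMK: at least one rule block, consistent indentation within rules.
    """
    if language.type is LanguageType.UNKNOWN:
        raise ValueError("cannot check syntax of an UNKNOWN-language descriptor")
    issues: list[SyntaxIssue] = []
    if language.type is LanguageType.CWL:
        try:
            doc = yaml.safe_load(content)
        except yaml.YAMLError as e:
            return [SyntaxIssue(Severity.ERROR, f"not valid YAML: {e}")]
        if not isinstance(doc, dict):
            return [SyntaxIssue(Severity.ERROR, "document is not a mapping")]
        if "cwlVersion" not in doc:
            issues.append(SyntaxIssue(Severity.ERROR, "missing key: cwlVersion"))
        if "class" not in doc:
            issues.append(SyntaxIssue(Severity.ERROR, "missing key: class"))
        elif doc["class"] not in _CWL_CLASSES:
            issues.append(
                SyntaxIssue(
                    Severity.ERROR,
                    f"unknown class {doc['class']!r}; expected one of {sorted(_CWL_CLASSES)}",
                )
            )
    elif language.type is LanguageType.WDL:
        if not _WDL_VERSION_RE.search(content):
            issues.append(SyntaxIssue(Severity.ERROR, "missing version statement"))
        issues.extend(_brace_issues(content, "#"))
    elif language.type is LanguageType.NFL:
        issues.extend(_brace_issues(content, "//"))
        if not _NFL_BLOCK_RE.search(content):
            issues.append(SyntaxIssue(Severity.ERROR, "no process or workflow block"))
    elif language.type is LanguageType.SMK:
        rules = list(_SMK_RULE_RE.finditer(content))
        if not rules:
            issues.append(SyntaxIssue(Severity.ERROR, "no rule block"))
        issues.extend(_smk_indent_issues(content))
    return issues


def _smk_indent_issues(content: str) -> list[SyntaxIssue]:
    """Within each rule, directive lines must share one indentation width."""
    issues: list[SyntaxIssue] = []
    lines = content.splitlines()
    in_rule = False
    indent: int | None = None
    for lineno, line in enumerate(lines, start=1):
        if _SMK_RULE_RE.match(line):
            in_rule, indent = True, None
            continue
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        stripped_len = len(line) - len(line.lstrip(" "))
        if in_rule:
            if stripped_len == 0:
                in_rule = False
                continue
            if indent is None:
                indent = stripped_len
            elif stripped_len != indent and re.match(r"^\s*\w+\s*:", line):
                issues.append(
                    SyntaxIssue(
                        Severity.ERROR,
                        f"inconsistent indentation in rule body ({stripped_len} vs {indent})",
                        location=lineno,
                    )
                )
    return issues


# ---------------------------------------------------------------------------
# dependency enumeration


def _is_remote(path: str) -> bool:
    return urllib.parse.urlparse(path).scheme in ("http", "https")


def _cwl_deps(content: str) -> list[str]:
    try:
        doc = yaml.safe_load(content)
    except yaml.YAMLError:
        return []
    found: list[str] = []

    def walk(node):
        if isinstance(node, dict):
            for key, val in node.items():
                if key in ("run", "$import", "$include") and isinstance(val, str):
                    found.append(val)
                else:
                    walk(val)
        elif isinstance(node, list):
            for item in node:
                walk(item)

    walk(doc)
    return found


_WDL_IMPORT_RE = re.compile(r'^\s*import\s+"([^"]+)"', re.MULTILINE)
_NFL_INCLUDE_RE = re.compile(r"include\s*\{[^}]*\}\s*from\s*['\"]([^'\"]+)['\"]")
_SMK_INCLUDE_RE = re.compile(r'^\s*include\s*:\s*["\']([^"\']+)["\']', re.MULTILINE)


def enumerate_dependencies(content: str, language: LanguageInfo) -> list[DependencyRef]:
    """References to other descriptor files, deduplicated in declaration order.

    CWL: ``run`` targets plus ``$import``/``$include``; WDL: ``import``
    statements; NFL: ``include ... from`` paths; SMK: ``include:`` directives.
    Absolute-URL targets are reported too, flagged ``remote=True``.
    """
    if language.type is LanguageType.UNKNOWN:
        raise ValueError("cannot enumerate dependencies of an UNKNOWN-language descriptor")
    if language.type is LanguageType.CWL:
        raw = _cwl_deps(content)
    elif language.type is LanguageType.WDL:
        raw = _WDL_IMPORT_RE.findall(content)
    elif language.type is LanguageType.NFL:
        raw = _NFL_INCLUDE_RE.findall(content)
    else:
        raw = _SMK_INCLUDE_RE.findall(content)
    seen: set[str] = set()
    out: list[DependencyRef] = []
    for path in raw:
        if path.startswith("#"):  # in-document fragment reference
            continue
        if path in seen:
            continue
        seen.add(path)
        out.append(DependencyRef(path=path, remote=_is_remote(path)))
    return out
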