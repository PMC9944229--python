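"""Synthetic workflow repositories with injectable defects.

The generator writes a small but complete on-disk workflow repository —
primary descriptor, dependent tool/module descriptors, README, LICENSE,
workflow-parameters file, a tiny input data file, and a full metadata
document — for each of the four supported languages.  The CWL shape mimics
a bacterial genome assembly that chains four command-line tool steps
(read statistics, quality control, trimming, assembly).

Every reusability requirement has a matching defect code whose injection is
the *minimal* mutation violating exactly that requirement, which is the
backbone of the validator's defect-isolation tests.  Two further codes
script the stub WES to fail, exercising the testing gate.

Fixture workflows exist at the descriptor level only; they are never run by
a real engine here — run outcomes come from the scripted stub executor.
"""

from __future__ import annotations

import os
import shutil
import tempfile
from dataclasses import dataclass, field

from .metadata import (
    UNKNOWN,
    Author,
    FileEntry,
    FileRole,
    LanguageInfo,
    LanguageType,
    TestCase,
    WorkflowMetadata,
    new_workflow_id,
    parse_metadata,
    serialize_metadata,
)
from .resources import file_url
from .wes import WesState

__all__ = [
    "FixtureRepo",
    "generate_repo",
    "generate_registry_corpus",
    "DEFECT_CODES",
    "DEFECT_BY_REQUIREMENT",
    "UnknownDefect",
]


class UnknownDefect(Exception):
    pass


#: Defect code per reusability requirement (validation defects) …
DEFECT_BY_REQUIREMENT = {
    "Main workflow description": "missing-primary",
    "Dependent materials": "dangling-dependency",
    "Testing materials": "missing-test-file",
    "Open-source license": "bad-license",
    "Language type": "language-type-unknown",
    "Language version": "language-version-unknown",
    "Language syntax": "syntax-error",
    "Authors and maintainers": "no-authors",
    "Documentation": "missing-readme",
    "Workflow ID": "bad-id",
    "Workflow metadata version": "bad-version",
}

#: … plus codes that script the stub WES to fail the testing gate.
WES_DEFECTS = {"wes-executor-error", "wes-system-error", "wes-canceled"}

DEFECT_CODES = frozenset(DEFECT_BY_REQUIREMENT.values()) | WES_DEFECTS

METADATA_FILENAME = "workflow-metadata.yml"

_LICENSE_TEXT = """\
Apache License
Version 2.0, January 2004

SPDX-License-Identifier: Apache-2.0

Licensed under the Apache License, Version 2.0 (the "License");
you may not use this file except in compliance with the License.
"""

_README_TEXT = """\
# Toy bacterial genome assembly workflow

A miniature workflow fixture: read statistics, quality control, read
trimming, and genome assembly chained over a tiny synthetic read set.
Generated programmatically for registry testing; not a real analysis.
"""

_READS = "@read1\nACGTACGTACGT\n+\nIIIIIIIIIIII\n@read2\nTTGGCCAATTGG\n+\nIIIIIIIIIIII\n"

_CWL_TOOL = """\
cwlVersion: v1.0
class: CommandLineTool
baseCommand: [{cmd}]
inputs:
  reads:
    type: File
    inputBinding: {{position: 1}}
outputs:
  {out}:
    type: stdout
stdout: {out}.txt
"""

_CWL_MAIN = """\
cwlVersion: v1.0
class: Workflow
label: toy bacterial genome assembly
inputs:
  reads:
    type: File
outputs:
  assembly:
    type: File
    outputSource: assemble/contigs
steps:
  stats:
    run: tools/seqkit_stats.cwl
    in: {reads: reads}
    out: [stats]
  qc:
    run: tools/fastqc.cwl
    in: {reads: reads}
    out: [report]
  trim:
    run: tools/fastp.cwl
    in: {reads: reads}
    out: [trimmed]
  assemble:
    run: tools/platanus_b.cwl
    in: {reads: reads}
    out: [contigs]
"""

_WDL_MAIN = """\
version 1.0

import "tasks/qc.wdl" as qc
import "tasks/assemble.wdl" as asm

workflow genome_assembly {
  input {
    File reads
  }
  call qc.fastqc { input: reads = reads }
  call asm.assemble { input: reads = reads }
}
"""

_WDL_TASK = """\
version 1.0

task {name} {{
  input {{
    File reads
  }}
  command <<<
    {cmd} ~{{reads}} > {name}.txt
  >>>
  output {{
    File out = "{name}.txt"
  }}
}}
"""

_NFL_MAIN = """\
nextflow.enable.dsl = 2

include { FASTQC } from './modules/fastqc.nf'
include { ASSEMBLE } from './modules/assemble.nf'

workflow {
  reads = Channel.fromPath(params.reads)
  FASTQC(reads)
  ASSEMBLE(reads)
}
"""

_NFL_MODULE = """\
process {name} {{
  input:
    path reads
  output:
    path "{out}.txt"
  script:
    \"\"\"
    {cmd} $reads > {out}.txt
    \"\"\"
}}
"""

_SMK_MAIN = """\
include: "rules/qc.smk"
include: "rules/assemble.smk"

rule all:
    input:
        "results/assembly.fa"
"""

_SMK_RULE = """\
rule {name}:
    input:
        "tests/reads.fq"
    output:
        "results/{out}"
    shell:
        "{cmd} {{input}} > {{output}}"
"""


@dataclass
class FixtureRepo:
    root: str
    language: LanguageInfo
    defects: frozenset[str]
    metadata_path: str
    #: Scripted stub-WES outcome per test id (only non-COMPLETE entries).
    wes_script: dict[str, tuple[WesState, float]] = field(default_factory=dict)

    def read_metadata(self, strict: bool = False) -> WorkflowMetadata:
        with open(self.metadata_path, encoding="utf-8") as fh:
            return parse_metadata(fh.read(), dialect="yaml", strict=strict)

    @property
    def metadata_url(self) -> str:
        return file_url(self.metadata_path)


def _layout(language: LanguageType) -> tuple[str, dict[str, str], str]:
    """(primary path, dependent files, language version) for one language."""
    if language is LanguageType.CWL:
        deps = {
            "tools/seqkit_stats.cwl": _CWL_TOOL.format(cmd="seqkit", out="stats"),
            "tools/fastqc.cwl": _CWL_TOOL.format(cmd="fastqc", out="report"),
            "tools/fastp.cwl": _CWL_TOOL.format(cmd="fastp", out="trimmed"),
            "tools/platanus_b.cwl": _CWL_TOOL.format(cmd="platanus_b", out="contigs"),
        }
        return "main.cwl", deps, "v1.0"
    if language is LanguageType.WDL:
        deps = {
            "tasks/qc.wdl": _WDL_TASK.format(name="fastqc", cmd="fastqc"),
            "tasks/assemble.wdl": _WDL_TASK.format(name="assemble", cmd="platanus_b"),
        }
        return "main.wdl", deps, "1.0"
    if language is LanguageType.NFL:
        deps = {
            "modules/fastqc.nf": _NFL_MODULE.format(name="FASTQC", cmd="fastqc", out="report"),
            "modules/assemble.nf": _NFL_MODULE.format(name="ASSEMBLE", cmd="platanus_b", out="assembly"),
        }
        return "main.nf", deps, "DSL2"
    if language is LanguageType.SMK:
        deps = {
            "rules/qc.smk": _SMK_RULE.format(name="fastqc", cmd="fastqc", out="report.txt"),
            "rules/assemble.smk": _SMK_RULE.format(name="assemble", cmd="platanus_b", out="assembly.fa"),
        }
        return "Snakefile", deps, "7.32"
    raise ValueError(f"unsupported fixture language: {language}")


def _primary_text(language: LanguageType) -> str:
    return {
        LanguageType.CWL: _CWL_MAIN,
        LanguageType.WDL: _WDL_MAIN,
        LanguageType.NFL: _NFL_MAIN,
        LanguageType.SMK: _SMK_MAIN,
    }[language]


def _corrupt(language: LanguageType, text: str) -> str:
    """The minimal syntax defect per language."""
    if language is LanguageType.CWL:
        return text.replace("class: Workflow\n", "")
    if language in (LanguageType.WDL, LanguageType.NFL):
        idx = text.rfind("}")
        return text[:idx] + text[idx + 1 :]
    # SMK: a directive at inconsistent indentation inside the rule body
    return text.replace(
        '    input:\n        "results/assembly.fa"',
        '    input:\n        "results/assembly.fa"\n      output: "broken"',
        1,
    )


def generate_repo(
    language: LanguageType | str = LanguageType.CWL,
    defects: set[str] | frozenset[str] = frozenset(),
    seed: int = 0,
    root: str | os.PathLike | None = None,
) -> FixtureRepo:
    """Write a synthetic workflow repository; deterministic under ``seed``.

    With no defects, the repository's metadata satisfies every reusability
    requirement and its test case passes against a stub scripted COMPLETE.
    Each defect code applies the minimal mutation that violates exactly its
    corresponding requirement.  Regenerating with the same seed into the
    same root yields a byte-identical tree.
    """
    language = LanguageType(language)
    defects = frozenset(defects)
    unknown = defects - DEFECT_CODES
    if unknown:
        raise UnknownDefect(f"unrecognized defect codes: {sorted(unknown)}")
    if root is None:
        root = tempfile.mkdtemp(prefix="wfrepo-")
    root = os.path.abspath(os.fspath(root))
    if os.path.isdir(root) and os.listdir(root):
        shutil.rmtree(root)
    os.makedirs(root, exist_ok=True)

    primary_path, deps, lang_version = _layout(language)
    primary_text = _primary_text(language)
    if "syntax-error" in defects:
        primary_text = _corrupt(language, primary_text)

    tree: dict[str, str] = {primary_path: primary_text, **deps}
    tree["README.md"] = _README_TEXT
    tree["LICENSE"] = _LICENSE_TEXT
    tree["tests/wf_params.json"] = (
        '{"reads": {"class": "File", "path": "tests/reads.fq"}}\n'
        if language is LanguageType.CWL
        else '{"reads": "tests/reads.fq"}\n'
    )
    tree["tests/reads.fq"] = _READS

    if "missing-primary" in defects:
        del tree[primary_path]
    if "dangling-dependency" in defects:
        del tree[next(iter(deps))]
    if "missing-test-file" in defects:
        del tree["tests/reads.fq"]
    if "missing-readme" in defects:
        del tree["README.md"]

    for rel, text in tree.items():
        dest = os.path.join(root, rel)
        os.makedirs(os.path.dirname(dest), exist_ok=True)
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)

    url = lambda rel: file_url(os.path.join(root, rel))
    files = [FileEntry(url=url(primary_path), target=primary_path, role=FileRole.PRIMARY)]
    files += [FileEntry(url=url(p), target=p, role=FileRole.SECONDARY) for p in deps]
    testing = [
        TestCase(
            test_id="test_1",
            files=[
                FileEntry(url=url("tests/wf_params.json"), target="tests/wf_params.json", role=FileRole.TEST),
                FileEntry(url=url("tests/reads.fq"), target="tests/reads.fq", role=FileRole.TEST),
            ],
        )
    ]
    meta = WorkflowMetadata(
        id=new_workflow_id(seed),
        version="1.0.0",
        license="Apache-2.0",
        authors=[Author(account="fixture-author", name="Fixture Author", orcid=None)],
        name=f"toy-genome-assembly-{language.value.lower()}",
        readme_url=url("README.md"),
        language=LanguageInfo(type=language, version=lang_version),
        files=files,
        testing=testing,
    )

    if "bad-license" in defects:
        meta.license = "proprietary-eula"
    if "language-type-unknown" in defects:
        meta.language.type = LanguageType.UNKNOWN
    if "language-version-unknown" in defects:
        meta.language.version = UNKNOWN
    if "no-authors" in defects:
        meta.authors = [Author(account="fixture-author", name="")]
    if "bad-id" in defects:
        meta.id = "not-a-uuid"
    if "bad-version" in defects:
        meta.version = "one.zero"

    wes_script: dict[str, tuple[WesState, float]] = {}
    if "wes-executor-error" in defects:
        wes_script["test_1"] = (WesState.EXECUTOR_ERROR, 0.0)
    if "wes-system-error" in defects:
        wes_script["test_1"] = (WesState.SYSTEM_ERROR, 0.0)
    if "wes-canceled" in defects:
        wes_script["test_1"] = (WesState.CANCELED, 0.0)

    metadata_path = os.path.join(root, METADATA_FILENAME)
    with open(metadata_path, "w", encoding="utf-8") as fh:
        fh.write(serialize_metadata(meta, "yaml"))

    return FixtureRepo(
        root=root,
        language=LanguageInfo(type=language, version=lang_version),
        defects=defects,
        metadata_path=metadata_path,
        wes_script=wes_script,
    )


_CORPUS_LANGS = [LanguageType.CWL, LanguageType.WDL, LanguageType.NFL, LanguageType.SMK]


def generate_registry_corpus(
    n: int, seed: int = 0, root: str | os.PathLike | None = None
) -> list[FixtureRepo]:
    """n defect-free repositories with distinct ids and mixed languages."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if root is None:
        root = tempfile.mkdtemp(prefix="wfcorpus-")
    root = os.path.abspath(os.fspath(root))
    repos: list[FixtureRepo] = []
    for i in range(n):
        child_seed = (seed * 1_000_003 + i + 1) % (2**31)
        repos.append(
            generate_repo(
                language=_CORPUS_LANGS[i % len(_CORPUS_LANGS)],
                defects=frozenset(),
                seed=child_seed,
                root=os.path.join(root, f"repo-{i:03d}"),
            )
        )
    return repos
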