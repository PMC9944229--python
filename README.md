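# wfregistry

Build and operate a **FAIR workflow registry** without running a server:
validate workflow metadata against a fixed set of reusability requirements,
execute workflow test cases through the GA4GH **Workflow Execution Service
(WES)** run-request protocol, and publish accepted workflows as a static
GA4GH **Tool Registry Service (TRS)** response tree with persisted files and
a DOI.

## Who this is for

Bioinformatics communities that want to share CWL / WDL / Nextflow /
Snakemake workflows in a form others can actually reuse — with a license,
authors, documentation, resolvable dependencies, and passing tests — but do
not want to build and maintain a registry web application. The output of
this toolkit is a directory of JSON documents; any static file server (or
pages hosting) then *is* the registry API.

## The model

A workflow version is described by one metadata document (JSON or YAML)
that names everything by URL: the primary descriptor, dependent files, test
cases, license, and authors. The toolkit enforces eleven requirements,
grouped in three categories:

| Category      | Requirements |
|---------------|--------------|
| availability  | main workflow description resolves; dependent materials resolve; testing materials resolve; open-source license |
| validity      | language type declared; language version declared; language syntax valid |
| traceability  | authors and maintainers identified; documentation resolves; workflow ID is a UUID; metadata version well formed |

Testing follows the WES run-request model: each test case is submitted as a
run (descriptor URL, language type/version, a workflow-parameters document,
attachments), the run state is polled, and the test **passes exactly when
the terminal state is `COMPLETE`** — output content is deliberately not
compared, because correct outputs of heuristic tools need not be
byte-identical.

Publication is a three-phase lifecycle — *submission* (validate + test),
*review* (a human gate), *publication* (persist files via a pluggable
archiver, mint a DOI, rewrite metadata URLs to the persisted locations, and
emit the TRS tree). Nothing is archived or emitted unless validation and
all tests pass. The bundled local archiver mints deterministic DOIs under
`10.5072/…`, the reserved test prefix.

The TRS layout follows the 2.x path scheme: each version is served at
`/tools/{id}/versions/{version_id}` with exactly two sub-paths, `…/files`
(role→file-type mapping with SHA-256 checksums) and `…/tests` (the test
parameter documents), and the source metadata document is co-published
beside the version document.

## Worked example

Generate a synthetic CWL repository (a toy bacterial genome assembly that
chains four tool steps) and validate it:

```sh
wfregistry fixtures --language CWL --out /tmp/lab/assembly-wf --seed 5
wfregistry validate /tmp/lab/assembly-wf/workflow-metadata.yml
```

The report lists one result per requirement and exits 0 only on a full
pass:

```
overall: true
categories:
  availability: true
  validity: true
  traceability: true
results:
- requirement: Main workflow description
  category: availability
  passed: true
  detail: file:///tmp/lab/assembly-wf/main.cwl
...
- requirement: Workflow metadata version
  category: traceability
  passed: true
  detail: version '1.0.0'
```

Publishing runs the whole lifecycle and emits the static registry:

```sh
wfregistry publish /tmp/lab/assembly-wf/workflow-metadata.yml \
    --out /tmp/registry --archive-dir /tmp/archive
```

```
[submission] validate: 11/11 requirements satisfied
[submission] test: 1/1 test cases passed
[submission] stage-for-review: submission complete; awaiting review
[review] approve: review approved
[publication] persist-files: archived under DOI 10.5072/5bc8fbbc.1.0.0
[publication] rewrite-urls: 7 URLs rewritten; doi set
[publication] write-registry: 7 documents written to /tmp/registry
```

The output directory now serves the TRS API statically — six endpoint
documents plus the co-published metadata file:

```
tools/index.json
tools/5bc8fbbc-…/index.json
tools/5bc8fbbc-…/versions/index.json
tools/5bc8fbbc-…/versions/1.0.0/index.json
tools/5bc8fbbc-…/versions/1.0.0/files/index.json
tools/5bc8fbbc-…/versions/1.0.0/tests/index.json
tools/5bc8fbbc-…/versions/1.0.0/workflow-metadata.json
```

A submitter's flow from the shell is four subcommands: `make-template`
(draft the metadata from the primary descriptor URL), edit the draft in any
editor, then `validate`, `test`, and `pull-request` (which stages the
validated, tested submission for a reviewer).

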