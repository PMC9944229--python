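# Methods

This note documents the model behind the toolkit, the choices made where
the design was genuinely open, and what the synthetic fixtures do and do
not demonstrate.

## The reusability model

A workflow version is one metadata document. Every other artifact — the
primary descriptor, dependent tool/module descriptors, documentation, test
parameter files, test input data — is referenced by URL, so the document is
self-contained and the registry never hosts opaque state. The validator
evaluates eleven requirements in three categories (availability, validity,
traceability); all checks always run, so one validation pass yields a
complete defect report rather than stopping at the first failure.
"Accessible without restriction" is operationalized as *resolvable without
credentials*: availability checks always go through a resolver stripped of
any bearer token.

Two validator behaviors exist purely to keep defect reporting one-to-one:

- When the declared language type is UNKNOWN, the syntax check falls back
  to content-based language detection, so a wrong *declaration* fails only
  the language-type requirement while the descriptor itself can still be
  syntax-checked.
- When the primary descriptor does not resolve, the syntax check reports
  "not assessable" as a pass: the missing file is already flagged under the
  main-description requirement, and each defect should surface exactly
  once.

Schema validity and validation are deliberately different layers. Strict
parsing rejects structural problems (a non-UUID id is a schema error naming
the `id` field); lenient parsing (`parse_metadata(..., strict=False)`)
loads such a document anyway so the validator can report the same problem
as a failed traceability requirement. Template drafts sit between the
layers on purpose: they are always schema-valid, but fail validation until
the submitter fills in the author name and the test stub.

### The workflow-parameters convention

Test-case file entries carry only a role (`test`/`other`), so the toolkit
needs a rule for which file is the WES `workflow_params` document. The
convention: the file whose target basename (without extension) is
`wf_params` is the parameters document; `wf_engine_params` likewise names
the optional engine-parameters document; exactly one `wf_params` file per
test case is a schema invariant. Everything else in the test case is
attached to the run at its target path.

## Language inspection

Detection is rule-based and ordered: a top-level `cwlVersion` key ⇒ CWL; a
leading `version` statement plus a workflow/task block ⇒ WDL; a
process/workflow block together with Nextflow idioms (channel operators,
`params.*`, `nextflow.enable.dsl`) ⇒ NFL, with the DSL version taken from
the declaration when present and UNKNOWN otherwise; `rule name:` blocks or
a Snakefile filename ⇒ SMK. UNKNOWN is a value, not an error — the
validator turns it into a requirement failure. A Nextflow workflow that
omits its DSL declaration therefore fails the language-version requirement;
declaring the version in the metadata is the submitter's fix.

Syntax checking is intentionally shallow — structural checks (required
keys for CWL; balanced braces outside string literals and comments for WDL
and Nextflow; rule blocks and consistent directive indentation for
Snakemake) rather than full parses. Deep validation belongs to each
language's own tooling; the shallow layer catches the broken-file defect
class a registry needs to reject while keeping the toolkit free of
language-toolchain dependencies. Dependency enumeration is similarly
syntactic (`run`/`$import`/`$include`, `import`, `include ... from`,
`include:`), deduplicated in declaration order; absolute-URL targets are
reported with a remote flag and availability-checked by the validator.

## Resolver and transports

All file access goes through one resolver contract. `file://` URLs read
the filesystem directly; `http(s)://` URLs go through an injectable
transport callable, which is how the tests script remote behavior without
sockets. Not-found (HTTP 404/410, missing local path) and transport
failure (timeout, refused connection, persistent 5xx) are strictly
distinct: the former is a metadata defect and a validation verdict, the
latter is an environment problem and an exception. Transport failures are
retried up to 3 times with exponential backoff (factor 2, initial 1 s,
10 s timeout) — conventional values, all configurable.

Repository facts come from walking a local directory (owner/repo from the
last two path segments, `default_ref` fixed to "main", license read from a
LICENSE file) or from decomposing the blob/raw URL shapes of the dominant
code-hosting service; other hosts are treated as opaque resolvable URLs.
License identification prefers an explicit `SPDX-License-Identifier:` line
and otherwise matches a short list of well-known license headers. The
accepted license vocabulary is a bundled list of 30 common OSI-approved
SPDX identifiers; an unknown identifier is a validation failure, not a
parse failure.

## WES testing

The runner submits a run, polls at `poll_interval` (default 5 s; tests and
the acceptance script use a deterministic fake clock), and stops at a
terminal state or at `timeout` (default 3600 s), which maps to
SYSTEM_ERROR. Pass ⇔ COMPLETE, exactly; transport failures during submit
or poll also become SYSTEM_ERROR results rather than exceptions, because an
unrunnable test is a failed test from the registry's point of view.
Unrecognized server states map to SYSTEM_ERROR (fail safe). Tests run
sequentially with no short-circuit, so a multi-test report is always
complete. The built-in stub executor implements the minimal WES surface
(submit → run id; poll → QUEUED → RUNNING → scripted terminal state after a
scripted delay) and is behaviorally interchangeable with the HTTP client —
the suite runs the same scenarios against both.

No output-content evaluation is performed: a COMPLETE state shows the
computation ran, not that its outputs are scientifically right. Comparing
outputs across runs of heuristic tools is a research problem of its own and
is out of scope here.

## Publication

The lifecycle is submission → review → publication, forward-only. The
two-call API (`submit`, then `approve_and_publish`) leaves room for a human
reviewer between testing and persistence; `publish` composes both for
auto-approved use. Atomicity: the archive and the registry output
directory are written only after validation and all tests pass, so a failed
pipeline leaves both untouched. A rejected submission is restarted from
the submission phase after edits; there is no resume.

The bundled archiver persists into a local directory and mints
deterministic DOIs `10.5072/<first 8 id hex>.<version>` — the 10.5072
prefix is reserved for testing, so these are valid-shaped and can never
collide with production identifiers. URL rewriting replaces every file URL
(including test files) with its persisted location and sets the DOI;
everything else is untouched, and the rewritten document re-validates
against the archive — a closure property the suite asserts. Per-test log
excerpts are retained alongside the staged submission record, so test
provenance does not expire with any CI artifact retention window.

TRS output targets the 2.x document shapes, restricted to the three
per-version paths plus the three listing paths; endpoints never mentioned
by the registry's consumers (container files, service-info) are omitted
rather than stubbed. `verified`/`verified_source` encode the
test-before-publish guarantee. Checksums are SHA-256 (configurable; the
algorithm is named in the checksum object, as TRS requires). Documents are
written as `<path>/index.json` so plain static hosting serves extensionless
API paths; serialization is deterministic, making registry output
byte-reproducible.

## Synthetic fixtures

The fixture generator emulates a small community workflow repository: a
primary descriptor chaining four named tool steps (read statistics, read
QC, trimming, assembly — the shape of a bacterial genome assembly), two to
four dependent descriptors, README, a short Apache-2.0 LICENSE header, a
workflow-parameters file, a tiny FASTQ input, and a complete metadata
document, in each of the four languages. Defect injection is the core
design: one code per requirement, each applying the *minimal* mutation that
violates exactly that requirement, plus codes that script the stub WES to
fail. The generator/validator closure — zero defects pass everything, one
defect fails exactly one check — is the backbone of the test suite.

What the fixtures do **not** show: descriptors are never executed by a real
engine (run outcomes are scripted), remote hosting is mocked at the
transport layer, and the toy descriptors exercise structural, not
semantic, complexity. Passing here demonstrates the registry machinery —
validation logic, protocol plumbing, lifecycle gating, layout and
determinism — not that any particular real workflow runs.

## Problem sizes and numerics

The suite and the acceptance script use desk-scale sizes chosen to make the
properties exhaustive rather than sampled: all 4 languages × 11 defect
codes for isolation (44 cases), 100 randomized metadata documents per
dialect for round-trip identity, all 4 terminal WES states plus the timeout
path, and registry corpora of 5 workflows. Polling loops run on an
injected fake clock, so timing semantics (QUEUED/RUNNING sequences,
timeout at 2 s against a 100 s run) are tested deterministically and in
milliseconds. Seeds control workflow-id generation and fixture layout;
regenerating a fixture with the same seed into the same root is
byte-identical.

## Known limitations

- Shallow syntax checks accept some files a full language parser would
  reject (e.g. type errors inside a CWL step).
- Hosting-URL inspection understands one host family's blob/raw shapes;
  other forges fall back to opaque-URL resolution without repository facts.
- One workflow version per metadata document; multi-workflow documents are
  unsupported by design.
- Rate-limit responses from remote services are treated as transport
  errors, not as a distinct outcome.
- The license vocabulary is a fixed list; registries with unusual licenses
  must extend it in code.
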