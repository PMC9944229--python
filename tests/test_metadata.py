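"""Metadata model: parsing, invariants, serialization round-trips."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from wfregistry.metadata import (
    Author,
    FileEntry,
    FileRole,
    InvariantError,
    LanguageInfo,
    LanguageType,
    SchemaError,
    TestCase,
    WorkflowMetadata,
    new_workflow_id,
    parse_metadata,
    serialize_metadata,
)

MINIMAL_YAML = """\
id: 123e4567-e89b-42d3-a456-426614174000
version: "1.0.0"
license: Apache-2.0
authors:
  - account: alice
    name: Alice Example
name: toy workflow
readme_url: file:///repo/README.md
language:
  type: CWL
  version: v1.0
files:
  - url: file:///repo/main.cwl
    target: main.cwl
    role: primary
testing:
  - test_id: test_1
    files:
      - url: file:///repo/tests/wf_params.json
        target: tests/wf_params.json
        role: test
"""


def make_meta(**overrides) -> WorkflowMetadata:
    base = dict(
        id="123e4567-e89b-42d3-a456-426614174000",
        version="1.0.0",
        license="MIT",
        authors=[Author(account="alice", name="Alice")],
        name="wf",
        readme_url="file:///repo/README.md",
        language=LanguageInfo(LanguageType.CWL, "v1.0"),
        files=[FileEntry("file:///repo/main.cwl", "main.cwl", FileRole.PRIMARY)],
        testing=[
            TestCase(
                "t1",
                [FileEntry("file:///repo/wf_params.json", "tests/wf_params.json", FileRole.TEST)],
            )
        ],
    )
    base.update(overrides)
    return WorkflowMetadata(**base)


class TestParse:
    def test_minimal_yaml_document(self):
        meta = parse_metadata(MINIMAL_YAML, dialect="yaml")
        assert meta.id == "123e4567-e89b-42d3-a456-426614174000"
        assert meta.language.type is LanguageType.CWL
        assert meta.language.version == "v1.0"
        assert meta.primary_file.target == "main.cwl"
        assert meta.authors[0].name == "Alice Example"
        assert meta.testing[0].test_id == "test_1"
        assert meta.doi is None

    def test_auto_dialect_tries_json_then_yaml(self):
        meta_yaml = parse_metadata(MINIMAL_YAML, dialect="auto")
        as_json = serialize_metadata(meta_yaml, "json")
        meta_json = parse_metadata(as_json, dialect="auto")
        assert meta_json == meta_yaml

    def test_two_primary_files_rejected(self):
        meta = parse_metadata(MINIMAL_YAML)
        meta.files.append(FileEntry("file:///x", "other.cwl", FileRole.PRIMARY))
        with pytest.raises(InvariantError, match="exactly one primary"):
            meta.check_invariants()

    def test_bad_uuid_is_schema_error_naming_id(self):
        doc = MINIMAL_YAML.replace("123e4567-e89b-42d3-a456-426614174000", "not-a-uuid")
        with pytest.raises(SchemaError) as exc:
            parse_metadata(doc)
        assert exc.value.field_path == "id"

    def test_lenient_parse_defers_invariants(self):
        doc = MINIMAL_YAML.replace("123e4567-e89b-42d3-a456-426614174000", "not-a-uuid")
        meta = parse_metadata(doc, strict=False)
        assert meta.id == "not-a-uuid"
        assert any(f.startswith("id:") for f in meta.invariant_failures())

    def test_unknown_top_level_keys_preserved(self):
        doc = MINIMAL_YAML + "x_custom: {note: kept}\n"
        meta = parse_metadata(doc)
        assert meta.extras == {"x_custom": {"note": "kept"}}
        assert "x_custom" in serialize_metadata(meta, "yaml")

    @pytest.mark.parametrize(
        "mutate, field_hint",
        [
            (lambda m: setattr(m, "version", "one.zero"), "version"),
            (lambda m: setattr(m, "name", ""), "name"),
            (lambda m: setattr(m.files[0], "target", "/abs/path"), "target"),
            (lambda m: setattr(m.files[0], "target", "../escape"), "target"),
            (lambda m: setattr(m.authors[0], "account", ""), "account"),
            (lambda m: setattr(m.authors[0], "orcid", "12-34"), "orcid"),
            (lambda m: setattr(m, "testing", []), "testing"),
            (
                lambda m: m.testing.__setitem__(
                    0, TestCase("t1", [FileEntry("u", "tests/other.json", FileRole.TEST)])
                ),
                "workflow-parameters",
            ),
        ],
    )
    def test_rejection_names_the_mutated_field(self, mutate, field_hint):
        meta = make_meta()
        mutate(meta)
        failures = meta.invariant_failures()
        assert failures and any(field_hint in f for f in failures)

    def test_duplicate_targets_rejected(self):
        meta = make_meta()
        meta.files.append(FileEntry("file:///y", "main.cwl", FileRole.SECONDARY))
        assert any("duplicate target" in f for f in meta.invariant_failures())


class TestSerialize:
    @pytest.mark.parametrize("dialect", ["json", "yaml"])
    def test_round_trip_identity(self, dialect):
        meta = make_meta()
        text = serialize_metadata(meta, dialect)
        assert parse_metadata(text, dialect=dialect) == meta

    def test_serialization_is_deterministic(self):
        meta = make_meta()
        assert serialize_metadata(meta, "json") == serialize_metadata(meta, "json")
        assert serialize_metadata(meta, "yaml") == serialize_metadata(meta, "yaml")

    def test_doi_emitted_only_when_set(self):
        without = make_meta()
        withdoi = make_meta(doi="10.5072/abc.1.0.0")
        assert "doi" not in serialize_metadata(without, "json")
        assert "10.5072/abc.1.0.0" in serialize_metadata(withdoi, "json")


class TestWorkflowId:
    def test_seeded_ids_reproducible(self):
        assert new_workflow_id(1) == new_workflow_id(1)
        assert new_workflow_id(1) != new_workflow_id(2)

    def test_uuid4_shape(self):
        pat = re.compile(r"^[0-9a-f]{8}-[0-9a-f]{4}-4[0-9a-f]{3}-[89ab][0-9a-f]{3}-[0-9a-f]{12}$")
        assert pat.match(new_workflow_id(99))
        assert pat.match(new_workflow_id())

    def test_unseeded_draws_distinct(self):
        assert len({new_workflow_id() for _ in range(10_000)}) == 10_000


# ---------------------------------------------------------------------------
# randomized round-trip property

_names = st.text(
    alphabet=st.characters(whitelist_categories=("Ll", "Lu", "Nd"), whitelist_characters=" -_"),
    min_size=1,
    max_size=20,
).map(str.strip).filter(bool)

_targets = st.lists(
    st.from_regex(r"[a-z][a-z0-9]{0,8}(/[a-z][a-z0-9]{0,8}){0,2}\.[a-z]{2,4}", fullmatch=True),
    min_size=1,
    max_size=4,
    unique=True,
)


@st.composite
def metadata_documents(draw):
    seed = draw(st.integers(0, 2**31 - 1))
    targets = draw(_targets)
    files = [
        FileEntry(f"file:///repo/{t}", t, FileRole.PRIMARY if i == 0 else FileRole.SECONDARY)
        for i, t in enumerate(targets)
    ]
    authors = [
        Author(
            account=draw(_names),
            name=draw(st.one_of(st.just(""), _names)),
            orcid=draw(st.one_of(st.none(), st.just("0000-0002-1825-0097"))),
        )
        for _ in range(draw(st.integers(1, 3)))
    ]
    testing = [
        TestCase(
            test_id=f"case_{i}",
            files=[
                FileEntry(f"file:///repo/tests/{i}/wf_params.json", f"tests/{i}/wf_params.json", FileRole.TEST),
                FileEntry(f"file:///repo/tests/{i}/data.txt", f"tests/{i}/data.txt", FileRole.OTHER),
            ],
        )
        for i in range(draw(st.integers(1, 2)))
    ]
    return WorkflowMetadata(
        id=new_workflow_id(seed),
        version=".".join(str(draw(st.integers(0, 20))) for _ in range(draw(st.integers(1, 3)))),
        license=draw(st.sampled_from(["Apache-2.0", "MIT", "GPL-3.0-only"])),
        authors=authors,
        name=draw(_names),
        readme_url="file:///repo/README.md",
        language=LanguageInfo(
            draw(st.sampled_from([LanguageType.CWL, LanguageType.WDL, LanguageType.NFL, LanguageType.SMK])),
            draw(st.sampled_from(["v1.0", "1.0", "DSL2", "7.32"])),
        ),
        files=files,
        testing=testing,
        doi=draw(st.one_of(st.none(), st.just("10.5072/ab12cd34.1.0.0"))),
        extras=draw(st.dictionaries(st.from_regex(r"x_[a-z]{1,8}", fullmatch=True), _names, max_size=2)),
    )


@settings(max_examples=100, derandomize=True, deadline=None)
@given(meta=metadata_documents(), dialect=st.sampled_from(["json", "yaml"]))
def test_parse_serialize_identity_on_random_documents(meta, dialect):
    meta.check_invariants()
    assert parse_metadata(serialize_metadata(meta, dialect), dialect=dialect) == meta
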