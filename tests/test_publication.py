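"""Three-phase lifecycle: persistence, URL rewriting, gated publication."""

import os

import pytest

from wfregistry.metadata import serialize_metadata
from wfregistry.publication import (
    LocalArchiver,
    Phase,
    approve_and_publish,
    persist_files,
    publish,
    rewrite_urls,
    submit,
)
from wfregistry.validator import validate
from wfregistry.wes import StubWes, WesState


@pytest.fixture
def archiver(tmp_path):
    return LocalArchiver(tmp_path / "archive")


def _fast(fake_time):
    return dict(poll_interval=0.01, timeout=5, sleep=fake_time.sleep)


class TestPersistence:
    def test_receipt_covers_every_file_with_test_prefix_doi(
        self, cwl_repo, resolver, archiver
    ):
        meta = cwl_repo.read_metadata()
        receipt = persist_files(meta, archiver, resolver)
        assert receipt.doi.startswith("10.5072/")
        expected_urls = {f.url for f in meta.files}
        for t in meta.testing:
            expected_urls |= {f.url for f in t.files}
        assert set(receipt.persisted_urls) == expected_urls
        for persisted in receipt.persisted_urls.values():
            assert resolver.resolve(persisted).exists

    def test_repeat_persistence_is_doi_idempotent(self, cwl_repo, resolver, archiver):
        meta = cwl_repo.read_metadata()
        r1 = persist_files(meta, archiver, resolver)
        r2 = persist_files(meta, archiver, resolver)
        assert r1.doi == r2.doi

    def test_rewrite_substitutes_urls_and_sets_doi(self, cwl_repo, resolver, archiver):
        meta = cwl_repo.read_metadata()
        receipt = persist_files(meta, archiver, resolver)
        rewritten = rewrite_urls(meta, receipt)
        assert rewritten.doi == receipt.doi
        for f in rewritten.files:
            assert f.url.startswith("file://") and str(archiver.archive_dir) in f.url
        # untouched fields are identical
        assert rewritten.name == meta.name
        assert rewritten.authors == meta.authors
        assert [t.test_id for t in rewritten.testing] == [t.test_id for t in meta.testing]
        # and the original is unmodified
        assert meta.doi is None

    def test_rewritten_metadata_revalidates_against_archive(
        self, cwl_repo, resolver, archiver
    ):
        meta = cwl_repo.read_metadata()
        rewritten = rewrite_urls(meta, persist_files(meta, archiver, resolver))
        report = validate(rewritten, resolver)
        assert report.overall, [r.detail for r in report.failed]

    def test_missing_receipt_entry_is_an_error(self, cwl_repo, resolver, archiver):
        meta = cwl_repo.read_metadata()
        receipt = persist_files(meta, archiver, resolver)
        del receipt.persisted_urls[meta.primary_file.url]
        with pytest.raises(KeyError):
            rewrite_urls(meta, receipt)


class TestLifecycle:
    def test_full_publish_traverses_three_phases_in_order(
        self, cwl_repo, resolver, archiver, tmp_path, fake_time
    ):
        meta = cwl_repo.read_metadata()
        out = tmp_path / "registry"
        record = publish(
            meta, resolver, StubWes(clock=fake_time.clock), archiver, out,
            **_fast(fake_time),
        )
        assert record.succeeded
        assert record.phases_traversed == [
            Phase.SUBMISSION, Phase.REVIEW, Phase.PUBLICATION,
        ]
        assert (out / "tools" / "index.json").is_file()

    def test_validation_defect_halts_in_submission(
        self, repo_factory, resolver, archiver, tmp_path, fake_time
    ):
        repo = repo_factory(defects={"bad-license"})
        out = tmp_path / "registry"
        record = publish(
            repo.read_metadata(), resolver, StubWes(clock=fake_time.clock),
            archiver, out, **_fast(fake_time),
        )
        assert not record.succeeded
        assert record.phases_traversed == [Phase.SUBMISSION]
        assert record.events[-1].action == "validate"
        assert not out.exists()
        assert not os.path.exists(archiver.archive_dir)

    def test_test_failure_halts_before_persist(
        self, repo_factory, resolver, archiver, tmp_path, fake_time
    ):
        repo = repo_factory(defects={"wes-executor-error"})
        out = tmp_path / "registry"
        record = publish(
            repo.read_metadata(), resolver,
            StubWes(repo.wes_script, clock=fake_time.clock),
            archiver, out, **_fast(fake_time),
        )
        assert not record.succeeded
        assert record.phases_traversed == [Phase.SUBMISSION]
        assert [e.action for e in record.events] == ["validate", "test"]
        assert not out.exists()
        assert not os.path.exists(archiver.archive_dir)

    def test_two_call_mode_inserts_review_gate(
        self, cwl_repo, resolver, archiver, tmp_path, fake_time
    ):
        meta = cwl_repo.read_metadata()
        record = submit(
            meta, resolver, StubWes(clock=fake_time.clock), **_fast(fake_time)
        )
        assert record.succeeded and record.phase is Phase.SUBMISSION
        record, published = approve_and_publish(
            meta, record, resolver, archiver, tmp_path / "registry"
        )
        assert record.phase is Phase.PUBLICATION
        assert published is not None and published.doi.startswith("10.5072/")

    def test_approval_without_submission_refused(
        self, cwl_repo, resolver, archiver, tmp_path
    ):
        from wfregistry.publication import LifecycleRecord

        record, published = approve_and_publish(
            cwl_repo.read_metadata(), LifecycleRecord(), resolver, archiver,
            tmp_path / "registry",
        )
        assert published is None and not record.succeeded

    def test_exactly_two_metadata_documents_per_published_version(
        self, cwl_repo, resolver, archiver, tmp_path, fake_time
    ):
        meta = cwl_repo.read_metadata()
        out = tmp_path / "registry"
        publish(
            meta, resolver, StubWes(clock=fake_time.clock), archiver, out,
            **_fast(fake_time),
        )
        vdir = out / "tools" / meta.id / "versions" / meta.version
        docs = sorted(p.name for p in vdir.iterdir() if p.is_file())
        assert docs == ["index.json", "workflow-metadata.json"]

    def test_phase_cannot_move_backwards(self):
        from wfregistry.publication import LifecycleRecord

        record = LifecycleRecord()
        record.advance(Phase.PUBLICATION)
        with pytest.raises(ValueError):
            record.advance(Phase.SUBMISSION)
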