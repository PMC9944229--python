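"""WES test runner: run requests, stub executor, polling semantics."""

import json

import pytest

from conftest import FakeTime, ScriptedTransport
from wfregistry.resources import Resolver
from wfregistry.wes import (
    HttpWesClient,
    StubWes,
    WesState,
    build_run_request,
    run_all_tests,
    run_test,
)


class TestBuildRunRequest:
    def test_request_mirrors_metadata_and_params(self, cwl_repo, resolver):
        meta = cwl_repo.read_metadata()
        req = build_run_request(meta, meta.testing[0], resolver)
        assert req.workflow_type == "CWL"
        assert req.workflow_type_version == "v1.0"
        assert json.loads(req.workflow_params) == {
            "reads": {"class": "File", "path": "tests/reads.fq"}
        }
        assert req.workflow_url == meta.primary_file.url
        assert req.test_id == "test_1"
        # the data file rides along as an attachment at its target path
        assert [t for t, _ in req.attachments] == ["tests/reads.fq"]

    def test_params_only_test_case_has_no_attachments(self, cwl_repo, resolver):
        meta = cwl_repo.read_metadata()
        meta.testing[0].files = [meta.testing[0].files[0]]  # keep wf_params only
        req = build_run_request(meta, meta.testing[0], resolver)
        assert req.attachments == []

    def test_unresolvable_test_file_is_an_error(self, cwl_repo, resolver, tmp_path):
        meta = cwl_repo.read_metadata()
        meta.testing[0].files[1].url = f"file://{tmp_path}/gone.fq"
        with pytest.raises(FileNotFoundError):
            build_run_request(meta, meta.testing[0], resolver)

    def test_foreign_test_case_rejected(self, cwl_repo, resolver):
        meta = cwl_repo.read_metadata()
        other = cwl_repo.read_metadata().testing[0]
        other.test_id = "alien"
        with pytest.raises(ValueError):
            build_run_request(meta, other, resolver)


def _request(test_id="t1"):
    from wfregistry.wes import WesRunRequest

    return WesRunRequest(
        workflow_url="file:///repo/main.cwl",
        workflow_type="CWL",
        workflow_type_version="v1.0",
        workflow_params="{}",
        test_id=test_id,
    )


class TestStub:
    @pytest.mark.parametrize(
        "terminal",
        [WesState.COMPLETE, WesState.EXECUTOR_ERROR, WesState.SYSTEM_ERROR, WesState.CANCELED],
    )
    def test_passed_iff_complete(self, terminal, fake_time):
        stub = StubWes({"t1": (terminal, 0.0)}, clock=fake_time.clock)
        result = run_test(
            _request(), stub, poll_interval=0.1, timeout=10,
            sleep=fake_time.sleep, clock=fake_time.clock,
        )
        assert result.state is terminal
        assert result.passed is (terminal is WesState.COMPLETE)

    def test_zero_delay_terminal_on_first_poll(self, fake_time):
        stub = StubWes({"t1": (WesState.COMPLETE, 0.0)}, clock=fake_time.clock)
        run_id = stub.submit(_request())
        assert stub.status(run_id) is WesState.COMPLETE
        assert stub.polls_for(run_id) == 1

    def test_delayed_run_is_polled_repeatedly(self, fake_time):
        stub = StubWes({"t1": (WesState.COMPLETE, 1.0)}, clock=fake_time.clock)
        result = run_test(
            _request(), stub, poll_interval=0.2, timeout=30,
            sleep=fake_time.sleep, clock=fake_time.clock,
        )
        assert result.passed
        assert len(stub.poll_log) >= 2  # observed QUEUED/RUNNING before terminal

    def test_timeout_maps_to_system_error(self, fake_time):
        stub = StubWes({"t1": (WesState.COMPLETE, 60.0)}, clock=fake_time.clock)
        result = run_test(
            _request(), stub, poll_interval=0.5, timeout=2.0,
            sleep=fake_time.sleep, clock=fake_time.clock,
        )
        assert result.state is WesState.SYSTEM_ERROR
        assert not result.passed
        assert "timed out" in result.log_excerpt
        assert fake_time.now <= 2.5

    def test_unknown_run_id_not_found(self, fake_time):
        stub = StubWes({}, clock=fake_time.clock)
        with pytest.raises(KeyError):
            stub.status("no-such-run")

    def test_concurrent_runs_isolated(self, fake_time):
        stub = StubWes(
            {"a": (WesState.COMPLETE, 0.0), "b": (WesState.EXECUTOR_ERROR, 0.0)},
            clock=fake_time.clock,
        )
        ra, rb = stub.submit(_request("a")), stub.submit(_request("b"))
        assert ra != rb
        assert stub.status(ra) is WesState.COMPLETE
        assert stub.status(rb) is WesState.EXECUTOR_ERROR


class TestHttpBackend:
    def _scripted_wes_transport(self, states):
        """Minimal WES HTTP surface over the scripted-transport protocol."""
        remaining = list(states)

        def transport(url, timeout, token):
            if "/runs?" in url:
                return 200, json.dumps({"run_id": "run-1"}).encode()
            if url.endswith("/runs/run-1/status"):
                state = remaining.pop(0) if len(remaining) > 1 else remaining[0]
                return 200, json.dumps({"state": state}).encode()
            return 404, b""

        return transport

    def test_http_and_stub_backends_agree(self, fake_time):
        http = HttpWesClient(
            "http://wes.example/ga4gh/wes/v1",
            transport=self._scripted_wes_transport(["QUEUED", "RUNNING", "COMPLETE"]),
        )
        stub = StubWes({"t1": (WesState.COMPLETE, 0.4)}, clock=fake_time.clock)
        kwargs = dict(poll_interval=0.2, timeout=10, sleep=fake_time.sleep, clock=fake_time.clock)
        res_http = run_test(_request(), http, **kwargs)
        res_stub = run_test(_request(), stub, **kwargs)
        assert res_http.state is res_stub.state is WesState.COMPLETE
        assert res_http.passed and res_stub.passed

    def test_unrecognized_server_state_fails_safe(self):
        http = HttpWesClient(
            "http://wes.example", transport=self._scripted_wes_transport(["WEIRD"])
        )
        assert http.status("run-1") is WesState.SYSTEM_ERROR

    def test_submit_transport_failure_is_system_error_verdict(self, fake_time):
        def broken(url, timeout, token):
            raise OSError("connection refused")

        http = HttpWesClient("http://wes.example", transport=broken)
        result = run_test(
            _request(), http, poll_interval=0.1, timeout=5,
            sleep=fake_time.sleep, clock=fake_time.clock,
        )
        assert result.state is WesState.SYSTEM_ERROR
        assert "submission failed" in result.log_excerpt


class TestRunAll:
    def _two_test_meta(self, cwl_repo):
        meta = cwl_repo.read_metadata()
        second = cwl_repo.read_metadata().testing[0]
        second.test_id = "test_2"
        meta.testing.append(second)
        return meta

    def test_all_complete_aggregate_pass(self, cwl_repo, resolver, fake_time):
        meta = self._two_test_meta(cwl_repo)
        stub = StubWes({}, clock=fake_time.clock)  # default COMPLETE
        results = run_all_tests(
            meta, stub, resolver, poll_interval=0.1, timeout=5,
            sleep=fake_time.sleep, clock=fake_time.clock,
        )
        assert [r.test_id for r in results] == ["test_1", "test_2"]
        assert all(r.passed for r in results)

    def test_one_failure_no_short_circuit(self, cwl_repo, resolver, fake_time):
        meta = self._two_test_meta(cwl_repo)
        stub = StubWes(
            {"test_1": (WesState.EXECUTOR_ERROR, 0.0)}, clock=fake_time.clock
        )
        results = run_all_tests(
            meta, stub, resolver, poll_interval=0.1, timeout=5,
            sleep=fake_time.sleep, clock=fake_time.clock,
        )
        assert len(results) == 2
        assert not results[0].passed and results[1].passed
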