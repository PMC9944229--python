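import pytest

from wfregistry import LanguageType, Resolver
from wfregistry.fixtures import generate_repo


class FakeTime:
    """Deterministic clock/sleep pair for polling loops."""

    def __init__(self, start: float = 0.0):
        self.now = start

    def clock(self) -> float:
        return self.now

    def sleep(self, seconds: float) -> None:
        self.now += seconds


class ScriptedTransport:
    """HTTP transport whose responses are scripted per URL.

    ``script`` maps a URL to a list of (status, body) responses, consumed
    one per call (the last repeats).  Unknown URLs get 404.
    """

    def __init__(self, script: dict[str, list[tuple[int, bytes]]]):
        self.script = {u: list(rs) for u, rs in script.items()}
        self.calls: list[str] = []

    def __call__(self, url: str, timeout: float, token: str | None):
        self.calls.append(url)
        responses = self.script.get(url)
        if not responses:
            return 404, b""
        if len(responses) > 1:
            return responses.pop(0)
        return responses[0]


@pytest.fixture
def fake_time():
    return FakeTime()


@pytest.fixture
def resolver():
    return Resolver(sleep=lambda s: None)


@pytest.fixture
def cwl_repo(tmp_path):
    """A defect-free CWL fixture repository under owner/repo path segments."""
    return generate_repo(
        LanguageType.CWL, seed=7, root=tmp_path / "fixture-owner" / "toy-assembly"
    )


@pytest.fixture
def repo_factory(tmp_path):
    """generate_repo with an auto-allocated root inside tmp_path."""
    counter = {"n": 0}

    def factory(language="CWL", defects=frozenset(), seed=7):
        counter["n"] += 1
        return generate_repo(
            language,
            defects=defects,
            seed=seed,
            root=tmp_path / f"owner{counter['n']}" / "repo",
        )

    return factory
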