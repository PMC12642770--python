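"""Chat-completion backends: mock oracle, record/replay, hosted adapter.

Every backend satisfies one contract: ``complete(CompletionRequest) -> str``.
The workhorse here is :class:`MockBackend`, a deterministic stand-in whose
answers are derived from the combinatorial reference fragmenter. It lets
the whole pipeline run and be tested offline, and — because its error
modes are configurable — it exercises the filtering machinery the same way
a fallible generative model would:

* ``corruption_rate`` replaces a seeded fraction of fragment entries with
  chemically invalid strings or valid-but-not-substructure decoys;
* ``drop_rate`` omits a seeded fraction of entries entirely;
* ``intensity_heuristic`` chooses how mock intensity levels are formed
  (``mass_fraction``: level = max(1, round(10 * fragment mass / parent
  mass)); ``uniform``: a constant mid-scale level).

Determinism: for a fixed config seed, a given request text always yields
the same response (the per-request RNG is seeded from the config seed and
a CRC of the user text).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Protocol, Tuple

import numpy as np

from .chem import MoleculeRecord, parse_molecule
from .fragmenter import enumerate_fragments
from .prompting import (
    TAG_FRAGMENTS_MZ,
    TAG_FRAGMENT_TASK,
    TAG_INTENSITY_TASK,
    TAG_MOL,
    extract_payload,
)


class BackendError(RuntimeError):
    """Raised when a backend cannot produce a response."""


@dataclass(frozen=True)
class CompletionRequest:
    """One chat-completion call: system + user text at a temperature."""

    system_text: str
    user_text: str
    temperature: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.temperature <= 1.0:
            raise ValueError("temperature must be in [0, 1]")


class Backend(Protocol):
    def complete(self, request: CompletionRequest) -> str: ...


@dataclass
class MockOracleConfig:
    """Error-injection and heuristic settings for the mock oracle."""

    corruption_rate: float = 0.0
    drop_rate: float = 0.0
    seed: int = 0
    fragment_depth: int = 2
    intensity_heuristic: str = "mass_fraction"  # or "uniform"
    scale_max: int = 10

    def __post_init__(self):
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0, 1]")
        if not 0.0 <= self.drop_rate <= 1.0:
            raise ValueError("drop_rate must be in [0, 1]")
        if self.intensity_heuristic not in ("mass_fraction", "uniform"):
            raise ValueError(f"unknown intensity heuristic {self.intensity_heuristic!r}")


def _request_rng(config: MockOracleConfig, user_text: str) -> np.random.Generator:
    digest = zlib.crc32(user_text.encode("utf-8"))
    return np.random.default_rng([config.seed % (2**31), digest])


def _parent_from_prompt(user_text: str) -> Tuple[MoleculeRecord, str]:
    payload = extract_payload(user_text, TAG_MOL)
    if not isinstance(payload, dict):
        raise BackendError("mock oracle: prompt carries no <<MOL>> payload")
    for dialect in ("smiles", "selfies"):
        if dialect in payload:
            return parse_molecule(payload[dialect], dialect=dialect), dialect
    raise BackendError("mock oracle: <<MOL>> payload has no recognized dialect key")


def _heuristic_level(fragment_mass: float, parent_mass: float, config: MockOracleConfig) -> int:
    if config.intensity_heuristic == "uniform":
        return max(1, config.scale_max // 2)
    level = int(round(config.scale_max * fragment_mass / parent_mass))
    return min(config.scale_max, max(1, level))


def mock_answer(request: CompletionRequest, config: MockOracleConfig) -> str:
    """Deterministic oracle response for a recognized task prompt."""
    text = request.user_text
    if TAG_FRAGMENT_TASK in text:
        return _mock_fragment_answer(text, config)
    if TAG_INTENSITY_TASK in text:
        return _mock_intensity_answer(text, config)
    raise BackendError("mock oracle: no recognized task tag in prompt")

def _mock_fragment_answer(user_text: str, config: MockOracleConfig) -> str:
    parent, dialect = _parent_from_prompt(user_text)
    fragments = enumerate_fragments(parent, max_depth=config.fragment_depth)
    ordered = sorted(
        fragments,
        key=lambda f: (
            -_heuristic_level(f.monoisotopic_mass, parent.monoisotopic_mass, config),
            -f.monoisotopic_mass,
            f.canonical_key,
        ),
    )
    rng = _request_rng(config, user_text)
    out: List[str] = []
    # two corruption flavors: an undecodable string, and a valid molecule
    # that cannot embed in the parent (two disconnected parent copies).
    non_substructure = f"{parent.smiles}.{parent.smiles}"
    for fragment in ordered:
        if rng.random() < config.drop_rate:
            continue
        if rng.random() < config.corruption_rate:
            out.append("not-a-molecule(((" if rng.random() < 0.5 else non_substructure)
        else:
            out.append(fragment.string(dialect))
    return json.dumps(out)


def _mock_intensity_answer(user_text: str, config: MockOracleConfig) -> str:
    parent, dialect = _parent_from_prompt(user_text)
    payload = extract_payload(user_text, TAG_FRAGMENTS_MZ)
    if not isinstance(payload, list):
        raise BackendError("mock oracle: intensity prompt carries no <<FRAGMENTS_MZ>> payload")
    rng = _request_rng(config, user_text)
    entries: List[Dict[str, object]] = []
    for item in payload:
        if rng.random() < config.drop_rate:
            continue
        fragment = parse_molecule(item["fragment"], dialect=dialect)
        level = _heuristic_level(fragment.monoisotopic_mass, parent.monoisotopic_mass, config)
        mz = item["mz"]
        if rng.random() < config.corruption_rate:
            if rng.random() < 0.5:
                level = 0  # invalid on the 1..scale_max scale
            else:
                mz = round(mz + 0.5, 4)  # never a queried value
        entries.append({"mz": mz, "intensity": level})
    return json.dumps(entries)


@dataclass
class MockBackend:
    """Deterministic offline backend backed by the reference fragmenter."""

    config: MockOracleConfig = field(default_factory=MockOracleConfig)
    n_calls: int = 0

    def complete(self, request: CompletionRequest) -> str:
        self.n_calls += 1
        return mock_answer(request, self.config)


@dataclass
class TranscriptRecorder:
    """Wrap any backend and capture request/response pairs to JSONL."""

    backend: Backend
    path: Path

    def complete(self, request: CompletionRequest) -> str:
        response = self.backend.complete(request)
        record = {
            "system_text": request.system_text,
            "user_text": request.user_text,
            "temperature": request.temperature,
            "response": response,
        }
        with open(self.path, "a", encoding="utf-8") as handle:
            handle.write(json.dumps(record) + "\n")
        return response


class ReplayBackend:
    """Replay a recorded JSONL transcript as a backend.

    Requests are matched by exact (system_text, user_text); a request with
    no recorded response raises :class:`BackendError`.
    """

    def __init__(self, path: "Path | str"):
        self._responses: Dict[Tuple[str, str], str] = {}
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                if not line.strip():
                    continue
                record = json.loads(line)
                key = (record["system_text"], record["user_text"])
                self._responses[key] = record["response"]

    def complete(self, request: CompletionRequest) -> str:
        key = (request.system_text, request.user_text)
        try:
            return self._responses[key]
        except KeyError:
            raise BackendError("replay transcript has no response for this request") from None


class OpenAIChatBackend:
    """Thin adapter for OpenAI-compatible chat-completion services.

    Configured via constructor arguments or the ``OPENAI_API_KEY``
    environment variable; requires the optional ``openai`` package and
    network access, so it is excluded from the offline test surface.
    """

    def __init__(self, model: str, api_key: Optional[str] = None, base_url: Optional[str] = None):
        try:
            from openai import OpenAI  # type: ignore
        except ImportError:
            raise BackendError(
                "the hosted adapter requires the optional 'openai' package "
                "(pip install gifms[openai])"
            ) from None
        self._client = OpenAI(api_key=api_key, base_url=base_url)
        self._model = model

    def complete(self, request: CompletionRequest) -> str:
        response = self._client.chat.completions.create(
            model=self._model,
            temperature=request.temperature,
            seed=request.seed,
            messages=[
                {"role": "system", "content": request.system_text},
                {"role": "user", "content": request.user_text},
            ],
        )
        return response.choices[0].message.content or ""


__all__ = [
    "Backend",
    "BackendError",
    "CompletionRequest",
    "MockBackend",
    "MockOracleConfig",
    "OpenAIChatBackend",
    "ReplayBackend",
    "TranscriptRecorder",
    "mock_answer",
]
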