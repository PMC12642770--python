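"""Prompt templating and tolerant response parsing.

Every backend query is rendered here as a :class:`PromptBundle`: a system
prompt naming the chemistry domain and the task, plus an instruction-style
user prompt carrying tagged JSON payloads. Rendering is pure — identical
inputs produce byte-identical bundles — which makes transcripts replayable
and fine-tuning answers re-parseable.

Tags
----
``<<FragmentListPrediction>>`` / ``<<IntensityPrediction>>`` mark the task;
``<<MOL>>``, ``<<EXP_SETTINGS>>``, ``<<VALID_FRAGMENTS>>``,
``<<NUM_INVALID>>``, ``<<FRAGMENTS_MZ>>`` and ``<<INTENSITY_ESTIMATES>>``
mark the data payloads, each followed by a JSON object or array.

Temperature schedule
--------------------
Fragment-generation queries explore at temperature 0.9 through the initial
query and the first refinement rounds, dropping to 0.1 for the final
round; intensity queries always run at 0.1 so the final spectrum is
generated near-deterministically.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .chem import ExperimentSettings, MoleculeRecord, settings_json
from .fragmenter import FragmentRecord

TAG_FRAGMENT_TASK = "<<FragmentListPrediction>>"
TAG_INTENSITY_TASK = "<<IntensityPrediction>>"
TAG_MOL = "<<MOL>>"
TAG_SETTINGS = "<<EXP_SETTINGS>>"
TAG_VALID_FRAGMENTS = "<<VALID_FRAGMENTS>>"
TAG_NUM_INVALID = "<<NUM_INVALID>>"
TAG_FRAGMENTS_MZ = "<<FRAGMENTS_MZ>>"
TAG_INTENSITY_ESTIMATES = "<<INTENSITY_ESTIMATES>>"

EXPLORE_TEMPERATURE = 0.9
FINAL_TEMPERATURE = 0.1

MZ_DECIMALS = 4  # printed precision of m/z values in all payloads

SYSTEM_FRAGMENT = (
    "You are an expert in small-molecule tandem mass spectrometry and "
    "collision-induced dissociation. Your task is molecular fragmentation: "
    "given a query molecule and its acquisition settings, reason about which "
    "bonds break and propose the fragment substructures that produce the "
    "peaks of the MS/MS spectrum."
)

SYSTEM_INTENSITY = (
    "You are an expert in small-molecule tandem mass spectrometry. Your task "
    "is peak intensity prediction: given a query molecule, its acquisition "
    "settings, and the list of fragment substructures with their m/z values, "
    "estimate the relative abundance of each fragment ion."
)

_FRAGMENT_INSTRUCTION = (
    "Instruction: list the fragments of the query molecule that you expect "
    "to appear as peaks in its MS/MS spectrum, in order of descending "
    "intensity. Respond with a JSON array of {dialect} strings only."
)

_REFINE_FRAGMENT_INSTRUCTION = (
    "Instruction: the fragments below survived validity filtering of your "
    "previous answer; the invalid count is given. Reconsider the molecule "
    "and respond with an improved JSON array of {dialect} strings, in order "
    "of descending intensity."
)

_INTENSITY_INSTRUCTION = (
    "Instruction: assign an intensity value to every m/z value listed below "
    "on a scale of 1 to {scale_max}. Respond with a JSON array of objects, "
    'each of the form {{"mz": <number>, "intensity": <integer>}}, one per '
    "queried m/z value."
)

_REFINE_INTENSITY_INSTRUCTION = (
    "Instruction: the current intensity estimates after cleaning are listed "
    "below. Refine them and respond with a JSON array of objects, each of "
    'the form {{"mz": <number>, "intensity": <integer>}}, one per queried '
    "m/z value on a scale of 1 to {scale_max}."
)


class ResponseFormatError(ValueError):
    """Raised when no JSON payload can be located in a backend response."""


@dataclass(frozen=True)
class PromptBundle:
    """One fully rendered backend query."""

    system_text: str
    user_text: str
    temperature: float
    task_tag: str
    iteration_index: int = 0


@dataclass
class ResponseParseReport:
    """Accounting of accepted vs rejected entries of one response."""

    accepted: List[object] = field(default_factory=list)
    rejection_reasons: Counter = field(default_factory=Counter)

    @property
    def rejected_count(self) -> int:
        return sum(self.rejection_reasons.values())

    @property
    def total(self) -> int:
        return len(self.accepted) + self.rejected_count

    def reject(self, reason: str, n: int = 1) -> None:
        self.rejection_reasons[reason] += n


def _mol_payload(mol: MoleculeRecord, dialect: str) -> str:
    return json.dumps({dialect: mol.string(dialect)}, sort_keys=True)


def build_fragment_prompt(
    mol: MoleculeRecord,
    settings: ExperimentSettings,
    dialect: str = "smiles",
    temperature: float = EXPLORE_TEMPERATURE,
) -> PromptBundle:
    """Initial fragment-generation query (iteration 0)."""
    user_text = "\n".join(
        [
            TAG_FRAGMENT_TASK,
            _FRAGMENT_INSTRUCTION.format(dialect=dialect.upper()),
            f"{TAG_MOL} {_mol_payload(mol, dialect)}",
            f"{TAG_SETTINGS} {settings_json(settings)}",
        ]
    )
    return PromptBundle(SYSTEM_FRAGMENT, user_text, temperature, TAG_FRAGMENT_TASK, 0)


def build_fragment_refinement_prompt(
    mol: MoleculeRecord,
    settings: ExperimentSettings,
    valid_fragments: Sequence[FragmentRecord],
    n_invalid: int,
    iteration_index: int,
    n_iterations: int = 5,
    dialect: str = "smiles",
) -> PromptBundle:
    """Refinement query embedding the filtered survivors and invalid count.

    Temperature is 0.9 for every refinement round before the last and 0.1
    for the final round.
    """
    if not 1 <= iteration_index <= n_iterations:
        raise ValueError(f"iteration_index must be in 1..{n_iterations}")
    temperature = FINAL_TEMPERATURE if iteration_index == n_iterations else EXPLORE_TEMPERATURE
    fragments_payload = json.dumps([f.string(dialect) for f in valid_fragments])
    user_text = "\n".join(
        [
            TAG_FRAGMENT_TASK,
            _REFINE_FRAGMENT_INSTRUCTION.format(dialect=dialect.upper()),
            f"{TAG_MOL} {_mol_payload(mol, dialect)}",
            f"{TAG_SETTINGS} {settings_json(settings)}",
            f"{TAG_VALID_FRAGMENTS} {fragments_payload}",
            f"{TAG_NUM_INVALID} {json.dumps({'n_invalid': int(n_invalid)})}",
        ]
    )
    return PromptBundle(SYSTEM_FRAGMENT, user_text, temperature, TAG_FRAGMENT_TASK, iteration_index)


def _fragments_mz_payload(fragments: Sequence[FragmentRecord], dialect: str) -> str:
    entries = []
    for fragment in fragments:
        if fragment.mz is None:
            raise ValueError(f"fragment {fragment.smiles!r} has no assigned m/z")
        entries.append({"fragment": fragment.string(dialect), "mz": round(fragment.mz, MZ_DECIMALS)})
    return json.dumps(entries)


def build_intensity_prompt(
    mol: MoleculeRecord,
    settings: ExperimentSettings,
    fragments: Sequence[FragmentRecord],
    scale_max: int = 10,
    dialect: str = "smiles",
) -> PromptBundle:
    """Initial intensity query over fragments in generation order."""
    user_text = "\n".join(
        [
            TAG_INTENSITY_TASK,
            _INTENSITY_INSTRUCTION.format(scale_max=scale_max),
            f"{TAG_MOL} {_mol_payload(mol, dialect)}",
            f"{TAG_SETTINGS} {settings_json(settings)}",
            f"{TAG_FRAGMENTS_MZ} {_fragments_mz_payload(fragments, dialect)}",
        ]
    )
    return PromptBundle(SYSTEM_INTENSITY, user_text, FINAL_TEMPERATURE, TAG_INTENSITY_TASK, 0)


def build_intensity_refinement_prompt(
    mol: MoleculeRecord,
    settings: ExperimentSettings,
    fragments: Sequence[FragmentRecord],
    levels: Mapping[float, int],
    iteration_index: int = 1,
    scale_max: int = 10,
    dialect: str = "smiles",
) -> PromptBundle:
    """Refinement query embedding the merged, cleaned intensity estimates."""
    estimates = [
        {"mz": round(f.mz, MZ_DECIMALS), "intensity": levels.get(round(f.mz, MZ_DECIMALS), 1)}
        for f in fragments
    ]
    user_text = "\n".join(
        [
            TAG_INTENSITY_TASK,
            _REFINE_INTENSITY_INSTRUCTION.format(scale_max=scale_max),
            f"{TAG_MOL} {_mol_payload(mol, dialect)}",
            f"{TAG_SETTINGS} {settings_json(settings)}",
            f"{TAG_FRAGMENTS_MZ} {_fragments_mz_payload(fragments, dialect)}",
            f"{TAG_INTENSITY_ESTIMATES} {json.dumps(estimates)}",
        ]
    )
    return PromptBundle(SYSTEM_INTENSITY, user_text, FINAL_TEMPERATURE, TAG_INTENSITY_TASK, iteration_index)


# ---------------------------------------------------------------------------
# Response parsing
# ---------------------------------------------------------------------------

_FENCE_RE = re.compile(r"```[a-zA-Z]*\n?|```")


def _first_json_array(text: str) -> list:
    """Locate and decode the first JSON array in free-form response text."""
    cleaned = _FENCE_RE.sub("", text)
    decoder = json.JSONDecoder()
    for pos, char in enumerate(cleaned):
        if char != "[":
            continue
        try:
            value, _ = decoder.raw_decode(cleaned, pos)
        except json.JSONDecodeError:
            continue
        if isinstance(value, list):
            return value
    raise ResponseFormatError("no JSON array found in response")


def parse_fragment_response(text: str) -> Tuple[List[str], ResponseParseReport]:
    """Extract fragment strings from a response; non-strings are malformed."""
    entries = _first_json_array(text)
    report = ResponseParseReport()
    strings: List[str] = []
    for entry in entries:
        if isinstance(entry, str):
            strings.append(entry)
            report.accepted.append(entry)
        else:
            report.reject("malformed_entry")
    return strings, report


def _entry_mz_level(entry: object) -> Optional[Tuple[float, object]]:
    if not isinstance(entry, dict):
        return None
    mz = entry.get("mz", entry.get("m/z"))
    if not isinstance(mz, (int, float)) or isinstance(mz, bool):
        return None
    if "intensity" not in entry:
        return None
    return float(mz), entry["intensity"]


def parse_intensity_response(
    text: str,
    queried_mz: Sequence[float],
    scale_max: int = 10,
) -> Tuple[List[Tuple[float, int]], ResponseParseReport]:
    """Extract and clean (m/z, level) pairs from an intensity response.

    Cleaning rules: an entry is rejected if its m/z was not queried
    (``unqueried_mz``, matched at 4-decimal printed precision), if its m/z
    repeats an already-accepted one (``duplicate_mz``, first occurrence
    wins), or if its intensity is not an integer in [1, scale_max]
    (``invalid_intensity``). Structurally unusable entries count as
    ``malformed_entry``.
    """
    if not queried_mz:
        raise ValueError("queried_mz must be non-empty")
    entries = _first_json_array(text)
    report = ResponseParseReport()
    lookup = {round(q, MZ_DECIMALS): q for q in queried_mz}
    seen: set = set()
    pairs: List[Tuple[float, int]] = []
    for entry in entries:
        parsed = _entry_mz_level(entry)
        if parsed is None:
            report.reject("malformed_entry")
            continue
        mz, level = parsed
        key = round(mz, MZ_DECIMALS)
        if key not in lookup:
            report.reject("unqueried_mz")
            continue
        if key in seen:
            report.reject("duplicate_mz")
            continue
        if isinstance(level, bool) or not isinstance(level, (int, float)) \
                or float(level) != int(level) or not 1 <= int(level) <= scale_max:
            report.reject("invalid_intensity")
            continue
        seen.add(key)
        pairs.append((lookup[key], int(level)))
        report.accepted.append((lookup[key], int(level)))
    return pairs, report


def extract_payload(user_text: str, tag: str):
    """Decode the JSON payload following ``tag`` in a rendered user prompt.

    Used by the mock backend and by transcript tooling; returns None when
    the tag is absent.
    """
    idx = user_text.find(tag)
    if idx < 0:
        return None
    rest = user_text[idx + len(tag):].lstrip()
    decoder = json.JSONDecoder()
    value, _ = decoder.raw_decode(rest)
    return value


__all__ = [
    "EXPLORE_TEMPERATURE",
    "FINAL_TEMPERATURE",
    "MZ_DECIMALS",
    "PromptBundle",
    "ResponseFormatError",
    "ResponseParseReport",
    "SYSTEM_FRAGMENT",
    "SYSTEM_INTENSITY",
    "TAG_FRAGMENTS_MZ",
    "TAG_FRAGMENT_TASK",
    "TAG_INTENSITY_ESTIMATES",
    "TAG_INTENSITY_TASK",
    "TAG_MOL",
    "TAG_NUM_INVALID",
    "TAG_SETTINGS",
    "TAG_VALID_FRAGMENTS",
    "build_fragment_prompt",
    "build_fragment_refinement_prompt",
    "build_intensity_prompt",
    "build_intensity_refinement_prompt",
    "extract_payload",
    "parse_fragment_response",
    "parse_intensity_response",
]
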