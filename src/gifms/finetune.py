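"""QA-dataset construction and fine-tuning file preparation.

Every annotated spectrum yields exactly two instruction-style QA pairs:

* a *fragment generation* pair, whose answer lists the peak-labeled
  fragments in order of descending observed intensity (so that, as in
  generation, higher-intensity fragments appear earlier in the sequence);
* an *intensity prediction* pair, whose answer assigns each fragment m/z
  an integer level on a 1-10 scale obtained by discretizing the relative
  peak intensity.

Training files are emitted as chat-format JSONL (system/user/assistant)
in curriculum order: pairs are sorted by increasing complexity, where
complexity is the sum of the prompt's token count and the fragment count,
each normalized by its maximum over the set being ordered. Answers are
constructed so that re-parsing them with the pipeline's own response
parsers yields zero rejections.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from .chem import ExperimentSettings, MoleculeRecord
from .fragmenter import FragmentRecord, PeakLabel
from .prompting import (
    MZ_DECIMALS,
    build_fragment_prompt,
    build_intensity_prompt,
)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def default_tokenizer(text: str) -> int:
    """Whitespace-and-punctuation token count (the shipped default)."""
    return len(_TOKEN_RE.findall(text))


@dataclass
class QAPair:
    """One instruction-style prompt/answer record."""

    task: str  # "fragment_generation" | "intensity_prediction"
    system_text: str
    user_text: str
    answer_text: str  # JSON payload
    source_id: str
    n_fragments: int
    n_tokens: int
    split: Optional[str] = None


@dataclass(frozen=True)
class ComplexityScore:
    """Curriculum difficulty: normalized tokens + normalized fragments."""

    value: float
    token_component: float
    fragment_component: float


class NoLabeledPeaksError(ValueError):
    """Raised when a spectrum has no peak that matched any fragment."""


def discretize_intensity(relative_intensity: float, scale_max: int = 10) -> int:
    """Map a base-peak-relative intensity in (0, 1] to a level in [1, scale_max].

    Rounding is half-away-from-zero, then floored at 1 so every labeled
    peak keeps a nonzero level.
    """
    if not 0.0 < relative_intensity <= 1.0:
        raise ValueError("relative intensity must be in (0, 1]")
    level = int(relative_intensity * scale_max + 0.5)  # half-away-from-zero for positives
    return max(1, min(scale_max, level))


def build_qa_pairs(
    spectrum_record: Tuple[Sequence[Tuple[float, float]], MoleculeRecord, ExperimentSettings],
    labels: Sequence[PeakLabel],
    source_id: str = "",
    split: Optional[str] = None,
    scale_max: int = 10,
    dialect: str = "smiles",
    tokenizer: Callable[[str], int] = default_tokenizer,
) -> Tuple[QAPair, QAPair]:
    """Build the fragment-generation and intensity-prediction pair of one spectrum.

    ``labels`` are peak-to-fragment assignments from
    :func:`gifms.fragmenter.label_peaks`. Fragments are ordered by
    descending observed intensity; fragments repeated across peaks keep
    their most intense occurrence, and m/z collisions at the printed
    precision keep the first (most intense) entry so the intensity answer
    re-parses cleanly.
    """
    peaks, mol, settings = spectrum_record
    if not labels:
        raise NoLabeledPeaksError(f"spectrum {source_id!r} has no labeled peaks")

    ordered = sorted(labels, key=lambda lab: -lab.intensity)
    base = max(lab.intensity for lab in ordered)
    seen_keys: set = set()
    seen_mz: set = set()
    fragments: List[FragmentRecord] = []
    levels: List[int] = []
    for label in ordered:
        key = label.fragment.canonical_key
        mz_key = round(label.theoretical_mz, MZ_DECIMALS)
        if key in seen_keys or mz_key in seen_mz:
            continue
        seen_keys.add(key)
        seen_mz.add(mz_key)
        fragments.append(replace(label.fragment, mz=label.theoretical_mz))
        levels.append(discretize_intensity(label.intensity / base, scale_max))

    frag_bundle = build_fragment_prompt(mol, settings, dialect=dialect)
    frag_answer = json.dumps([f.string(dialect) for f in fragments])
    fragment_pair = QAPair(
        task="fragment_generation",
        system_text=frag_bundle.system_text,
        user_text=frag_bundle.user_text,
        answer_text=frag_answer,
        source_id=source_id,
        n_fragments=len(fragments),
        n_tokens=tokenizer(frag_bundle.system_text + "\n" + frag_bundle.user_text),
        split=split,
    )

    int_bundle = build_intensity_prompt(mol, settings, fragments, scale_max=scale_max, dialect=dialect)
    int_answer = json.dumps(
        [
            {"mz": round(f.mz, MZ_DECIMALS), "intensity": level}
            for f, level in zip(fragments, levels)
        ]
    )
    intensity_pair = QAPair(
        task="intensity_prediction",
        system_text=int_bundle.system_text,
        user_text=int_bundle.user_text,
        answer_text=int_answer,
        source_id=source_id,
        n_fragments=len(fragments),
        n_tokens=tokenizer(int_bundle.system_text + "\n" + int_bundle.user_text),
        split=split,
    )
    return fragment_pair, intensity_pair


def complexity_score(pair: QAPair, max_tokens: int, max_fragments: int) -> ComplexityScore:
    """Normalized-token + normalized-fragment curriculum score."""
    if max_tokens <= 0 or max_fragments <= 0:
        raise ValueError("normalization maxima must be positive")
    token_component = pair.n_tokens / max_tokens
    fragment_component = pair.n_fragments / max_fragments
    return ComplexityScore(
        value=token_component + fragment_component,
        token_component=token_component,
        fragment_component=fragment_component,
    )


def order_training_set(pairs: Sequence[QAPair]) -> List[QAPair]:
    """Stable sort by ascending complexity; maxima taken over ``pairs``."""
    if not pairs:
        raise ValueError("cannot order an empty training set")
    max_tokens = max(p.n_tokens for p in pairs)
    max_fragments = max(p.n_fragments for p in pairs)
    return sorted(pairs, key=lambda p: complexity_score(p, max_tokens, max_fragments).value)


def emit_finetune_file(
    pairs: Sequence[QAPair],
    split: str,
    path: "Path | str",
) -> Path:
    """Write chat-format JSONL; the train split is curriculum-ordered."""
    if split not in ("train", "test"):
        raise ValueError("split must be 'train' or 'test'")
    ordered = order_training_set(pairs) if split == "train" else list(pairs)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for pair in ordered:
            record = {
                "messages": [
                    {"role": "system", "content": pair.system_text},
                    {"role": "user", "content": pair.user_text},
                    {"role": "assistant", "content": pair.answer_text},
                ]
            }
            handle.write(json.dumps(record) + "\n")
    return path


def emit_pair_index(pairs: Sequence[QAPair], path: "Path | str") -> Path:
    """TSV index of pairs (id, task, split, sizes) for bookkeeping."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("source_id\ttask\tsplit\tn_fragments\tn_tokens\n")
        for pair in pairs:
            handle.write(
                f"{pair.source_id}\t{pair.task}\t{pair.split or ''}"
                f"\t{pair.n_fragments}\t{pair.n_tokens}\n"
            )
    return path


__all__ = [
    "ComplexityScore",
    "NoLabeledPeaksError",
    "QAPair",
    "build_qa_pairs",
    "complexity_score",
    "default_tokenizer",
    "discretize_intensity",
    "emit_finetune_file",
    "emit_pair_index",
    "order_training_set",
]
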