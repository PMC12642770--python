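"""End-to-end orchestration of the two-step spectrum simulation.

Step 1 (fragment generation) queries the backend for candidate fragment
strings, filters each response — entries that do not decode to a valid
structure or are not substructures of the query molecule are removed —
and re-prompts with the survivors plus the invalid count. By default the
initial query is followed by five refinement rounds; the last round runs
at low temperature and its filtered output, deduplicated by 2-D identity
with the earlier (higher-intensity) occurrence winning, becomes the final
ranked fragment list.

The m/z value of every fragment is then computed offline from its
monoisotopic mass and the adduct — the backend is never trusted with mass
arithmetic.

Step 2 (intensity prediction) queries the backend for an integer level in
[1, 10] per m/z value, cleans the response (unqueried, duplicate and
out-of-scale entries removed), merges the levels onto the fragment list,
runs one refinement round, and assembles the final spectrum: levels are
mapped to relative intensities and renormalized so the base peak is 1.0.
Fragments whose entries were removed by cleaning persist at the floor
level 1 rather than vanishing, so the fragment list remains the skeleton
of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .backend import Backend, CompletionRequest
from .chem import (
    AdductSpec,
    ExperimentSettings,
    MoleculeRecord,
    MoleculeParseError,
    is_substructure,
    parse_molecule,
    resolve_adduct,
)
from .fragmenter import FragmentRecord
from .prompting import (
    MZ_DECIMALS,
    PromptBundle,
    ResponseFormatError,
    ResponseParseReport,
    build_fragment_prompt,
    build_fragment_refinement_prompt,
    build_intensity_prompt,
    build_intensity_refinement_prompt,
    parse_fragment_response,
    parse_intensity_response,
)


@dataclass
class GifRunConfig:
    """Run-level knobs: refinement counts, scale, temperatures, dialect."""

    n_fragment_refinements: int = 5
    n_intensity_refinements: int = 1
    intensity_scale_max: int = 10
    explore_temperature: float = 0.9
    final_temperature: float = 0.1
    dialect: str = "smiles"
    max_format_retries: int = 1  # automatic re-queries on unusable responses

    def __post_init__(self):
        if self.n_fragment_refinements < 0 or self.n_intensity_refinements < 0:
            raise ValueError("refinement counts must be >= 0")


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    label: Optional[FragmentRecord] = None


@dataclass
class LabeledSpectrum:
    """The simulated spectrum: sorted unique peaks, each optionally labeled.

    ``fragments`` preserves the full ranked fragment list of step 1 —
    isomeric fragments sharing an m/z value are merged into a single peak,
    so the peak labels alone may undercount the generated structures.
    """

    peaks: List[Peak]
    settings: ExperimentSettings
    parent: MoleculeRecord
    fragments: Optional[List[FragmentRecord]] = None

    def __post_init__(self):
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs) or len(set(mzs)) != len(mzs):
            raise ValueError("peaks must be sorted by strictly ascending m/z")
        if self.peaks and abs(max(p.intensity for p in self.peaks) - 1.0) > 1e-9:
            raise ValueError("base peak intensity must be 1.0")

    def peak_array(self) -> List[Tuple[float, float]]:
        return [(p.mz, p.intensity) for p in self.peaks]


@dataclass
class StepTrace:
    """One query/response exchange, kept for auditing and testing."""

    bundle: PromptBundle
    response: str
    report: ResponseParseReport


@dataclass
class RunTrace:
    fragment_steps: List[StepTrace] = field(default_factory=list)
    intensity_steps: List[StepTrace] = field(default_factory=list)

    @property
    def n_backend_calls(self) -> int:
        return len(self.fragment_steps) + len(self.intensity_steps)


class PipelineError(RuntimeError):
    """Raised when the backend yields no usable response after retries."""


def _complete(backend: Backend, bundle: PromptBundle, seed: int = 0) -> str:
    request = CompletionRequest(
        system_text=bundle.system_text,
        user_text=bundle.user_text,
        temperature=bundle.temperature,
        seed=seed,
    )
    return backend.complete(request)


def _parse_with_retry(backend, bundle, parser, config):
    """Query, parse; on a format error re-query up to max_format_retries."""
    attempts = config.max_format_retries + 1
    last_error: Optional[Exception] = None
    for _ in range(attempts):
        response = _complete(backend, bundle)
        try:
            return response, parser(response)
        except ResponseFormatError as exc:
            last_error = exc
    raise PipelineError(f"unusable backend response after {attempts} attempts: {last_error}")


def filter_fragments(
    raw_strings: Sequence[str],
    parent: MoleculeRecord,
    report: ResponseParseReport,
    dialect: str = "smiles",
) -> List[FragmentRecord]:
    """Chemistry filter: drop undecodable strings and non-substructures.

    The parse report is extended in place so that its rejected count is
    the total number of invalid entries in the response (malformed JSON
    entries + invalid strings + non-substructures) — the figure echoed
    back to the backend in refinement prompts.
    """
    report.accepted = []
    survivors: List[FragmentRecord] = []
    for raw in raw_strings:
        try:
            record = parse_molecule(raw, dialect=dialect)
        except (MoleculeParseError, ValueError):
            report.reject("invalid_string")
            continue
        if not is_substructure(record, parent):
            report.reject("not_substructure")
            continue
        fragment = FragmentRecord.from_record(record)
        if dialect == "selfies":
            fragment = replace(fragment, selfies=raw)
        survivors.append(fragment)
        report.accepted.append(raw)
    return survivors


def _dedupe(fragments: Sequence[FragmentRecord]) -> List[FragmentRecord]:
    seen: set = set()
    unique: List[FragmentRecord] = []
    for fragment in fragments:
        if fragment.canonical_key not in seen:
            seen.add(fragment.canonical_key)
            unique.append(fragment)
    return unique


def generate_fragments(
    mol: MoleculeRecord,
    settings: ExperimentSettings,
    backend: Backend,
    config: Optional[GifRunConfig] = None,
    trace: Optional[RunTrace] = None,
) -> List[FragmentRecord]:
    """Step 1: iteratively refined, filtered fragment generation.

    Issues 1 + n_fragment_refinements backend calls (absent retries); the
    returned list is the filtered final response, deduplicated by
    canonical key with first occurrence winning, ranks assigned by order.
    """
    config = config or GifRunConfig()
    n_rounds = config.n_fragment_refinements
    bundle = build_fragment_prompt(
        mol, settings, dialect=config.dialect, temperature=config.explore_temperature
    )
    fragments: List[FragmentRecord] = []
    for round_index in range(n_rounds + 1):
        response, (strings, report) = _parse_with_retry(
            backend, bundle, parse_fragment_response, config
        )
        fragments = filter_fragments(strings, mol, report, dialect=config.dialect)
        if trace is not None:
            trace.fragment_steps.append(StepTrace(bundle, response, report))
        if round_index < n_rounds:
            bundle = build_fragment_refinement_prompt(
                mol,
                settings,
                _dedupe(fragments),
                n_invalid=report.rejected_count,
                iteration_index=round_index + 1,
                n_iterations=n_rounds,
                dialect=config.dialect,
            )
    final = _dedupe(fragments)
    return [replace(fragment, rank=i) for i, fragment in enumerate(final)]


def assign_mz(
    fragments: Sequence[FragmentRecord],
    adduct: "AdductSpec | str",
) -> List[FragmentRecord]:
    """Offline m/z assignment; order preserved."""
    spec = resolve_adduct(adduct)
    return [fragment.with_mz(spec) for fragment in fragments]


def predict_intensities(
    mol: MoleculeRecord,
    settings: ExperimentSettings,
    fragments: Sequence[FragmentRecord],
    backend: Backend,
    config: Optional[GifRunConfig] = None,
    trace: Optional[RunTrace] = None,
) -> LabeledSpectrum:
    """Step 2: intensity levels, cleaning, one refinement, assembly.

    Fragments sharing an m/z value at the printed precision are merged
    into one queried peak (the earlier-ranked fragment carries the label),
    preserving the spectrum's unique-m/z invariant.
    """
    config = config or GifRunConfig()
    for fragment in fragments:
        if fragment.mz is None:
            raise ValueError("all fragments must carry an assigned m/z")
    if not fragments:
        raise ValueError("cannot predict intensities for an empty fragment list")

    # one queried peak per distinct printed m/z; first fragment carries the label
    groups: Dict[float, FragmentRecord] = {}
    for fragment in fragments:
        groups.setdefault(round(fragment.mz, MZ_DECIMALS), fragment)
    queried = [f.mz for f in groups.values()]
    prompt_fragments = list(groups.values())

    levels: Dict[float, int] = {}
    bundle = build_intensity_prompt(
        mol, settings, prompt_fragments, scale_max=config.intensity_scale_max,
        dialect=config.dialect,
    )
    for round_index in range(config.n_intensity_refinements + 1):
        response, (pairs, report) = _parse_with_retry(
            backend,
            bundle,
            lambda text: parse_intensity_response(text, queried, config.intensity_scale_max),
            config,
        )
        for mz, level in pairs:  # merge cleaned levels onto the fragment list
            levels[round(mz, MZ_DECIMALS)] = level
        if trace is not None:
            trace.intensity_steps.append(StepTrace(bundle, response, report))
        if round_index < config.n_intensity_refinements:
            bundle = build_intensity_refinement_prompt(
                mol, settings, prompt_fragments, levels,
                iteration_index=round_index + 1,
                scale_max=config.intensity_scale_max, dialect=config.dialect,
            )

    scale = float(config.intensity_scale_max)
    raw = [
        (key, levels.get(key, 1) / scale, fragment)  # floor level 1 for cleaned-out peaks
        for key, fragment in groups.items()
    ]
    base = max(value for _, value, _ in raw)
    peaks = sorted(
        (Peak(mz=key, intensity=value / base, label=fragment) for key, value, fragment in raw),
        key=lambda p: p.mz,
    )
    return LabeledSpectrum(peaks=peaks, settings=settings, parent=mol, fragments=list(fragments))


def simulate_spectrum(
    mol: "MoleculeRecord | str",
    settings: ExperimentSettings,
    backend: Backend,
    config: Optional[GifRunConfig] = None,
    trace: Optional[RunTrace] = None,
) -> LabeledSpectrum:
    """Full two-step simulation: fragments -> offline m/z -> intensities.

    Accepts a molecule record or a string in the configured dialect. If
    step 1 yields no fragments at all, the spectrum degrades to the
    precursor peak alone (the parent is always a valid 'fragment').
    """
    config = config or GifRunConfig()
    if isinstance(mol, str):
        mol = parse_molecule(mol, dialect=config.dialect)
    fragments = generate_fragments(mol, settings, backend, config, trace)
    if not fragments:
        fragments = [FragmentRecord.from_record(mol)]
    fragments = assign_mz(fragments, settings.adduct)
    return predict_intensities(mol, settings, fragments, backend, config, trace)


def rank_candidates(
    query_spectrum: "LabeledSpectrum | Sequence[Tuple[float, float]]",
    candidates: Sequence[MoleculeRecord],
    settings: ExperimentSettings,
    backend: Backend,
    config: Optional[GifRunConfig] = None,
    bin_width: Optional[float] = None,
    max_mz: Optional[float] = None,
) -> List[Tuple[MoleculeRecord, float]]:
    """Score candidate structures against a query spectrum.

    Each candidate's spectrum is simulated and compared to the query by
    binned cosine similarity; candidates are returned in descending score
    order, ties broken by input order.
    """
    from . import evaluation  # local import: evaluation depends on this module

    if not candidates:
        raise ValueError("at least one candidate is required")
    kwargs = {}
    if bin_width is not None:
        kwargs["bin_width"] = bin_width
    if max_mz is not None:
        kwargs["max_mz"] = max_mz
    peaks = (
        query_spectrum.peak_array()
        if isinstance(query_spectrum, LabeledSpectrum)
        else list(query_spectrum)
    )
    query_binned = evaluation.bin_spectrum(peaks, **kwargs)
    scored = []
    for index, candidate in enumerate(candidates):
        simulated = simulate_spectrum(candidate, settings, backend, config)
        binned = evaluation.bin_spectrum(simulated.peak_array(), **kwargs)
        scored.append((index, candidate, evaluation.cosine_similarity(query_binned, binned)))
    scored.sort(key=lambda item: (-item[2], item[0]))
    return [(candidate, score) for _, candidate, score in scored]


__all__ = [
    "GifRunConfig",
    "LabeledSpectrum",
    "Peak",
    "PipelineError",
    "RunTrace",
    "StepTrace",
    "assign_mz",
    "filter_fragments",
    "generate_fragments",
    "predict_intensities",
    "rank_candidates",
    "simulate_spectrum",
]
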