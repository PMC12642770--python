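"""Spectral similarity and fragment-accuracy metrics, plus the precursor baseline.

Spectra are vectorized onto a fixed m/z grid (default 0.01 Da bins up to
1005 Da) before comparison. Two similarity measures are reported on a 0-1
scale: cosine similarity of the binned vectors (angular agreement) and
Jensen-Shannon similarity, 1 - JSD of the sum-normalized vectors with
base-2 logarithms (distributional agreement; 1 for identical
distributions, 0 for disjoint supports).

Fragment-generation quality is scored against the reference fragmenter:
*fragment accuracy* is the fraction of reference fragments whose 2-D
structure was generated, *subformula accuracy* the fraction of distinct
reference formulas that were generated, *chemical validity* the fraction
of generated strings that decode at all, and *substructure validity* the
fraction of generated structures that embed in the query molecule.
Percentages use deduplicated numerators and denominators, so they cannot
exceed 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial.distance import jensenshannon

from .chem import (
    AdductSpec,
    ExperimentSettings,
    MoleculeRecord,
    MoleculeParseError,
    compute_mz,
    is_substructure,
    parse_molecule,
)
from .fragmenter import FragmentRecord, FragmentSet
from .pipeline import LabeledSpectrum, Peak

DEFAULT_BIN_WIDTH = 0.01  # Da
DEFAULT_MAX_MZ = 1005.0  # Da


@dataclass
class BinnedSpectrum:
    """Fixed-grid vectorization of a peak list."""

    vector: np.ndarray
    bin_width: float
    max_mz: float
    n_dropped: int = 0  # peaks at or above max_mz

    def compatible(self, other: "BinnedSpectrum") -> bool:
        return self.bin_width == other.bin_width and self.max_mz == other.max_mz


def bin_spectrum(
    peaks: Sequence[Tuple[float, float]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_mz: float = DEFAULT_MAX_MZ,
) -> BinnedSpectrum:
    """Sum peak intensities into half-open uniform bins [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(max_mz / bin_width))
    vector = np.zeros(n_bins)
    dropped = 0
    for mz, intensity in peaks:
        index = int(np.floor(mz / bin_width))
        if 0 <= index < n_bins and mz < max_mz:
            vector[index] += intensity
        else:
            dropped += 1
    return BinnedSpectrum(vector=vector, bin_width=bin_width, max_mz=max_mz, n_dropped=dropped)


def _check_compatible(a: BinnedSpectrum, b: BinnedSpectrum) -> None:
    if not a.compatible(b):
        raise ValueError("binned spectra use different bin parameters")


def cosine_similarity(a: BinnedSpectrum, b: BinnedSpectrum) -> float:
    """dot(a, b) / (||a|| ||b||); 0 when either vector is all-zero."""
    _check_compatible(a, b)
    norm = np.linalg.norm(a.vector) * np.linalg.norm(b.vector)
    if norm == 0.0:
        return 0.0
    return float(np.dot(a.vector, b.vector) / norm)


def jensen_shannon_similarity(a: BinnedSpectrum, b: BinnedSpectrum) -> float:
    """1 - JSD(P || Q) with sum-normalized vectors and base-2 logs."""
    _check_compatible(a, b)
    sa, sb = a.vector.sum(), b.vector.sum()
    if sa == 0.0 and sb == 0.0:
        raise ValueError("Jensen-Shannon similarity is undefined for two empty spectra")
    if sa == 0.0 or sb == 0.0:
        return 0.0
    divergence = float(jensenshannon(a.vector, b.vector, base=2) ** 2)
    return 1.0 - divergence


def fragment_accuracy(
    generated: Sequence[FragmentRecord],
    reference: FragmentSet,
) -> float:
    """% of reference fragments whose 2-D structure appears among generated."""
    if len(reference) == 0:
        raise ValueError("reference fragment set is empty")
    generated_keys = {f.canonical_key for f in generated}
    return 100.0 * len(generated_keys & reference.keys()) / len(reference)


def subformula_accuracy(
    generated: Sequence[FragmentRecord],
    reference: FragmentSet,
) -> float:
    """% of distinct reference formulas recovered among generated fragments."""
    reference_formulas = reference.formulas()
    if not reference_formulas:
        raise ValueError("reference fragment set is empty")
    generated_formulas = {f.formula.hill() for f in generated}
    return 100.0 * len(generated_formulas & reference_formulas) / len(reference_formulas)


def chemical_validity(raw_strings: Sequence[str], dialect: str = "smiles") -> float:
    """% of strings that decode to a valid structure."""
    if not raw_strings:
        raise ValueError("chemical_validity requires at least one string")
    valid = 0
    for raw in raw_strings:
        try:
            parse_molecule(raw, dialect=dialect)
            valid += 1
        except (MoleculeParseError, ValueError):
            pass
    return 100.0 * valid / len(raw_strings)


def substructure_validity(
    fragments: Sequence["MoleculeRecord | FragmentRecord"],
    parent: MoleculeRecord,
) -> float:
    """% of structures that embed in the parent's heavy-atom graph."""
    if not fragments:
        raise ValueError("substructure_validity requires at least one fragment")
    passed = 0
    for fragment in fragments:
        record = fragment.record if isinstance(fragment, FragmentRecord) else fragment
        if is_substructure(record, parent):
            passed += 1
    return 100.0 * passed / len(fragments)


def precursor_baseline(
    mol: MoleculeRecord,
    adduct: "AdductSpec | str",
    settings: Optional[ExperimentSettings] = None,
) -> LabeledSpectrum:
    """Single-peak baseline: the precursor m/z at full intensity."""
    if settings is None:
        adduct_name = adduct if isinstance(adduct, str) else adduct.name
        settings = ExperimentSettings(adduct=adduct_name)
    mz = compute_mz(mol.monoisotopic_mass, adduct)
    label = FragmentRecord.from_record(mol, depth=0)
    peak = Peak(mz=mz, intensity=1.0, label=label)
    return LabeledSpectrum(peaks=[peak], settings=settings, parent=mol, fragments=[label])


@dataclass
class EvalReport:
    """Unweighted per-item means of every metric over an evaluation run."""

    fragment_accuracy: float
    subformula_accuracy: float
    chemical_validity: float
    substructure_validity: float
    cosine_similarity: float
    jensen_shannon_similarity: float
    n_items: int

    def to_dict(self) -> dict:
        return {
            "fragment_accuracy": self.fragment_accuracy,
            "subformula_accuracy": self.subformula_accuracy,
            "chemical_validity": self.chemical_validity,
            "substructure_validity": self.substructure_validity,
            "cosine_similarity": self.cosine_similarity,
            "jensen_shannon_similarity": self.jensen_shannon_similarity,
            "n_items": self.n_items,
        }


def evaluate_run(
    simulated: Sequence[LabeledSpectrum],
    references: Sequence[Tuple[Sequence[Tuple[float, float]], FragmentSet]],
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_mz: float = DEFAULT_MAX_MZ,
    dialect: str = "smiles",
) -> EvalReport:
    """Score each simulated spectrum against its reference, then average.

    ``references`` pairs the observed peak list with the reference
    fragment set of the same query molecule.
    """
    if not simulated:
        raise ValueError("no simulated spectra to evaluate")
    if len(simulated) != len(references):
        raise ValueError("simulated and reference arrays must be aligned")
    rows = []
    for spectrum, (peaks, fragment_set) in zip(simulated, references):
        # step-1 metrics score the full generated fragment list; m/z-merged
        # peak labels alone would undercount isomeric fragments
        labels = (
            list(spectrum.fragments)
            if spectrum.fragments is not None
            else [p.label for p in spectrum.peaks if p.label is not None]
        )
        strings = [f.string(dialect) for f in labels]
        binned_sim = bin_spectrum(spectrum.peak_array(), bin_width, max_mz)
        binned_ref = bin_spectrum(peaks, bin_width, max_mz)
        rows.append(
            (
                fragment_accuracy(labels, fragment_set),
                subformula_accuracy(labels, fragment_set),
                chemical_validity(strings, dialect) if strings else 0.0,
                substructure_validity(labels, spectrum.parent) if labels else 0.0,
                cosine_similarity(binned_sim, binned_ref),
                jensen_shannon_similarity(binned_sim, binned_ref),
            )
        )
    means = np.mean(np.asarray(rows), axis=0)
    return EvalReport(*[float(x) for x in means], n_items=len(rows))


__all__ = [
    "BinnedSpectrum",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_MAX_MZ",
    "EvalReport",
    "bin_spectrum",
    "chemical_validity",
    "cosine_similarity",
    "evaluate_run",
    "fragment_accuracy",
    "jensen_shannon_similarity",
    "precursor_baseline",
    "subformula_accuracy",
    "substructure_validity",
]
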