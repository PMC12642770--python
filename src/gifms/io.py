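"""Spectral-library readers/writers and the deterministic fixture generator.

Readers validate every record (parseable molecule, resolvable adduct,
positive intensities) and skip invalid rows with a logged reason rather
than silently coercing them; a summary count accompanies the result.

The fixture generator synthesizes small, fully annotated spectral
libraries from a packaged list of common small organic molecules: peaks
are placed at the exact adduct m/z of the reference fragments, intensity
follows the mass-fraction heuristic with optional seeded Gaussian noise,
and unlabelable decoy peaks can be injected at a configurable rate. The
output is bit-reproducible per (seed, config) and serves as test and
demonstration data throughout the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import (
    ExperimentSettings,
    HYDROGEN_MASS,
    MoleculeRecord,
    MoleculeParseError,
    UnknownAdductError,
    compute_mz,
    parse_molecule,
    resolve_adduct,
)
from .fragmenter import enumerate_fragments
from .pipeline import LabeledSpectrum, Peak

logger = logging.getLogger(__name__)

MZ_FMT = "{:.4f}"  # m/z printed to 4 decimals in every text output


@dataclass
class SpectrumLibraryRecord:
    """One annotated library spectrum: molecule, settings, peak list."""

    identifier: str
    molecule: MoleculeRecord
    settings: ExperimentSettings
    peaks: List[Tuple[float, float]]
    split: Optional[str] = None

    def __post_init__(self):
        if not self.peaks:
            raise ValueError(f"record {self.identifier!r} has no peaks")
        if any(intensity <= 0 for _, intensity in self.peaks):
            raise ValueError(f"record {self.identifier!r} has non-positive intensities")
        self.peaks = sorted(self.peaks)


@dataclass
class ReadSummary:
    n_read: int = 0
    n_skipped: int = 0
    skip_reasons: Dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.n_skipped += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1


def _build_record(
    identifier: str,
    smiles: str,
    adduct: str,
    instrument: str,
    collision_energy,
    mzs: Sequence[float],
    intensities: Sequence[float],
    split: Optional[str],
    summary: ReadSummary,
) -> Optional[SpectrumLibraryRecord]:
    try:
        molecule = parse_molecule(str(smiles))
    except (MoleculeParseError, ValueError):
        summary.skip("unparseable_molecule")
        logger.warning("skipping %s: unparseable molecule %r", identifier, smiles)
        return None
    try:
        settings = ExperimentSettings(
            adduct=str(adduct), instrument=str(instrument), collision_energy=collision_energy
        )
    except UnknownAdductError:
        summary.skip("unresolvable_adduct")
        logger.warning("skipping %s: unresolvable adduct %r", identifier, adduct)
        return None
    if len(mzs) != len(intensities) or not len(mzs):
        summary.skip("malformed_peaks")
        return None
    try:
        record = SpectrumLibraryRecord(
            identifier=str(identifier),
            molecule=molecule,
            settings=settings,
            peaks=list(zip(map(float, mzs), map(float, intensities))),
            split=str(split) if split else None,
        )
    except ValueError:
        summary.skip("malformed_peaks")
        return None
    summary.n_read += 1
    return record


def _read_massspecgym_tsv(path: Path, summary: ReadSummary) -> List[SpectrumLibraryRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame.columns = [c.lower() for c in frame.columns]
    instrument_col = "instrument_type" if "instrument_type" in frame.columns else "instrument"
    split_col = "fold" if "fold" in frame.columns else ("split" if "split" in frame.columns else None)
    records = []
    for _, row in frame.iterrows():
        try:
            mzs = [float(x) for x in str(row["mzs"]).split(",")]
            intensities = [float(x) for x in str(row["intensities"]).split(",")]
        except ValueError:
            summary.skip("malformed_peaks")
            continue
        record = _build_record(
            row.get("identifier", ""),
            row.get("smiles", ""),
            row.get("adduct", ""),
            row.get(instrument_col, ""),
            row.get("collision_energy", ""),
            mzs,
            intensities,
            row.get(split_col) if split_col else None,
            summary,
        )
        if record is not None:
            records.append(record)
    return records


def _read_mgf(path: Path, summary: ReadSummary) -> List[SpectrumLibraryRecord]:
    from pyteomics import mgf

    records = []
    with mgf.read(str(path)) as reader:
        for index, entry in enumerate(reader):
            params = {k.lower(): v for k, v in entry.get("params", {}).items()}
            record = _build_record(
                params.get("title", f"MGF{index:05d}"),
                params.get("smiles", ""),
                params.get("adduct", "[M+H]+"),
                params.get("instrument", ""),
                params.get("collision_energy", ""),
                entry["m/z array"],
                entry["intensity array"],
                params.get("split"),
                summary,
            )
            if record is not None:
                records.append(record)
    return records


def _read_msp(path: Path, summary: ReadSummary) -> List[SpectrumLibraryRecord]:
    from matchms.importing import load_from_msp

    records = []
    for index, spectrum in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
        if spectrum is None:
            summary.skip("unreadable_block")
            continue
        meta = {k.lower(): v for k, v in spectrum.metadata.items()}
        record = _build_record(
            meta.get("name", meta.get("compound_name", f"MSP{index:05d}")),
            meta.get("smiles", ""),
            meta.get("adduct", "[M+H]+"),
            meta.get("instrument", ""),
            meta.get("collision_energy", ""),
            spectrum.peaks.mz,
            spectrum.peaks.intensities,
            meta.get("split"),
            summary,
        )
        if record is not None:
            records.append(record)
    return records


def read_library(
    path: "Path | str",
    format: str = "massspecgym_tsv",
) -> Tuple[List[SpectrumLibraryRecord], ReadSummary]:
    """Read an annotated spectral library; invalid rows are skipped and counted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    summary = ReadSummary()
    readers = {"massspecgym_tsv": _read_massspecgym_tsv, "mgf": _read_mgf, "msp": _read_msp}
    try:
        reader = readers[format]
    except KeyError:
        raise ValueError(f"unknown library format {format!r}") from None
    records = reader(path, summary)
    if not records:
        raise ValueError(f"no valid records in {path}")
    if summary.n_skipped:
        logger.info("read %d records, skipped %d: %s", summary.n_read, summary.n_skipped,
                    summary.skip_reasons)
    return records, summary


def write_library_tsv(records: Sequence[SpectrumLibraryRecord], path: "Path | str") -> Path:
    """Write records in the MassSpecGym-style TSV layout."""
    path = Path(path)
    rows = []
    for record in records:
        rows.append(
            {
                "identifier": record.identifier,
                "smiles": record.molecule.smiles,
                "adduct": record.settings.adduct,
                "instrument_type": record.settings.instrument,
                "collision_energy": record.settings.collision_energy,
                "mzs": ",".join(MZ_FMT.format(mz) for mz, _ in record.peaks),
                "intensities": ",".join(f"{i:.6f}" for _, i in record.peaks),
                "fold": record.split or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Simulated-spectrum output
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.jsonl")


def write_spectrum(
    spectrum: LabeledSpectrum,
    path: "Path | str",
    format: str = "msp",
    dialect: str = "smiles",
) -> Path:
    """Persist a simulated spectrum as MSP or MGF plus a JSONL label sidecar.

    The sidecar carries one line per peak mapping its printed m/z to the
    fragment label string (null for unlabeled peaks).
    """
    path = Path(path)
    if not spectrum.peaks:
        raise ValueError("refusing to write a spectrum with no peaks")
    if format == "msp":
        lines = [
            f"NAME: {spectrum.parent.smiles}",
            f"SMILES: {spectrum.parent.smiles}",
            f"ADDUCT: {spectrum.settings.adduct}",
            f"INSTRUMENT: {spectrum.settings.instrument}",
            f"COLLISION_ENERGY: {spectrum.settings.collision_energy}",
            f"NUM PEAKS: {len(spectrum.peaks)}",
        ]
        for peak in spectrum.peaks:
            lines.append(f"{MZ_FMT.format(peak.mz)} {peak.intensity:.6f}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "mgf":
        from pyteomics import mgf

        entry = {
            "m/z array": np.array([p.mz for p in spectrum.peaks]),
            "intensity array": np.array([p.intensity for p in spectrum.peaks]),
            "params": {
                "title": spectrum.parent.smiles,
                "smiles": spectrum.parent.smiles,
                "adduct": spectrum.settings.adduct,
                "instrument": spectrum.settings.instrument,
                "collision_energy": spectrum.settings.collision_energy,
            },
        }
        mgf.write([entry], str(path), file_mode="w")
    else:
        raise ValueError(f"unknown spectrum format {format!r}")

    with open(_sidecar_path(path), "w", encoding="utf-8") as handle:
        for peak in spectrum.peaks:
            handle.write(
                json.dumps(
                    {
                        "mz": round(peak.mz, 4),
                        "label": peak.label.string(dialect) if peak.label else None,
                    }
                )
                + "\n"
            )
    return path


def read_spectrum_peaks(path: "Path | str", format: str = "msp") -> List[Tuple[float, float]]:
    """Read back the peak list of a written spectrum (round-trip helper)."""
    path = Path(path)
    if format == "msp":
        peaks = []
        for line in path.read_text(encoding="utf-8").splitlines():
            parts = line.split()
            if len(parts) == 2:
                try:
                    peaks.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    continue
        return peaks
    if format == "mgf":
        from pyteomics import mgf

        with mgf.read(str(path)) as reader:
            entry = next(iter(reader))
        return list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
    raise ValueError(f"unknown spectrum format {format!r}")


def read_spectrum_labels(path: "Path | str") -> List[Optional[str]]:
    """Label strings from a spectrum's JSONL sidecar, in peak order."""
    sidecar = _sidecar_path(Path(path))
    return [
        json.loads(line)["label"]
        for line in sidecar.read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

#: Packaged small-organic molecule list the fixture generator draws from.
FIXTURE_SMILES: Tuple[str, ...] = (
    "CCO",                     # ethanol
    "NCC(=O)O",                # glycine
    "c1ccccc1",                # benzene
    "Cc1ccccc1",               # toluene
    "Oc1ccccc1",               # phenol
    "Nc1ccccc1",               # aniline
    "CC(=O)O",                 # acetic acid
    "CCC",                     # propane
    "CCCCO",                   # 1-butanol
    "CC(C)=O",                 # acetone
    "c1ccncc1",                # pyridine
    "c1ccoc1",                 # furan
    "OCC(N)C(=O)O",            # serine
    "CC(N)C(=O)O",             # alanine
    "OC(=O)c1ccccc1",          # benzoic acid
    "CC(=O)c1ccccc1",          # acetophenone
    "Cc1ccc(O)cc1",            # p-cresol
    "CCOC(C)=O",               # ethyl acetate
    "OCC(O)CO",                # glycerol
    "CC(O)C(=O)O",             # lactic acid
    "OC(=O)c1ccccc1O",         # salicylic acid
    "CC(=O)Oc1ccccc1C(=O)O",   # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",  # caffeine
    "COc1cc(C=O)ccc1O",        # vanillin
    "NCCc1ccc(O)cc1",          # tyramine
)


@dataclass
class FixtureConfig:
    """Settings for deterministic fixture-library synthesis."""

    n_molecules: int = 20
    seed: int = 0
    fragment_depth: int = 1
    noise_sd: float = 0.0
    decoy_rate: float = 0.0
    adduct: str = "[M+H]+"
    train_fraction: float = 0.8

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy_rate must be in [0, 1]")


_COLLISION_ENERGIES = (10.0, 20.0, 40.0)


def generate_fixtures(config: FixtureConfig) -> List[SpectrumLibraryRecord]:
    """Synthesize an annotated fixture library; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    records = []
    n_train = int(round(config.train_fraction * config.n_molecules))
    for index in range(config.n_molecules):
        smiles = FIXTURE_SMILES[index % len(FIXTURE_SMILES)]
        molecule = parse_molecule(smiles)
        settings = ExperimentSettings(
            adduct=config.adduct,
            instrument="Orbitrap",
            collision_energy=_COLLISION_ENERGIES[index % len(_COLLISION_ENERGIES)],
        )
        fragments = enumerate_fragments(molecule, max_depth=config.fragment_depth)
        seen = set()
        peaks: List[Tuple[float, float]] = []
        theoretical: List[float] = []
        for fragment in fragments:
            mz = round(compute_mz(fragment.monoisotopic_mass, config.adduct), 4)
            if mz in seen:
                continue
            seen.add(mz)
            theoretical.append(mz)
            intensity = max(
                1, round(10 * fragment.monoisotopic_mass / molecule.monoisotopic_mass)
            ) / 10.0
            if config.noise_sd:
                intensity = max(0.01, intensity + rng.normal(0.0, config.noise_sd))
            peaks.append((mz, intensity))
        # decoy peaks placed well away from every candidate +- hydrogen shifts
        decoys = []
        for mz, _ in list(peaks):
            if rng.random() < config.decoy_rate:
                decoy_mz = mz + rng.uniform(1.5, 4.5)
                while any(
                    abs(decoy_mz - (t + k * HYDROGEN_MASS)) < 0.2
                    for t in theoretical
                    for k in (-2, -1, 0, 1, 2)
                ):
                    decoy_mz += 0.37
                decoys.append((round(decoy_mz, 4), float(rng.uniform(0.05, 0.3))))
        peaks.extend(decoys)
        base = max(intensity for _, intensity in peaks)
        peaks = [(mz, intensity / base) for mz, intensity in peaks]
        records.append(
            SpectrumLibraryRecord(
                identifier=f"FIX{index:04d}",
                molecule=molecule,
                settings=settings,
                peaks=peaks,
                split="train" if index < n_train else "test",
            )
        )
    return records


__all__ = [
    "FIXTURE_SMILES",
    "FixtureConfig",
    "ReadSummary",
    "SpectrumLibraryRecord",
    "generate_fixtures",
    "read_library",
    "read_spectrum_labels",
    "read_spectrum_peaks",
    "write_library_tsv",
    "write_spectrum",
]
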