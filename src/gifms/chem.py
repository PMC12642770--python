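"""Molecular parsing, formula/mass arithmetic and substructure checks.

This module is the chemistry foundation for the whole package: it turns
SMILES (or, optionally, SELFIES) strings into validated molecule records,
computes monoisotopic masses from molecular formulas, maps neutral masses
to observed m/z values through an adduct table, and provides the 2-D
identity key and heavy-atom subgraph test that every downstream filtering
and accuracy metric relies on.

Conventions
-----------
* Masses are monoisotopic, in daltons (Da), taken from the most abundant
  isotope of each element.
* Charge carriers use the proton mass (not the hydrogen-atom mass), the
  standard mass-spectrometry convention.
* Substructure matching operates on the heavy-atom graph: hydrogen counts
  are ignored because fragmentation changes them, and bond orders are
  matched loosely by default so that kekulized and aromatic forms of the
  same ring system agree (a ``strict_bond_order`` flag restores exact
  bond-order matching).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # RDKit's parse warnings are reported as exceptions instead

_PT = Chem.GetPeriodicTable()

#: Mass of a proton in Da (CODATA); used for charge carriers.
PROTON_MASS = 1.00727646688
#: Mass of an electron in Da.
ELECTRON_MASS = 0.00054857990
#: Monoisotopic mass of a hydrogen atom in Da.
HYDROGEN_MASS = 1.00782503207


class MoleculeParseError(ValueError):
    """Raised when a molecular string cannot be decoded to a valid structure."""


class UnknownElementError(KeyError):
    """Raised when a formula references an element absent from the isotope table."""


class UnknownAdductError(KeyError):
    """Raised when an adduct name cannot be resolved against the adduct table."""


class MissingDependencyError(ImportError):
    """Raised when an optional dependency (e.g. ``selfies``) is required but absent."""


# ---------------------------------------------------------------------------
# Formula arithmetic
# ---------------------------------------------------------------------------


class FormulaVector(dict):
    """Element-symbol -> count mapping with mass arithmetic.

    A thin dict subclass so it can be built and inspected like a plain
    mapping while providing the union/sum and canonical-string helpers the
    subformula metrics need. Counts are non-negative integers.
    """

    def __init__(self, counts: Optional[Mapping[str, int]] = None):
        super().__init__()
        if counts:
            for element, count in counts.items():
                if count < 0 or int(count) != count:
                    raise ValueError(f"negative or non-integer count for {element!r}: {count}")
                if count:
                    self[element] = int(count)

    @classmethod
    def from_mol(cls, mol: Chem.Mol) -> "FormulaVector":
        """Count every atom, including implicit hydrogens."""
        counts: Dict[str, int] = {}
        for atom in mol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
            n_h = atom.GetTotalNumHs()
            if n_h:
                counts["H"] = counts.get("H", 0) + n_h
        return cls(counts)

    def __add__(self, other: "FormulaVector") -> "FormulaVector":
        merged = dict(self)
        for element, count in other.items():
            merged[element] = merged.get(element, 0) + count
        return FormulaVector(merged)

    def hill(self) -> str:
        """Canonical Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        for element in ("C", "H"):
            if element in self:
                n = self[element]
                parts.append(element if n == 1 else f"{element}{n}")
        for element in sorted(e for e in self if e not in ("C", "H")):
            n = self[element]
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Sum of most-abundant-isotope masses times element counts, in Da."""
    total = 0.0
    for element, count in formula.items():
        mass = _PT.GetMostCommonIsotopeMass(element)
        if mass <= 0.0:
            raise UnknownElementError(element)
        total += mass * count
    return total


# ---------------------------------------------------------------------------
# Adducts and m/z
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdductSpec:
    """Charge-carrying modification mapping neutral mass to observed m/z."""

    name: str
    mass_shift: float  # Da added to the neutral monoisotopic mass
    charge: int

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")


_NH4_MASS = 14.0030740048 + 4 * HYDROGEN_MASS - ELECTRON_MASS
_H2O_MASS = 2 * HYDROGEN_MASS + 15.9949146196

#: Built-in adduct table; extensible via :func:`register_adduct`.
ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", PROTON_MASS, +1),
    "[M+Na]+": AdductSpec("[M+Na]+", 22.9897692809 - ELECTRON_MASS, +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", _NH4_MASS, +1),
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    "[M+H-H2O]+": AdductSpec("[M+H-H2O]+", PROTON_MASS - _H2O_MASS, +1),
}


def register_adduct(spec: AdductSpec) -> None:
    ADDUCTS[spec.name] = spec


def resolve_adduct(adduct: "AdductSpec | str") -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    try:
        return ADDUCTS[adduct]
    except KeyError:
        raise UnknownAdductError(adduct) from None


def compute_mz(neutral_mass: float, adduct: "AdductSpec | str") -> float:
    """Observed m/z of a neutral mass under an adduct: (M + shift) / |z|."""
    spec = resolve_adduct(adduct)
    return (neutral_mass + spec.mass_shift) / abs(spec.charge)


@dataclass(frozen=True)
class ExperimentSettings:
    """Acquisition context carried through every prompt."""

    adduct: str = "[M+H]+"
    instrument: str = "Orbitrap"
    collision_energy: "str | float" = 20.0

    def __post_init__(self):
        resolve_adduct(self.adduct)  # fail fast on unresolvable names

    def to_dict(self) -> Dict[str, object]:
        return {
            "adduct": self.adduct,
            "instrument": self.instrument,
            "collision_energy": self.collision_energy,
        }


# ---------------------------------------------------------------------------
# Molecule records
# ---------------------------------------------------------------------------


def _selfies_module():
    try:
        import selfies  # type: ignore
    except ImportError:
        raise MissingDependencyError(
            "the SELFIES dialect requires the optional 'selfies' package "
            "(pip install gifms[selfies]); use dialect='smiles' otherwise"
        ) from None
    return selfies


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed query molecule or fragment structure.

    ``selfies`` is populated only when the optional encoder is available;
    ``smiles`` is always the canonical RDKit SMILES. ``canonical_key`` is a
    2-D identity key that is invariant to input spelling and hydrogen
    counts (see :func:`canonical_fragment_key`).
    """

    smiles: str
    canonical_key: str
    formula: FormulaVector
    monoisotopic_mass: float
    selfies: Optional[str] = None
    mol: Chem.Mol = field(default=None, compare=False, repr=False, hash=False)

    def string(self, dialect: str = "smiles") -> str:
        """The molecule serialized in the requested dialect."""
        if dialect == "smiles":
            return self.smiles
        if dialect == "selfies":
            if self.selfies is not None:
                return self.selfies
            return _selfies_module().encoder(self.smiles)
        raise ValueError(f"unknown dialect {dialect!r}")


def _mol_from_text(text: str, dialect: str) -> Chem.Mol:
    if dialect == "selfies":
        sf = _selfies_module()
        try:
            smiles = sf.decoder(text)
        except Exception as exc:
            raise MoleculeParseError(f"undecodable SELFIES {text!r}: {exc}") from None
    elif dialect == "smiles":
        smiles = text
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"chemically invalid {dialect} string {text!r}")
    return mol


def canonical_fragment_key(mol: "Chem.Mol | MoleculeRecord") -> str:
    """Canonical 2-D identity key, normalized over hydrogen counts.

    Explicit hydrogens are stripped and every heavy atom's valence is
    refilled with implicit hydrogens, so two fragments with the same
    heavy-atom graph but different saturation states share one key. Formal
    charges and bond orders are preserved.
    """
    if isinstance(mol, MoleculeRecord):
        mol = mol.mol
    editable = Chem.RWMol(mol)
    # work on the kekulized form: zeroing explicit hydrogens on aromatic
    # heteroatoms (e.g. pyrrole-type [nH]) would otherwise make the ring
    # unkekulizable; aromaticity is re-perceived by the final sanitize
    Chem.Kekulize(editable, clearAromaticFlags=True)
    editable.BeginBatchEdit()
    for atom in editable.GetAtoms():
        if atom.GetAtomicNum() == 1:
            editable.RemoveAtom(atom.GetIdx())
    editable.CommitBatchEdit()
    for atom in editable.GetAtoms():
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    normalized = editable.GetMol()
    Chem.SanitizeMol(normalized)
    return Chem.MolToSmiles(normalized)


def record_from_mol(mol: Chem.Mol, selfies: Optional[str] = None) -> MoleculeRecord:
    formula = FormulaVector.from_mol(mol)
    return MoleculeRecord(
        smiles=Chem.MolToSmiles(mol),
        canonical_key=canonical_fragment_key(mol),
        formula=formula,
        monoisotopic_mass=monoisotopic_mass(formula),
        selfies=selfies,
        mol=mol,
    )


def parse_molecule(text: str, dialect: str = "smiles") -> MoleculeRecord:
    """Decode a SMILES or SELFIES string into a fully populated record.

    Raises :class:`MoleculeParseError` on undecodable input.
    """
    if not text or not text.strip():
        raise MoleculeParseError("empty molecular string")
    mol = _mol_from_text(text.strip(), dialect)
    return record_from_mol(mol, selfies=text.strip() if dialect == "selfies" else None)


def is_substructure(
    fragment: "MoleculeRecord | Chem.Mol",
    parent: "MoleculeRecord | Chem.Mol",
    strict_bond_order: bool = False,
) -> bool:
    """True iff the fragment's heavy-atom graph embeds in the parent's.

    Hydrogen counts are ignored. With the default relaxed matching, bond
    orders are treated as generic so aromatic/kekulized representations of
    the same ring system match; ``strict_bond_order=True`` requires exact
    bond-order agreement.
    """
    frag_mol = fragment.mol if isinstance(fragment, MoleculeRecord) else fragment
    parent_mol = parent.mol if isinstance(parent, MoleculeRecord) else parent
    query = Chem.RemoveHs(frag_mol)
    if not strict_bond_order:
        params = Chem.AdjustQueryParameters.NoAdjustments()
        params.makeBondsGeneric = True
        query = Chem.AdjustQueryProperties(query, params)
    return parent_mol.HasSubstructMatch(query)


def settings_json(settings: ExperimentSettings) -> str:
    """Deterministic JSON serialization used in prompt payloads."""
    return json.dumps(settings.to_dict(), sort_keys=True)


__all__ = [
    "ADDUCTS",
    "AdductSpec",
    "ExperimentSettings",
    "FormulaVector",
    "HYDROGEN_MASS",
    "MissingDependencyError",
    "MoleculeParseError",
    "MoleculeRecord",
    "PROTON_MASS",
    "UnknownAdductError",
    "UnknownElementError",
    "canonical_fragment_key",
    "compute_mz",
    "is_substructure",
    "monoisotopic_mass",
    "parse_molecule",
    "record_from_mol",
    "register_adduct",
    "resolve_adduct",
]
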