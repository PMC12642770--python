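"""Combinatorial bond-breaking reference fragmenter and peak labeling.

A simplified MAGMa-style engine: starting from the parent molecule's
heavy-atom graph, bonds are broken combinatorially — one acyclic bond per
step, or a pair of ring bonds per step (a single ring-bond cleavage leaves
the graph connected and therefore yields no fragment) — down to a
configurable depth. Open valences are capped with hydrogens, and matching
against observed peaks allows a +-k hydrogen-mass rearrangement window to
compensate for that saturation model.

The fragment sets produced here serve three roles: ground-truth
substructure labels when building QA datasets from annotated spectra, the
knowledge base of the deterministic mock backend, and the reference
denominator of the fragment/subformula accuracy metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from rdkit import Chem

from .chem import (
    HYDROGEN_MASS,
    AdductSpec,
    FormulaVector,
    MoleculeRecord,
    canonical_fragment_key,
    compute_mz,
    is_substructure,
    monoisotopic_mass,
    record_from_mol,
    resolve_adduct,
)

DEFAULT_MAX_DEPTH = 2
DEFAULT_TOLERANCE = 0.01  # Da
DEFAULT_H_SHIFT = 1


@dataclass
class FragmentRecord:
    """One candidate fragment, optionally with an assigned m/z and rank.

    ``rank`` is the 0-based position in descending predicted intensity
    once assigned by the pipeline; ``depth`` is the number of cleavage
    steps that produced the fragment in the reference engine (0 = parent).
    """

    smiles: str
    canonical_key: str
    formula: FormulaVector
    monoisotopic_mass: float
    mz: Optional[float] = None
    rank: Optional[int] = None
    depth: Optional[int] = None
    selfies: Optional[str] = None
    record: MoleculeRecord = field(default=None, repr=False, compare=False)

    @classmethod
    def from_record(cls, record: MoleculeRecord, depth: Optional[int] = None) -> "FragmentRecord":
        return cls(
            smiles=record.smiles,
            canonical_key=record.canonical_key,
            formula=record.formula,
            monoisotopic_mass=record.monoisotopic_mass,
            depth=depth,
            selfies=record.selfies,
            record=record,
        )

    def string(self, dialect: str = "smiles") -> str:
        if dialect == "smiles":
            return self.smiles
        return self.record.string(dialect)

    def with_mz(self, adduct: "AdductSpec | str") -> "FragmentRecord":
        return replace(self, mz=compute_mz(self.monoisotopic_mass, adduct))


@dataclass
class FragmentSet:
    """Deduplicated fragments of one parent, keyed by 2-D identity."""

    parent: MoleculeRecord
    members: List[FragmentRecord]
    max_depth: int

    def __post_init__(self):
        self._by_key = {m.canonical_key: m for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def keys(self) -> set:
        return set(self._by_key)

    def formulas(self) -> set:
        return {m.formula.hill() for m in self.members}

    def __contains__(self, key: str) -> bool:
        return key in self._by_key


def _submol(mol: Chem.Mol, atoms: FrozenSet[int]) -> Chem.Mol:
    """Induced subgraph on ``atoms`` with open valences hydrogen-capped."""
    editable = Chem.RWMol(mol)
    editable.BeginBatchEdit()
    for atom in editable.GetAtoms():
        if atom.GetIdx() not in atoms:
            editable.RemoveAtom(atom.GetIdx())
    editable.CommitBatchEdit()
    fragment = editable.GetMol()
    for atom in fragment.GetAtoms():
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    Chem.SanitizeMol(fragment)
    return fragment


def _components(atoms: FrozenSet[int], adjacency: Dict[int, List[int]],
                removed: Tuple[Tuple[int, int], ...]) -> List[FrozenSet[int]]:
    """Connected components of the subgraph after removing ``removed`` bonds."""
    banned = {frozenset(b) for b in removed}
    seen = set()
    comps = []
    for start in atoms:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            for nbr in adjacency[node]:
                if nbr in atoms and nbr not in comp and frozenset((node, nbr)) not in banned:
                    stack.append(nbr)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def enumerate_fragments(parent: MoleculeRecord, max_depth: int = DEFAULT_MAX_DEPTH) -> FragmentSet:
    """All connected substructures reachable by <= max_depth cleavage steps.

    One step breaks a single acyclic bond or a pair of ring bonds; both
    resulting pieces are retained. The parent itself is the depth-0 member.
    Results are hydrogen-saturated and deduplicated by canonical key
    (keeping the minimal depth).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    mol = Chem.Mol(parent.mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)  # fragments of aromatic rings must sanitize
    adjacency: Dict[int, List[int]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[i].append(j)
        adjacency[j].append(i)

    all_atoms = frozenset(adjacency)
    records: Dict[str, FragmentRecord] = {}
    seen_subsets: Dict[FrozenSet[int], int] = {}

    def register(atoms: FrozenSet[int], depth: int) -> None:
        record = record_from_mol(_submol(mol, atoms))
        existing = records.get(record.canonical_key)
        if existing is None or (existing.depth is not None and depth < existing.depth):
            records[record.canonical_key] = FragmentRecord.from_record(record, depth=depth)

    frontier = [all_atoms]
    seen_subsets[all_atoms] = 0
    register(all_atoms, 0)

    for depth in range(1, max_depth + 1):
        next_frontier: List[FrozenSet[int]] = []
        for atoms in frontier:
            bonds = [
                (i, j)
                for i in atoms
                for j in adjacency[i]
                if j in atoms and i < j
            ]
            acyclic, ring_bonds = [], []
            for bond in bonds:
                if len(_components(atoms, adjacency, (bond,))) > 1:
                    acyclic.append(bond)
                else:
                    ring_bonds.append(bond)
            cleavages: List[Tuple[Tuple[int, int], ...]] = [(b,) for b in acyclic]
            for a in range(len(ring_bonds)):
                for b in range(a + 1, len(ring_bonds)):
                    cleavages.append((ring_bonds[a], ring_bonds[b]))
            for removed in cleavages:
                comps = _components(atoms, adjacency, removed)
                if len(comps) < 2:
                    continue  # the ring-bond pair did not disconnect
                for comp in comps:
                    register(comp, depth)
                    if comp not in seen_subsets:
                        seen_subsets[comp] = depth
                        next_frontier.append(comp)
        frontier = next_frontier

    ordered = sorted(
        records.values(),
        key=lambda r: (r.depth, -r.monoisotopic_mass, r.canonical_key),
    )
    return FragmentSet(parent=parent, members=ordered, max_depth=max_depth)


@dataclass(frozen=True)
class PeakLabel:
    """A peak-to-fragment assignment with its mass error in Da.

    ``theoretical_mz`` is the candidate m/z that matched, i.e.
    compute_mz(fragment mass + h_shift hydrogens, adduct).
    """

    peak_mz: float
    intensity: float
    fragment: FragmentRecord
    mass_error: float
    theoretical_mz: float
    h_shift: int


def label_peaks(
    peaks: Sequence[Tuple[float, float]],
    fragments: FragmentSet,
    adduct: "AdductSpec | str",
    tolerance: float = DEFAULT_TOLERANCE,
    h_shift: int = DEFAULT_H_SHIFT,
) -> List[PeakLabel]:
    """Assign each peak the fragment minimizing |mass error| within tolerance.

    Candidate m/z values are fragment masses shifted by -h_shift..+h_shift
    hydrogen masses, mapped through the adduct. Peaks with no candidate in
    the window are left unlabeled (omitted from the result).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if h_shift < 0:
        raise ValueError("h_shift must be >= 0")
    spec = resolve_adduct(adduct)
    candidates = []  # (theoretical mz, shift k, fragment)
    for fragment in fragments:
        for k in range(-h_shift, h_shift + 1):
            mz = compute_mz(fragment.monoisotopic_mass + k * HYDROGEN_MASS, spec)
            candidates.append((mz, k, fragment))
    labels: List[PeakLabel] = []
    for peak_mz, intensity in peaks:
        best = None
        for mz, k, fragment in candidates:
            err = peak_mz - mz
            if abs(err) <= tolerance and (best is None or abs(err) < abs(best[0])):
                best = (err, mz, k, fragment)
        if best is not None:
            err, mz, k, fragment = best
            labels.append(
                PeakLabel(
                    peak_mz=peak_mz,
                    intensity=intensity,
                    fragment=fragment,
                    mass_error=err,
                    theoretical_mz=mz,
                    h_shift=k,
                )
            )
    return labels


__all__ = [
    "DEFAULT_H_SHIFT",
    "DEFAULT_MAX_DEPTH",
    "DEFAULT_TOLERANCE",
    "FragmentRecord",
    "FragmentSet",
    "PeakLabel",
    "enumerate_fragments",
    "label_peaks",
]
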