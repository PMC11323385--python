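"""Chemistry primitives: parsing, fingerprints, similarity, SMARTS extraction.

The one non-standard operation here is :func:`selection_to_smarts`, which
turns a chemist's atom selection into a pair of SMARTS patterns:

* a *core* pattern encoding, for every selected atom, its element,
  aromaticity, ring membership and total hydrogen count, plus the bonds
  between selected atoms;
* an *expanded* pattern that additionally includes every atom directly
  bonded to the selection.  Shell atoms are encoded loosely (element and
  aromaticity only) so that, e.g., a flagged ketone carbonyl generalizes
  across ketones while still being distinguished from an amide.

Everything else (SMILES parsing, Morgan/ECFP fingerprints, substructure
matching) delegates to RDKit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

# RDKit logs every rejected SMILES at error level; invalid input is an
# expected condition here (we raise typed errors instead).
RDLogger.DisableLog("rdApp.error")


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class SmartsError(ValueError):
    """Raised for syntactically invalid SMARTS patterns."""


@dataclass(frozen=True, eq=False)
class ParsedMolecule:
    """A parsed molecular graph with its canonical identity.

    Attributes
    ----------
    mol:
        The underlying RDKit molecule (heavy atoms only; hydrogens implicit).
    heavy_atom_count:
        Number of non-hydrogen atoms; this is the molecular size MS(x) used
        by the size-desirability term of the reward.
    canonical_smiles:
        RDKit canonical SMILES; two ParsedMolecules compare equal iff their
        canonical SMILES agree.
    """

    mol: Chem.Mol = field(repr=False)
    heavy_atom_count: int
    canonical_smiles: str

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParsedMolecule):
            return NotImplemented
        return self.canonical_smiles == other.canonical_smiles

    def __hash__(self) -> int:
        return hash(self.canonical_smiles)


def parse_molecule(smiles: str) -> ParsedMolecule:
    """Parse a SMILES string, raising :class:`MoleculeParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise MoleculeParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"invalid SMILES: {smiles!r}")
    return ParsedMolecule(
        mol=mol,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        canonical_smiles=Chem.MolToSmiles(mol),
    )


@dataclass(frozen=True)
class Fingerprint:
    """A binary circular fingerprint stored as its set of on-bit positions."""

    bits: frozenset[int]
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit position outside [0, n_bits)")


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def morgan_fingerprint(
    mol: ParsedMolecule, radius: int = 2, n_bits: int = 2048
) -> Fingerprint:
    """Morgan (ECFP-style) circular fingerprint; radius 2 / 2048 bits = ECFP4."""
    bv = _morgan_generator(radius, n_bits).GetFingerprint(mol.mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), n_bits=n_bits, radius=radius)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a∩b| / |a∪b|; 0.0 when both fingerprints are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def _atom_smarts(atom: Chem.Atom, full: bool) -> str:
    """SMARTS primitive for one atom.

    Core atoms (``full=True``) carry element, aromaticity, ring membership
    and total-H count; shell atoms only element and aromaticity.
    """
    parts = [f"#{atom.GetAtomicNum()}", "a" if atom.GetIsAromatic() else "A"]
    if full:
        parts.append("R" if atom.IsInRing() else "!R")
        parts.append(f"H{atom.GetTotalNumHs()}")
    return "[" + ";".join(parts) + "]"


def _fragment_smarts(mol: Chem.Mol, atoms: Sequence[int], core: set[int]) -> str:
    symbols = [""] * mol.GetNumAtoms()
    for idx in atoms:
        symbols[idx] = _atom_smarts(mol.GetAtomWithIdx(idx), full=idx in core)
    # MolFragmentToSmiles with bracketed atom symbols and explicit bond
    # symbols yields a string that is simultaneously valid SMARTS.
    # Disconnected selections come out dot-separated (component grouping);
    # stereo is deliberately dropped (isomericSmiles=False).
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=list(atoms),
        atomSymbols=symbols,
        allBondsExplicit=True,
        isomericSmiles=False,
        canonical=True,
    )


def selection_to_smarts(
    mol: ParsedMolecule, atom_indices: Iterable[int]
) -> tuple[str, str]:
    """Derive (core_smarts, expanded_smarts) from a highlighted atom selection.

    Parameters
    ----------
    mol:
        The molecule the chemist annotated.
    atom_indices:
        0-based indices of the highlighted atoms (any non-empty subset;
        disconnected selections allowed and emitted as dot-joined components).

    Returns
    -------
    core_smarts, expanded_smarts:
        Both patterns are guaranteed to match ``mol``; the core pattern has
        an embedding whose atom set equals the selection, and the expanded
        pattern adds every distance-1 neighbor of the selection.
    """
    selection = set(atom_indices)
    if not selection:
        raise ValueError("atom selection must be non-empty")
    n = mol.heavy_atom_count
    bad = [i for i in selection if not (0 <= i < n)]
    if bad:
        raise IndexError(f"atom indices {bad} out of range for {n} heavy atoms")

    shell: set[int] = set()
    for idx in selection:
        for nbr in mol.mol.GetAtomWithIdx(idx).GetNeighbors():
            if nbr.GetIdx() not in selection:
                shell.add(nbr.GetIdx())

    core_smarts = _fragment_smarts(mol.mol, sorted(selection), selection)
    expanded_smarts = _fragment_smarts(
        mol.mol, sorted(selection | shell), selection
    )
    return core_smarts, expanded_smarts


def _compile_smarts(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise SmartsError(f"invalid SMARTS pattern: {pattern!r}")
    return query


def matches_pattern(mol: ParsedMolecule, smarts: str) -> bool:
    """Whether *mol* has at least one embedding of the SMARTS pattern."""
    return mol.mol.HasSubstructMatch(_compile_smarts(smarts))


def pattern_embeddings(
    mol: ParsedMolecule, smarts: str, max_matches: int = 10_000
) -> list[frozenset[int]]:
    """All distinct atom-sets of embeddings of *smarts* in *mol*."""
    matches = mol.mol.GetSubstructMatches(
        _compile_smarts(smarts), uniquify=True, maxMatches=max_matches
    )
    return [frozenset(m) for m in matches]


def count_liability_matches(
    mol: ParsedMolecule, smarts_list: Iterable[str]
) -> int:
    """Number of distinct patterns with at least one embedding in *mol*.

    Identical pattern strings are deduplicated first and multiple embeddings
    of one pattern count once, so a molecule with three ester groups and one
    flagged ester pattern contributes 1.
    """
    seen: set[str] = set()
    count = 0
    for pattern in smarts_list:
        if pattern in seen:
            continue
        seen.add(pattern)
        if mol.mol.HasSubstructMatch(_compile_smarts(pattern)):
            count += 1
    return count
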