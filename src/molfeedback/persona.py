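"""Simulated chemist: a deterministic feedback oracle and a fixture pool.

A :class:`Persona` is a rule set standing in for a medicinal chemist:
SMARTS patterns it dislikes (liabilities) and likes, plus an acceptable
heavy-atom size range.  :func:`simulate_feedback` applies the rules to one
molecule and emits a complete :class:`~molfeedback.feedback.FeedbackRecord`
— rating, substructure annotations derived from actual pattern embeddings,
and size property flags — so the whole closed loop is exercisable without a
human or a GUI.

:func:`generate_fixture_pool` enumerates a small scaffold × substituent
grammar (benzene, pyridine, cyclohexane, biphenyl decorated with up to two
of methyl / hydroxyl / nitro / acetamido / carboxyl) producing a few hundred
unique drug-like-ish fragments — deliberately tiny so loop experiments stay
desk-scale.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

from rdkit import Chem

from .chem import ParsedMolecule, selection_to_smarts
from .feedback import (
    FeedbackRecord,
    GlobalFeedback,
    LiabilityLabel,
    MoleculeEntry,
    SubstructureAnnotation,
)

RATING_ORDER = ("dislike", "sort_of_like", "like")


@dataclass(frozen=True)
class Persona:
    """A chemist's preference rules.

    Dislike dominates: any disliked pattern match sinks the molecule
    regardless of liked features, mirroring how a single liability vetoes a
    candidate in practice.  ``noise_rate`` resamples the rating uniformly
    with that probability, for robustness experiments.
    """

    disliked_smarts: tuple[str, ...] = ()
    liked_smarts: tuple[str, ...] = ()
    size_range: tuple[int, int] = (5, 50)
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must lie in [0, 1)")
        if not self.size_range[0] < self.size_range[1]:
            raise ValueError("size_range must satisfy min < max")
        for pattern in (*self.disliked_smarts, *self.liked_smarts):
            if Chem.MolFromSmarts(pattern) is None:
                raise ValueError(f"invalid persona SMARTS: {pattern!r}")


def _annotate(
    mol: ParsedMolecule,
    molecule_id: str,
    patterns: Sequence[str],
    polarity: str,
) -> list[SubstructureAnnotation]:
    annotations = []
    for i, pattern in enumerate(patterns):
        query = Chem.MolFromSmarts(pattern)
        match = mol.mol.GetSubstructMatch(query)
        if not match:
            continue
        atoms = frozenset(match)
        core, expanded = selection_to_smarts(mol, atoms)
        annotations.append(
            SubstructureAnnotation(
                molecule_id=molecule_id,
                atom_indices=atoms,
                label=LiabilityLabel(
                    name=f"{polarity}_feature_{i}", polarity=polarity, scope="project"
                ),
                core_smarts=core,
                expanded_smarts=expanded,
            )
        )
    return annotations


def simulate_feedback(
    mol: ParsedMolecule,
    persona: Persona,
    seed: int = 0,
    molecule_id: str = "m0",
    iteration: int = 0,
    external_score: float | None = None,
) -> FeedbackRecord:
    """Produce the persona's complete feedback on one molecule.

    Rating rule: any disliked pattern match → ``dislike``; else a liked
    pattern match with size in range → ``like``; else ``sort_of_like``.
    Every matched pattern yields an annotation over one embedding's atoms;
    a size outside the persona's range yields a ``size: concern`` flag.
    At ``noise_rate`` 0 the record is a deterministic function of
    (molecule, persona).
    """
    disliked = _annotate(mol, molecule_id, persona.disliked_smarts, "disliked")
    liked = _annotate(mol, molecule_id, persona.liked_smarts, "liked")
    n = mol.heavy_atom_count
    lo, hi = persona.size_range
    size_ok = lo <= n <= hi

    if disliked:
        rating = "dislike"
    elif liked and size_ok:
        rating = "like"
    else:
        rating = "sort_of_like"

    rng = random.Random(seed)
    if persona.noise_rate > 0 and rng.random() < persona.noise_rate:
        rating = rng.choice(RATING_ORDER)

    flags: tuple[tuple[str, str], ...] = ()
    if not size_ok:
        flags = (("size", "concern"),)

    return FeedbackRecord(
        molecule=MoleculeEntry(
            id=molecule_id,
            smiles=mol.canonical_smiles,
            source_iteration=iteration,
            external_score=external_score,
        ),
        global_feedback=GlobalFeedback(rating=rating, property_flags=flags),
        local=tuple(disliked + liked),
        iteration=iteration,
    )


# -- fixture pool grammar ------------------------------------------------

# Each scaffold template has two substitution slots; several positional
# variants per scaffold so the grammar yields distinct regio-isomers.
_SCAFFOLD_TEMPLATES = [
    "c1cc{0}cc{1}c1",          # benzene, meta
    "c1c{0}c{1}ccc1",          # benzene, ortho
    "c1c{0}cc{1}cc1",          # benzene, para
    "c1cc{0}nc{1}c1",          # pyridine
    "c1c{0}cnc{1}c1",          # pyridine variant
    "c1{0}ccnc{1}c1",          # pyridine variant
    "c1cc{0}cnc1{1}",          # pyridine variant
    "C1CC{0}CC{1}C1",          # cyclohexane 1,4
    "C1C{0}CC{1}CC1",          # cyclohexane 1,3
    "C1C{0}C{1}CCC1",          # cyclohexane 1,2
    "c1cc{0}c(-c2cc{1}ccc2)cc1",  # biphenyl, cross-ring
    "c1ccc(-c2cc{0}cc{1}c2)cc1",  # biphenyl, one-ring
    "c1cc{0}ccc1-c1cc{1}ccc1",    # biphenyl, cross-ring variant
    "c1c{0}cc(-c2c{1}cccc2)cc1",  # biphenyl, ortho-linked
]

_SUBSTITUENTS = ["", "(C)", "(O)", "([N+](=O)[O-])", "(NC(C)=O)", "(C(=O)O)"]


def grammar_capacity() -> list[str]:
    """All unique valid canonical SMILES the grammar can produce (sorted)."""
    seen: set[str] = set()
    for template in _SCAFFOLD_TEMPLATES:
        for a, b in product(_SUBSTITUENTS, repeat=2):
            smiles = template.format(a, b)
            mol = Chem.MolFromSmiles(smiles)
            if mol is not None:
                seen.add(Chem.MolToSmiles(mol))
    return sorted(seen)


def generate_fixture_pool(n: int, seed: int = 0) -> list[str]:
    """Seeded sample of *n* unique valid SMILES from the scaffold grammar."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = grammar_capacity()
    rng = random.Random(seed)
    rng.shuffle(pool)
    if n > len(pool):
        warnings.warn(
            f"requested {n} molecules but the grammar holds {len(pool)};"
            " returning all",
            stacklevel=2,
        )
        return pool
    return pool[:n]
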