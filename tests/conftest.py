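"""Shared fixtures: molecule pools, personas and random feedback tables."""

from __future__ import annotations

import random

import pytest

from molfeedback.chem import parse_molecule
from molfeedback.feedback import FeedbackTable
from molfeedback.persona import Persona, generate_fixture_pool, simulate_feedback

NITRO = "[N+](=O)[O-]"
CARBOXYL = "C(=O)[OX2H1]"
ACETAMIDO = "NC(C)=O"
HYDROXYL = "[OX2H]"

PERSONA_PATTERNS = [NITRO, CARBOXYL, ACETAMIDO, HYDROXYL]


@pytest.fixture(scope="session")
def pool() -> list[str]:
    return generate_fixture_pool(234, seed=0)


@pytest.fixture(scope="session")
def nitro_persona() -> Persona:
    return Persona(disliked_smarts=(NITRO,))


def random_persona(rng: random.Random) -> Persona:
    patterns = list(PERSONA_PATTERNS)
    rng.shuffle(patterns)
    n_dis = rng.randint(1, 2)
    n_like = rng.randint(0, 1)
    return Persona(
        disliked_smarts=tuple(patterns[:n_dis]),
        liked_smarts=tuple(patterns[n_dis : n_dis + n_like]),
        size_range=(rng.randint(3, 8), rng.randint(20, 60)),
    )


def random_table(
    rng: random.Random, pool: list[str], n_records: int | None = None
) -> FeedbackTable:
    """A feedback table populated by a random persona reviewing random molecules."""
    persona = random_persona(rng)
    n = n_records if n_records is not None else rng.randint(1, 6)
    table = FeedbackTable(global_properties=["size"])
    chosen = rng.sample(pool, min(n, len(pool)))
    for i, smiles in enumerate(chosen):
        record = simulate_feedback(
            parse_molecule(smiles),
            persona,
            seed=rng.randint(0, 10**6),
            molecule_id=f"r{i}",
            iteration=0,
        )
        table.add(record)
    return table
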