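"""Molecule file I/O: plain SMILES files and CSVs with a smiles column."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .chem import parse_molecule
from .feedback import MoleculeEntry

logger = logging.getLogger(__name__)


class MoleculeFileError(ValueError):
    """The molecule file is unreadable or contains no parseable molecules."""


def read_molecules(path: str | Path) -> list[MoleculeEntry]:
    """Read candidate molecules from a ``.smi`` or ``.csv`` file.

    ``.smi``: one SMILES per line, optionally followed by whitespace and an
    id.  ``.csv``: requires a ``smiles`` column; an ``id`` column is used
    when present.  Unparsable SMILES are skipped with a logged warning; ids
    are autogenerated (``m0``, ``m1``, …) when absent.
    """
    path = Path(path)
    if not path.exists():
        raise MoleculeFileError(f"molecule file not found: {path}")
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "smiles" not in frame.columns:
            raise MoleculeFileError(f"{path}: CSV must have a 'smiles' column")
        pairs = [
            (row["smiles"].strip(), str(row["id"]).strip() if "id" in frame.columns else "")
            for row in frame.to_dict("records")
        ]
    else:
        pairs = []
        for line in path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 1)
            pairs.append((fields[0], fields[1].strip() if len(fields) > 1 else ""))

    entries: list[MoleculeEntry] = []
    skipped = 0
    for i, (smiles, mol_id) in enumerate(pairs):
        try:
            parse_molecule(smiles)
        except ValueError:
            skipped += 1
            logger.warning("%s: skipping unparsable SMILES %r (entry %d)", path, smiles, i)
            continue
        entries.append(MoleculeEntry(id=mol_id or f"m{i}", smiles=smiles))
    if skipped:
        logger.warning("%s: skipped %d of %d entries", path, skipped, len(pairs))
    if not entries:
        raise MoleculeFileError(f"{path}: no parseable molecules")
    return entries
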