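"""Data model and persistence for chemist feedback.

A :class:`FeedbackTable` is an append-only list of :class:`FeedbackRecord`
objects — one per reviewed molecule per iteration — together with views
derived purely from the records:

* the liked / disliked / sort-of-liked SMILES sets (one per overall rating),
* the liked / disliked expanded-SMARTS lists (from local annotations),
* the current adaptive :class:`~molfeedback.reward.SizeWindow`, replayed
  deterministically from size flags in record order.

Persistence is a CSV of per-molecule rows plus a JSON sidecar of
substructure annotations; chemistry is persisted as SMARTS, never as bare
atom indices (indices are not stable across re-canonicalization).
Timestamps are informational and excluded from equality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chem import (
    Fingerprint,
    ParsedMolecule,
    morgan_fingerprint,
    parse_molecule,
    pattern_embeddings,
)
from .reward import RewardInputs, SizeWindow, update_size_window

RATINGS = ("dislike", "sort_of_like", "like")
POLARITIES = ("liked", "disliked")
SCOPES = ("project", "general")

_CSV_FIXED_COLUMNS = [
    "id",
    "smiles",
    "iteration",
    "rating",
    "external_score",
    "alternative_smiles",
]


class FeedbackValidationError(ValueError):
    """A record violates one of the data-model invariants."""


class DuplicateRecordError(FeedbackValidationError):
    """A (molecule id, iteration) pair was added twice."""


class FeedbackIOError(ValueError):
    """Feedback files are malformed or mutually inconsistent."""


@dataclass(frozen=True)
class MoleculeEntry:
    """One candidate molecule: id, structure and optional external score f(x)."""

    id: str
    smiles: str
    source_iteration: int = 0
    external_score: float | None = None


@dataclass(frozen=True)
class LiabilityLabel:
    """A named liability (or liked-feature) tag with polarity and scope.

    ``scope`` records whether the critique applies only to the current
    project or is generally valid across projects.
    """

    name: str
    polarity: str
    scope: str = "project"


@dataclass(frozen=True)
class SubstructureAnnotation:
    """A highlighted atom set with its derived core and expanded SMARTS."""

    molecule_id: str
    atom_indices: frozenset[int]
    label: LiabilityLabel
    core_smarts: str
    expanded_smarts: str


@dataclass(frozen=True)
class GlobalFeedback:
    """Whole-molecule feedback: overall rating, property flags, alternative."""

    rating: str
    property_flags: tuple[tuple[str, str], ...] = ()
    alternative_smiles: str | None = None

    def flags_dict(self) -> dict[str, str]:
        return dict(self.property_flags)


@dataclass(frozen=True)
class FeedbackRecord:
    """Complete feedback on one molecule at one loop iteration."""

    molecule: MoleculeEntry
    global_feedback: GlobalFeedback
    local: tuple[SubstructureAnnotation, ...] = ()
    iteration: int = 0
    timestamp: str = ""

    def stamped(self) -> "FeedbackRecord":
        if self.timestamp:
            return self
        return replace(
            self, timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds")
        )


def records_equal(a: FeedbackRecord, b: FeedbackRecord) -> bool:
    """Field-by-field equality, ignoring the informational timestamp."""
    return replace(a, timestamp="") == replace(b, timestamp="")


def _validate_record(
    record: FeedbackRecord, global_properties: Sequence[str] | None
) -> ParsedMolecule:
    mol_entry = record.molecule
    if not mol_entry.id:
        raise FeedbackValidationError("molecule id must be non-empty")
    if record.iteration < 0 or mol_entry.source_iteration < 0:
        raise FeedbackValidationError("iteration indices must be >= 0")
    try:
        pmol = parse_molecule(mol_entry.smiles)
    except ValueError as exc:
        raise FeedbackValidationError(
            f"record {mol_entry.id!r}: molecule smiles invalid ({exc})"
        ) from exc
    score = mol_entry.external_score
    if score is not None and not (math.isfinite(score) and 0 <= score <= 1):
        raise FeedbackValidationError(
            f"record {mol_entry.id!r}: external_score must be finite in [0,1]"
        )
    gf = record.global_feedback
    if gf.rating not in RATINGS:
        raise FeedbackValidationError(
            f"record {mol_entry.id!r}: rating {gf.rating!r} not one of {RATINGS}"
        )
    for prop, value in gf.property_flags:
        if value not in ("ok", "concern"):
            raise FeedbackValidationError(
                f"record {mol_entry.id!r}: flag value {value!r} for {prop!r}"
            )
        if global_properties is not None and prop not in global_properties:
            raise FeedbackValidationError(
                f"record {mol_entry.id!r}: unknown global property {prop!r}"
            )
    if gf.alternative_smiles is not None:
        try:
            parse_molecule(gf.alternative_smiles)
        except ValueError as exc:
            raise FeedbackValidationError(
                f"record {mol_entry.id!r}: alternative_smiles invalid ({exc})"
            ) from exc
    for ann in record.local:
        if ann.molecule_id != mol_entry.id:
            raise FeedbackValidationError(
                f"annotation molecule_id {ann.molecule_id!r} != record id"
                f" {mol_entry.id!r}"
            )
        if not ann.atom_indices:
            raise FeedbackValidationError("annotation atom_indices must be non-empty")
        if any(i < 0 or i >= pmol.heavy_atom_count for i in ann.atom_indices):
            raise FeedbackValidationError(
                f"record {mol_entry.id!r}: annotation atom index out of range"
            )
        if ann.label.polarity not in POLARITIES:
            raise FeedbackValidationError(
                f"annotation polarity {ann.label.polarity!r} not in {POLARITIES}"
            )
        if ann.label.scope not in SCOPES:
            raise FeedbackValidationError(
                f"annotation scope {ann.label.scope!r} not in {SCOPES}"
            )
        if not ann.label.name:
            raise FeedbackValidationError("annotation label name must be non-empty")
        if ann.atom_indices not in pattern_embeddings(pmol, ann.core_smarts):
            raise FeedbackValidationError(
                f"record {mol_entry.id!r}: core_smarts has no embedding equal to"
                " the annotated atom set"
            )
        if not any(
            ann.atom_indices <= emb
            for emb in pattern_embeddings(pmol, ann.expanded_smarts)
        ):
            raise FeedbackValidationError(
                f"record {mol_entry.id!r}: expanded_smarts has no embedding"
                " containing the annotated atom set"
            )
    return pmol


class FeedbackTable:
    """Append-only store of feedback records with derived reward views."""

    def __init__(
        self,
        global_properties: Sequence[str] | None = None,
        vocabulary: Sequence[str] | None = None,
        size_window: SizeWindow | None = None,
    ) -> None:
        self.global_properties = list(global_properties) if global_properties else []
        self.vocabulary = list(vocabulary) if vocabulary else []
        self._initial_window = size_window or SizeWindow()
        self.size_window = self._initial_window
        self._records: list[FeedbackRecord] = []
        self._keys: set[tuple[str, int]] = set()

    # -- views ----------------------------------------------------------
    @property
    def records(self) -> tuple[FeedbackRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def _smiles_by_rating(self, rating: str) -> set[str]:
        return {
            r.molecule.smiles for r in self._records if r.global_feedback.rating == rating
        }

    @property
    def liked_smiles(self) -> set[str]:
        return self._smiles_by_rating("like")

    @property
    def disliked_smiles(self) -> set[str]:
        return self._smiles_by_rating("dislike")

    @property
    def sort_of_liked_smiles(self) -> set[str]:
        return self._smiles_by_rating("sort_of_like")

    def _smarts_by_polarity(self, polarity: str) -> list[str]:
        return [
            ann.expanded_smarts
            for r in self._records
            for ann in r.local
            if ann.label.polarity == polarity
        ]

    @property
    def liked_smarts(self) -> list[str]:
        return self._smarts_by_polarity("liked")

    @property
    def disliked_smarts(self) -> list[str]:
        return self._smarts_by_polarity("disliked")

    def is_vocabulary_label(self, name: str) -> bool:
        """False for free-text labels the chemist typed outside the vocabulary."""
        return not self.vocabulary or name in self.vocabulary

    # -- mutation -------------------------------------------------------
    def add(self, record: FeedbackRecord) -> "FeedbackTable":
        key = (record.molecule.id, record.iteration)
        if key in self._keys:
            raise DuplicateRecordError(
                f"feedback for molecule {key[0]!r} at iteration {key[1]} already"
                " recorded"
            )
        pmol = _validate_record(record, self.global_properties or None)
        flags = record.global_feedback.flags_dict()
        if "size" in flags:
            n = pmol.heavy_atom_count
            if flags["size"] == "concern":
                mid = (self.size_window.low_center + self.size_window.high_center) / 2
                verdict = "too_small" if n < mid else "too_large"
            else:
                verdict = "ok"
            self.size_window = update_size_window(self.size_window, n, verdict)
        self._records.append(record.stamped())
        self._keys.add(key)
        return self


def add_record(table: FeedbackTable, record: FeedbackRecord) -> FeedbackTable:
    """Append one validated record; rejects duplicates and invalid records."""
    return table.add(record)


# -- persistence --------------------------------------------------------

def save_feedback(table: FeedbackTable, path: str | Path) -> None:
    """Write ``<path>.csv``-style per-molecule rows plus an annotation sidecar.

    *path* is treated as a directory; it receives ``feedback.csv`` and
    ``annotations.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in table.records:
        flags = r.global_feedback.flags_dict()
        row = {
            "id": r.molecule.id,
            "smiles": r.molecule.smiles,
            "iteration": r.iteration,
            "rating": r.global_feedback.rating,
            "external_score": (
                "" if r.molecule.external_score is None else r.molecule.external_score
            ),
            "alternative_smiles": r.global_feedback.alternative_smiles or "",
        }
        for prop in table.global_properties:
            row[prop] = flags.get(prop, "")
        rows.append(row)
    columns = _CSV_FIXED_COLUMNS + list(table.global_properties)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path / "feedback.csv", index=False, lineterminator="\n")

    annotations = [
        {
            "molecule_id": ann.molecule_id,
            "atom_indices": sorted(ann.atom_indices),
            "label_name": ann.label.name,
            "polarity": ann.label.polarity,
            "scope": ann.label.scope,
            "core_smarts": ann.core_smarts,
            "expanded_smarts": ann.expanded_smarts,
        }
        for r in table.records
        for ann in r.local
    ]
    (path / "annotations.json").write_text(
        json.dumps(annotations, indent=1) + "\n", encoding="utf-8"
    )


def load_feedback(
    path: str | Path,
    vocabulary: Sequence[str] | None = None,
    size_window: SizeWindow | None = None,
) -> FeedbackTable:
    """Reconstruct a table saved by :func:`save_feedback`.

    Records are replayed through :meth:`FeedbackTable.add`, so derived views
    and the adaptive size window are recomputed rather than trusted from
    disk.  The initial *size_window* must match the one the original table
    started from for the replayed window to agree.
    """
    path = Path(path)
    csv_path = path / "feedback.csv"
    ann_path = path / "annotations.json"
    if not csv_path.exists():
        raise FeedbackIOError(f"missing feedback CSV: {csv_path}")
    try:
        frame = pd.read_csv(csv_path, dtype={"id": str}, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FeedbackIOError(f"cannot parse {csv_path}: {exc}") from exc
    missing = [c for c in _CSV_FIXED_COLUMNS if c not in frame.columns]
    if missing:
        raise FeedbackIOError(f"{csv_path}: missing columns {missing}")
    properties = [c for c in frame.columns if c not in _CSV_FIXED_COLUMNS]

    raw_annotations: list[dict] = []
    if ann_path.exists():
        try:
            raw_annotations = json.loads(ann_path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise FeedbackIOError(f"cannot parse {ann_path}: {exc}") from exc

    ids = list(frame["id"])
    known = set(ids)
    by_molecule: dict[str, list[SubstructureAnnotation]] = {}
    for i, obj in enumerate(raw_annotations):
        try:
            ann = SubstructureAnnotation(
                molecule_id=obj["molecule_id"],
                atom_indices=frozenset(int(a) for a in obj["atom_indices"]),
                label=LiabilityLabel(
                    name=obj["label_name"],
                    polarity=obj["polarity"],
                    scope=obj["scope"],
                ),
                core_smarts=obj["core_smarts"],
                expanded_smarts=obj["expanded_smarts"],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FeedbackIOError(f"{ann_path}: annotation {i} malformed: {exc}") from exc
        if ann.molecule_id not in known:
            raise FeedbackIOError(
                f"{ann_path}: annotation {i} references unknown molecule_id"
                f" {ann.molecule_id!r}"
            )
        if ids.count(ann.molecule_id) > 1:
            raise FeedbackIOError(
                f"{ann_path}: molecule_id {ann.molecule_id!r} is ambiguous"
                " (multiple records share it)"
            )
        by_molecule.setdefault(ann.molecule_id, []).append(ann)

    table = FeedbackTable(
        global_properties=properties, vocabulary=vocabulary, size_window=size_window
    )
    for line, row in enumerate(frame.to_dict("records"), start=2):
        try:
            score_raw = str(row["external_score"]).strip()
            flags = tuple(
                (prop, str(row[prop]).strip())
                for prop in properties
                if str(row[prop]).strip()
            )
            record = FeedbackRecord(
                molecule=MoleculeEntry(
                    id=str(row["id"]),
                    smiles=str(row["smiles"]),
                    source_iteration=int(row["iteration"]),
                    external_score=float(score_raw) if score_raw else None,
                ),
                global_feedback=GlobalFeedback(
                    rating=str(row["rating"]),
                    property_flags=flags,
                    alternative_smiles=str(row["alternative_smiles"]).strip() or None,
                ),
                local=tuple(by_molecule.get(str(row["id"]), ())),
                iteration=int(row["iteration"]),
            )
            table.add(record)
        except (ValueError, FeedbackValidationError) as exc:
            raise FeedbackIOError(f"{csv_path} line {line}: {exc}") from exc
    return table


def derive_reward_inputs(
    table: FeedbackTable, radius: int = 2, n_bits: int = 2048
) -> RewardInputs:
    """Bridge the feedback table to the reward function's reference sets.

    Fingerprints one representative per distinct SMILES per rating class and
    deduplicates the expanded-SMARTS lists per polarity (first occurrence
    order preserved).  Deterministic given the table contents.
    """

    def fps(smiles_set: set[str]) -> frozenset[Fingerprint]:
        out = set()
        for smi in sorted(smiles_set):
            try:
                pmol = parse_molecule(smi)
            except ValueError as exc:
                raise FeedbackIOError(f"stored smiles unparsable: {smi!r}") from exc
            out.add(morgan_fingerprint(pmol, radius=radius, n_bits=n_bits))
        return frozenset(out)

    def dedupe(patterns: list[str]) -> tuple[str, ...]:
        return tuple(dict.fromkeys(patterns))

    return RewardInputs(
        liked_fps=fps(table.liked_smiles),
        disliked_fps=fps(table.disliked_smiles),
        sort_of_fps=fps(table.sort_of_liked_smiles),
        liked_smarts=dedupe(table.liked_smarts),
        disliked_smarts=dedupe(table.disliked_smarts),
        size_window=table.size_window,
    )
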