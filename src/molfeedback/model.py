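"""Preference reward model: a binary like/dislike classifier over fingerprints.

Feedback records are mapped to weighted binary training rows (like → 1,
dislike → 0, sort-of-like → 1 at half weight by default), optionally merged
with prior QSAR data (weight 1), and fitted with a seeded random-forest over
radius-2/2048-bit Morgan fingerprints.  The predicted probability of the
"liked" class is used directly as the scoring-function component f(x).

Also provides the nearest-reference lookup backing a "most similar active"
display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .chem import Fingerprint, ParsedMolecule, morgan_fingerprint, parse_molecule, tanimoto
from .feedback import FeedbackTable


class TrainingError(ValueError):
    """Raised when the feedback cannot support model training."""


@dataclass(frozen=True)
class TrainingRow:
    fingerprint: Fingerprint
    label: int
    weight: float
    origin: str  # "feedback" | "prior"


@dataclass(frozen=True)
class ClassifierSpec:
    """Injectable classifier configuration (tree ensemble by default)."""

    n_estimators: int = 100
    radius: int = 2
    n_bits: int = 2048


@dataclass
class RewardModelState:
    """A fitted preference classifier plus its featurizer and provenance."""

    spec: ClassifierSpec
    classifier: RandomForestClassifier | None = None
    n_feedback: int = 0
    n_prior: int = 0
    seed: int = 0

    @property
    def fitted(self) -> bool:
        return self.classifier is not None


def build_training_set(
    table: FeedbackTable,
    prior_rows: Sequence[tuple[str, int]] | None = None,
    feedback_weight: float = 1.0,
    sort_of_weight: float = 0.5,
    sort_of_policy: str = "half",
    radius: int = 2,
    n_bits: int = 2048,
) -> list[TrainingRow]:
    """Map feedback (and optional prior QSAR data) to weighted binary rows.

    like → label 1, dislike → label 0; sort_of_like → label 1 with weight
    ``sort_of_weight * feedback_weight`` under the default ``half`` policy,
    or omitted under ``drop``.  Prior rows get weight 1.
    """
    if feedback_weight < 1:
        raise ValueError("feedback_weight must be >= 1")
    if sort_of_policy not in ("half", "drop"):
        raise ValueError(f"unknown sort_of_policy: {sort_of_policy!r}")

    rows: list[TrainingRow] = []
    for record in table.records:
        rating = record.global_feedback.rating
        smiles = record.molecule.smiles
        try:
            pmol = parse_molecule(smiles)
        except ValueError as exc:
            raise TrainingError(
                f"record {record.molecule.id!r}: unparsable smiles {smiles!r}"
            ) from exc
        fp = morgan_fingerprint(pmol, radius=radius, n_bits=n_bits)
        if rating == "like":
            rows.append(TrainingRow(fp, 1, feedback_weight, "feedback"))
        elif rating == "dislike":
            rows.append(TrainingRow(fp, 0, feedback_weight, "feedback"))
        elif sort_of_policy == "half":
            rows.append(TrainingRow(fp, 1, sort_of_weight * feedback_weight, "feedback"))
    for i, (smiles, label) in enumerate(prior_rows or ()):
        if label not in (0, 1):
            raise TrainingError(f"prior row {i}: label must be 0 or 1, got {label!r}")
        try:
            pmol = parse_molecule(smiles)
        except ValueError as exc:
            raise TrainingError(f"prior row {i}: unparsable smiles {smiles!r}") from exc
        fp = morgan_fingerprint(pmol, radius=radius, n_bits=n_bits)
        rows.append(TrainingRow(fp, int(label), 1.0, "prior"))
    return rows


def _design_matrix(rows: Sequence[TrainingRow], n_bits: int) -> np.ndarray:
    X = np.zeros((len(rows), n_bits), dtype=np.uint8)
    for i, row in enumerate(rows):
        X[i, sorted(row.fingerprint.bits)] = 1
    return X


def train_reward_model(
    rows: Sequence[TrainingRow],
    spec: ClassifierSpec = ClassifierSpec(),
    seed: int = 0,
) -> RewardModelState:
    """Fit the preference classifier; deterministic under a fixed seed."""
    labels = {r.label for r in rows}
    if labels != {0, 1}:
        raise TrainingError(
            "training requires at least one liked and one disliked example;"
            " collect more feedback"
        )
    X = _design_matrix(rows, spec.n_bits)
    y = np.array([r.label for r in rows], dtype=np.int64)
    w = np.array([r.weight for r in rows], dtype=np.float64)
    clf = RandomForestClassifier(
        n_estimators=spec.n_estimators, random_state=seed, n_jobs=1
    )
    clf.fit(X, y, sample_weight=w)
    return RewardModelState(
        spec=spec,
        classifier=clf,
        n_feedback=sum(1 for r in rows if r.origin == "feedback"),
        n_prior=sum(1 for r in rows if r.origin == "prior"),
        seed=seed,
    )


def predict_preference(model: RewardModelState, mol: ParsedMolecule) -> float:
    """Probability that the chemist would like *mol*, in [0, 1]."""
    if not model.fitted:
        raise TrainingError("reward model is not fitted yet")
    fp = morgan_fingerprint(mol, radius=model.spec.radius, n_bits=model.spec.n_bits)
    x = np.zeros((1, model.spec.n_bits), dtype=np.uint8)
    x[0, sorted(fp.bits)] = 1
    proba = model.classifier.predict_proba(x)[0]
    idx = list(model.classifier.classes_).index(1)
    return float(proba[idx])


def most_similar_reference(
    query: ParsedMolecule,
    references: Sequence[tuple[str, ParsedMolecule]],
    radius: int = 2,
    n_bits: int = 2048,
) -> tuple[str, float]:
    """Nearest reference by Tanimoto similarity; ties broken by first occurrence."""
    if not references:
        raise ValueError("reference list must be non-empty")
    qfp = morgan_fingerprint(query, radius=radius, n_bits=n_bits)
    best_id, best_sim = references[0][0], -1.0
    for ref_id, ref_mol in references:
        sim = tanimoto(qfp, morgan_fingerprint(ref_mol, radius=radius, n_bits=n_bits))
        if sim > best_sim:
            best_id, best_sim = ref_id, sim
    return best_id, best_sim


# -- persistence --------------------------------------------------------

def save_model(model: RewardModelState, directory: str | Path) -> None:
    """Persist the fitted classifier plus a JSON manifest of its provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.classifier, directory / "model.bin")
    manifest = {
        "n_feedback": model.n_feedback,
        "n_prior": model.n_prior,
        "seed": model.seed,
        "n_estimators": model.spec.n_estimators,
        "radius": model.spec.radius,
        "n_bits": model.spec.n_bits,
        "fitted": model.fitted,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n", encoding="utf-8"
    )


def load_model(directory: str | Path) -> RewardModelState:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    spec = ClassifierSpec(
        n_estimators=manifest["n_estimators"],
        radius=manifest["radius"],
        n_bits=manifest["n_bits"],
    )
    classifier = joblib.load(directory / "model.bin") if manifest["fitted"] else None
    return RewardModelState(
        spec=spec,
        classifier=classifier,
        n_feedback=manifest["n_feedback"],
        n_prior=manifest["n_prior"],
        seed=manifest["seed"],
    )
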