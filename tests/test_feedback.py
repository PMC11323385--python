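"""Feedback table: validation, derived views, persistence round trips."""

import json
import random

import pytest

from molfeedback.chem import parse_molecule, selection_to_smarts
from molfeedback.feedback import (
    DuplicateRecordError,
    FeedbackIOError,
    FeedbackRecord,
    FeedbackTable,
    FeedbackValidationError,
    GlobalFeedback,
    LiabilityLabel,
    MoleculeEntry,
    SubstructureAnnotation,
    derive_reward_inputs,
    load_feedback,
    records_equal,
    save_feedback,
)
from molfeedback.reward import SizeWindow
from conftest import random_table


def make_record(
    mol_id="m1",
    smiles="c1ccccc1",
    rating="like",
    iteration=0,
    annotations=(),
    flags=(),
):
    return FeedbackRecord(
        molecule=MoleculeEntry(id=mol_id, smiles=smiles),
        global_feedback=GlobalFeedback(rating=rating, property_flags=tuple(flags)),
        local=tuple(annotations),
        iteration=iteration,
    )


def annotation_for(smiles, atoms, mol_id, polarity="disliked"):
    pmol = parse_molecule(smiles)
    core, expanded = selection_to_smarts(pmol, atoms)
    return SubstructureAnnotation(
        molecule_id=mol_id,
        atom_indices=frozenset(atoms),
        label=LiabilityLabel(name="test_label", polarity=polarity),
        core_smarts=core,
        expanded_smarts=expanded,
    )


class TestAddRecord:
    def test_like_routes_to_liked_set(self):
        table = FeedbackTable()
        table.add(make_record(rating="like"))
        assert table.liked_smiles == {"c1ccccc1"}
        assert table.disliked_smiles == set()
        assert table.liked_smarts == [] and table.disliked_smarts == []

    def test_two_disliked_annotations_grow_smarts_by_two(self):
        smiles = "O=[N+]([O-])c1ccc(O)cc1"
        anns = [
            annotation_for(smiles, {0, 1, 2}, "m1"),
            annotation_for(smiles, {6}, "m1"),
        ]
        table = FeedbackTable()
        table.add(make_record(smiles=smiles, rating="dislike", annotations=anns))
        assert len(table.disliked_smarts) == 2
        assert table.liked_smarts == []

    def test_duplicate_id_iteration_rejected(self):
        table = FeedbackTable()
        table.add(make_record())
        with pytest.raises(DuplicateRecordError):
            table.add(make_record(rating="dislike"))

    def test_rating_partition_is_total(self, pool):
        rng = random.Random(5)
        table = random_table(rng, pool, n_records=6)
        n = (
            len(table.liked_smiles)
            + len(table.disliked_smiles)
            + len(table.sort_of_liked_smiles)
        )
        assert n == len(table)

    @pytest.mark.parametrize(
        "record, fragment",
        [
            (make_record(smiles="C("), "smiles"),
            (make_record(rating="love"), "rating"),
            (make_record(mol_id=""), "id"),
            (
                make_record(annotations=[annotation_for("c1ccccc1", {0}, "other_id")]),
                "molecule_id",
            ),
        ],
    )
    def test_invalid_record_error_names_invariant(self, record, fragment):
        with pytest.raises(FeedbackValidationError, match=fragment):
            FeedbackTable().add(record)

    def test_unknown_global_property_rejected(self):
        table = FeedbackTable(global_properties=["size"])
        with pytest.raises(FeedbackValidationError, match="permeability"):
            table.add(make_record(flags=[("permeability", "concern")]))

    def test_append_only_does_not_mutate_existing(self):
        table = FeedbackTable()
        table.add(make_record(mol_id="a"))
        before = table.records[0]
        table.add(make_record(mol_id="b", smiles="CCO"))
        assert table.records[0] is before


class TestSizeWindowReplay:
    def test_concern_above_midpoint_shrinks_high(self):
        table = FeedbackTable(global_properties=["size"])
        big = "C" * 50
        table.add(make_record(smiles=big, rating="dislike", flags=[("size", "concern")]))
        assert table.size_window.high_center == pytest.approx(60 + 0.25 * (50 - 60))

    def test_ok_inside_window_leaves_window(self):
        table = FeedbackTable(global_properties=["size"])
        table.add(make_record(smiles="C" * 30, rating="like", flags=[("size", "ok")]))
        assert table.size_window == SizeWindow()


class TestPersistence:
    def test_round_trip_five_records(self, tmp_path, pool):
        rng = random.Random(17)
        table = random_table(rng, pool, n_records=5)
        save_feedback(table, tmp_path)
        loaded = load_feedback(tmp_path)
        assert len(loaded) == len(table)
        for a, b in zip(table.records, loaded.records):
            assert records_equal(a, b)
        assert loaded.liked_smiles == table.liked_smiles
        assert loaded.disliked_smarts == table.disliked_smarts
        assert loaded.size_window == table.size_window

    def test_empty_table_round_trip(self, tmp_path):
        save_feedback(FeedbackTable(global_properties=["size"]), tmp_path)
        loaded = load_feedback(tmp_path)
        assert len(loaded) == 0
        assert loaded.global_properties == ["size"]

    def test_round_trip_many_random_tables(self, tmp_path, pool):
        """Load(save(T)) equals T for 100 generated tables."""
        rng = random.Random(23)
        for i in range(100):
            table = random_table(rng, pool)
            directory = tmp_path / f"t{i}"
            save_feedback(table, directory)
            loaded = load_feedback(directory)
            assert len(loaded) == len(table)
            assert all(
                records_equal(a, b) for a, b in zip(table.records, loaded.records)
            )
            assert loaded.size_window == table.size_window

    def test_annotation_with_unknown_molecule_id_fails_load(self, tmp_path):
        table = FeedbackTable()
        table.add(make_record())
        save_feedback(table, tmp_path)
        ann = {
            "molecule_id": "ghost",
            "atom_indices": [0],
            "label_name": "x",
            "polarity": "disliked",
            "scope": "project",
            "core_smarts": "[#6]",
            "expanded_smarts": "[#6]",
        }
        (tmp_path / "annotations.json").write_text(json.dumps([ann]))
        with pytest.raises(FeedbackIOError, match="ghost"):
            load_feedback(tmp_path)

    def test_truncated_csv_reports_context(self, tmp_path):
        table = FeedbackTable()
        table.add(make_record())
        save_feedback(table, tmp_path)
        csv = tmp_path / "feedback.csv"
        csv.write_text(csv.read_text().replace("c1ccccc1", "c1ccccc"))
        with pytest.raises(FeedbackIOError, match="line 2"):
            load_feedback(tmp_path)


class TestDeriveRewardInputs:
    def test_empty_table_yields_empty_inputs(self):
        inputs = derive_reward_inputs(FeedbackTable())
        assert not inputs.liked_fps and not inputs.disliked_fps and not inputs.sort_of_fps
        assert inputs.liked_smarts == () and inputs.disliked_smarts == ()

    def test_identical_expanded_smarts_deduplicated(self):
        smiles = "O=[N+]([O-])c1ccccc1"
        table = FeedbackTable()
        table.add(
            make_record(
                mol_id="a",
                smiles=smiles,
                rating="dislike",
                annotations=[annotation_for(smiles, {0, 1, 2}, "a")],
            )
        )
        table.add(
            make_record(
                mol_id="b",
                smiles=smiles,
                rating="dislike",
                iteration=1,
                annotations=[annotation_for(smiles, {0, 1, 2}, "b")],
            )
        )
        inputs = derive_reward_inputs(table)
        assert len(inputs.disliked_smarts) == 1
        assert len(table.disliked_smarts) == 2  # the raw view keeps both

    def test_one_like_one_dislike_fingerprint_counts(self):
        table = FeedbackTable()
        table.add(make_record(mol_id="a", smiles="c1ccccc1", rating="like"))
        table.add(make_record(mol_id="b", smiles="CCO", rating="dislike"))
        inputs = derive_reward_inputs(table)
        assert len(inputs.liked_fps) == 1
        assert len(inputs.disliked_fps) == 1
        assert len(inputs.sort_of_fps) == 0
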