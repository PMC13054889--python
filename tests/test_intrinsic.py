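"""Route popularity, fill-a-plate ledger dynamics and persistence."""

import pytest

from routerewards.extrinsic import ConfigurationError
from routerewards.intrinsic import (
    BatchContext,
    BatchMolecule,
    LedgerError,
    PlateLedger,
    fill_a_plate_update,
    filled_plate_count,
    ledger_load,
    ledger_save,
    popularity_scores,
)

from conftest import linear_route


def mol(mol_id: str, *code_lists: list[str], solved: bool = True) -> BatchMolecule:
    return BatchMolecule(
        mol_id,
        [linear_route(mol_id, codes, solved=solved) for codes in code_lists],
    )


class TestPopularity:
    def test_cohort_fraction(self):
        batch = BatchContext(
            [
                mol("m1", ["2.1.10"]),
                mol("m2", ["2.1.3"]),
                mol("m3", ["2.1.7"]),
                mol("m4", ["3.1.2"]),
            ]
        )
        scores = popularity_scores(batch)
        assert scores["m1"] == scores["m2"] == scores["m3"] == pytest.approx(0.75)
        assert scores["m4"] == pytest.approx(0.25)

    def test_universally_shared_signature_scores_one(self):
        batch = BatchContext([mol(f"m{i}", ["2.1.10"]) for i in range(8)])
        assert set(popularity_scores(batch).values()) == {1.0}

    def test_unrecognized_reaction_scores_zero(self):
        batch = BatchContext(
            [mol("m1", ["2.1.10"]), mol("m2", ["not a code"])]
        )
        assert popularity_scores(batch)["m2"] == 0.0

    def test_unsolved_routes_do_not_count(self):
        batch = BatchContext(
            [mol("m1", ["2.1.10"]), mol("m2", ["2.1.3"], solved=False)]
        )
        scores = popularity_scores(batch)
        assert scores["m1"] == pytest.approx(0.5)  # cohort of 1 out of N=2
        assert scores["m2"] == 0.0

    def test_molecule_takes_its_best_signature(self):
        batch = BatchContext(
            [
                mol("m1", ["2.1.10"], ["3.1.2"]),
                mol("m2", ["2.1.3"]),
                mol("m3", ["9.9.9"]),
            ]
        )
        assert popularity_scores(batch)["m1"] == pytest.approx(2 / 3)

    def test_empty_batch_is_an_error(self):
        with pytest.raises(ValueError):
            popularity_scores(BatchContext([]))

    def test_max_score_equals_largest_cohort_fraction(self):
        batch = BatchContext(
            [mol(f"a{i}", ["2.1.1"]) for i in range(3)]
            + [mol(f"b{i}", ["3.1.1"]) for i in range(2)]
        )
        assert max(popularity_scores(batch).values()) == pytest.approx(3 / 5)


def preloaded_ledger(capacity: int, n_preload: int, codes: list[str]) -> PlateLedger:
    """Fill one signature by replaying batches through the update rule."""
    ledger = PlateLedger(capacity=capacity)
    batch = BatchContext([mol(f"pre{i}", codes) for i in range(n_preload)])
    fill_a_plate_update(batch, ledger, exclude_molecules=False)
    return ledger


class TestFillAPlate:
    def test_reward_is_filling_ratio_after_assignment(self):
        ledger = preloaded_ledger(1000, 699, ["2.1.10"])
        rewards, ledger = fill_a_plate_update(
            BatchContext([mol("new", ["2.1.3"])]), ledger
        )
        assert rewards["new"] == pytest.approx(0.7)

    def test_first_molecule_of_fresh_plate_bootstraps(self):
        ledger = PlateLedger(capacity=1000)
        rewards, _ = fill_a_plate_update(BatchContext([mol("m", ["2.1.1"])]), ledger)
        assert rewards["m"] == pytest.approx(0.001)

    def test_hand_replay_of_three_molecule_batch(self):
        ledger = PlateLedger(capacity=10)
        batch = BatchContext(
            [mol("m1", ["2.1.1"]), mol("m2", ["2.1.2"]), mol("m3", ["3.1.1"])]
        )
        rewards, ledger = fill_a_plate_update(batch, ledger)
        # m1 opens plate {2.1} (1/10); m2 joins it (2/10); m3 opens {3.1}
        assert rewards == {
            "m1": pytest.approx(0.1),
            "m2": pytest.approx(0.2),
            "m3": pytest.approx(0.1),
        }

    def test_saturated_signature_scores_zero(self):
        ledger = preloaded_ledger(5, 5, ["2.1.1"])
        assert filled_plate_count(ledger) == 1
        rewards, _ = fill_a_plate_update(BatchContext([mol("m", ["2.1.9"])]), ledger)
        assert rewards["m"] == 0.0

    def test_molecule_prefers_fullest_unsaturated_plate(self):
        ledger = preloaded_ledger(10, 4, ["2.1.1"])
        batch = BatchContext([mol("m", ["2.1.2"], ["3.1.1"])])
        rewards, ledger = fill_a_plate_update(batch, ledger)
        assert ledger.assignments["m"] == ("2.1",)
        assert rewards["m"] == pytest.approx(0.5)

    def test_tie_broken_lexicographically(self):
        ledger = PlateLedger(capacity=10)
        batch = BatchContext([mol("m", ["3.1.1"], ["2.1.1"])])
        _, ledger = fill_a_plate_update(batch, ledger)
        assert ledger.assignments["m"] == ("2.1",)

    def test_invalid_signature_scores_zero(self):
        rewards, _ = fill_a_plate_update(
            BatchContext([mol("m", ["garbage"])]), PlateLedger(capacity=10)
        )
        assert rewards["m"] == 0.0

    def test_unsolved_routes_still_contribute_signatures(self):
        rewards, _ = fill_a_plate_update(
            BatchContext([mol("m", ["2.1.1"], solved=False)]),
            PlateLedger(capacity=10),
        )
        assert rewards["m"] == pytest.approx(0.1)

    def test_exclusion_retires_contributors(self):
        ledger = PlateLedger(capacity=2)
        batch = BatchContext([mol("m1", ["2.1.1"]), mol("m2", ["2.1.2"])])
        _, ledger = fill_a_plate_update(batch, ledger, exclude_molecules=True)
        assert ledger.consumed == {"m1", "m2"}
        rewards, _ = fill_a_plate_update(
            BatchContext([mol("m1", ["3.1.1"])]), ledger, exclude_molecules=True
        )
        assert rewards["m1"] == 0.0

    def test_no_molecule_on_two_plates_under_exclusion(self):
        ledger = PlateLedger(capacity=3)
        for codes in (["2.1.1"], ["3.1.1"], ["2.1.1"]):
            batch = BatchContext([mol("dup", codes)])
            fill_a_plate_update(batch, ledger, exclude_molecules=True)
        assert sum("dup" in members for members in ledger.members.values()) == 1

    def test_duplicate_without_exclusion_gets_current_ratio(self):
        ledger = PlateLedger(capacity=10)
        fill_a_plate_update(
            BatchContext([mol("dup", ["2.1.1"])]), ledger, exclude_molecules=False
        )
        fill_a_plate_update(
            BatchContext([mol("other", ["2.1.2"])]), ledger, exclude_molecules=False
        )
        rewards, ledger = fill_a_plate_update(
            BatchContext([mol("dup", ["2.1.3"])]), ledger, exclude_molecules=False
        )
        assert rewards["dup"] == pytest.approx(0.2)  # not re-incremented
        assert ledger.count(("2.1",)) == 2

    def test_count_conservation(self):
        ledger = PlateLedger(capacity=50)
        for i in range(5):
            batch = BatchContext(
                [mol(f"m{i}-{j}", [f"{1 + j % 3}.1.{j + 1}"]) for j in range(8)]
            )
            fill_a_plate_update(batch, ledger)
        assert sum(ledger.counts.values()) == len(ledger.assignments)

    def test_filled_plate_count_monotone(self):
        ledger = PlateLedger(capacity=2)
        counts = []
        for i in range(6):
            batch = BatchContext([mol(f"m{i}", [f"{1 + i % 2}.1.1"])])
            fill_a_plate_update(batch, ledger)
            counts.append(filled_plate_count(ledger))
        assert counts == sorted(counts)
        assert filled_plate_count(PlateLedger()) == 0

    def test_nonpositive_capacity_rejected(self):
        with pytest.raises(ConfigurationError):
            PlateLedger(capacity=0)


class TestLedgerPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        ledger = preloaded_ledger(3, 3, ["2.1.1"])
        fill_a_plate_update(BatchContext([mol("x", ["3.1.1"])]), ledger)
        path = tmp_path / "ledger.json"
        ledger_save(ledger, path)
        loaded = ledger_load(path)
        assert loaded.capacity == ledger.capacity
        assert loaded.members == ledger.members
        assert loaded.saturated == ledger.saturated
        assert loaded.consumed == ledger.consumed
        assert loaded.assignments == ledger.assignments

    def test_loading_then_updating_equals_uninterrupted_run(self, tmp_path):
        batches = [
            BatchContext([mol(f"m{i}-{j}", [f"{1 + j % 2}.1.{j + 1}"])
                          for j in range(4)])
            for i in range(4)
        ]
        straight = PlateLedger(capacity=5)
        for b in batches:
            fill_a_plate_update(b, straight)

        resumed = PlateLedger(capacity=5)
        path = tmp_path / "ledger.json"
        for i, b in enumerate(batches):
            fill_a_plate_update(b, resumed)
            if i == 1:
                ledger_save(resumed, path)
                resumed = ledger_load(path)
        assert resumed.members == straight.members
        assert resumed.saturated == straight.saturated

    def test_fresh_ledger_serializes_minimally(self, tmp_path):
        path = tmp_path / "fresh.json"
        ledger_save(PlateLedger(capacity=7), path)
        loaded = ledger_load(path)
        assert loaded.capacity == 7 and not loaded.members

    def test_corrupt_file_raises_ledger_error(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text("{not json")
        with pytest.raises(LedgerError):
            ledger_load(bad)
        bad.write_text('{"schema": "something-else"}')
        with pytest.raises(LedgerError):
            ledger_load(bad)


class TestBatchContext:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            BatchContext([mol("m", ["2.1.1"]), mol("m", ["3.1.1"])])
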