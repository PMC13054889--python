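"""Batch-level intrinsic rewards: route popularity and plate filling.

Route popularity rewards molecules whose solved routes share a route
signature with many other molecules in the same batch: for signature S,
``Pop(S) = |M_S| / N`` where ``M_S`` is the set of batch molecules with
a solved route of signature S and N the batch size; each molecule takes
the maximum over its own solved-route signatures.

Fill-a-plate extends this across batches with a persistent ledger of
virtual parallel-synthesis plates.  Each valid signature owns one plate
of capacity C; a molecule is assigned to the fullest unsaturated plate
among its candidate signatures and rewarded with that plate's filling
ratio (0.7 for a plate 70% full).  A plate that reaches capacity is
saturated: its signature is never scored again, and (optionally) its
member molecules are excluded from all future plates, which pushes
generation toward fresh synthetic routes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .extrinsic import ConfigurationError
from .route_model import RouteSignature, RouteTree, route_signature
from .taxonomy import SignatureLevel

SigKey = tuple[str, ...]


class LedgerError(ValueError):
    pass


@dataclass
class BatchMolecule:
    """One generated molecule with its candidate routes.

    ``archetype``, ``hit`` and ``property_score`` are optional
    annotations attached by generators (the simulator uses them); the
    rewards themselves only read ``mol_id`` and ``trees``.
    """

    mol_id: str
    trees: list[RouteTree]
    archetype: int | None = None
    hit: bool | None = None
    property_score: float | None = None


@dataclass
class BatchContext:
    molecules: list[BatchMolecule]
    epoch: int = 0

    def __post_init__(self) -> None:
        ids = [m.mol_id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mol_ids within a batch")

    @property
    def N(self) -> int:
        return len(self.molecules)


def _usable(sig: RouteSignature) -> bool:
    # the empty signature (zero-step route) is not a synthesis plate
    return sig.valid and bool(sig.codes)


def popularity_scores(
    batch: BatchContext, level: SignatureLevel = SignatureLevel.CLASS
) -> dict[str, float]:
    """Per-molecule route-popularity scores Q_i in [0, 1].

    Only solved routes contribute; molecules with no solved route or
    only invalid signatures score 0.
    """
    if batch.N == 0:
        raise ValueError("empty batch")
    cohorts: dict[SigKey, set[str]] = {}
    per_mol: dict[str, set[SigKey]] = {m.mol_id: set() for m in batch.molecules}
    for mol in batch.molecules:
        for tree in mol.trees:
            if not tree.solved:
                continue
            sig = route_signature(tree, level)
            if not _usable(sig):
                continue
            cohorts.setdefault(sig.key, set()).add(mol.mol_id)
            per_mol[mol.mol_id].add(sig.key)
    return {
        mol_id: max((len(cohorts[k]) / batch.N for k in keys), default=0.0)
        for mol_id, keys in per_mol.items()
    }


@dataclass
class PlateLedger:
    """Cross-batch plate state: one plate per route signature.

    ``members`` maps each signature key to the set of distinct molecules
    assigned to it (the plate count is its size); ``saturated`` holds
    signatures whose plate reached capacity; ``consumed`` the molecules
    retired with a filled plate when exclusion is enabled;
    ``assignments`` the signature each molecule was assigned to.
    """

    capacity: int = 1000
    members: dict[SigKey, set[str]] = field(default_factory=dict)
    saturated: set[SigKey] = field(default_factory=set)
    consumed: set[str] = field(default_factory=set)
    assignments: dict[str, SigKey] = field(default_factory=dict)
    filled_epoch: dict[SigKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ConfigurationError("plate capacity must be positive")

    def count(self, key: SigKey) -> int:
        return len(self.members.get(key, ()))

    @property
    def counts(self) -> dict[SigKey, int]:
        return {k: len(v) for k, v in self.members.items()}


def fill_a_plate_update(
    batch: BatchContext,
    ledger: PlateLedger,
    exclude_molecules: bool = True,
    level: SignatureLevel = SignatureLevel.CLASS,
) -> tuple[dict[str, float], PlateLedger]:
    """Score a batch and advance the plate ledger (mutated in place).

    Molecules are processed in batch order.  Both solved and unsolved
    routes contribute candidate signatures.  Each new molecule joins the
    fullest unsaturated plate among its valid signatures (ties broken by
    lexicographically smallest signature) and is rewarded with the
    filling ratio *after* its own assignment, so the first molecule of a
    fresh plate earns 1/C rather than a hard zero.  Molecules retired
    into a filled plate (with exclusion) and molecules whose every
    candidate plate is saturated score 0.  Re-appearing molecules never
    re-increment a count: they keep their original plate and are scored
    on its current ratio (0 under exclusion).
    """
    C = ledger.capacity
    rewards: dict[str, float] = {}
    for mol in batch.molecules:
        if mol.mol_id in ledger.consumed:
            rewards[mol.mol_id] = 0.0
            continue
        if mol.mol_id in ledger.assignments:
            if exclude_molecules:
                rewards[mol.mol_id] = 0.0
            else:
                key = ledger.assignments[mol.mol_id]
                rewards[mol.mol_id] = (
                    0.0 if key in ledger.saturated else ledger.count(key) / C
                )
            continue
        candidates = set()
        for tree in mol.trees:
            sig = route_signature(tree, level)
            if _usable(sig) and sig.key not in ledger.saturated:
                candidates.add(sig.key)
        if not candidates:
            rewards[mol.mol_id] = 0.0
            continue
        key = min(candidates, key=lambda k: (-ledger.count(k), k))
        plate = ledger.members.setdefault(key, set())
        plate.add(mol.mol_id)
        ledger.assignments[mol.mol_id] = key
        rewards[mol.mol_id] = len(plate) / C
        if len(plate) >= C:
            ledger.saturated.add(key)
            ledger.filled_epoch.setdefault(key, batch.epoch)
            if exclude_molecules:
                ledger.consumed.update(plate)
    return rewards, ledger


def filled_plate_count(ledger: PlateLedger) -> int:
    """Cumulative number of saturated (filled) plates."""
    return len(ledger.saturated)


LEDGER_SCHEMA = "plate-ledger/1"


def ledger_save(ledger: PlateLedger, path: str | Path) -> None:
    doc = {
        "schema": LEDGER_SCHEMA,
        "capacity": ledger.capacity,
        "plates": [
            {
                "signature": list(key),
                "members": sorted(members),
                "saturated": key in ledger.saturated,
                "filled_epoch": ledger.filled_epoch.get(key),
            }
            for key, members in sorted(ledger.members.items())
        ],
        "consumed": sorted(ledger.consumed),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def ledger_load(path: str | Path) -> PlateLedger:
    """Load a ledger; raises :class:`LedgerError` on corrupt documents."""
    try:
        doc: Any = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise LedgerError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("schema") != LEDGER_SCHEMA:
        raise LedgerError(f"{path}: missing or unsupported ledger schema")
    try:
        ledger = PlateLedger(capacity=int(doc["capacity"]))
        for plate in doc.get("plates", []):
            key = tuple(plate["signature"])
            members = set(plate["members"])
            if len(members) > ledger.capacity:
                raise LedgerError(f"{path}: plate {key} exceeds capacity")
            ledger.members[key] = members
            for mol_id in members:
                if mol_id in ledger.assignments:
                    raise LedgerError(
                        f"{path}: molecule {mol_id!r} appears on two plates"
                    )
                ledger.assignments[mol_id] = key
            if plate.get("saturated"):
                if len(members) != ledger.capacity:
                    raise LedgerError(
                        f"{path}: plate {key} marked saturated below capacity"
                    )
                ledger.saturated.add(key)
            if plate.get("filled_epoch") is not None:
                ledger.filled_epoch[key] = int(plate["filled_epoch"])
        ledger.consumed = set(doc.get("consumed", []))
    except (KeyError, TypeError) as exc:
        raise LedgerError(f"{path}: malformed ledger field ({exc})") from exc
    if not ledger.consumed <= set(ledger.assignments):
        raise LedgerError(f"{path}: consumed molecules must be assigned")
    return ledger
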