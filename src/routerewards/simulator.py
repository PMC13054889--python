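"""Desk-scale synthetic world and generation loop for exercising rewards.

The simulator replaces the full generative stack (an RNN generator,
retrosynthesis search over a real building-block stock, a reaction
classifier, 3D property oracles) with the smallest system that the
reward functions can still steer:

* a **world** with a hierarchical reaction taxonomy, a finite stock
  catalog, and a handful of **route archetypes** — families of
  molecules sharing reaction chemistry, step-count statistics,
  solvability and a surrogate "hit" probability standing in for
  property oracles;
* a **bandit policy** over archetypes updated by multiplicative
  weights, the smallest policy that can respond to a per-molecule
  reward signal.

Every molecule is identified by (archetype, draw index) with a finite
per-archetype analogue pool, so duplicate regeneration — a real feature
of generative runs that the cumulative-unique metrics depend on — can
occur.  All of a molecule's properties (routes, solvability, hit) are
derived from a per-identity RNG, so the same molecule always reappears
with the same routes.  Runs are fully deterministic per seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .extrinsic import (
    ConfigurationError,
    RRConfig,
    SFConfig,
    best_reference_distance,
    rrscore_molecule,
    sfscore_molecule,
)
from .intrinsic import (
    BatchContext,
    BatchMolecule,
    PlateLedger,
    fill_a_plate_update,
    filled_plate_count,
    popularity_scores,
)
from .mpo import ComponentScore, combine
from .route_model import (
    MoleculeNode,
    MoleculeRecord,
    ReactionNode,
    RouteTree,
    StockCatalog,
    StockStatus,
    _parse_classification,
)
from .taxonomy import SignatureLevel, parse_code
from .ted import OrderedTree

REWARD_NAMES = ("sfscore", "rrscore", "popularity", "fill_a_plate", "control")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class Archetype:
    """A family of molecules sharing route chemistry and properties.

    ``steps`` is a distribution over reaction-step counts; each step's
    reaction is drawn from ``classes`` (class-level codes) with a random
    named-reaction id, except when ``named_route`` pins the primary
    route to an exact named-level chain.  ``pool`` bounds the number of
    distinct analogues the family can ever produce.
    """

    name: str
    classes: tuple[str, ...]
    steps: tuple[tuple[int, float], ...]
    solvability: float
    hit_rate: float
    pool: int = 2000
    named_route: tuple[str, ...] | None = None


def default_archetypes() -> tuple[Archetype, ...]:
    return (
        Archetype(
            "ref-ester-amide-suzuki",
            classes=("2.1", "3.1"),
            steps=((2, 1.0),),
            solvability=0.9,
            hit_rate=0.15,
            pool=1500,
            named_route=("2.1.10", "3.1.2"),
        ),
        Archetype(
            "amide",
            classes=("2.1", "2.2", "2.3"),
            steps=((1, 0.6), (2, 0.3), (3, 0.1)),
            solvability=0.85,
            hit_rate=0.17,
            pool=2500,
        ),
        Archetype(
            "suzuki",
            classes=("3.1", "3.2", "3.3"),
            steps=((1, 0.5), (2, 0.4), (3, 0.1)),
            solvability=0.8,
            hit_rate=0.13,
            pool=2500,
        ),
        Archetype(
            "n-arylation",
            classes=("1.3", "1.7", "1.8"),
            steps=((1, 0.7), (2, 0.3)),
            solvability=0.75,
            hit_rate=0.12,
            pool=2000,
        ),
        Archetype(
            "s-substitution",
            classes=("1.8",),
            steps=((1, 0.9), (2, 0.1)),
            solvability=0.9,
            hit_rate=0.14,
            pool=3000,
        ),
        Archetype(
            "multi-step-mixed",
            classes=("2.1", "3.1", "1.3", "2.2", "9.1", "10.1"),
            steps=((2, 0.4), (3, 0.6)),
            solvability=0.65,
            hit_rate=0.10,
            pool=2000,
        ),
    )


@dataclass(frozen=True)
class WorldSpec:
    """Sizes and distributions defining the synthetic world."""

    superclasses: int = 12
    classes_per_superclass: int = 3
    named_per_class: int = 12
    stock_size: int = 5000
    internal_fraction: float = 0.3
    archetypes: tuple[Archetype, ...] = field(default_factory=default_archetypes)
    second_tree_prob: float = 0.4
    unrecognized_rate: float = 0.02
    hit_property_score: float = 0.85
    miss_property_score: float = 0.25

    def validate(self) -> None:
        if self.superclasses < 1 or self.stock_size < 1:
            raise ConfigurationError("world sizes must be positive")
        if len(self.archetypes) < 2:
            raise ConfigurationError("need at least 2 archetypes")
        for p in (
            self.internal_fraction,
            self.second_tree_prob,
            self.unrecognized_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        for arch in self.archetypes:
            if not 0.0 <= arch.solvability <= 1.0 or not 0.0 <= arch.hit_rate <= 1.0:
                raise ConfigurationError(f"bad probabilities in archetype {arch.name}")
            if abs(sum(p for _, p in arch.steps) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"step distribution of {arch.name} must sum to 1"
                )
            if any(n < 1 for n, _ in arch.steps):
                raise ConfigurationError("generated routes have at least one step")


@dataclass
class World:
    spec: WorldSpec
    seed: int
    catalog: StockCatalog
    reference_route: OrderedTree


def _chain(codes: Sequence[str]) -> OrderedTree:
    tree: OrderedTree | None = None
    for code in reversed(codes):
        tree = OrderedTree(parse_code(code), (tree,) if tree else ())
    assert tree is not None
    return tree


def build_world(spec: WorldSpec, seed: int) -> World:
    """Deterministic taxonomy, stock and reference route for a seed."""
    spec.validate()
    n_internal = int(spec.stock_size * spec.internal_fraction)
    entries = {
        f"S{i:06d}": (
            StockStatus.INTERNAL if i < n_internal else StockStatus.COMMERCIAL
        )
        for i in range(spec.stock_size)
    }
    reference = _chain(("2.1.10", "3.1.2"))
    return World(spec, seed % _SEED_MOD, StockCatalog(entries), reference)


def _stock_leaf(world: World, rng: np.random.Generator) -> MoleculeNode:
    idx = int(rng.integers(world.spec.stock_size))
    mol_id = f"S{idx:06d}"
    return MoleculeNode(MoleculeRecord(mol_id, world.catalog.lookup(mol_id)))


def _make_route(
    world: World,
    arch: Archetype,
    rng: np.random.Generator,
    mol_id: str,
    primary: bool,
) -> RouteTree:
    spec = world.spec
    if primary and arch.named_route is not None:
        code_texts = list(arch.named_route)
    else:
        counts = [n for n, _ in arch.steps]
        probs = [p for _, p in arch.steps]
        n_steps = int(rng.choice(counts, p=probs))
        code_texts = [
            f"{arch.classes[int(rng.integers(len(arch.classes)))]}"
            f".{int(rng.integers(1, spec.named_per_class + 1))}"
            for _ in range(n_steps)
        ]
    classifications = [
        "unknown transformation" if rng.random() < spec.unrecognized_rate else text
        for text in code_texts
    ]
    solved = bool(rng.random() < arch.solvability)

    # build a linear chain bottom-up; each reaction has two precursors
    inner: MoleculeNode | None = None
    for depth, text in enumerate(reversed(classifications)):
        code, raw = _parse_classification(text)
        children = [c for c in (inner,) if c is not None]
        while len(children) < 2:
            children.append(_stock_leaf(world, rng))
        reaction = ReactionNode(code, raw, children)
        target = (
            MoleculeRecord(mol_id)
            if depth == len(classifications) - 1
            else MoleculeRecord(f"I-{mol_id}-{depth}")
        )
        inner = MoleculeNode(target, reaction)
    assert inner is not None
    if not solved:
        # break one terminal precursor: not purchasable anywhere
        leaf = next(m for m in RouteTree(inner).molecule_nodes() if m.reaction is None)
        leaf.record = MoleculeRecord(f"X-{mol_id}", StockStatus.UNAVAILABLE)
    tree = RouteTree(inner, provenance=arch.name)
    tree.solved = all(
        l.stock_status is not StockStatus.UNAVAILABLE for l in tree.leaves()
    )
    return tree


def make_molecule(world: World, arch_idx: int, draw: int) -> BatchMolecule:
    """Materialize a molecule identity; deterministic per (world, id)."""
    arch = world.spec.archetypes[arch_idx]
    rng = np.random.default_rng([world.seed, 7919, arch_idx, draw])
    mol_id = f"{arch.name}-{draw:05d}"
    trees = [_make_route(world, arch, rng, mol_id, primary=True)]
    if rng.random() < world.spec.second_tree_prob:
        trees.append(_make_route(world, arch, rng, mol_id, primary=False))
    hit = bool(rng.random() < arch.hit_rate)
    score = world.spec.hit_property_score if hit else world.spec.miss_property_score
    return BatchMolecule(mol_id, trees, archetype=arch_idx, hit=hit,
                         property_score=score)


@dataclass
class Policy:
    """Multiplicative-weights bandit over route archetypes."""

    weights: np.ndarray
    learning_rate: float = 0.35

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("policy weights must be non-negative, sum > 0")
        self.weights = w / w.sum()

    @classmethod
    def uniform(cls, k: int, learning_rate: float = 0.35) -> "Policy":
        return cls(np.full(k, 1.0 / k), learning_rate)


def sample_batch(
    world: World, policy: Policy, n: int, seed: int, epoch: int = 0
) -> BatchContext:
    """Draw n molecules from the policy; unique mol_ids within the batch."""
    if n < 1:
        raise ConfigurationError("batch size must be at least 1")
    rng = np.random.default_rng([seed % _SEED_MOD, 104729, epoch])
    arch_idxs = rng.choice(len(world.spec.archetypes), size=n, p=policy.weights)
    used: set[tuple[int, int]] = set()
    molecules = []
    for arch_idx in arch_idxs:
        arch = world.spec.archetypes[int(arch_idx)]
        draw = int(rng.integers(arch.pool))
        while (int(arch_idx), draw) in used:  # unique within the batch only
            draw = (draw + 1) % arch.pool
        used.add((int(arch_idx), draw))
        molecules.append(make_molecule(world, int(arch_idx), draw))
    return BatchContext(molecules, epoch=epoch)


def policy_update(
    policy: Policy, rewards: dict[str, float], batch: BatchContext
) -> Policy:
    """Multiplicative-weights step on mean per-archetype rewards.

    Archetypes unrepresented in the batch are updated with the overall
    batch mean (a no-information default), so uniform rewards leave the
    policy unchanged regardless of which archetypes were sampled.
    """
    k = len(policy.weights)
    sums = np.zeros(k)
    counts = np.zeros(k)
    for mol in batch.molecules:
        if mol.archetype is None:
            continue
        sums[mol.archetype] += rewards.get(mol.mol_id, 0.0)
        counts[mol.archetype] += 1
    overall = sums.sum() / counts.sum() if counts.sum() else 0.0
    means = np.where(counts > 0, sums / np.maximum(counts, 1), overall)
    new_w = policy.weights * np.exp(policy.learning_rate * means)
    return Policy(new_w, policy.learning_rate)


@dataclass
class ExperimentConfig:
    """One simulated optimization run.

    ``reward`` selects the component fed into the geometric-mean MPO;
    ``control`` runs give it weight 0 while still logging every
    synthetic metric, so control curves are directly comparable.
    """

    reward: str = "sfscore"
    epochs: int = 200
    batch_size: int = 128
    seed: int = 1
    world_spec: WorldSpec = field(default_factory=WorldSpec)
    plate_capacity: int = 50
    exclude_molecules: bool = True
    level: SignatureLevel = SignatureLevel.CLASS
    learning_rate: float = 0.35
    sf: SFConfig | None = None
    rr_transform: str = "reciprocal"
    rr_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.reward not in REWARD_NAMES:
            raise ConfigurationError(
                f"unknown reward {self.reward!r}; expected one of {REWARD_NAMES}"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch size must be positive")
        if self.sf is None:
            # study-style defaults: amide (2.1), Suzuki (3.1) and
            # N-arylation (1.3) preferred, at most 3 steps per route
            self.sf = SFConfig(
                preferred_reactions=frozenset(
                    parse_code(c) for c in ("2.1", "3.1", "1.3")
                ),
                max_steps=3,
            )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "reward": self.reward,
                "epochs": self.epochs,
                "batch_size": self.batch_size,
                "seed": self.seed,
                "plate_capacity": self.plate_capacity,
                "exclude_molecules": self.exclude_molecules,
                "level": int(self.level),
                "learning_rate": self.learning_rate,
                "rr_transform": self.rr_transform,
                "rr_scale": self.rr_scale,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame
    ledger: PlateLedger
    policy: Policy
    config: ExperimentConfig


METRIC_COLUMNS = [
    "epoch",
    "mean_active",
    "mean_combined",
    "mean_sfscore",
    "mean_rrscore",
    "mean_ted",
    "mean_popularity",
    "mean_fill",
    "dominant_fraction",
    "unique_molecules",
    "unique_hits",
    "filled_plates",
]


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the toy generation loop and return per-epoch metrics.

    Every synthetic metric (feasibility, reference-route distance,
    popularity, plate filling) is computed and logged each epoch
    regardless of which reward is active, mirroring zero-weight logging;
    only the active component (none, for ``control``) shapes the policy.
    """
    world = build_world(config.world_spec, config.seed)
    policy = Policy.uniform(len(config.world_spec.archetypes), config.learning_rate)
    ledger = PlateLedger(capacity=config.plate_capacity)
    rr_cfg = RRConfig(
        world.reference_route, transform=config.rr_transform, scale=config.rr_scale
    )
    synth_weight = 0.0 if config.reward == "control" else 1.0

    seen: set[str] = set()
    hits: set[str] = set()
    rows = []
    for epoch in range(1, config.epochs + 1):
        batch = sample_batch(world, policy, config.batch_size, config.seed, epoch)

        sf = {
            m.mol_id: sfscore_molecule(m.trees, world.catalog, config.sf)
            for m in batch.molecules
        }
        dists = {
            m.mol_id: best_reference_distance(m.trees, rr_cfg)
            for m in batch.molecules
        }
        rr = {m.mol_id: rrscore_molecule(m.trees, rr_cfg) for m in batch.molecules}
        pop = popularity_scores(batch, config.level)
        fill, ledger = fill_a_plate_update(
            batch, ledger, config.exclude_molecules, config.level
        )

        active = {
            "sfscore": sf,
            "rrscore": rr,
            "popularity": pop,
            "fill_a_plate": fill,
            "control": {m.mol_id: 0.0 for m in batch.molecules},
        }[config.reward]
        combined = {
            m.mol_id: combine(
                [
                    ComponentScore("synth", active[m.mol_id], synth_weight),
                    ComponentScore("property", m.property_score or 0.0, 1.0),
                ]
            )
            for m in batch.molecules
        }
        policy = policy_update(policy, combined, batch)

        for m in batch.molecules:
            seen.add(m.mol_id)
            if m.hit:
                hits.add(m.mol_id)
        solved_dists = [d for d in dists.values() if d is not None]
        rows.append(
            {
                "epoch": epoch,
                "mean_active": float(np.mean(list(active.values()))),
                "mean_combined": float(np.mean(list(combined.values()))),
                "mean_sfscore": float(np.mean(list(sf.values()))),
                "mean_rrscore": float(np.mean(list(rr.values()))),
                "mean_ted": float(np.mean(solved_dists)) if solved_dists else np.nan,
                "mean_popularity": float(np.mean(list(pop.values()))),
                "mean_fill": float(np.mean(list(fill.values()))),
                "dominant_fraction": max(pop.values(), default=0.0),
                "unique_molecules": len(seen),
                "unique_hits": len(hits),
                "filled_plates": filled_plate_count(ledger),
            }
        )
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return ExperimentResult(metrics, ledger, policy, config)
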