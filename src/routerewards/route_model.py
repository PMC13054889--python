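"""Retrosynthetic route trees: data model, parsing, signatures and I/O.

A route tree is rooted at the target molecule and alternates molecule
and reaction layers: each molecule node is either a leaf precursor or
carries exactly one reaction node whose children are the precursor
molecules of that step.  A route is *solved* when every leaf precursor
is available in the stock catalog (internal or commercial).

Two JSON dialects are supported:

* ``native`` — the package's own schema, versioned with a ``"schema"``
  field (``route-tree/1``); see the README for the layout.  Molecule
  nodes embed their stock status so documents round-trip without a
  catalog.
* ``aizynthfinder`` — nested ``{"type": "mol"|"reaction"}`` nodes with
  ``in_stock`` flags on molecules and the reaction classification string
  under ``metadata.classification``.  Unknown metadata is ignored.

Reaction classification strings that do not parse as taxonomy codes are
kept verbatim and coded with the unrecognized sentinel; they invalidate
route signatures but never abort parsing.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

from .taxonomy import (
    ReactionCode,
    SignatureLevel,
    TaxonomyError,
    UNRECOGNIZED,
    parse_code,
    truncate,
)
from .ted import OrderedTree

NATIVE_SCHEMA = "route-tree/1"


class SchemaError(ValueError):
    """A route document violates its dialect; names the offending node."""

    def __init__(self, message: str, path: str = "root") -> None:
        super().__init__(f"{path}: {message}")
        self.path = path


class StockStatus(str, enum.Enum):
    INTERNAL = "internal"
    COMMERCIAL = "commercial"
    UNAVAILABLE = "unavailable"


def canonicalize_id(mol_id: str, use_rdkit: bool = False) -> str:
    """The single normalization applied to molecule identifiers.

    Whitespace is trimmed; with ``use_rdkit`` identifiers that parse as
    SMILES are additionally replaced by their RDKit canonical form, so
    catalogs and routes written with different SMILES conventions still
    match.  Applied identically on the catalog and the route side.
    """
    out = mol_id.strip()
    if use_rdkit:
        from rdkit import Chem  # local import: optional heavy dependency

        mol = Chem.MolFromSmiles(out, sanitize=True)
        if mol is not None:
            out = Chem.MolToSmiles(mol)
    return out


@dataclass
class StockCatalog:
    """Mapping of canonical molecule ids to their stock status.

    Lookup of an id absent from the catalog yields ``UNAVAILABLE``.
    """

    entries: dict[str, StockStatus] = field(default_factory=dict)
    use_rdkit: bool = False

    def __post_init__(self) -> None:
        self.entries = {
            canonicalize_id(k, self.use_rdkit): StockStatus(v)
            for k, v in self.entries.items()
        }

    def lookup(self, mol_id: str) -> StockStatus:
        return self.entries.get(
            canonicalize_id(mol_id, self.use_rdkit), StockStatus.UNAVAILABLE
        )

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path, use_rdkit: bool = False) -> "StockCatalog":
        """Read a ``id,source`` CSV with source in {internal, commercial}."""
        entries: dict[str, StockStatus] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "id" not in reader.fieldnames:
                raise SchemaError("stock CSV must have an 'id' column", str(path))
            for lineno, row in enumerate(reader, start=2):
                source = (row.get("source") or "internal").strip()
                if source not in ("internal", "commercial"):
                    raise SchemaError(
                        f"line {lineno}: unknown stock source {source!r}", str(path)
                    )
                entries[row["id"]] = StockStatus(source)
        return cls(entries, use_rdkit=use_rdkit)

    @classmethod
    def from_text(cls, path: str | Path, use_rdkit: bool = False) -> "StockCatalog":
        """Read a plain id-per-line list; all entries are internal stock."""
        entries = {}
        for line in Path(path).read_text().splitlines():
            if line.strip():
                entries[line] = StockStatus.INTERNAL
        return cls(entries, use_rdkit=use_rdkit)


@dataclass
class MoleculeRecord:
    mol_id: str
    stock_status: StockStatus = StockStatus.UNAVAILABLE

    def __post_init__(self) -> None:
        if not self.mol_id:
            raise SchemaError("empty molecule id")
        self.stock_status = StockStatus(self.stock_status)


@dataclass
class ReactionNode:
    code: ReactionCode
    classification: str  # original classification text, preserved verbatim
    children: list["MoleculeNode"]


@dataclass
class MoleculeNode:
    record: MoleculeRecord
    reaction: ReactionNode | None = None


@dataclass
class RouteTree:
    """A rooted retrosynthetic tree for one target molecule."""

    root: MoleculeNode
    solved: bool = False
    provenance: str = ""

    @property
    def target_id(self) -> str:
        return self.root.record.mol_id

    def molecule_nodes(self) -> Iterator[MoleculeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.reaction is not None:
                stack.extend(reversed(node.reaction.children))

    def reaction_nodes(self) -> Iterator[ReactionNode]:
        for mol in self.molecule_nodes():
            if mol.reaction is not None:
                yield mol.reaction

    def leaves(self) -> list[MoleculeRecord]:
        return [m.record for m in self.molecule_nodes() if m.reaction is None]


@dataclass(frozen=True)
class RouteSignature:
    """The set of a route's reaction codes truncated to one level.

    ``valid`` is false when any reaction in the route is unrecognized or
    shallower than the requested level.  The empty signature (zero-step
    route) is representable; intrinsic rewards treat it as invalid.
    """

    level: SignatureLevel
    codes: frozenset[ReactionCode]
    valid: bool

    @property
    def key(self) -> tuple[str, ...]:
        """Deterministic hashable key: the sorted rendered codes."""
        return tuple(sorted(c.render() for c in self.codes))


# ---------------------------------------------------------------------------
# parsing


def _parse_classification(text: str | None) -> tuple[ReactionCode, str]:
    raw = text or ""
    try:
        return parse_code(raw), raw
    except TaxonomyError:
        return UNRECOGNIZED, raw


def _parse_native_mol(doc: Any, path: str) -> MoleculeNode:
    if not isinstance(doc, dict) or doc.get("type") != "mol":
        raise SchemaError("expected a molecule node ({'type': 'mol'})", path)
    mol_id = doc.get("id")
    if not isinstance(mol_id, str) or not mol_id:
        raise SchemaError("molecule node missing non-empty 'id'", path)
    status = doc.get("stock", "unavailable")
    try:
        record = MoleculeRecord(mol_id, StockStatus(status))
    except ValueError as exc:
        raise SchemaError(f"bad stock status {status!r}", path) from exc
    children = doc.get("children", [])
    if not isinstance(children, list) or len(children) > 1:
        raise SchemaError("molecule node takes at most one reaction child", path)
    reaction = None
    if children:
        reaction = _parse_native_reaction(children[0], f"{path}.children[0]")
    return MoleculeNode(record, reaction)


def _parse_native_reaction(doc: Any, path: str) -> ReactionNode:
    if not isinstance(doc, dict) or doc.get("type") != "reaction":
        raise SchemaError("expected a reaction node ({'type': 'reaction'})", path)
    children = doc.get("children")
    if not isinstance(children, list) or not children:
        raise SchemaError("reaction node needs at least one precursor", path)
    code, raw = _parse_classification(doc.get("classification"))
    mols = [
        _parse_native_mol(c, f"{path}.children[{i}]") for i, c in enumerate(children)
    ]
    return ReactionNode(code, raw, mols)


def _parse_aizynth_mol(doc: Any, path: str) -> MoleculeNode:
    if not isinstance(doc, dict) or doc.get("type") != "mol":
        raise SchemaError("expected a molecule node ({'type': 'mol'})", path)
    smiles = doc.get("smiles") or doc.get("id")
    if not isinstance(smiles, str) or not smiles:
        raise SchemaError("molecule node missing 'smiles'", path)
    in_stock = bool(doc.get("in_stock", False))
    record = MoleculeRecord(
        smiles,
        StockStatus.COMMERCIAL if in_stock else StockStatus.UNAVAILABLE,
    )
    children = doc.get("children", [])
    if not isinstance(children, list) or len(children) > 1:
        raise SchemaError("molecule node takes at most one reaction child", path)
    reaction = None
    if children:
        rdoc = children[0]
        rpath = f"{path}.children[0]"
        if not isinstance(rdoc, dict) or rdoc.get("type") != "reaction":
            raise SchemaError("expected a reaction node", rpath)
        rchildren = rdoc.get("children")
        if not isinstance(rchildren, list) or not rchildren:
            raise SchemaError("reaction node needs at least one precursor", rpath)
        meta = rdoc.get("metadata") or {}
        code, raw = _parse_classification(
            meta.get("classification") if isinstance(meta, dict) else None
        )
        mols = [
            _parse_aizynth_mol(c, f"{rpath}.children[{i}]")
            for i, c in enumerate(rchildren)
        ]
        reaction = ReactionNode(code, raw, mols)
    return MoleculeNode(record, reaction)


def parse_route(
    document: dict,
    dialect: str = "native",
    catalog: StockCatalog | None = None,
) -> RouteTree:
    """Parse a structured route record into a validated :class:`RouteTree`.

    When a catalog is supplied every molecule node is (re)annotated from
    it; otherwise the statuses embedded in the document are kept.  The
    solved flag is always recomputed from the leaf statuses.
    """
    if dialect == "native":
        if not isinstance(document, dict):
            raise SchemaError("route document must be a JSON object")
        if document.get("schema", NATIVE_SCHEMA) != NATIVE_SCHEMA:
            raise SchemaError(f"unsupported schema {document.get('schema')!r}")
        root_doc = document.get("root", document if "type" in document else None)
        if root_doc is None:
            raise SchemaError("missing 'root' molecule node")
        root = _parse_native_mol(root_doc, "root")
        provenance = str(document.get("provenance", ""))
    elif dialect == "aizynthfinder":
        root = _parse_aizynth_mol(document, "root")
        provenance = "aizynthfinder"
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")

    tree = RouteTree(root, provenance=provenance)
    if catalog is not None:
        for mol in tree.molecule_nodes():
            mol.record.stock_status = catalog.lookup(mol.record.mol_id)
    tree.solved = all(
        leaf.stock_status is not StockStatus.UNAVAILABLE for leaf in tree.leaves()
    )
    return tree


def write_route(tree: RouteTree) -> dict:
    """Serialize to the native schema; inverse of :func:`parse_route`."""

    def mol_doc(node: MoleculeNode) -> dict:
        doc: dict[str, Any] = {
            "type": "mol",
            "id": node.record.mol_id,
            "stock": node.record.stock_status.value,
        }
        if node.reaction is not None:
            r = node.reaction
            doc["children"] = [
                {
                    "type": "reaction",
                    "classification": r.classification or r.code.render(),
                    "children": [mol_doc(c) for c in r.children],
                }
            ]
        return doc

    return {
        "schema": NATIVE_SCHEMA,
        "provenance": tree.provenance,
        "solved": tree.solved,
        "root": mol_doc(tree.root),
    }


def load_routes(path: str | Path, dialect: str = "native",
                catalog: StockCatalog | None = None) -> list[RouteTree]:
    """Load one route document or a list of them from a JSON file."""
    data = json.loads(Path(path).read_text())
    docs = data if isinstance(data, list) else [data]
    return [parse_route(doc, dialect=dialect, catalog=catalog) for doc in docs]


# ---------------------------------------------------------------------------
# derived views


def count_steps(tree: RouteTree) -> int:
    """Number of reaction steps n(t): the count of reaction nodes.

    This is a node count, not a depth — a convergent route with two
    parallel branches has more steps than its depth.
    """
    return sum(1 for _ in tree.reaction_nodes())


def route_signature(
    tree: RouteTree, level: SignatureLevel = SignatureLevel.CLASS
) -> RouteSignature:
    """The set of the route's reaction codes truncated to ``level``.

    Duplicate codes collapse.  Routes containing an unrecognized
    reaction (or one coded more shallowly than the requested level)
    yield ``valid=False``; zero-step routes yield the empty set.
    """
    codes: set[ReactionCode] = set()
    valid = True
    for reaction in tree.reaction_nodes():
        code = reaction.code
        if code.is_unrecognized or code.depth < int(level):
            valid = False
            codes.add(truncate(code, SignatureLevel(min(code.depth, int(level)))))
        else:
            codes.add(truncate(code, level))
    return RouteSignature(level, frozenset(codes), valid)


def _canon_key(t: OrderedTree) -> tuple:
    return (t.label.render(), tuple(_canon_key(c) for c in t.children))


def canonical_reaction_tree(tree: RouteTree) -> OrderedTree | None:
    """The route's reaction-only tree with deterministically sorted children.

    Molecule nodes are elided; children are ordered by a recursive
    (label, subtree) key so that routes differing only in child order
    map to the same ordered tree.  Zero-step routes map to ``None``.
    """

    def convert(rnode: ReactionNode) -> OrderedTree:
        subs = [convert(c.reaction) for c in rnode.children if c.reaction is not None]
        subs.sort(key=_canon_key)
        return OrderedTree(rnode.code, tuple(subs))

    if tree.root.reaction is None:
        return None
    return convert(tree.root.reaction)
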