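# routerewards

Synthesis-aware reward functions over retrosynthetic route trees, for
steering generative molecular design toward compounds that can actually
be made — and made *together*.

Generative models propose molecules; retrosynthesis tools propose route
trees for them (target at the root, reaction steps as internal nodes,
purchasable precursors at the leaves). This package scores those routes
so that a reinforcement-learning generator can optimize synthesizability
alongside potency or drug-likeness:

* **SFScore** (extrinsic, per molecule) — synthetic feasibility as the
  product of three factors over a molecule's best route *t*:
  `S(t) = Stock(t) · React(t) · Step(t)`, with
  `Stock(t) = ∏_{p ∈ P(t)} s(p)` over leaf precursors (internal 1.0,
  commercial 0.8, unavailable 0.1), `React(t) = ∏_{r ∈ R(t)} s(r)`
  (preferred reactions 1.0, others 0.1) and `Step(t) = k^{n(t)}` with
  `k = 0.9`, so a three-step route contributes `0.9³ = 0.729`.
* **RRScore** (extrinsic) — closeness of a molecule's best *solved*
  route to a predefined reference route, measured by ordered tree edit
  distance (TED) over reaction-labeled trees. Delete/insert cost 4.0;
  renames are hierarchical over the reaction taxonomy `X` / `X.Y` /
  `X.Y.Z`: superclass disagreement 3.0, class 2.0, named reaction 1.0.
  The distance is mapped to a similarity `1/(1+d)` (or `exp(-d/τ)`),
  so an identical route scores 1 and unroutable molecules score 0.
* **Route Popularity** (intrinsic, per batch) — for route signature `S`
  (the set of class-level reaction codes in a route),
  `Pop(S) = |M_S|/N`; each molecule scores the popularity of its most
  popular solved-route signature, rewarding batch-level route coherence.
* **Fill-a-Plate** (intrinsic, cross-batch) — a persistent ledger of
  virtual parallel-synthesis plates, one per signature, capacity `C`.
  A molecule joins the fullest unsaturated plate among its candidate
  signatures and earns that plate's filling ratio (0.7 when 70% full);
  saturated plates stop scoring and their members can be retired,
  pushing the generator to pivot into fresh synthetic space.

Components are combined by a weighted geometric mean
`(∏ vᵢ^{wᵢ})^{1/∑wᵢ}`; a zero-weight component is still evaluated and
logged, which is how synthesis-unaware control runs are instrumented.

A seeded desk-scale simulator (`routerewards.simulator`) exercises all
four rewards inside a toy generation loop: a multiplicative-weights
bandit over route archetypes stands in for the generative model, and a
synthetic world (taxonomy, stock catalog, archetype route generators,
surrogate property hits) stands in for the retrosynthesis stack.

## Worked example

```python
from routerewards import (
    RRConfig, SFConfig, OrderedTree, parse_code,
    parse_route, sfscore_molecule, rrscore_molecule, tree_edit_distance,
)

doc = {
    "schema": "route-tree/1",
    "root": {
        "type": "mol", "id": "target",
        "children": [{
            "type": "reaction",
            "classification": "2.1.10 Carboxylic ester + amine reaction",
            "children": [
                {"type": "mol", "id": "ester", "stock": "internal",
                 "children": [{
                     "type": "reaction",
                     "classification": "3.1.2 Chloro Suzuki coupling",
                     "children": [
                         {"type": "mol", "id": "ArCl", "stock": "internal"},
                         {"type": "mol", "id": "boronic", "stock": "commercial"},
                     ]}]},
                {"type": "mol", "id": "amine", "stock": "internal"},
            ]}]},
}
tree = parse_route(doc)

sf_cfg = SFConfig(preferred_reactions=frozenset(
    {parse_code("2.1"), parse_code("3.1")}))
print(sfscore_molecule([tree], None, sf_cfg))
# 0.6480000000000001   (stock 1.0*0.8*1.0 = 0.8, reactions 1.0, steps 0.9^2)

ref = OrderedTree(parse_code("2.1.10"), (OrderedTree(parse_code("3.1.2")),))
print(rrscore_molecule([tree], RRConfig(ref)))
# 1.0   (the route's reaction tree is identical to the reference: TED 0)
```

The two-step route is solved (every leaf is in stock), scores
0.648 on feasibility — penalized only by the commercial boronic acid
(0.8) and the two-step decay (0.81) — and exactly matches the
ester-amide → Suzuki reference route, so its reference-route score is 1.

The same computations are available from the shell:

```bash
routerewards score --routes routes.json --reward sfscore --out scores.jsonl
routerewards ted --route routes.json --ref reference.json
routerewards simulate --reward fill_a_plate --seed 1 --epochs 200 --out run/
routerewards plates-report --ledger run/ledger.json --out plates.csv
```

## Route JSON

The native schema (`"schema": "route-tree/1"`) nests molecule nodes
(`{"type": "mol", "id", "stock", "children"}`) and reaction nodes
(`{"type": "reaction", "classification", "children"}`), alternating
from the target molecule down to stock leaves. An AiZynthFinder-style
dialect (`--dialect aizynthfinder`) reads nested `mol`/`reaction` nodes
with `in_stock` flags and `metadata.classification` strings. Stock
catalogs are `id,source` CSV (source `internal`/`commercial`) or plain
id-per-line text. Unclassifiable reactions are kept verbatim and marked
unrecognized; they invalidate route signatures without aborting parses.

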