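# Methods

## Route trees, solvedness and signatures

A route tree is rooted at the target molecule and alternates molecule
and reaction layers; each molecule node carries at most one reaction
(a single route — alternative disconnections are separate trees), and
every reaction node has at least one precursor molecule. A route is
*solved* when every leaf precursor resolves to internal or commercial
stock in the catalog supplied at parse time; the flag is always
recomputed from the leaves, never trusted from the document. The step
count `n(t)` is the number of reaction nodes, not the tree depth: a
convergent route with two parallel one-step branches under a final
coupling has three steps at depth two.

Reaction steps carry hierarchical taxonomy codes `X` (superclass),
`X.Y` (class), `X.Y.Z` (named reaction). A route signature at level L
is the *set* of the route's codes truncated to L (duplicates collapse).
Signatures are invalid if any step is unrecognized or coded more
shallowly than L. Two boundary choices are deliberate:

* a zero-step route (target already purchasable) has the empty
  signature, which the intrinsic rewards treat as invalid — a "plate"
  of purchasable compounds is not a synthesis plate — while its
  feasibility step factor is the empty product, 1.0;
* unrecognized reactions are coded with the sentinel `0.0`, which
  differs from every real code at superclass level and equals itself,
  making distance computations total without special cases.

Codes of unequal depth compare component-wise: two absent components
agree, absent-versus-present disagrees at that depth. This is a package
choice — the taxonomy itself does not define cross-depth renames.

Identifier matching uses a single normalization on both catalog and
route sides: whitespace trimming, plus optional RDKit SMILES
canonicalization when enabled (off by default so runs do not depend on
a chemistry toolkit).

## Tree edit distance

For reference-route scoring, routes are reduced to reaction-only trees
(molecule nodes elided — they carry no label information once stock is
scored separately) and children are sorted by a recursive
(label, subtree) key. Child order in a retrosynthetic tree is
chemically meaningless; canonical sorting makes it so formally, which
lets us use *ordered* TED — exact and polynomial — instead of the
intractable unordered variant. The distance is computed with the
Zhang–Shasha dynamic program over keyroots and forest distances, with
delete = insert = 4.0 and renames 3.0 / 2.0 / 1.0 by the shallowest
level of disagreement (so a rename is always cheaper than
delete+insert, and the distance degrades gracefully as routes diverge
taxonomically). An exhaustive edit-mapping oracle — enumeration of all
ancestor- and sibling-order-preserving partial matchings — verifies the
dynamic program on hundreds of random tree pairs of up to six nodes in
the test suite.

The TED→similarity map is configurable because only its constraints
are fixed (1 at distance 0, strictly decreasing toward 0): default
reciprocal `1/(1 + d/τ)`, alternative exponential `exp(-d/τ)`, τ = 1.
The reciprocal default keeps a usable gradient at large distances,
which matters early in a run when every route is far from the
reference.

## Reward semantics

**SFScore** uses both solved and unsolved trees by default (an
unsolved route is still informative — its unavailable leaves already
multiply the stock factor by 0.1 each); `use_unsolved=False` restricts
to solved routes. Preferred reactions may be given at any taxonomy
level; a route's named-level code matches a class-level preference by
truncation, so preferring `3.1` admits every Suzuki named reaction.
The optional `max_steps` filter drops longer routes at score time.
Stock status is looked up in the catalog at score time, so swapping
catalogs re-scores a parsed tree correctly. A molecule with no routes
scores 0 — a generator should not be rewarded for unroutable output.

**RRScore** and **Route Popularity** use solved routes only;
**Fill-a-Plate** uses both solved and unsolved routes. Popularity
runs at class level so plates can tolerate named-reaction diversity.

**Fill-a-Plate** processes molecules in batch order against a
persistent ledger. Each new molecule joins the fullest unsaturated
plate among its valid signatures (ties broken by lexicographically
smallest signature for determinism) and is rewarded with the filling
ratio *after* its own assignment: scoring before assignment would give
every fresh route a hard zero and the reward could never bootstrap
exploration; with the chosen order the first molecule of a new plate
earns 1/C. A molecule increments exactly one plate, ever. Reappearing
molecules never re-increment: without exclusion they are scored on
their plate's current ratio, with exclusion they score 0, and members
of a filled plate are retired outright. Consequently the sum of plate
counts always equals the number of distinct assigned molecules, and
under exclusion no molecule appears on two plates.

**Combiner.** The weighted geometric mean over positively weighted
components; zero-weight components are evaluated and logged but
excluded from the product. A zero value with positive weight yields a
combined score of exactly 0 — no epsilon flooring — so any hard-failed
component vetoes the molecule.

## The simulator

The simulator's purpose is to let the rewards *steer* something at
desk scale, not to model a neural generator. The generator surrogate
is a multiplicative-weights bandit over **route archetypes**: families
of molecules sharing reaction chemistry (a class repertoire and
step-count distribution), a solvability probability, a surrogate hit
probability standing in for property oracles, and a finite analogue
pool. Six default archetypes mirror common medicinal-chemistry route
families — amide couplings (2.x), Suzuki-type couplings (3.x),
N-arylation/alkylation and S-substitution (1.x), one exact two-step
reference chain (ester amidation then chloro-Suzuki, which is also the
default reference route), and one broad multi-step mixed family. Class
repertoires are deliberately wide (3–6 classes each): route-set
signatures then span many more distinct class subsets than one run can
saturate, which is the regime real campaigns operate in — if the
signature space were smaller than the run's throughput every plate
would fill under any policy and the plate count would measure the
ceiling, not the reward.

Molecule identity is (archetype, draw index) with a finite pool, so
duplicate regeneration happens as in real runs; all of a molecule's
properties (routes, solvability, hit status) derive from a per-identity
RNG and are stable across reappearances. Policy updates multiply each
archetype's weight by `exp(lr · mean reward)` of its batch molecules;
archetypes absent from a batch use the overall batch mean (a
no-information default that leaves uniform-reward batches fixed
points). Runs are fully deterministic per seed: batch composition,
rewards, ledger state and metrics.

Defaults: batch 128, 200 epochs, plate capacity 50, learning rate
0.35, exclusion on, class-level signatures, surrogate property score
0.85 for hits / 0.25 otherwise, hit rates 0.10–0.17, solvability
0.60–0.90, stock of 5000 ids (30% internal). The dynamics tests run 80
epochs with seeds 1–3, enough for every directional effect at a
minute-scale runtime. Control runs give the synthetic component zero
weight but still log every synthetic metric, so active-versus-control
comparisons share instrumentation.

What passing dynamics tests show: with these archetypes the reference
reward drives mean TED down, popularity concentrates batches onto a
dominant signature well beyond property-driven drift, and plate
rewards fill strictly more plates than control. What they do not show:
anything about absolute magnitudes on a real generator/retrosynthesis
stack — the bandit has no chemistry inside molecules, no scaffolds, no
sequence model, and its property surrogate is a two-valued stand-in.

## Numerical and degenerate-input choices

* TED on empty trees: the distance to the empty tree is size × the
  delete (or insert) cost; two empty trees are at distance 0.
* The edit-mapping oracle refuses trees above seven nodes (it is
  exponential by design and exists only to check the dynamic program).
* `combine` rejects non-finite values, negative weights and all-zero
  weights; values are clipped only against sub-1e-9 floating overshoot.
* Empty batches are an error for popularity (the normalizer is N);
  fill-a-plate accepts any batch but requires positive capacity.
* Ledger files are validated on load (schema tag, counts within
  capacity, saturation consistent with capacity, no molecule on two
  plates) and fail with a diagnostic rather than loading silently.

## Known limitations

* Ordered TED on canonically sorted trees can in principle differ from
  unordered TED on adversarial label multisets; for reaction trees of
  the sizes retrosynthesis produces (≲ 10 nodes, near-linear) no such
  case has been observed, and determinism was judged more valuable.
* The plate ledger keeps member sets in memory; at capacity 1000 and
  tens of thousands of molecules this is megabytes, fine for intended
  use but not for library-scale bookkeeping.
* The simulator's archetype signatures are drawn independently per
  step, so step-order correlations within real route families are not
  modeled; signatures are sets, so this does not affect the rewards'
  inputs, only route-tree realism for TED (where only the reference
  archetype is meant to match the reference).
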