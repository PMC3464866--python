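# Methods

## Graph mapping of an ontology

An OBO 1.2 file is mapped onto a typed directed graph with two edge layers
kept strictly apart: the subsumption hierarchy (`is_a`, child → parent,
multiple parents allowed, acyclic by contract and checked at load) and
named relation edges (`relationship:` lines). The hierarchy is mandatory
structure; relations are semantics a traversal must opt into via a
`TraversalPolicy` (direction, allowed relation names, hierarchy on/off).
Every traversal-facing neighbour list is returned sorted lexicographically
so results are deterministic across runs and platforms.

Only the tags the semantic functions need are given structure (`id`,
`name`, `is_a`, `relationship`, `is_obsolete`); all other tag lines pass
through verbatim into a per-class annotation mapping keyed by tag name.
This is deliberate: field-restricted search must be able to cover arbitrary
annotation fields without the parser knowing them. Obsolete classes are
loaded (they stay addressable) but are stripped of outgoing edges and
excluded from search and traversal — the usual OBO convention. Dangling
`is_a`/`relationship` targets are dropped with a logged warning rather than
failing the load, because real exports are imperfect; a `[Term]` stanza
without an id is a hard parse error with its line number. The writer emits
terms sorted by id plus a `[Typedef]` stanza per relation name, and
`read ∘ write ∘ read` is the identity on graphs (verified for all fixtures
and cross-checked against the independent `obonet` parser).

## Levels and the virtual root

A virtual root class `thing` is inserted above all parentless non-obsolete
classes and defines level 1 (the insertion is idempotent). Two level
notions coexist and both are needed:

* `level(c)` — the *longest*-path distance to the root. This drives the
  farthest-first selection in the cluster reduction: the class with the
  greatest distance to the root is the one mapped in each iteration.
* `path_levels(c)` — the set of positions `c` occupies across *all* root
  paths. This drives `reduceToLevel`, where every root path of the input
  class is considered.

Both are computed in one topological-order sweep and cached on the graph;
any mutation invalidates the cache. "Distance to root" is not uniquely
determined for a DAG; the longest-path convention was chosen because it is
the only one consistent with a class at hierarchy depth 6 clustering next
to a representative at depth 5 while still being selected after a depth-8
class (see the `go_regulation` walk-through in the README). A shortest-path
variant would be a one-line change in `_compute_levels` and is deliberately
not exposed as an option.

## reduceToLevel

`c` maps to `{a : a ∈ ancestors(c) ∪ {c}, ℓ ∈ path_levels(a)}`. Because
the hierarchy is a DAG, any root→a path concatenates with any a→c path, so
this set equals "all classes at position ℓ on at least one root→c path"
without enumerating paths (the property suite checks exactly that
equivalence against a path-enumeration oracle on 200 seeded DAGs). A class
whose every root path is shorter than ℓ maps to itself — copied, mirroring
how the cluster reduction copies classes it cannot map further — rather
than disappearing from the result.

## reduceToClusterSize

State is a mapping representative → member set, initialised to identity.
Each iteration replaces *every* representative whose level equals the
current maximum by all of its parents; members travel with their
representative and pool when representatives merge. The stop condition
(count ≤ k) is checked after each full iteration, never mid-iteration —
checking mid-iteration would make the result depend on dictionary order.
Termination: the maximal level strictly decreases each iteration, and at
the root everything has merged into one cluster; if only parentless
representatives remain above the limit (possible only without a common
root) the loop stops rather than spinning. A member may appear in several
clusters when a representative has multiple parents, consistent with the
multi-ancestor behaviour of `reduceToLevel`. Raising `k` can only stop the
same trajectory earlier, which yields the tested monotonicity: the minimum
representative level never decreases as `k` grows.

## Key-class rollup

Key classes are the `is_a` descendants of a configured anchor (`organ`,
`physiological_system`), excluding the anchor itself. The rollup is a BFS
from the start class following `is_a` toward parents plus the partonomy
relations `isPartOf`, `isPartOfOrgan`, `isCellOf`; any other relation is
simply absent from the neighbour function, so a forbidden edge can never be
crossed. A reached key class is recorded and not expanded further, so the
most specific organs are reported (an organ containing a reached organ is
not); `expand_key_classes=True` flips that choice for ontologies where
organ-within-organ reporting is wanted. A start that is itself a key class
returns only itself. Relation names configured but absent from the loaded
ontology are dropped at plugin construction instead of being rejected —
the same plugin configuration must serve ontologies with different
relation subsets.

## Set-restricted breadth-first search

`find_in_set` walks level-synchronously: the frontier at depth d is
intersected with the member set before expansion, so the search stops in
the iteration with the first match and returns *all* matches of that
depth — never a subset, never a deeper member. Depth 0 counts: a start
class that is itself a member is its own answer. Upstream steps are `is_a`
parents plus stored relation edges source→target; downstream steps are
`is_a` children plus inverted relation edges (the on-the-fly `hasPart`).
Correctness is checked against `networkx` shortest-path depths on an
explicitly materialised move graph, a genuinely independent route.

## Stage partitioning

Stages are the `is_a` descendants of the stage anchor
(`developmental_stage`); the anchor itself belongs to neither side of the
partition and is excluded along with the virtual root. Concrete classes
are found by one reverse BFS from all stages over inverted link edges
(`is_a` children and sources of incoming `isPartOf`), equivalent to
"classes from which some stage is reachable by any mixture of `is_a`-up
and `isPartOf` steps" but linear in the graph; generic classes are the
complement. The partition is computed once at plugin construction and
cached; rebuilding the plugin is the invalidation path after an ontology
reload. `concrete_for_dev_stage` recomputes stage reachability restricted
to the single queried stage — membership in the global concrete set would
let sibling-stage classes (a pupal antenna in a larval query) leak into
the result. Generic-to-generic partonomy edges participate in the
downstream closure through the same inverted relation; no separate flag
is maintained for them.

## Search

Matching is case-insensitive substring containment over the label and the
indexed annotation fields, with field restriction excluding the label.
Substring (not token) semantics were chosen because mid-word hits
(`cistern` inside `vein_of_cerebellomedullary_cistern`) are wanted in
anatomical vocabularies. At the target scale (ontologies of 10³–10⁵
classes, interactive use) a linear scan is adequate; no inverted index is
built. No ranking, stemming or fuzzy matching is attempted.

## Stored sets

One JSON document per partition under a storage directory; `put ∘ get` is
the identity on id lists including order and duplicates, and the store
survives close/reopen. Partition and list names are restricted to
`[A-Za-z0-9_.-]` so a name can never escape the directory. Unknown
partition and unknown list raise distinct not-found errors (they map to
different user mistakes); ids are validated only at query time, so lists
may be uploaded before their ontology. No quota or eviction policy is
implemented.

## REST service and client

The dispatcher is a pure function request → (status, content type, body);
WSGI and the stdlib HTTP server are thin shims over it, which is also what
makes the transport-transparency tests cheap: the same client code runs
against an in-process transport and a real socket. Matrix parameters
(`;name=value` inside the function path segment) carry keyword arguments,
the following path segment the primary input. Three representations are
negotiated (`application/json`, `text/plain` with one id per line,
`text/html` as a minimal anchor list); the JSON field names (`id`,
`label`, `href`, `representative`, `members`) are this package's stable
schema. The client's `ClassProxy` objects fetch each subresource at most
once and memoize it; equality is by (ontology, id). Network failures
raise a transport error distinct from not-found. The service is optional:
library and CLI never import a running server.

## Synthetic fixtures and what they do not show

The four named fixtures are the smallest graphs realising the documented
behaviours: a nested-regulation GO fragment (13 classes, depth 8, one
diamond — `positive_regulation_of_protein_binding` exists solely so the
deepest input is mapped in *each* of the two clustering iterations), an
abstract organ fragment with one deliberately forbidden developmental
edge, an anatomy fragment with a three-member stored vocabulary, and a
minimal staged insect anatomy (two stages, three generic structures, a
three-hop `isPartOf` chain to the stage). Random DAGs for the property
suites draw, per node, one parent uniformly from earlier nodes plus a
second with probability 0.3, giving rooted acyclic multi-parent graphs of
5–50 nodes whose path counts stay enumerable; optional `isPartOf` edges
(rate 0.3 where used) exercise mixed-relation traversal. Property suites
run 100–200 seeded graphs each; the full test suite and the acceptance
script each finish in seconds on one core.

These fixtures validate the algorithms, not real curation: they contain no
annotation noise, no obsolete-term churn, no cross-product or relation
variety of a production anatomy ontology, and their sizes are far below
GO-scale. Counts measured on real ontologies (how many classes an organ
rollup visits, how many hits a search returns) depend on the ontology
version and are not asserted anywhere; what the suites do establish is
exact agreement of every traversal operation with brute-force oracles on
graphs small enough to enumerate.
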