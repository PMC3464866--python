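# ontoquery

Semantic queries over OBO ontologies for application developers who are not
ontologists.

Biomedical ontologies encode far more than a controlled vocabulary: the
`is_a` hierarchy and typed relations such as `isPartOf`, `isCellOf` or
`differentiatesInto` carry knowledge that an application should exploit — a
search for *nephron* should find data annotated to *kidney*, expression data
from a *hepatocyte* should be grouped under its organ, and a phenotype
screen's staged anatomy should map the generic *antenna* to the *larval
antenna* its annotations actually use. Exploiting that knowledge requires
knowing, per ontology, which relations to follow and where to stop.
`ontoquery` packages that knowledge as *semantic functions* over a typed
directed graph, with a Python API, a command-line tool and a small REST
service with a lazy-loading client.

## The graph model and the core operations

An ontology is loaded from an OBO 1.2 flat file into a graph
`G = (C, E_isa, E_rel)`: classes `C`, the acyclic subsumption hierarchy
`E_isa` (child → parent, multiple parents allowed) and typed relation edges
`E_rel ⊆ C × C × R`. A virtual root `thing` is inserted above every
parentless class and defines **level 1**; the level of a class is
`1 + max{level(p) : p ∈ parents(c)}`, i.e. the longest root path, while
`path_levels(c)` is the set of positions `c` takes over *all* root paths.

On top of this sit the semantic functions:

* **searchCls** — case-insensitive substring match over the class label and
  the annotation fields the ontology's config indexes; a query may restrict
  matching to named fields only.
* **reduceToLevel(X, ℓ)** — maps each class `x ∈ X` to every ancestor
  occurring at position `ℓ` on at least one root path of `x`. Multi-parent
  classes can map to several ancestors at one level; classes with only
  shorter root paths are copied unchanged.
* **reduceToClusterSize(X, k)** — farthest-first agglomeration: in each
  iteration every current representative at the maximal root distance is
  replaced by all of its parents (members pooled on merge), until at most
  `k` representatives remain. Representatives may end at different root
  distances; processing the farthest first keeps the spread minimal.
* **organsOf / physiologicalSystemsOf** — breadth-first rollup from an
  anatomical entity along `is_a` and the partonomy relations `isPartOf`,
  `isPartOfOrgan`, `isCellOf` only; every reached *key class* (an `is_a`
  descendant of the `organ` / `physiological_system` anchor) is collected
  and not expanded further. Developmental relations are never crossed.
* **findUpstreamInSet / findDownstreamInSet** — level-synchronous BFS from
  a query class toward a stored project vocabulary; at the first depth
  containing members of the set, *all* members at that depth are returned.
  Downstream traversal inverts the partonomy on the fly (`hasPart`).
* **stage partitioning** — for a staged anatomy ontology (one class per
  structure per developmental stage), classes are split at load time into
  *stages*, *concrete* classes (those reaching a stage via `is_a`/`isPartOf`
  chains) and *generic* stage-free classes; `concreteForDevStage(g, s)`
  intersects the downstream closure of a generic class with the classes
  linked to the one queried stage.

Named lists of class ids live in a persistent store partitioned by name, so
a project uploads its vocabulary once and refers to it in every query.

## Worked example

Four small built-in fixture ontologies (`ontoquery fixtures list`) make the
commands runnable without any files. Mapping a multi-parent regulation term
to level 5 returns both of its level-5 ancestors:

```console
$ ontoquery reduce-level go_regulation -l 5 negative_regulation_of_binding
negative_regulation_of_molecular_function
regulation_of_binding
```

Clustering three terms of very different depths to at most two clusters
takes two iterations; the deepest term is mapped in each step while the
shallow one is just copied, and the two surviving representatives sit at
root distances 5 and 6:

```console
$ ontoquery reduce-cluster go_regulation -k 2 regulation_of_signaling \
    negative_regulation_of_protein_binding regulation_of_cytokine_activity --json
[
 {
  "representative": "regulation_of_protein_binding",
  "members": [
   "negative_regulation_of_protein_binding",
   "regulation_of_cytokine_activity"
  ]
 },
 {
  "representative": "regulation_of_signaling",
  "members": [
   "regulation_of_signaling"
  ]
 }
]
```

Organ rollup follows `isCellOf`/`isPartOf`/`isPartOfOrgan` but never the
developmental relation, so `Cell_2` reports its two containing organs and
not the organ of the cell it differentiates into:

```console
$ ontoquery rollup cytomer_organs Cell_2 --policy organs
Organ_1
Organ_2
```

Stage-aware expansion of a generic structure returns the concrete classes
of the queried stage only:

```console
$ ontoquery stage for-stage tribolium antenna larva
larval_antenna
larval_flagellum
```

The same operations are available in Python (`ontoquery.reduce_to_level`,
`ontoquery.organs_of`, `ontoquery.StagePlugin`, ...), over HTTP
(`ontoquery serve`, URLs like
`/go_regulation/functions/basic/reduceToLevel;level=5/negative_regulation_of_binding`)
and through the lazy client:

```python
from ontoquery import Connector
c = Connector("http://127.0.0.1:8080")
cls = c.get_class("go_regulation", "negative_regulation_of_binding")
[p.id for p in cls.parents()]   # one request, memoized afterwards
# ['negative_regulation_of_molecular_function', 'regulation_of_binding']
```

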