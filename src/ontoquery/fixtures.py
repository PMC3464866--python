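"""Built-in example ontologies and seeded random DAGs.

Four small hand-built graphs exercise every semantic function without any
external download, plus a reproducible random-DAG generator for property
tests:

``go_regulation``
    A nested-regulation fragment of the Gene Ontology's biological-process
    branch (pure ``is_a``, multi-parent), rooted at a virtual ``thing``.
    Demonstrates level mapping and farthest-first clustering.

``cytomer_organs``
    An abstract anatomy fragment in the style of the Cytomer human-anatomy
    ontology: an ``organ`` anchor with three organs, cells and tissues
    connected by ``isCellOf``/``isPartOf``/``isPartOfOrgan``, and one
    developmental ``differentiatesInto`` edge that organ rollup must ignore.

``endonet``
    A fragment of an anatomy vocabulary as used by an endocrine-pathway
    database: a ``digestive_organ`` superclass, a ``nephron -isPartOf->
    kidney`` partonomy link, and the stored set [kidney, liver, pancreas].

``tribolium``
    A minimal staged insect anatomy: stages larva/pupa under a
    ``developmental_stage`` anchor, generic head/antenna/flagellum, and
    stage-concrete counterparts chained by ``isPartOf``.

All named fixtures are byte-stable across runs; random fixtures are fully
determined by their seed.
"""

from __future__ import annotations

import random

from .errors import NotFoundError
from .model import OntologyClass, OntologyGraph, add_virtual_root

#: go_regulation classes whose clustering the docs walk through
GO_REGULATION_MARKED = (
    "regulation_of_signaling",
    "negative_regulation_of_protein_binding",
    "regulation_of_cytokine_activity",
)

#: the stored anatomy vocabulary accompanying the endonet fixture
ENDONET_SET = ("kidney", "liver", "pancreas")


def go_regulation() -> OntologyGraph:
    """Nested-regulation GO fragment; root ``thing`` at level 1, depth 8."""
    g = OntologyGraph("go_regulation")
    edges = {
        "biological_process": [],
        "biological_regulation": ["biological_process"],
        "regulation_of_biological_process": ["biological_regulation"],
        "regulation_of_molecular_function": ["biological_regulation"],
        "regulation_of_signaling": ["regulation_of_biological_process"],
        "regulation_of_binding": ["regulation_of_molecular_function"],
        "negative_regulation_of_molecular_function": ["regulation_of_molecular_function"],
        "regulation_of_protein_binding": ["regulation_of_binding"],
        "negative_regulation_of_binding": [
            "regulation_of_binding",
            "negative_regulation_of_molecular_function",
        ],
        "negative_regulation_of_protein_binding": ["regulation_of_protein_binding"],
        "positive_regulation_of_protein_binding": ["regulation_of_protein_binding"],
        "regulation_of_cytokine_activity": ["positive_regulation_of_protein_binding"],
    }
    for cls_id in edges:
        g.add_class(OntologyClass(cls_id, cls_id.replace("_", " ")))
    for child, parents in edges.items():
        for parent in parents:
            g.add_is_a(child, parent)
    return add_virtual_root(g)


def cytomer_organs() -> OntologyGraph:
    """Abstract organ-rollup fragment with one developmental relation."""
    g = OntologyGraph("cytomer_organs")
    for cls_id in (
        "organ", "Organ_1", "Organ_2", "Organ_3",
        "Cell_1", "Cell_2", "Structure_A", "Tissue_1",
    ):
        g.add_class(cls_id)
    for org in ("Organ_1", "Organ_2", "Organ_3"):
        g.add_is_a(org, "organ")
    g.add_relation("Cell_1", "Structure_A", "isCellOf")
    g.add_relation("Structure_A", "Organ_3", "isPartOf")
    g.add_relation("Cell_2", "Organ_1", "isCellOf")
    g.add_relation("Cell_2", "Tissue_1", "isPartOf")
    g.add_relation("Tissue_1", "Organ_2", "isPartOfOrgan")
    g.add_relation("Cell_2", "Cell_1", "differentiatesInto")
    return add_virtual_root(g)


def endonet() -> OntologyGraph:
    """Anatomy fragment for stored-set up/downstream search."""
    g = OntologyGraph("endonet")
    for cls_id in ("digestive_organ", "liver", "pancreas", "stomach", "kidney", "nephron"):
        g.add_class(cls_id)
    for org in ("liver", "pancreas", "stomach"):
        g.add_is_a(org, "digestive_organ")
    g.add_relation("nephron", "kidney", "isPartOf")
    return add_virtual_root(g)


def tribolium() -> OntologyGraph:
    """Minimal staged insect anatomy (larval/pupal concrete classes)."""
    g = OntologyGraph("tribolium")
    for cls_id in (
        "developmental_stage", "larva", "pupa",
        "head", "antenna", "flagellum",
        "larval_head", "larval_antenna", "larval_flagellum", "pupal_antenna",
    ):
        g.add_class(cls_id)
    g.add_is_a("larva", "developmental_stage")
    g.add_is_a("pupa", "developmental_stage")
    g.add_is_a("larval_head", "head")
    g.add_is_a("larval_antenna", "antenna")
    g.add_is_a("larval_flagellum", "flagellum")
    g.add_is_a("pupal_antenna", "antenna")
    g.add_relation("larval_head", "larva", "isPartOf")
    g.add_relation("larval_antenna", "larval_head", "isPartOf")
    g.add_relation("larval_flagellum", "larval_antenna", "isPartOf")
    g.add_relation("pupal_antenna", "pupa", "isPartOf")
    return add_virtual_root(g)


def random_dag(
    size: int,
    seed: int,
    max_parents: int = 2,
    extra_parent_prob: float = 0.3,
    relation_rate: float = 0.0,
    relation_name: str = "isPartOf",
) -> OntologyGraph:
    """Seeded random rooted DAG for property tests.

    Node 0 is the root ``thing``; every later node ``n<i>`` draws one parent
    uniformly from the earlier nodes and, with probability
    *extra_parent_prob* per slot, up to ``max_parents - 1`` further distinct
    parents — so the graph is acyclic and every class has a root path by
    construction.  With ``relation_rate > 0`` that fraction of nodes also
    gains a typed relation edge to an earlier node, for traversal tests.
    """
    rng = random.Random(seed)
    g = OntologyGraph(f"random_{seed}_{size}")
    g.add_class(OntologyClass("thing"))
    ids = ["thing"]
    for i in range(1, size):
        cls_id = f"n{i:03d}"
        g.add_class(cls_id)
        parents = {rng.choice(ids)}
        for _ in range(max_parents - 1):
            if rng.random() < extra_parent_prob:
                parents.add(rng.choice(ids))
        for parent in sorted(parents):
            g.add_is_a(cls_id, parent)
        if relation_rate and rng.random() < relation_rate:
            g.add_relation(cls_id, rng.choice(ids), relation_name)
        ids.append(cls_id)
    return add_virtual_root(g)


#: constructors of the byte-stable named fixtures
NAMED_FIXTURES = {
    "go_regulation": go_regulation,
    "cytomer_organs": cytomer_organs,
    "endonet": endonet,
    "tribolium": tribolium,
}


def make_fixture(name: str, seed: int = 0, size: int = 30) -> OntologyGraph:
    """Build a fixture by name (``random`` takes *seed* and *size*)."""
    if name == "random":
        return random_dag(size, seed)
    try:
        return NAMED_FIXTURES[name]()
    except KeyError:
        raise NotFoundError(
            f"unknown fixture {name!r}; choose from "
            f"{', '.join(sorted(NAMED_FIXTURES))}, random"
        ) from None
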