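"""In-memory ontology model.

An ontology is represented as a typed directed graph with two separate edge
layers:

* the mandatory subsumption hierarchy (``is_a``), stored as a DAG with edges
  pointing from child to parent, and
* arbitrary named relations (``isPartOf``, ``isCellOf``, ...), stored as a
  multigraph keyed by relation name.

Keeping the hierarchy apart from the other relations mirrors how ontology
curation treats them: ``is_a`` is structural and mandatory, everything else is
semantics that a traversal policy must opt into.

Levels follow the convention that a (possibly virtual) root class sits at
level 1 and the level of any other class is one more than the maximum level of
its parents, i.e. the *longest* root path.  ``path_levels`` additionally
exposes the positions a class takes across *all* root paths, which is what
level-based ancestor mapping needs for multi-parent classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, NamedTuple

import networkx as nx

from .errors import ArgumentError, NotFoundError, StructuralError

Direction = Literal["upstream", "downstream"]

#: Conventional label (and id) of the virtual root class.
DEFAULT_ROOT_LABEL = "thing"


@dataclass
class OntologyClass:
    """A single ontology class (term).

    Parameters
    ----------
    id:
        Unique identifier within a graph; treated as an opaque string
        (an OBO id like ``GO:0008150`` or an underscore name).
    label:
        Human-readable display name.  Defaults to the id.
    annotations:
        Mapping from annotation field name (``"def"``, ``"synonym"``,
        ``"definitionEnglish"``, ...) to the list of values carried under
        that field.
    obsolete:
        Obsolete classes are kept in the graph so they remain addressable,
        but they carry no outgoing edges and are excluded from traversal.
    """

    id: str
    label: str = ""
    annotations: dict[str, list[str]] = field(default_factory=dict)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ArgumentError("ontology class id must be non-empty")
        if not self.label:
            self.label = self.id


class RelationEdge(NamedTuple):
    """A typed, directed edge between two classes (never ``is_a``)."""

    source: str
    target: str
    relation: str


@dataclass(frozen=True)
class TraversalPolicy:
    """Contract for a rollup or breadth-first search.

    ``direction`` fixes which way hierarchy and relation edges are walked:
    *upstream* follows ``is_a`` toward parents and relation edges from source
    to target; *downstream* follows ``is_a`` toward children and relation
    edges inverted on the fly (the ``hasPart`` view of ``isPartOf``).
    """

    direction: Direction
    relation_names: frozenset[str] = frozenset()
    use_hierarchy: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("upstream", "downstream"):
            raise ArgumentError(f"unknown direction: {self.direction!r}")
        object.__setattr__(self, "relation_names", frozenset(self.relation_names))

    def restricted_to(self, graph: "OntologyGraph") -> "TraversalPolicy":
        """Drop relation names not present in *graph* (they can never fire)."""
        return TraversalPolicy(
            self.direction,
            self.relation_names & graph.relation_names(),
            self.use_hierarchy,
        )


class OntologyGraph:
    """Directed graph of ontology classes with an ``is_a`` DAG plus typed relations."""

    def __init__(self, name: str = "ontology"):
        self.name = name
        self.classes: dict[str, OntologyClass] = {}
        self.root_id: str | None = None
        # _isa edges point child -> parent; _rel edges source -> target, key = relation
        self._isa = nx.DiGraph()
        self._rel = nx.MultiDiGraph()
        self._level_cache: dict[str, int] = {}
        self._path_levels_cache: dict[str, frozenset[int]] = {}

    # -- construction -------------------------------------------------------

    def add_class(self, cls: OntologyClass | str, label: str | None = None) -> OntologyClass:
        if isinstance(cls, str):
            cls = OntologyClass(cls, label or cls)
        if cls.id in self.classes:
            raise ArgumentError(f"duplicate class id: {cls.id!r}")
        self.classes[cls.id] = cls
        self._isa.add_node(cls.id)
        self._rel.add_node(cls.id)
        self._dirty()
        return cls

    def add_is_a(self, child: str, parent: str) -> None:
        self._require(child)
        self._require(parent)
        self._isa.add_edge(child, parent)
        self._dirty()

    def add_relation(self, source: str, target: str, relation: str) -> None:
        if not relation:
            raise ArgumentError("relation name must be non-empty")
        if relation == "is_a":
            raise ArgumentError("is_a is the hierarchy, not a relation edge")
        self._require(source)
        self._require(target)
        self._rel.add_edge(source, target, key=relation)
        self._dirty()

    def _dirty(self) -> None:
        self._level_cache.clear()
        self._path_levels_cache.clear()

    def _require(self, cls_id: str) -> None:
        if cls_id not in self.classes:
            raise NotFoundError(f"unknown class id: {cls_id!r} in ontology {self.name!r}")

    # -- basic queries -------------------------------------------------------

    def __contains__(self, cls_id: str) -> bool:
        return cls_id in self.classes

    def __iter__(self) -> Iterator[str]:
        return iter(self.classes)

    def __len__(self) -> int:
        return len(self.classes)

    def get(self, cls_id: str) -> OntologyClass:
        self._require(cls_id)
        return self.classes[cls_id]

    def is_obsolete(self, cls_id: str) -> bool:
        return self.get(cls_id).obsolete

    def parents(self, cls_id: str) -> list[str]:
        """is_a parents, sorted lexicographically."""
        self._require(cls_id)
        return sorted(self._isa.successors(cls_id))

    def children(self, cls_id: str) -> list[str]:
        """is_a children, sorted lexicographically."""
        self._require(cls_id)
        return sorted(self._isa.predecessors(cls_id))

    def relation_targets(self, cls_id: str, relation: str, direction: Direction = "upstream") -> list[str]:
        """Neighbours over one relation type.

        ``upstream`` returns the stored edge targets; ``downstream`` returns
        the sources of incoming edges, i.e. the inverse relation generated on
        the fly (``hasPart`` for a stored ``isPartOf``).
        """
        self._require(cls_id)
        if direction == "upstream":
            found = [t for _, t, k in self._rel.out_edges(cls_id, keys=True) if k == relation]
        elif direction == "downstream":
            found = [s for s, _, k in self._rel.in_edges(cls_id, keys=True) if k == relation]
        else:
            raise ArgumentError(f"unknown direction: {direction!r}")
        return sorted(set(found))

    def relations_of(self, cls_id: str, direction: Direction = "upstream") -> list[RelationEdge]:
        """All typed relation edges touching *cls_id* in the given direction."""
        self._require(cls_id)
        if direction == "upstream":
            edges = self._rel.out_edges(cls_id, keys=True)
        else:
            edges = self._rel.in_edges(cls_id, keys=True)
        return sorted(RelationEdge(s, t, k) for s, t, k in edges)

    def relation_edges(self) -> set[RelationEdge]:
        return {RelationEdge(s, t, k) for s, t, k in self._rel.edges(keys=True)}

    def is_a_edges(self) -> set[tuple[str, str]]:
        return set(self._isa.edges())

    def relation_names(self) -> frozenset[str]:
        return frozenset(k for _, _, k in self._rel.edges(keys=True))

    def ancestors(self, cls_id: str) -> set[str]:
        """All is_a ancestors (transitive parents), excluding the class itself."""
        self._require(cls_id)
        # _isa edges run child -> parent, so graph-descendants are ancestors
        return set(nx.descendants(self._isa, cls_id))

    def subclasses(self, cls_id: str) -> set[str]:
        """All is_a descendants (transitive children), excluding the class itself."""
        self._require(cls_id)
        return set(nx.ancestors(self._isa, cls_id))

    def parentless(self, include_obsolete: bool = False) -> list[str]:
        """Classes without is_a parents (candidates for virtual rooting)."""
        out = [
            c
            for c in self.classes
            if self._isa.out_degree(c) == 0
            and (include_obsolete or not self.classes[c].obsolete)
        ]
        return sorted(out)

    # -- structure -----------------------------------------------------------

    def check_acyclic(self) -> None:
        """Raise :class:`StructuralError` naming one cycle member if is_a cycles."""
        if not nx.is_directed_acyclic_graph(self._isa):
            cycle = nx.find_cycle(self._isa)
            raise StructuralError(
                f"is_a cycle detected involving class {cycle[0][0]!r}"
            )

    # -- levels --------------------------------------------------------------

    def level_of(self, cls_id: str) -> int:
        """Longest-path distance to the root, with the root at level 1."""
        self._require(cls_id)
        if not self._level_cache:
            self._compute_levels()
        return self._level_cache[cls_id]

    def path_levels(self, cls_id: str) -> frozenset[int]:
        """Positions of *cls_id* over all root paths (root at position 1).

        For a parentless class this is ``{1}``; otherwise the union over
        parents of their path levels, shifted by one.  Equals the set of
        lengths of all root->class is_a paths.
        """
        self._require(cls_id)
        if not self._path_levels_cache:
            self._compute_levels()
        return self._path_levels_cache[cls_id]

    def _compute_levels(self) -> None:
        self.check_acyclic()
        # topological order of the child->parent DAG, reversed, yields parents first
        order = list(reversed(list(nx.topological_sort(self._isa))))
        for node in order:
            ps = list(self._isa.successors(node))
            if not ps:
                self._level_cache[node] = 1
                self._path_levels_cache[node] = frozenset({1})
            else:
                self._level_cache[node] = 1 + max(self._level_cache[p] for p in ps)
                self._path_levels_cache[node] = frozenset(
                    d + 1 for p in ps for d in self._path_levels_cache[p]
                )

    # -- comparison ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            self.name == other.name
            and self.classes == other.classes
            and self.is_a_edges() == other.is_a_edges()
            and self.relation_edges() == other.relation_edges()
        )

    def __repr__(self) -> str:
        return (
            f"<OntologyGraph {self.name!r}: {len(self.classes)} classes, "
            f"{self._isa.number_of_edges()} is_a, "
            f"{self._rel.number_of_edges()} relation edges>"
        )


def add_virtual_root(graph: OntologyGraph, root_label: str = DEFAULT_ROOT_LABEL) -> OntologyGraph:
    """Insert a virtual root so every non-obsolete class has a path to it.

    The root class (id = label, conventionally ``"thing"``) sits at level 1;
    every formerly parentless non-obsolete class gains an ``is_a`` edge to it.
    Idempotent when the graph already has that sole root.  Raises
    :class:`StructuralError` if the hierarchy contains a cycle.
    """
    graph.check_acyclic()
    root_id = root_label
    parentless = graph.parentless()
    if root_id in graph and parentless == [root_id]:
        graph.root_id = root_id
        return graph
    if root_id not in graph:
        graph.add_class(OntologyClass(root_id, root_label))
    for cls_id in parentless:
        if cls_id != root_id:
            graph.add_is_a(cls_id, root_id)
    graph.root_id = root_id
    return graph


# Thin functional aliases over the graph methods; convenient for a
# one-import functional style and mirrored by the REST layer.

def parents(graph: OntologyGraph, cls_id: str) -> list[str]:
    return graph.parents(cls_id)


def children(graph: OntologyGraph, cls_id: str) -> list[str]:
    return graph.children(cls_id)


def relation_targets(
    graph: OntologyGraph, cls_id: str, relation: str, direction: Direction = "upstream"
) -> list[str]:
    return graph.relation_targets(cls_id, relation, direction)


def level_of(graph: OntologyGraph, cls_id: str) -> int:
    return graph.level_of(cls_id)


def path_levels(graph: OntologyGraph, cls_id: str) -> frozenset[int]:
    return graph.path_levels(cls_id)
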