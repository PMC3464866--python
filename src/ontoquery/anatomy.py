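"""Anatomy-ontology semantic functions: key-class rollup and set-restricted BFS.

An anatomical structure (a cell, a tissue, a body part) usually needs to be
reported at a coarser, fixed granularity — "which organ(s) does this belong
to?".  The knowledge of *which* classes count as organs and *which* relations
may be crossed on the way is ontology-specific; this module encapsulates it:

* key classes are the ``is_a`` descendants of a configured anchor class
  (e.g. ``organ`` or ``physiological_system``);
* a rollup walks upstream from a start class along the hierarchy and a fixed
  set of partonomy-like relations (``isPartOf``, ``isPartOfOrgan``,
  ``isCellOf``), collecting every key class it reaches without expanding it
  further; all other relations (e.g. developmental ones such as
  ``differentiatesInto``) are never crossed.

``find_in_set`` answers the complementary question — map a query class onto a
project's fixed vocabulary — with a level-synchronous breadth-first search
that stops at the first depth containing a member of the stored set and
returns every member found at that depth.
"""

from __future__ import annotations

from collections.abc import Iterable, Set
from dataclasses import dataclass, field

from .errors import ArgumentError, ConfigError, NotFoundError
from .model import OntologyGraph, TraversalPolicy

#: Relations an organ/system rollup is allowed to cross.
PARTONOMY_RELATIONS = frozenset({"isPartOf", "isPartOfOrgan", "isCellOf"})

ORGAN_ANCHOR = "organ"
SYSTEM_ANCHOR = "physiological_system"


@dataclass(frozen=True)
class KeyClassPolicy:
    """Rollup configuration: which classes are targets, which edges to walk."""

    anchor_id: str
    traversal: TraversalPolicy = field(
        default_factory=lambda: TraversalPolicy("upstream", PARTONOMY_RELATIONS, True)
    )
    #: expand key classes further (report organs containing reached organs)?
    expand_key_classes: bool = False


def key_classes(graph: OntologyGraph, anchor_id: str) -> set[str]:
    """The key set: is_a descendants of the anchor, the anchor itself excluded."""
    if anchor_id not in graph:
        raise NotFoundError(f"anchor class {anchor_id!r} not in ontology {graph.name!r}")
    return {c for c in graph.subclasses(anchor_id) if not graph.is_obsolete(c)}


def _neighbours(graph: OntologyGraph, cls_id: str, policy: TraversalPolicy) -> set[str]:
    """One traversal step under *policy*; obsolete neighbours are dropped."""
    out: set[str] = set()
    if policy.use_hierarchy:
        if policy.direction == "upstream":
            out.update(graph.parents(cls_id))
        else:
            out.update(graph.children(cls_id))
    for rel in sorted(policy.relation_names):
        out.update(graph.relation_targets(cls_id, rel, policy.direction))
    return {c for c in out if not graph.is_obsolete(c)}


def rollup_to_key_classes(
    graph: OntologyGraph, start_id: str, policy: KeyClassPolicy
) -> set[str]:
    """Collect every key class reachable from *start_id* under the policy.

    Breadth-first over the hierarchy plus the policy relations only.  A key
    class that is reached is added to the result and, unless
    ``expand_key_classes`` is set, not expanded further, so the most specific
    key classes are returned.  If the start is itself a key class it alone is
    returned.
    """
    graph.get(start_id)
    keys = key_classes(graph, policy.anchor_id)
    traversal = policy.traversal.restricted_to(graph)
    found: set[str] = set()
    seen = {start_id}
    frontier = [start_id]
    while frontier:
        nxt: list[str] = []
        for cls_id in frontier:
            if cls_id in keys:
                found.add(cls_id)
                if not policy.expand_key_classes:
                    continue
            for nb in sorted(_neighbours(graph, cls_id, traversal)):
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
    return found


def organs_of(graph: OntologyGraph, start_id: str) -> set[str]:
    """The organs an anatomical entity belongs to.

    Configured rollup anchored at the ``organ`` class, crossing the class
    hierarchy and the partonomy relations only.
    """
    return rollup_to_key_classes(graph, start_id, _anchored_policy(graph, ORGAN_ANCHOR))


def physiological_systems_of(graph: OntologyGraph, start_id: str) -> set[str]:
    """The physiological systems an anatomical entity belongs to (rollup)."""
    return rollup_to_key_classes(graph, start_id, _anchored_policy(graph, SYSTEM_ANCHOR))


def _anchored_policy(graph: OntologyGraph, anchor_id: str) -> KeyClassPolicy:
    if anchor_id not in graph:
        raise ConfigError(
            f"ontology {graph.name!r} has no {anchor_id!r} anchor class"
        )
    return KeyClassPolicy(anchor_id)


def find_in_set(
    graph: OntologyGraph,
    start_id: str,
    member_ids: Iterable[str],
    policy: TraversalPolicy,
) -> set[str]:
    """Level-synchronous BFS that stops at the first depth holding set members.

    Starting from *start_id* (depth 0, which counts if it is itself a
    member), the hierarchy and the policy relations are walked in the policy
    direction; at the first BFS depth where at least one member of
    *member_ids* appears, all members found at that depth are returned.  Path
    length is unbounded; the empty set is returned when no member is
    reachable.
    """
    graph.get(start_id)
    members = set(member_ids)
    if not members:
        raise ArgumentError("member set must be non-empty")
    traversal = policy.restricted_to(graph)
    seen = {start_id}
    frontier = {start_id}
    while frontier:
        hits = frontier & members
        if hits:
            return hits
        nxt: set[str] = set()
        for cls_id in frontier:
            nxt.update(nb for nb in _neighbours(graph, cls_id, traversal) if nb not in seen)
        seen.update(nxt)
        frontier = nxt
    return set()


class AnatomyPlugin:
    """Named key-class rollup policies plus up/downstream set search for one ontology.

    Refuses to load if a configured anchor class is absent from the ontology,
    so a misconfigured deployment fails at startup rather than at query time.
    """

    def __init__(
        self,
        graph: OntologyGraph,
        anchors: dict[str, str] | None = None,
        relations: Set[str] = PARTONOMY_RELATIONS,
    ):
        self.graph = graph
        # relations absent from this ontology can never traverse; drop them
        self.relations = frozenset(relations) & graph.relation_names()
        if anchors is None:
            anchors = {}
            if ORGAN_ANCHOR in graph:
                anchors["organs"] = ORGAN_ANCHOR
            if SYSTEM_ANCHOR in graph:
                anchors["systems"] = SYSTEM_ANCHOR
            if not anchors:
                raise ConfigError(
                    f"ontology {graph.name!r} has neither an {ORGAN_ANCHOR!r} nor a "
                    f"{SYSTEM_ANCHOR!r} anchor class"
                )
        self.policies: dict[str, KeyClassPolicy] = {}
        for name, anchor in anchors.items():
            if anchor not in graph:
                raise ConfigError(
                    f"anchor class {anchor!r} for policy {name!r} not in "
                    f"ontology {graph.name!r}"
                )
            self.policies[name] = KeyClassPolicy(
                anchor, TraversalPolicy("upstream", self.relations, True)
            )

    def rollup(self, policy_name: str, start_id: str) -> set[str]:
        if policy_name not in self.policies:
            raise NotFoundError(f"unknown rollup policy: {policy_name!r}")
        return rollup_to_key_classes(self.graph, start_id, self.policies[policy_name])

    def organs_of(self, start_id: str) -> set[str]:
        return self.rollup("organs", start_id)

    def physiological_systems_of(self, start_id: str) -> set[str]:
        return self.rollup("systems", start_id)

    def find_upstream_in_set(self, start_id: str, member_ids: Iterable[str]) -> set[str]:
        return find_in_set(
            self.graph, start_id, member_ids,
            TraversalPolicy("upstream", self.relations, True),
        )

    def find_downstream_in_set(self, start_id: str, member_ids: Iterable[str]) -> set[str]:
        return find_in_set(
            self.graph, start_id, member_ids,
            TraversalPolicy("downstream", self.relations, True),
        )
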