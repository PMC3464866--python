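"""Developmental-stage partitioning of an anatomy ontology.

A staged anatomy ontology (the Tribolium castaneum anatomy is the archetype)
carries one class per structure *per developmental stage* — larval antenna
and pupal antenna are distinct classes, both subclasses of a stage-free
generic ``antenna`` and each linked by ``isPartOf`` (possibly through several
intermediate structures) to its stage.  Phenotype annotations attach to the
stage-linked ("concrete") classes; user-facing search starts from the
stage-free ("generic") ones.

This plugin computes the partition once at load time:

* *stages*: the ``is_a`` descendants of a configured stage anchor;
* *concrete*: every non-stage class from which some stage is reachable by
  any mixture of ``is_a`` (toward parents) and the configured link relations;
* *generic*: everything else (excluding the anchor and the virtual root).

``concrete_for_dev_stage`` then maps a (generic class, stage) query to the
concrete classes a database lookup should use: the downstream closure of the
generic class via subclasses and the on-the-fly inverse of the partonomy
relation (``hasPart``), restricted to classes linked to *that* stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .basic import SearchQuery, search_cls
from .errors import ArgumentError, ConfigError
from .model import OntologyGraph
from .obo_io import OntologyConfig

STAGE_ANCHOR = "developmental_stage"


@dataclass(frozen=True)
class StageConfig:
    """Which class anchors the stages and which relations link structures to them."""

    stage_anchor_id: str = STAGE_ANCHOR
    link_relations: frozenset[str] = frozenset({"isPartOf"})
    #: relation inverted on the fly for downstream expansion
    part_relation: str = "isPartOf"

    def __post_init__(self) -> None:
        object.__setattr__(self, "link_relations", frozenset(self.link_relations))


class StagePlugin:
    """Stage/concrete/generic partition of one ontology, cached at load."""

    def __init__(self, graph: OntologyGraph, cfg: StageConfig | None = None):
        self.graph = graph
        self.cfg = cfg or StageConfig()
        anchor = self.cfg.stage_anchor_id
        if anchor not in graph:
            raise ConfigError(
                f"ontology {graph.name!r} has no stage anchor class {anchor!r}"
            )
        self.stages: frozenset[str] = frozenset(
            c for c in graph.subclasses(anchor) if not graph.is_obsolete(c)
        )
        if not self.stages:
            raise ConfigError(
                f"stage anchor {anchor!r} has no subclasses in {graph.name!r}"
            )
        self._concrete = frozenset(self._reach_from_stages(self.stages))
        excluded = self.stages | self._concrete | {anchor}
        if graph.root_id is not None:
            excluded |= {graph.root_id}
        self._generic = frozenset(
            c
            for c in graph.classes
            if c not in excluded and not graph.is_obsolete(c)
        )

    # -- partition -----------------------------------------------------------

    def _reach_from_stages(self, targets: frozenset[str]) -> set[str]:
        """Classes that can reach one of *targets* via is_a-up / link relations.

        Computed as a reverse BFS from the targets: step to is_a children and
        to the sources of incoming link-relation edges.
        """
        g = self.graph
        seen: set[str] = set()
        frontier = list(targets)
        while frontier:
            nxt: list[str] = []
            for cls_id in frontier:
                back = set(g.children(cls_id))
                for rel in sorted(self.cfg.link_relations):
                    back.update(g.relation_targets(cls_id, rel, "downstream"))
                for nb in back:
                    if nb not in seen and nb not in targets and not g.is_obsolete(nb):
                        seen.add(nb)
                        nxt.append(nb)
            frontier = nxt
        return seen - self.stages

    def concrete_classes(self) -> frozenset[str]:
        """All classes linked (possibly indirectly) to some developmental stage."""
        return self._concrete

    def generic_classes(self) -> frozenset[str]:
        """All stage-free classes (auto-completion vocabulary)."""
        return self._generic

    # -- queries -------------------------------------------------------------

    def find_in_generic(self, pattern: str) -> list[str]:
        """Substring search over labels and synonyms of generic classes, sorted."""
        synonym_config = OntologyConfig(self.graph.name, indexed_fields=["synonym"])
        hits = search_cls(self.graph, synonym_config, SearchQuery(pattern))
        return sorted(h for h in hits if h in self._generic)

    def concrete_for_dev_stage(self, generic_id: str, stage_id: str) -> set[str]:
        """Concrete classes downstream of *generic_id* and linked to *stage_id*.

        Downstream means subclasses plus the inverse of the partonomy
        relation, unbounded depth; stage linkage is re-evaluated against the
        single given stage so classes of sibling stages never leak in.
        """
        g = self.graph
        g.get(generic_id)
        if stage_id not in self.stages:
            raise ArgumentError(f"{stage_id!r} is not a developmental stage")
        # downstream closure of the generic class
        closure: set[str] = set()
        frontier = [generic_id]
        while frontier:
            nxt: list[str] = []
            for cls_id in frontier:
                down = set(g.children(cls_id))
                down.update(g.relation_targets(cls_id, self.cfg.part_relation, "downstream"))
                for nb in down:
                    if nb != generic_id and nb not in closure and not g.is_obsolete(nb):
                        closure.add(nb)
                        nxt.append(nb)
            frontier = nxt
        stage_linked = self._reach_from_stages(frozenset({stage_id}))
        return closure & stage_linked
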