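"""Built-in semantic functions: search and ancestor mapping.

Three operations that work on any loaded ontology because they rely only on
labels, annotations and the class hierarchy:

``search_cls``
    Case-insensitive substring search over the class label and the
    annotation fields the ontology's config marks as indexed, optionally
    restricted to a subset of those fields.

``reduce_to_level``
    Map classes to all ancestors at a fixed level beneath the root,
    considering every root path (multi-parent classes can yield several
    ancestors at one level).

``reduce_to_cluster_size``
    Farthest-first agglomeration: repeatedly replace the representatives
    with the greatest root distance by their parents until no more than the
    requested number of clusters remain.  Because a maximum cluster count is
    given instead of a level, the surviving representatives may sit at
    different root distances; processing the farthest classes first keeps
    that spread minimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ArgumentError, UnknownFieldError
from .model import OntologyGraph
from .obo_io import OntologyConfig


@dataclass(frozen=True)
class SearchQuery:
    """A substring search pattern, optionally restricted to annotation fields.

    With no restriction the label and every indexed field are searched; with
    a restriction only the named fields are searched (the label is excluded).
    """

    pattern: str
    restrict_fields: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.pattern.strip():
            raise ArgumentError("search pattern must be non-empty")
        if self.restrict_fields is not None:
            object.__setattr__(self, "restrict_fields", frozenset(self.restrict_fields))


@dataclass
class ClusterAssignment:
    """A cluster representative together with the input classes mapped onto it."""

    representative: str
    members: list[str] = field(default_factory=list)


def search_cls(
    graph: OntologyGraph,
    config: OntologyConfig | None,
    query: SearchQuery | str,
) -> list[str]:
    """Return ids of classes matching *query*, sorted, duplicates removed.

    A class matches if the lower-cased pattern is a substring of its
    lower-cased label or of any value of a searched annotation field.
    Obsolete classes never match.

    Raises :class:`UnknownFieldError` if a restriction names a field outside
    the config's indexed fields.
    """
    if isinstance(query, str):
        query = SearchQuery(query)
    indexed = list(config.indexed_fields) if config is not None else []
    if query.restrict_fields is not None:
        unknown = query.restrict_fields - set(indexed)
        if unknown:
            raise UnknownFieldError(
                f"field(s) not indexed for {graph.name!r}: {', '.join(sorted(unknown))}"
            )
        fields = sorted(query.restrict_fields)
        search_label = False
    else:
        fields = indexed
        search_label = True

    needle = query.pattern.lower()
    hits: set[str] = set()
    for cls in graph.classes.values():
        if cls.obsolete:
            continue
        if search_label and needle in cls.label.lower():
            hits.add(cls.id)
            continue
        for fld in fields:
            if any(needle in v.lower() for v in cls.annotations.get(fld, ())):
                hits.add(cls.id)
                break
    return sorted(hits)


def reduce_to_level(
    graph: OntologyGraph, class_ids: list[str] | str, level: int
) -> dict[str, set[str]]:
    """Map each input class to its ancestors at the given level beneath the root.

    An ancestor qualifies if it occurs at position *level* on at least one
    root path of the input class; a class occurring at that level itself maps
    to itself.  A class whose every root path is shorter than *level* is
    copied unchanged into the result.
    """
    if isinstance(class_ids, str):
        class_ids = [class_ids]
    if level < 1:
        raise ArgumentError(f"level must be >= 1, got {level}")
    result: dict[str, set[str]] = {}
    for cls_id in class_ids:
        graph.get(cls_id)
        candidates = graph.ancestors(cls_id) | {cls_id}
        at_level = {a for a in candidates if level in graph.path_levels(a)}
        if not at_level:
            # every root path ends before the requested level; copy the class
            at_level = {cls_id}
        result[cls_id] = at_level
    return result


def reduce_to_cluster_size_trace(
    graph: OntologyGraph, class_ids: list[str], max_clusters: int
) -> list[dict[str, set[str]]]:
    """Full iteration trace of the cluster reduction.

    Returns the list of representative states, the first being the identity
    assignment; each subsequent state is one iteration in which every
    representative at the current maximum root distance has been replaced by
    all of its parents (members pooled on merge, unaffected representatives
    copied).  The number of iterations performed is ``len(trace) - 1``.
    """
    if not class_ids:
        raise ArgumentError("input class list must be non-empty")
    if max_clusters < 1:
        raise ArgumentError(f"max_clusters must be >= 1, got {max_clusters}")
    state: dict[str, set[str]] = {}
    for cls_id in class_ids:
        graph.get(cls_id)
        state.setdefault(cls_id, set()).add(cls_id)
    trace = [state]
    while len(state) > max_clusters:
        top = max(graph.level_of(rep) for rep in state)
        nxt: dict[str, set[str]] = {}
        progressed = False
        for rep, members in state.items():
            parents = graph.parents(rep) if graph.level_of(rep) == top else []
            if parents:
                progressed = True
                for parent in parents:
                    nxt.setdefault(parent, set()).update(members)
            else:
                nxt.setdefault(rep, set()).update(members)
        if not progressed:  # only parentless representatives left
            break
        state = nxt
        trace.append(state)
    return trace


def reduce_to_cluster_size(
    graph: OntologyGraph, class_ids: list[str], max_clusters: int
) -> list[ClusterAssignment]:
    """Cluster the input classes onto at most *max_clusters* common ancestors.

    Iteratively maps the representatives farthest from the root to their
    parents until the representative count is within the limit (checked after
    each full iteration; an input already within the limit is returned as
    identity clusters).  A member can appear in several clusters when a
    representative on its path has multiple parents.
    """
    final = reduce_to_cluster_size_trace(graph, class_ids, max_clusters)[-1]
    return [
        ClusterAssignment(rep, sorted(members))
        for rep, members in sorted(final.items())
    ]
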