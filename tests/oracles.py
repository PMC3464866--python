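"""Independent brute-force oracles used by the property tests.

These deliberately avoid the library's level/path caches and BFS code:
root paths are enumerated recursively from the raw is_a adjacency, and
shortest traversal depths come from networkx on an explicitly materialized
move graph.
"""

from __future__ import annotations

import networkx as nx

from ontoquery.model import OntologyGraph, TraversalPolicy


def root_paths(graph: OntologyGraph, cls_id: str) -> list[list[str]]:
    """All is_a paths from a parentless class down to *cls_id* (inclusive)."""
    parents = graph.parents(cls_id)
    if not parents:
        return [[cls_id]]
    return [p + [cls_id] for parent in parents for p in root_paths(graph, parent)]


def level_oracle(graph: OntologyGraph, cls_id: str) -> int:
    return max(len(p) for p in root_paths(graph, cls_id))


def path_levels_oracle(graph: OntologyGraph, cls_id: str) -> set[int]:
    return {len(p) for p in root_paths(graph, cls_id)}


def reduce_to_level_oracle(graph: OntologyGraph, cls_id: str, level: int) -> set[str]:
    paths = root_paths(graph, cls_id)
    hits = {p[level - 1] for p in paths if len(p) >= level}
    return hits or {cls_id}


def move_graph(graph: OntologyGraph, policy: TraversalPolicy) -> nx.DiGraph:
    """Materialize every legal traversal step under *policy* as an edge."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.classes)
    if policy.use_hierarchy:
        for child, parent in graph.is_a_edges():
            if policy.direction == "upstream":
                g.add_edge(child, parent)
            else:
                g.add_edge(parent, child)
    for source, target, relation in graph.relation_edges():
        if relation in policy.relation_names:
            if policy.direction == "upstream":
                g.add_edge(source, target)
            else:
                g.add_edge(target, source)
    return g


def find_in_set_oracle(
    graph: OntologyGraph, start: str, members: set[str], policy: TraversalPolicy
) -> set[str]:
    """All-and-only the set members at minimum traversal depth from *start*."""
    depths = nx.single_source_shortest_path_length(move_graph(graph, policy), start)
    member_depths = {m: depths[m] for m in members if m in depths}
    if not member_depths:
        return set()
    best = min(member_depths.values())
    return {m for m, d in member_depths.items() if d == best}
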