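import pytest
from hypothesis import given, settings, strategies as st

from ontoquery import (
    ArgumentError,
    OntologyConfig,
    SearchQuery,
    UnknownFieldError,
    reduce_to_cluster_size,
    reduce_to_cluster_size_trace,
    reduce_to_level,
    search_cls,
)
from ontoquery.fixtures import GO_REGULATION_MARKED, random_dag

from oracles import reduce_to_level_oracle, root_paths


class TestSearch:
    def test_label_substring_match(self, go_regulation):
        hits = search_cls(go_regulation, None, "binding")
        assert hits == [
            "negative_regulation_of_binding",
            "negative_regulation_of_protein_binding",
            "positive_regulation_of_protein_binding",
            "regulation_of_binding",
            "regulation_of_protein_binding",
        ]

    def test_no_match_returns_empty(self, go_regulation):
        assert search_cls(go_regulation, None, "zzz") == []

    def test_case_insensitive(self, go_regulation):
        assert search_cls(go_regulation, None, "BINDING") == search_cls(
            go_regulation, None, "binding"
        )

    def test_annotation_fields_included(self, go_regulation):
        cfg = OntologyConfig("go", indexed_fields=["definitionEnglish"])
        go_regulation.get("biological_process").annotations["definitionEnglish"] = [
            "any process in a cistern or elsewhere"
        ]
        assert search_cls(go_regulation, cfg, "cistern") == ["biological_process"]

    def test_field_restriction_excludes_label(self, go_regulation):
        cfg = OntologyConfig("go", indexed_fields=["definitionEnglish"])
        query = SearchQuery("binding", frozenset({"definitionEnglish"}))
        assert search_cls(go_regulation, cfg, query) == []

    def test_unknown_restriction_field(self, go_regulation):
        cfg = OntologyConfig("go", indexed_fields=["synonym"])
        with pytest.raises(UnknownFieldError, match="definitionEnglish"):
            search_cls(go_regulation, cfg, SearchQuery("x", frozenset({"definitionEnglish"})))

    def test_blank_pattern_rejected(self):
        with pytest.raises(ArgumentError):
            SearchQuery("   ")


class TestReduceToLevel:
    def test_diamond_class_maps_to_both_level5_ancestors(self, go_regulation):
        result = reduce_to_level(go_regulation, ["negative_regulation_of_binding"], 5)
        assert result == {
            "negative_regulation_of_binding": {
                "negative_regulation_of_molecular_function",
                "regulation_of_binding",
            }
        }

    def test_root_maps_to_itself_at_level_one(self, go_regulation):
        assert reduce_to_level(go_regulation, ["thing"], 1) == {"thing": {"thing"}}

    def test_class_at_requested_level_maps_to_itself(self, go_regulation):
        result = reduce_to_level(go_regulation, ["regulation_of_signaling"], 5)
        assert result == {"regulation_of_signaling": {"regulation_of_signaling"}}

    def test_shallow_class_copied(self, go_regulation):
        # every root path of biological_process is shorter than the level
        result = reduce_to_level(go_regulation, ["biological_process"], 7)
        assert result == {"biological_process": {"biological_process"}}

    def test_level_below_one_rejected(self, go_regulation):
        with pytest.raises(ArgumentError):
            reduce_to_level(go_regulation, ["thing"], 0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**20), size=st.integers(2, 50))
    def test_matches_root_path_enumeration(self, seed, size):
        g = random_dag(size, seed)
        ids = sorted(g)
        max_level = max(g.level_of(c) for c in ids)
        for level in range(1, max_level + 1):
            got = reduce_to_level(g, ids, level)
            for cls_id in ids:
                assert got[cls_id] == reduce_to_level_oracle(g, cls_id, level)


def ancestors_or_self(graph, cls_id):
    return graph.ancestors(cls_id) | {cls_id}


class TestReduceToClusterSize:
    def test_two_iteration_trace(self, go_regulation):
        """Farthest-first: the deepest class maps in each step, a shallow one is copied."""
        trace = reduce_to_cluster_size_trace(go_regulation, list(GO_REGULATION_MARKED), 2)
        assert len(trace) - 1 == 2
        # first iteration maps only the deepest class (level 8) to its parent
        assert set(trace[1]) == {
            "regulation_of_signaling",
            "negative_regulation_of_protein_binding",
            "positive_regulation_of_protein_binding",
        }
        final = trace[-1]
        assert final == {
            "regulation_of_signaling": {"regulation_of_signaling"},
            "regulation_of_protein_binding": {
                "negative_regulation_of_protein_binding",
                "regulation_of_cytokine_activity",
            },
        }

    def test_final_representative_levels_differ(self, go_regulation):
        reps = [c.representative for c in reduce_to_cluster_size(go_regulation, list(GO_REGULATION_MARKED), 2)]
        assert sorted(go_regulation.level_of(r) for r in reps) == [5, 6]

    def test_input_within_limit_returns_identity(self, go_regulation):
        clusters = reduce_to_cluster_size(go_regulation, list(GO_REGULATION_MARKED), 3)
        assert {c.representative: c.members for c in clusters} == {
            m: [m] for m in GO_REGULATION_MARKED
        }

    def test_single_cluster_representative_is_common_ancestor(self, go_regulation):
        (cluster,) = reduce_to_cluster_size(go_regulation, list(GO_REGULATION_MARKED), 1)
        for member in GO_REGULATION_MARKED:
            assert cluster.representative in ancestors_or_self(go_regulation, member)

    def test_empty_input_rejected(self, go_regulation):
        with pytest.raises(ArgumentError):
            reduce_to_cluster_size(go_regulation, [], 2)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**20),
        size=st.integers(3, 40),
        k=st.integers(1, 4),
        n_inputs=st.integers(1, 8),
    )
    def test_invariants_on_random_dags(self, seed, size, k, n_inputs):
        import random

        g = random_dag(size, seed)
        rng = random.Random(seed + 1)
        inputs = rng.sample(sorted(g), min(n_inputs, len(g)))
        clusters = reduce_to_cluster_size(g, inputs, k)
        assert 1 <= len(clusters) <= k
        covered = set()
        for cluster in clusters:
            covered.update(cluster.members)
            for member in cluster.members:
                assert cluster.representative in ancestors_or_self(g, member)
        assert covered == set(inputs)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**20), size=st.integers(4, 40))
    def test_raising_limit_never_lowers_minimum_level(self, seed, size):
        import random

        g = random_dag(size, seed)
        rng = random.Random(seed + 2)
        inputs = rng.sample(sorted(g), min(5, len(g)))
        min_levels = []
        for k in (1, 2, 4):
            clusters = reduce_to_cluster_size(g, inputs, k)
            min_levels.append(min(g.level_of(c.representative) for c in clusters))
        assert min_levels == sorted(min_levels)
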