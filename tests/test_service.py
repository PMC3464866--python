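import json
import threading

import pytest

from ontoquery import (
    Connector,
    HttpTransport,
    LocalTransport,
    NotFoundError,
    organs_of,
    reduce_to_level,
    search_cls,
)
from ontoquery import fixtures as fx
from ontoquery.service import make_service_server, route
from ontoquery.stage import StagePlugin


def get(state, path, accept="application/json"):
    return route(state, "GET", path, accept)


class TestRouting:
    def test_index_lists_ontologies_and_plugins(self, service_state):
        status, _, body = get(service_state, "/")
        doc = json.loads(body)["ontologies"]
        assert status == 200
        assert set(doc) == set(fx.NAMED_FIXTURES)
        assert doc["cytomer_organs"] == ["basic", "cytomer"]
        assert doc["tribolium"] == ["basic", "tribolium"]

    def test_class_resource_with_links(self, service_state):
        status, ctype, body = get(service_state, "/go_regulation/cls/regulation_of_binding")
        assert (status, ctype) == (200, "application/json")
        doc = json.loads(body)
        assert doc["id"] == "regulation_of_binding"
        assert doc["label"] == "regulation of binding"
        assert doc["links"]["parents"].endswith("/parents")

    def test_parents_subresource(self, service_state):
        _, _, body = get(service_state, "/go_regulation/cls/negative_regulation_of_binding/parents")
        assert [e["id"] for e in json.loads(body)] == [
            "negative_regulation_of_molecular_function",
            "regulation_of_binding",
        ]

    def test_function_dispatch_with_matrix_params(self, service_state):
        _, _, body = get(
            service_state,
            "/go_regulation/functions/basic/reduceToLevel;level=5/negative_regulation_of_binding",
        )
        assert json.loads(body) == {
            "negative_regulation_of_binding": [
                "negative_regulation_of_molecular_function",
                "regulation_of_binding",
            ]
        }

    def test_empty_search_is_success(self, service_state):
        status, _, body = get(service_state, "/go_regulation/functions/basic/searchCls/zzz")
        assert status == 200
        assert json.loads(body) == []

    def test_rollup_entity_list(self, service_state):
        _, _, body = get(service_state, "/cytomer_organs/functions/cytomer/organsOf/Cell_2")
        assert {e["id"] for e in json.loads(body)} == {"Organ_1", "Organ_2"}

    def test_stored_set_function_roundtrip(self, service_state):
        _, _, body = get(
            service_state,
            "/endonet/functions/basic/findUpstreamInSet;partition=endonet;list=anatomy/nephron",
        )
        assert [e["id"] for e in json.loads(body)] == ["kidney"]

    def test_not_found_statuses(self, service_state):
        assert get(service_state, "/nope/cls/x")[0] == 404
        assert get(service_state, "/go_regulation/cls/nope")[0] == 404
        assert get(service_state, "/go_regulation/functions/nope/searchCls/x")[0] == 404
        assert get(service_state, "/go_regulation/functions/basic/nope/x")[0] == 404

    def test_bad_arguments_are_400(self, service_state):
        assert get(service_state, "/go_regulation/functions/basic/reduceToLevel/thing")[0] == 400
        assert get(
            service_state, "/go_regulation/functions/basic/reduceToLevel;level=zero/thing"
        )[0] == 400


class TestContentNegotiation:
    def test_plain_text_one_id_per_line(self, service_state):
        status, ctype, body = get(
            service_state,
            "/cytomer_organs/functions/cytomer/organsOf/Cell_2",
            accept="text/plain",
        )
        assert (status, ctype) == (200, "text/plain")
        assert body == "Organ_1\nOrgan_2\n"

    def test_html_is_an_anchor_list(self, service_state):
        _, ctype, body = get(
            service_state,
            "/cytomer_organs/functions/cytomer/organsOf/Cell_1",
            accept="text/html",
        )
        assert ctype == "text/html"
        assert '<a href="/cytomer_organs/cls/Organ_3">' in body

    def test_default_is_json(self, service_state):
        _, ctype, _ = get(service_state, "/", accept="*/*")
        assert ctype == "application/json"


class TestStorageApi:
    def test_put_get_delete_cycle(self, service_state):
        assert route(service_state, "PUT", "/storage/lab")[0] == 201
        assert route(service_state, "PUT", "/storage/lab/genes", body="tcas1\ntcas2\n")[0] == 201
        _, _, body = route(service_state, "GET", "/storage/lab/genes", "text/plain")
        assert body == "tcas1\ntcas2\n"
        assert route(service_state, "DELETE", "/storage/lab/genes")[0] == 204
        assert route(service_state, "GET", "/storage/lab/genes")[0] == 404

    def test_duplicate_partition_is_conflict(self, service_state):
        assert route(service_state, "PUT", "/storage/endonet")[0] == 409


class TestClient:
    def test_proxy_lazy_loading_counts_requests(self, connector):
        proxy = connector.get_class("go_regulation", "negative_regulation_of_binding")
        assert connector.request_count == 0  # nothing fetched yet
        parents = proxy.parents()
        assert connector.request_count == 1
        assert [p.id for p in parents] == [
            "negative_regulation_of_molecular_function",
            "regulation_of_binding",
        ]
        assert proxy.parents() is parents  # memoized: no new request
        assert connector.request_count == 1
        assert parents[0].label == "negative regulation of molecular function"
        assert connector.request_count == 1  # label came with the entity list

    def test_proxy_equality_by_identity_tuple(self, connector):
        a = connector.get_class("go_regulation", "thing")
        b = connector.get_class("go_regulation", "thing")
        assert a == b and hash(a) == hash(b)

    def test_client_traversal_equals_library(self, connector, go_regulation):
        """Full upstream closure through proxies matches library ancestors."""
        proxy = connector.get_class("go_regulation", "regulation_of_cytokine_activity")
        seen = set()
        frontier = [proxy]
        while frontier:
            nxt = []
            for p in frontier:
                for parent in p.parents():
                    if parent.id not in seen:
                        seen.add(parent.id)
                        nxt.append(parent)
            frontier = nxt
        assert seen == go_regulation.ancestors("regulation_of_cytokine_activity")

    def test_request_budget_for_neighbourhood_walk(self, connector, go_regulation):
        """Walking k classes costs at most one request per touched subresource."""
        ids = sorted(go_regulation.classes)
        for cls_id in ids:
            connector.get_class("go_regulation", cls_id).parents()
        assert connector.request_count <= len(ids)

    def test_not_found_is_distinct_from_transport_error(self, connector):
        with pytest.raises(NotFoundError):
            connector.get_class("go_regulation", "nope").parents()

    def test_storage_methods(self, connector):
        connector.create_partition("clientside")
        connector.put_list("clientside", "l", ["a", "b"])
        assert connector.get_list("clientside", "l") == ["a", "b"]
        connector.delete_list("clientside", "l")
        with pytest.raises(NotFoundError):
            connector.get_list("clientside", "l")


class TestTransportTransparency:
    """REST results equal direct library calls on every fixture function."""

    def test_basic_functions(self, connector, go_regulation):
        assert connector.call_ids(
            "go_regulation", "basic", "searchCls", "binding"
        ) == set(search_cls(go_regulation, None, "binding"))
        remote = connector.call(
            "go_regulation", "basic", "reduceToLevel",
            "negative_regulation_of_binding", level=5,
        )
        local = reduce_to_level(go_regulation, ["negative_regulation_of_binding"], 5)
        assert {k: set(v) for k, v in remote.items()} == local
        remote_clusters = connector.call(
            "go_regulation", "basic", "reduceToClusterSize",
            ",".join(fx.GO_REGULATION_MARKED), max=2,
        )
        assert {c["representative"] for c in remote_clusters} == {
            "regulation_of_signaling", "regulation_of_protein_binding",
        }

    def test_anatomy_functions(self, connector, cytomer_organs, endonet):
        for start in cytomer_organs:
            assert connector.call_ids(
                "cytomer_organs", "cytomer", "organsOf", start
            ) == organs_of(cytomer_organs, start)
        from ontoquery.anatomy import PARTONOMY_RELATIONS
        from ontoquery import TraversalPolicy, find_in_set

        up = TraversalPolicy("upstream", PARTONOMY_RELATIONS, True)
        down = TraversalPolicy("downstream", PARTONOMY_RELATIONS, True)
        assert connector.call_ids(
            "endonet", "basic", "findUpstreamInSet", "nephron",
            partition="endonet", list="anatomy",
        ) == find_in_set(endonet, "nephron", fx.ENDONET_SET, up)
        assert connector.call_ids(
            "endonet", "basic", "findDownstreamInSet", "digestive_organ",
            ids=",".join(fx.ENDONET_SET),
        ) == find_in_set(endonet, "digestive_organ", fx.ENDONET_SET, down)

    def test_stage_functions(self, connector, tribolium):
        plugin = StagePlugin(tribolium)
        assert connector.call_ids(
            "tribolium", "tribolium", "concreteClasses"
        ) == set(plugin.concrete_classes())
        assert connector.call_ids(
            "tribolium", "tribolium", "genericClasses"
        ) == set(plugin.generic_classes())
        assert connector.call_ids(
            "tribolium", "tribolium", "findInGeneric", "antenna"
        ) == {"antenna"}
        assert connector.call_ids(
            "tribolium", "tribolium", "concreteForDevStage", "antenna", stage="larva"
        ) == plugin.concrete_for_dev_stage("antenna", "larva")


def test_http_server_end_to_end(service_state):
    """The same results arrive over a real socket."""
    server = make_service_server(service_state, "127.0.0.1", 0)
    port = server.server_address[1]
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        connector = Connector(f"http://127.0.0.1:{port}")
        assert connector.call_ids(
            "cytomer_organs", "cytomer", "organsOf", "Cell_2"
        ) == {"Organ_1", "Organ_2"}
        proxy = connector.get_class("go_regulation", "negative_regulation_of_binding")
        assert len(proxy.parents()) == 2
        with pytest.raises(NotFoundError):
            connector.get_class("go_regulation", "nope").label
    finally:
        server.shutdown()
        server.server_close()


def test_local_and_http_transports_agree(service_state):
    local = Connector(transport=LocalTransport(service_state))
    server = make_service_server(service_state, "127.0.0.1", 0)
    port = server.server_address[1]
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        remote = Connector(transport=HttpTransport(f"http://127.0.0.1:{port}"))
        path = "/tribolium/functions/tribolium/concreteForDevStage;stage=larva/antenna"
        assert local.transport.request("GET", path)[2] == remote.transport.request("GET", path)[2]
    finally:
        server.shutdown()
        server.server_close()
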