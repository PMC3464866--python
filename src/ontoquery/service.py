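"""REST façade over the semantic functions.

URL scheme (one ontology per top-level segment)::

    /                                      -> loaded ontologies and plugins
    /{ont}/cls/{id}                        -> class resource
    /{ont}/cls/{id}/parents | /children | /relations
    /{ont}/functions/{plugin}/{fn};k=v/{arg}
    /storage/{partition}                   (PUT creates, DELETE removes)
    /storage/{partition}/{list}            (PUT stores ids, GET/DELETE)

The function path segment may carry matrix parameters (``;name=value``)
which are passed to the plugin operation as keyword arguments; the segment
after the function name is its primary argument (comma-separated ids where a
list is expected).

Three representations are negotiated via the ``Accept`` header:
``application/json`` (stable schema below), ``text/plain`` (one id per
line) and ``text/html`` (a minimal anchor list).  JSON schemas:

* entity list  -> ``[{"id", "label", "href"}, ...]``
* class        -> ``{"id", "label", "annotations", "obsolete", "links"}``
* level map    -> ``{input_id: [ancestor ids]}``
* cluster list -> ``[{"representative", "members"}, ...]``

The module is deliberately framework-free: :func:`route` is a pure function
from a request to ``(status, content_type, body)``, and the WSGI wrapper
plus ``wsgiref`` server are thin shims over it, so the whole surface is
testable in-process.
"""

from __future__ import annotations

import json
from urllib.parse import quote, unquote
from wsgiref.simple_server import WSGIServer, make_server

from . import basic
from .anatomy import AnatomyPlugin
from .basic import ClusterAssignment, SearchQuery
from .errors import (
    ArgumentError,
    ConfigError,
    ConflictError,
    NotFoundError,
    OntoQueryError,
)
from .model import OntologyGraph
from .obo_io import OntologyConfig
from .stage import StagePlugin
from .store import SetStore

JSON = "application/json"
PLAIN = "text/plain"
HTML = "text/html"
_CONTENT_TYPES = (JSON, PLAIN, HTML)


class OntologyContext:
    """One served ontology: graph, config and the plugins it supports.

    The ``basic`` plugin is always available; the anatomy plugin (served as
    ``cytomer``) and the stage plugin (served as ``tribolium``) register only
    when their anchor classes exist in the ontology.
    """

    def __init__(self, graph: OntologyGraph, config: OntologyConfig | None = None):
        self.graph = graph
        self.config = config or OntologyConfig(graph.name)
        self.name = self.config.ontology_name
        self.plugins: dict[str, dict] = {"basic": self._basic_functions()}
        try:
            anatomy = AnatomyPlugin(graph)
        except ConfigError:
            pass
        else:
            self.plugins["cytomer"] = self._anatomy_functions(anatomy)
        try:
            stage = StagePlugin(graph)
        except ConfigError:
            pass
        else:
            self.plugins["tribolium"] = self._stage_functions(stage)

    # each function: callable(arg: str | None, params: dict, store) -> result
    def _basic_functions(self) -> dict:
        def search(arg, params, store):
            fields = params.get("field")
            restrict = frozenset(fields.split(",")) if fields else None
            if arg is None:
                raise ArgumentError("searchCls requires a pattern argument")
            return basic.search_cls(
                self.graph, self.config, SearchQuery(arg, restrict)
            )

        def reduce_level(arg, params, store):
            if "level" not in params:
                raise ArgumentError("reduceToLevel requires a ;level=N parameter")
            ids = _id_list(arg)
            return basic.reduce_to_level(self.graph, ids, _int(params["level"], "level"))

        def reduce_cluster(arg, params, store):
            if "max" not in params:
                raise ArgumentError("reduceToClusterSize requires a ;max=N parameter")
            ids = _id_list(arg)
            return basic.reduce_to_cluster_size(self.graph, ids, _int(params["max"], "max"))

        def in_set(direction):
            def fn(arg, params, store):
                from .anatomy import PARTONOMY_RELATIONS, find_in_set
                from .model import TraversalPolicy

                policy = TraversalPolicy(direction, PARTONOMY_RELATIONS, True)
                return sorted(
                    find_in_set(self.graph, _one_id(arg), _members_from(params, store), policy)
                )

            return fn

        return {
            "searchCls": search,
            "reduceToLevel": reduce_level,
            "reduceToClusterSize": reduce_cluster,
            # set search needs only the hierarchy plus partonomy relations,
            # so it is available for every ontology, anchored plugin or not
            "findUpstreamInSet": in_set("upstream"),
            "findDownstreamInSet": in_set("downstream"),
        }

    def _anatomy_functions(self, plugin: AnatomyPlugin) -> dict:
        members_from = _members_from
        fns = {}
        if "organs" in plugin.policies:
            fns["organsOf"] = lambda arg, params, store: sorted(
                plugin.organs_of(_one_id(arg))
            )
        if "systems" in plugin.policies:
            fns["physiologicalSystemsOf"] = lambda arg, params, store: sorted(
                plugin.physiological_systems_of(_one_id(arg))
            )
        fns["findUpstreamInSet"] = lambda arg, params, store: sorted(
            plugin.find_upstream_in_set(_one_id(arg), members_from(params, store))
        )
        fns["findDownstreamInSet"] = lambda arg, params, store: sorted(
            plugin.find_downstream_in_set(_one_id(arg), members_from(params, store))
        )
        return fns

    def _stage_functions(self, plugin: StagePlugin) -> dict:
        def for_stage(arg, params, store):
            if "stage" not in params:
                raise ArgumentError("concreteForDevStage requires a ;stage=S parameter")
            return sorted(plugin.concrete_for_dev_stage(_one_id(arg), params["stage"]))

        return {
            "concreteClasses": lambda arg, params, store: sorted(plugin.concrete_classes()),
            "genericClasses": lambda arg, params, store: sorted(plugin.generic_classes()),
            "findInGeneric": lambda arg, params, store: plugin.find_in_generic(_one_id(arg)),
            "concreteForDevStage": for_stage,
        }


def _members_from(params: dict, store: SetStore | None) -> list[str]:
    if "ids" in params:
        return params["ids"].split(",")
    if "partition" in params and "list" in params:
        if store is None:
            raise ArgumentError("no storage configured on this server")
        return store.get_list(params["partition"], params["list"])
    raise ArgumentError(
        "set search requires ;ids=a,b or ;partition=P;list=L parameters"
    )


def _one_id(arg: str | None) -> str:
    if not arg:
        raise ArgumentError("this function requires a path argument")
    return arg


def _id_list(arg: str | None) -> list[str]:
    if not arg:
        raise ArgumentError("this function requires comma-separated class ids")
    return arg.split(",")


def _int(value: str, name: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ArgumentError(f"parameter {name!r} must be an integer, got {value!r}") from None


class ServiceState:
    """Everything one server instance holds: ontologies and the set store."""

    def __init__(self, store: SetStore | None = None):
        self.ontologies: dict[str, OntologyContext] = {}
        self.store = store

    def add_ontology(
        self, graph: OntologyGraph, config: OntologyConfig | None = None
    ) -> OntologyContext:
        ctx = OntologyContext(graph, config)
        self.ontologies[ctx.name] = ctx
        return ctx

    def context(self, name: str) -> OntologyContext:
        if name not in self.ontologies:
            raise NotFoundError(f"unknown ontology: {name!r}")
        return self.ontologies[name]


# -- request handling --------------------------------------------------------


def _negotiate(accept: str | None) -> str:
    if not accept or accept == "*/*":
        return JSON
    for ctype in _CONTENT_TYPES:
        if ctype in accept:
            return ctype
    return JSON


def _split_matrix(segment: str) -> tuple[str, dict[str, str]]:
    parts = segment.split(";")
    params: dict[str, str] = {}
    for p in parts[1:]:
        if "=" not in p:
            raise ArgumentError(f"malformed matrix parameter: {p!r}")
        key, value = p.split("=", 1)
        params[key] = value
    return parts[0], params


def _entity(ctx: OntologyContext, cls_id: str) -> dict:
    cls = ctx.graph.get(cls_id)
    return {
        "id": cls.id,
        "label": cls.label,
        "href": f"/{quote(ctx.name, safe='')}/cls/{quote(cls.id, safe='')}",
    }


def _render(result, ctx: OntologyContext | None, ctype: str) -> str:
    """Serialize a plugin/library result in the negotiated representation."""
    if isinstance(result, dict) and not isinstance(result, list):
        # level map: input -> ancestor set
        mapping = {k: sorted(v) for k, v in sorted(result.items())}
        if ctype == JSON:
            return json.dumps(mapping, indent=1)
        ids = sorted({a for v in mapping.values() for a in v})
        if ctype == PLAIN:
            return "\n".join(ids) + ("\n" if ids else "")
        return _html_list(ctx, ids)
    if result and isinstance(result, list) and isinstance(result[0], ClusterAssignment):
        if ctype == JSON:
            return json.dumps(
                [{"representative": c.representative, "members": c.members} for c in result],
                indent=1,
            )
        reps = [c.representative for c in result]
        if ctype == PLAIN:
            return "\n".join(reps) + "\n"
        return _html_list(ctx, reps)
    ids = sorted(result)
    if ctype == JSON:
        if ctx is not None:
            return json.dumps([_entity(ctx, i) if i in ctx.graph else {"id": i} for i in ids], indent=1)
        return json.dumps(ids, indent=1)
    if ctype == PLAIN:
        return "\n".join(ids) + ("\n" if ids else "")
    return _html_list(ctx, ids)


def _html_list(ctx: OntologyContext | None, ids: list[str]) -> str:
    items = []
    for i in ids:
        if ctx is not None and i in ctx.graph:
            ent = _entity(ctx, i)
            items.append(f'<li><a href="{ent["href"]}">{ent["label"]}</a></li>')
        else:
            items.append(f"<li>{i}</li>")
    return "<ul>\n" + "\n".join(items) + "\n</ul>\n"


def route(
    state: ServiceState,
    method: str,
    path: str,
    accept: str | None = JSON,
    body: str | None = None,
) -> tuple[int, str, str]:
    """Dispatch one request; returns ``(status, content_type, body)``."""
    ctype = _negotiate(accept)
    try:
        return _route(state, method.upper(), path, ctype, body)
    except ConflictError as exc:
        return 409, PLAIN, f"{exc}\n"
    except NotFoundError as exc:
        return 404, PLAIN, f"{exc}\n"
    except (ArgumentError, OntoQueryError) as exc:
        return 400, PLAIN, f"{exc}\n"


def _route(state, method, path, ctype, body) -> tuple[int, str, str]:
    segments = [unquote(s) for s in path.strip("/").split("/")] if path.strip("/") else []
    if not segments:
        index = {
            "ontologies": {
                name: sorted(ctx.plugins) for name, ctx in sorted(state.ontologies.items())
            }
        }
        return 200, JSON, json.dumps(index, indent=1)

    if segments[0] == "storage":
        return _route_storage(state, method, segments[1:], ctype, body)

    if method != "GET":
        return 405, PLAIN, "only GET is supported outside /storage\n"
    ctx = state.context(segments[0])
    if len(segments) < 2:
        return 200, JSON, json.dumps({"name": ctx.name, "plugins": {
            p: sorted(fns) for p, fns in sorted(ctx.plugins.items())
        }}, indent=1)

    if segments[1] == "cls":
        return _route_cls(ctx, segments[2:], ctype)
    if segments[1] == "functions":
        return _route_function(state, ctx, segments[2:], ctype)
    raise NotFoundError(f"unknown resource kind: {segments[1]!r}")


def _route_cls(ctx: OntologyContext, segments: list[str], ctype: str) -> tuple[int, str, str]:
    if not segments:
        raise ArgumentError("missing class id")
    cls = ctx.graph.get(segments[0])
    if len(segments) == 1:
        if ctype == PLAIN:
            return 200, PLAIN, cls.id + "\n"
        if ctype == HTML:
            return 200, HTML, _html_list(ctx, [cls.id])
        doc = {
            "id": cls.id,
            "label": cls.label,
            "annotations": cls.annotations,
            "obsolete": cls.obsolete,
            "links": {
                sub: _entity(ctx, cls.id)["href"] + f"/{sub}"
                for sub in ("parents", "children", "relations")
            },
        }
        return 200, JSON, json.dumps(doc, indent=1)
    sub = segments[1]
    if sub == "parents":
        return 200, ctype, _render(ctx.graph.parents(cls.id), ctx, ctype)
    if sub == "children":
        return 200, ctype, _render(ctx.graph.children(cls.id), ctx, ctype)
    if sub == "relations":
        edges = ctx.graph.relations_of(cls.id, "upstream") + ctx.graph.relations_of(
            cls.id, "downstream"
        )
        doc = [
            {"relation": e.relation, "source": e.source, "target": e.target}
            for e in sorted(set(edges))
        ]
        if ctype == JSON:
            return 200, JSON, json.dumps(doc, indent=1)
        lines = [f"{e['relation']}\t{e['source']}\t{e['target']}" for e in doc]
        return 200, PLAIN, "\n".join(lines) + ("\n" if lines else "")
    raise NotFoundError(f"unknown class subresource: {sub!r}")


def _route_function(state, ctx, segments, ctype) -> tuple[int, str, str]:
    if len(segments) < 2:
        raise ArgumentError("expected /functions/{plugin}/{function}[/{argument}]")
    plugin_name = segments[0]
    if plugin_name not in ctx.plugins:
        raise NotFoundError(
            f"ontology {ctx.name!r} has no plugin {plugin_name!r}"
        )
    fn_name, params = _split_matrix(segments[1])
    fns = ctx.plugins[plugin_name]
    if fn_name not in fns:
        raise NotFoundError(f"plugin {plugin_name!r} has no function {fn_name!r}")
    arg = segments[2] if len(segments) > 2 else None
    result = fns[fn_name](arg, params, state.store)
    return 200, ctype, _render(result, ctx, ctype)


def _route_storage(state, method, segments, ctype, body) -> tuple[int, str, str]:
    store = state.store
    if store is None:
        raise NotFoundError("this server has no storage configured")
    if not segments:
        return 200, JSON, json.dumps(store.partitions(), indent=1)
    partition = segments[0]
    if len(segments) == 1:
        if method == "PUT":
            store.create_partition(partition)
            return 201, PLAIN, f"created partition {partition}\n"
        if method == "DELETE":
            store.delete_partition(partition)
            return 204, PLAIN, ""
        if method == "GET":
            return 200, JSON, json.dumps(store.lists(partition), indent=1)
        return 405, PLAIN, "unsupported method\n"
    list_name = segments[1]
    if method == "PUT":
        ids = _parse_ids_body(body)
        store.put_list(partition, list_name, ids)
        return 201, PLAIN, f"stored {len(ids)} ids in {partition}/{list_name}\n"
    if method == "GET":
        ids = store.get_list(partition, list_name)
        if ctype == PLAIN:
            return 200, PLAIN, "\n".join(ids) + ("\n" if ids else "")
        return 200, JSON, json.dumps(ids, indent=1)
    if method == "DELETE":
        store.delete_list(partition, list_name)
        return 204, PLAIN, ""
    return 405, PLAIN, "unsupported method\n"


def _parse_ids_body(body: str | None) -> list[str]:
    if body is None:
        raise ArgumentError("PUT of a list requires a body")
    stripped = body.strip()
    if stripped.startswith("["):
        ids = json.loads(stripped)
        if not isinstance(ids, list) or not all(isinstance(i, str) for i in ids):
            raise ArgumentError("JSON body must be an array of id strings")
        return ids
    return [line.strip() for line in body.splitlines() if line.strip()]


# -- WSGI / server -----------------------------------------------------------


def wsgi_app(state: ServiceState):
    """A WSGI callable serving :func:`route`."""

    def app(environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        accept = environ.get("HTTP_ACCEPT")
        body = None
        if method in ("PUT", "POST"):
            length = int(environ.get("CONTENT_LENGTH") or 0)
            body = environ["wsgi.input"].read(length).decode("utf-8")
        status, ctype, payload = route(state, method, path, accept, body)
        reason = {200: "OK", 201: "Created", 204: "No Content", 400: "Bad Request",
                  404: "Not Found", 405: "Method Not Allowed", 409: "Conflict"}
        data = payload.encode("utf-8")
        start_response(
            f"{status} {reason.get(status, '')}".strip(),
            [("Content-Type", f"{ctype}; charset=utf-8"),
             ("Content-Length", str(len(data)))],
        )
        return [data]

    return app


def make_service_server(state: ServiceState, host: str = "127.0.0.1", port: int = 8080) -> WSGIServer:
    """Build (but do not start) a wsgiref HTTP server for *state*."""
    return make_server(host, port, wsgi_app(state))


def serve(state: ServiceState, host: str = "127.0.0.1", port: int = 8080) -> None:
    """Serve forever (CLI entry point)."""
    with make_service_server(state, host, port) as httpd:
        httpd.serve_forever()
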