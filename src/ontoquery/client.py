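"""Native client for the REST service with lazy-loading class proxies.

A :class:`Connector` talks to a server through a pluggable transport — HTTP
via ``urllib`` by default, or an in-process transport that calls the
dispatcher directly (useful for tests and for embedding client code without
a socket).  Ontology classes come back as :class:`ClassProxy` objects that
fetch their subresources (label/annotations, parents, children, relations)
on first access and memoize them, so traversing the neighbourhood of a class
costs at most one request per subresource and network access stays
transparent to the application.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
from urllib.parse import quote

from .errors import NotFoundError, OntoQueryError, TransportError
from .service import JSON, ServiceState, route


class HttpTransport:
    """Talk to a remote server over HTTP."""

    def __init__(self, base_url: str):
        self.base_url = base_url.rstrip("/")

    def request(self, method: str, path: str, accept: str = JSON, body: str | None = None):
        req = urllib.request.Request(
            self.base_url + path,
            method=method,
            data=body.encode("utf-8") if body is not None else None,
            headers={"Accept": accept},
        )
        try:
            with urllib.request.urlopen(req) as resp:
                return resp.status, resp.headers.get_content_type(), resp.read().decode("utf-8")
        except urllib.error.HTTPError as exc:
            return exc.code, exc.headers.get_content_type(), exc.read().decode("utf-8")
        except urllib.error.URLError as exc:
            raise TransportError(f"cannot reach {self.base_url}: {exc.reason}") from exc


class LocalTransport:
    """Call the request dispatcher in-process (no sockets)."""

    def __init__(self, state: ServiceState):
        self.state = state

    def request(self, method: str, path: str, accept: str = JSON, body: str | None = None):
        return route(self.state, method, path, accept, body)


class Connector:
    """Entry point for client code; counts requests for instrumentation."""

    def __init__(self, base_url: str | None = None, transport=None):
        if transport is None:
            if base_url is None:
                raise OntoQueryError("Connector needs a base_url or a transport")
            transport = HttpTransport(base_url)
        self.transport = transport
        self.request_count = 0

    def _request(self, method: str, path: str, accept: str = JSON, body: str | None = None):
        self.request_count += 1
        status, ctype, payload = self.transport.request(method, path, accept, body)
        if status == 404:
            raise NotFoundError(payload.strip())
        if status >= 400:
            raise OntoQueryError(f"server returned {status}: {payload.strip()}")
        return payload

    def _get_json(self, path: str):
        return json.loads(self._request("GET", path, JSON))

    # -- classes -------------------------------------------------------------

    def get_class(self, ontology: str, cls_id: str) -> "ClassProxy":
        return ClassProxy(self, ontology, cls_id)

    # -- functions -----------------------------------------------------------

    def call(self, ontology: str, plugin: str, function: str, arg: str | None = None, **params):
        """Invoke a semantic function; returns the parsed JSON result."""
        fn = quote(function, safe="")
        for key, value in sorted(params.items()):
            fn += f";{quote(key, safe='')}={quote(str(value), safe=',')}"
        path = f"/{quote(ontology, safe='')}/functions/{quote(plugin, safe='')}/{fn}"
        if arg is not None:
            path += f"/{quote(arg, safe=',')}"
        return self._get_json(path)

    def call_ids(self, ontology, plugin, function, arg=None, **params) -> set[str]:
        """Like :meth:`call` but flattens any result shape to the set of ids."""
        result = self.call(ontology, plugin, function, arg, **params)
        if isinstance(result, dict):  # level map
            return {a for v in result.values() for a in v}
        out: set[str] = set()
        for item in result:
            if isinstance(item, str):
                out.add(item)
            elif "representative" in item:
                out.add(item["representative"])
            else:
                out.add(item["id"])
        return out

    def call_proxies(self, ontology, plugin, function, arg=None, **params) -> list["ClassProxy"]:
        result = self.call(ontology, plugin, function, arg, **params)
        proxies = []
        for item in result:
            if isinstance(item, dict) and "id" in item:
                proxies.append(ClassProxy(self, ontology, item["id"], label=item.get("label")))
        return proxies

    # -- storage -------------------------------------------------------------

    def create_partition(self, name: str) -> None:
        self._request("PUT", f"/storage/{quote(name, safe='')}")

    def put_list(self, partition: str, list_name: str, ids: list[str]) -> None:
        self._request(
            "PUT",
            f"/storage/{quote(partition, safe='')}/{quote(list_name, safe='')}",
            body=json.dumps(list(ids)),
        )

    def get_list(self, partition: str, list_name: str) -> list[str]:
        return json.loads(
            self._request("GET", f"/storage/{quote(partition, safe='')}/{quote(list_name, safe='')}")
        )

    def delete_list(self, partition: str, list_name: str) -> None:
        self._request(
            "DELETE", f"/storage/{quote(partition, safe='')}/{quote(list_name, safe='')}"
        )


class ClassProxy:
    """Lazy remote ontology class; each subresource is fetched at most once."""

    def __init__(self, connector: Connector, ontology: str, cls_id: str, label: str | None = None):
        self._connector = connector
        self.ontology = ontology
        self.id = cls_id
        self._label = label
        self._core: dict | None = None
        self._parents: list[ClassProxy] | None = None
        self._children: list[ClassProxy] | None = None
        self._relations: list[dict] | None = None

    @property
    def _path(self) -> str:
        return f"/{quote(self.ontology, safe='')}/cls/{quote(self.id, safe='')}"

    def _load_core(self) -> dict:
        if self._core is None:
            self._core = self._connector._get_json(self._path)
            self._label = self._core["label"]
        return self._core

    @property
    def label(self) -> str:
        if self._label is None:
            self._load_core()
        return self._label

    @property
    def annotations(self) -> dict[str, list[str]]:
        return self._load_core()["annotations"]

    @property
    def obsolete(self) -> bool:
        return self._load_core()["obsolete"]

    def _entity_list(self, sub: str) -> list["ClassProxy"]:
        entities = self._connector._get_json(f"{self._path}/{sub}")
        return [
            ClassProxy(self._connector, self.ontology, e["id"], label=e.get("label"))
            for e in entities
        ]

    def parents(self) -> list["ClassProxy"]:
        if self._parents is None:
            self._parents = self._entity_list("parents")
        return self._parents

    def children(self) -> list["ClassProxy"]:
        if self._children is None:
            self._children = self._entity_list("children")
        return self._children

    def _relation_edges(self) -> list[dict]:
        if self._relations is None:
            self._relations = self._connector._get_json(f"{self._path}/relations")
        return self._relations

    def relation(self, name: str, direction: str = "upstream") -> list["ClassProxy"]:
        """Classes linked to this one by the named relation (memoized fetch)."""
        edges = self._relation_edges()
        if direction == "upstream":
            ids = sorted({e["target"] for e in edges if e["relation"] == name and e["source"] == self.id})
        else:
            ids = sorted({e["source"] for e in edges if e["relation"] == name and e["target"] == self.id})
        return [ClassProxy(self._connector, self.ontology, i) for i in ids]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClassProxy):
            return NotImplemented
        return (self.ontology, self.id) == (other.ontology, other.id)

    def __hash__(self) -> int:
        return hash((self.ontology, self.id))

    def __repr__(self) -> str:
        return f"<ClassProxy {self.ontology}/{self.id}>"
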