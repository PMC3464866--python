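"""Reading and writing OBO 1.2 flat files and per-ontology config files.

The reader gives structure only to the tags the semantic functions need
(``id``, ``name``, ``is_a``, ``relationship``, ``is_obsolete``); every other
tag line lands verbatim in the class's annotation mapping under its tag name,
so field-restricted search can cover arbitrary annotation fields.  Dangling
``is_a``/``relationship`` targets are dropped with a logged warning — real
ontology exports are imperfect and a hard failure would make them unloadable.

The config ("property") file that accompanies an ontology is plain
``key=value`` text naming the ontology and the annotation fields to index::

    name=cytomer
    file=cytomer.obo
    indexed_fields=definitionEnglish,synonym
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, ParseError
from .model import OntologyClass, OntologyGraph

logger = logging.getLogger(__name__)

# tags handled structurally; everything else passes through as an annotation
_STRUCTURAL_TAGS = {"id", "name", "is_a", "relationship", "is_obsolete"}


@dataclass
class OntologyConfig:
    """Per-ontology server configuration.

    ``ontology_name`` is the URL segment the ontology is served under;
    ``indexed_fields`` are the annotation fields included in unrestricted
    search (the class label is always searched).
    """

    ontology_name: str
    indexed_fields: list[str] = field(default_factory=list)
    file_path: str | None = None

    def __post_init__(self) -> None:
        if not self.ontology_name or "/" in self.ontology_name:
            raise ConfigError(f"invalid ontology name: {self.ontology_name!r}")


def _strip_comment(value: str) -> str:
    # OBO trailing comments: "is_a: GO:0008150 ! biological_process"
    return value.split(" ! ", 1)[0].strip()


def read_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    One class per ``[Term]`` stanza.  ``is_a`` lines become hierarchy edges,
    ``relationship: <rel> <id>`` lines become typed relation edges, unknown
    tags become annotations.  Obsolete classes are loaded but stripped of
    outgoing edges.  No virtual root is added — see
    :func:`ontoquery.model.add_virtual_root`.

    Raises :class:`ParseError` (with line number) on a stanza without an id.
    """
    path = Path(path)
    name = path.stem
    graph = OntologyGraph(name)

    is_a_lines: list[tuple[str, str, int]] = []  # child, parent, line no
    rel_lines: list[tuple[str, str, str, int]] = []  # source, rel, target, line no
    typedefs: set[str] = set()

    stanza_type: str | None = None
    stanza_start = 0
    current: dict[str, list[str]] | None = None

    def flush() -> None:
        nonlocal current
        if stanza_type != "Term" or current is None:
            if stanza_type == "Typedef" and current and "id" in current:
                typedefs.add(current["id"][0])
            current = None
            return
        if "id" not in current:
            raise ParseError("[Term] stanza without an id tag", stanza_start)
        cls_id = current.pop("id")[0]
        label = current.pop("name", [cls_id])[0]
        obsolete = current.pop("is_obsolete", ["false"])[0].lower() == "true"
        is_a = current.pop("is_a", [])
        rels = current.pop("relationship", [])
        cls = OntologyClass(cls_id, label, annotations=dict(current), obsolete=obsolete)
        graph.add_class(cls)
        if not obsolete:  # obsolete classes carry no outgoing edges
            for parent in is_a:
                is_a_lines.append((cls_id, parent, stanza_start))
            for rel_line in rels:
                parts = rel_line.split(None, 1)
                if len(parts) != 2:
                    raise ParseError(
                        f"malformed relationship line: {rel_line!r}", stanza_start
                    )
                rel, target = parts
                rel_lines.append((cls_id, rel, target.strip(), stanza_start))
        current = None

    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("["):
                flush()
                stanza_type = line.strip("[]").strip()
                stanza_start = lineno
                current = {}
                continue
            if not line.strip() or line.lstrip().startswith("!"):
                continue
            if current is None:
                # header line; pick up the ontology name if declared
                if line.startswith("ontology:"):
                    graph.name = line.split(":", 1)[1].strip()
                continue
            if ":" not in line:
                raise ParseError(f"malformed tag line: {line!r}", lineno)
            tag, value = line.split(":", 1)
            current.setdefault(tag.strip(), []).append(_strip_comment(value))
        flush()

    for child, parent, lineno in is_a_lines:
        if parent not in graph:
            logger.warning(
                "%s:%d: dropping is_a edge %s -> %s (unknown target)",
                path.name, lineno, child, parent,
            )
            continue
        graph.add_is_a(child, parent)
    for source, rel, target, lineno in rel_lines:
        if target not in graph:
            logger.warning(
                "%s:%d: dropping relationship %s %s %s (unknown target)",
                path.name, lineno, source, rel, target,
            )
            continue
        graph.add_relation(source, target, rel)
    graph.check_acyclic()
    return graph


def write_obo(graph: OntologyGraph, path: str | Path) -> None:
    """Serialize *graph* as an OBO 1.2 flat file (terms sorted by id).

    A ``[Typedef]`` stanza is emitted for every relation name in use so the
    output is self-contained.  ``read_obo(write_obo(g))`` reproduces ``g``.
    """
    path = Path(path)
    lines = ["format-version: 1.2", f"ontology: {graph.name}"]
    for cls_id in sorted(graph.classes):
        cls = graph.classes[cls_id]
        lines += ["", "[Term]", f"id: {cls.id}"]
        lines.append(f"name: {cls.label}")
        for tag in sorted(cls.annotations):
            for value in cls.annotations[tag]:
                lines.append(f"{tag}: {value}")
        if cls.obsolete:
            lines.append("is_obsolete: true")
        for parent in graph.parents(cls_id):
            lines.append(f"is_a: {parent}")
        for edge in graph.relations_of(cls_id, "upstream"):
            lines.append(f"relationship: {edge.relation} {edge.target}")
    for rel in sorted(graph.relation_names()):
        lines += ["", "[Typedef]", f"id: {rel}", f"name: {rel}"]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_config(path: str | Path) -> OntologyConfig:
    """Read a ``key=value`` ontology property file.

    Mandatory key: ``name``.  Optional: ``file`` (OBO path, resolved relative
    to the config file), ``indexed_fields`` (comma-separated, may be empty).
    """
    path = Path(path)
    values: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"expected key=value, got {line!r}", lineno)
        key, value = line.split("=", 1)
        values[key.strip()] = value.strip()
    if "name" not in values:
        raise ConfigError(f"{path}: missing mandatory key 'name'")
    fields = [f.strip() for f in values.get("indexed_fields", "").split(",") if f.strip()]
    file_path = values.get("file")
    if file_path is not None and not Path(file_path).is_absolute():
        file_path = str(path.parent / file_path)
    return OntologyConfig(values["name"], indexed_fields=fields, file_path=file_path)
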