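"""Persistent named lists of class ids, grouped into partitions.

A project uploads the vocabulary it actually uses (e.g. the anatomical
structures annotated in its database) once, then refers to it by
``partition/list`` name in every query.  Partitions are only reachable
through their assigned name, which provides basic access control; one JSON
document per partition on disk keeps the store trivially inspectable and
restart-safe.

Ids are not validated against any ontology at storage time — a list may be
uploaded before its ontology is loaded; validation happens when the list is
used in a query.
"""

from __future__ import annotations

import json
import re
import time
from pathlib import Path

from .errors import ArgumentError, ConflictError, ListNotFoundError, PartitionNotFoundError

_NAME_RE = re.compile(r"^[A-Za-z0-9_.-]+$")


def _check_name(name: str, what: str) -> None:
    if not _NAME_RE.match(name):
        raise ArgumentError(
            f"invalid {what} name {name!r}: use letters, digits, '_', '-', '.'"
        )


class SetStore:
    """Flat-file store of named class-id lists under a directory."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, partition: str) -> Path:
        return self.directory / f"{partition}.json"

    def _load(self, partition: str) -> dict:
        path = self._path(partition)
        if not path.exists():
            raise PartitionNotFoundError(f"unknown partition: {partition!r}")
        return json.loads(path.read_text(encoding="utf-8"))

    def _save(self, partition: str, doc: dict) -> None:
        self._path(partition).write_text(
            json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8"
        )

    # -- partitions ----------------------------------------------------------

    def create_partition(self, name: str) -> None:
        _check_name(name, "partition")
        if self._path(name).exists():
            raise ConflictError(f"partition already exists: {name!r}")
        self._save(name, {"partition_name": name, "created_at": time.time(), "lists": {}})

    def has_partition(self, name: str) -> bool:
        return self._path(name).exists()

    def partitions(self) -> list[str]:
        return sorted(p.stem for p in self.directory.glob("*.json"))

    def delete_partition(self, name: str) -> None:
        path = self._path(name)
        if not path.exists():
            raise PartitionNotFoundError(f"unknown partition: {name!r}")
        path.unlink()

    # -- lists ---------------------------------------------------------------

    def put_list(self, partition: str, list_name: str, ids: list[str]) -> None:
        """Store *ids* (order and duplicates preserved) under partition/list."""
        _check_name(list_name, "list")
        doc = self._load(partition)
        doc["lists"][list_name] = list(ids)
        self._save(partition, doc)

    def get_list(self, partition: str, list_name: str) -> list[str]:
        doc = self._load(partition)
        if list_name not in doc["lists"]:
            raise ListNotFoundError(
                f"unknown list {list_name!r} in partition {partition!r}"
            )
        return list(doc["lists"][list_name])

    def delete_list(self, partition: str, list_name: str) -> None:
        doc = self._load(partition)
        if list_name not in doc["lists"]:
            raise ListNotFoundError(
                f"unknown list {list_name!r} in partition {partition!r}"
            )
        del doc["lists"][list_name]
        self._save(partition, doc)

    def lists(self, partition: str) -> list[str]:
        return sorted(self._load(partition)["lists"])
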