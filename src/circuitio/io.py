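"""Serialization of circuits: CSV type tables and HDF5 instance tables.

On-disk layout
--------------
Type tables are space-separated CSV with a single header line; fields
containing spaces are double-quoted and the token ``NONE`` renders an
absent value.

Node files place each population under ``/nodes/<name>/`` with integer
datasets ``node_id``, ``node_type_id``, ``node_group_id`` and
``node_group_index``, and per-group attribute datasets under
``/nodes/<name>/<group_id>/``.  Edge files mirror this under
``/edges/<name>/`` with ``source_node_id``, ``target_node_id``,
``edge_type_id``, ``edge_group_id`` and ``edge_group_index``; the
source/target node-population names are stored as a ``node_population``
attribute on the respective id datasets.  Optional range indices live
under ``/edges/<name>/indices/{target_to_source,source_to_target}``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import IO, Any, Iterable

import h5py
import numpy as np

from .model import (
    Circuit,
    CircuitError,
    EdgeGroup,
    EdgePopulation,
    NodeGroup,
    NodePopulation,
    RangeIndex,
    TypeTable,
    NULL_TOKEN,
)

#: Default HDF5 chunk length for 1-D instance-table datasets.
DEFAULT_CHUNK = 1 << 16

_INDEX_GROUP = {"by_target": "target_to_source", "by_source": "source_to_target"}
_INDEX_COLUMN = {"by_target": "target_node_id", "by_source": "source_node_id"}


class FormatError(CircuitError):
    """A file violates the expected on-disk structure."""


# ---------------------------------------------------------------------------
# CSV type tables
# ---------------------------------------------------------------------------

def _parse_scalar(text: str) -> Any:
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    return text


def _format_scalar(value: Any) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_type_table(source: str | os.PathLike | IO[str], role: str) -> TypeTable:
    """Read a space-separated CSV type table.

    ``source`` may be a path or an open text stream.  Numeric-looking
    fields are parsed as int then float; the token ``NONE`` marks an
    absent value and is dropped from the row.  Raises
    :class:`FormatError` on a missing id column, ragged rows, or
    duplicate type ids.
    """
    if hasattr(source, "read"):
        return _read_type_table_stream(source, role)  # type: ignore[arg-type]
    with open(source, "r", newline="") as fh:
        return _read_type_table_stream(fh, role)


def _read_type_table_stream(stream: IO[str], role: str) -> TypeTable:
    table = TypeTable(role=role)
    reader = csv.reader(stream, delimiter=" ", quotechar='"')
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError("type table has no header line") from None
    id_column = table.id_column
    if id_column not in header:
        raise FormatError(f"type table header lacks {id_column!r} column")
    id_pos = header.index(id_column)
    table.columns = [name for name in header if name != id_column]
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(
                f"ragged row at line {lineno}: expected {len(header)} fields, "
                f"got {len(row)}"
            )
        try:
            type_id = int(row[id_pos])
        except ValueError:
            raise FormatError(f"non-integer {id_column} at line {lineno}") from None
        if type_id in table.rows:
            raise FormatError(f"duplicate {id_column} {type_id} at line {lineno}")
        attrs = {}
        for name, text in zip(header, row):
            if name == id_column or text == NULL_TOKEN:
                continue
            attrs[name] = _parse_scalar(text)
        table.rows[type_id] = attrs
    return table


def write_type_table(table: TypeTable, target: str | os.PathLike | IO[str]) -> None:
    """Write ``table`` as space-separated CSV (absent values as ``NONE``)."""
    if hasattr(target, "write"):
        _write_type_table_stream(table, target)  # type: ignore[arg-type]
        return
    with open(target, "w", newline="") as fh:
        _write_type_table_stream(table, fh)


def _write_type_table_stream(table: TypeTable, stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter=" ", quotechar='"', lineterminator="\n")
    writer.writerow([table.id_column] + list(table.columns))
    for type_id, attrs in table.rows.items():
        row = [str(type_id)]
        for name in table.columns:
            if name in attrs:
                row.append(_format_scalar(attrs[name]))
            else:
                row.append(NULL_TOKEN)
        writer.writerow(row)


# ---------------------------------------------------------------------------
# HDF5 helpers
# ---------------------------------------------------------------------------

def _write_column(parent: h5py.Group, name: str, values: np.ndarray) -> h5py.Dataset:
    values = np.asarray(values)
    if values.dtype.kind in ("U", "O"):
        data = np.asarray([str(v) for v in values], dtype=object)
        dtype = h5py.string_dtype(encoding="utf-8")
        chunks = (min(DEFAULT_CHUNK, len(data)),) if len(data) else None
        return parent.create_dataset(name, data=data, dtype=dtype, chunks=chunks)
    chunks = (min(DEFAULT_CHUNK, len(values)),) if len(values) else None
    return parent.create_dataset(name, data=values, chunks=chunks)


def _read_column(ds: h5py.Dataset) -> np.ndarray:
    if h5py.check_string_dtype(ds.dtype):
        return ds.asstr()[...]
    return ds[...]


# ---------------------------------------------------------------------------
# Node files
# ---------------------------------------------------------------------------

def write_nodes(populations: Iterable[NodePopulation], path: str | os.PathLike) -> None:
    """Write node populations to an HDF5 file (overwrites ``path``)."""
    with h5py.File(path, "w") as fh:
        root = fh.create_group("nodes")
        for pop in populations:
            grp = root.create_group(pop.name)
            _write_column(grp, "node_id", pop.node_id)
            _write_column(grp, "node_type_id", pop.node_type_id)
            _write_column(grp, "node_group_id", pop.group_id)
            _write_column(grp, "node_group_index", pop.group_index)
            for gid, group in sorted(pop.groups.items()):
                ggrp = grp.create_group(str(gid))
                ggrp.attrs["size"] = group.size
                for name, col in group.attributes.items():
                    _write_column(ggrp, name, col)


def read_nodes(path: str | os.PathLike) -> list[NodePopulation]:
    """Read all node populations from an HDF5 file."""
    populations = []
    with h5py.File(path, "r") as fh:
        if "nodes" not in fh:
            raise FormatError(f"{path}: missing /nodes root group")
        root = fh["nodes"]
        for name in sorted(root):
            grp = root[name]
            if "node_type_id" not in grp:
                raise FormatError(f"{path}: population {name!r} lacks node_type_id")
            node_type_id = grp["node_type_id"][...]
            n = len(node_type_id)
            if "node_id" in grp:
                node_id = grp["node_id"][...]
            else:
                node_id = np.arange(n, dtype=np.int64)
            group_id = (
                grp["node_group_id"][...]
                if "node_group_id" in grp
                else np.zeros(n, dtype=np.int64)
            )
            group_index = (
                grp["node_group_index"][...]
                if "node_group_index" in grp
                else np.arange(n, dtype=np.int64)
            )
            for col_name, col in (
                ("node_id", node_id),
                ("node_group_id", group_id),
                ("node_group_index", group_index),
            ):
                if len(col) != n:
                    raise FormatError(
                        f"{path}: column {col_name} of population {name!r} has "
                        f"length {len(col)} != {n}"
                    )
            groups = _read_groups(grp, group_id, group_index, path, name)
            populations.append(
                NodePopulation(
                    name=name,
                    node_id=node_id,
                    node_type_id=node_type_id,
                    group_id=group_id,
                    group_index=group_index,
                    groups=groups,
                )
            )
    return populations


def _read_groups(
    grp: h5py.Group,
    group_id: np.ndarray,
    group_index: np.ndarray,
    path: Any,
    pop_name: str,
) -> dict[int, NodeGroup]:
    groups: dict[int, NodeGroup] = {}
    for key in grp:
        if not key.lstrip("-").isdigit():
            continue
        gid = int(key)
        ggrp = grp[key]
        attributes = {name: _read_column(ggrp[name]) for name in ggrp}
        size = int(ggrp.attrs.get("size", -1))
        if size < 0:
            members = group_index[group_id == gid]
            size = int(members.max()) + 1 if members.size else 0
            if attributes:
                size = len(next(iter(attributes.values())))
        groups[gid] = NodeGroup(group_id=gid, attributes=attributes, size=size)
    for gid in np.unique(group_id):
        if int(gid) not in groups:
            raise FormatError(
                f"{path}: population {pop_name!r} references unknown group {gid}"
            )
    return groups


# ---------------------------------------------------------------------------
# Edge files
# ---------------------------------------------------------------------------

def write_edges(populations: Iterable[EdgePopulation], path: str | os.PathLike) -> None:
    """Write edge populations (and any attached indices) to an HDF5 file."""
    with h5py.File(path, "w") as fh:
        root = fh.create_group("edges")
        for pop in populations:
            grp = root.create_group(pop.name)
            src = _write_column(grp, "source_node_id", pop.source_node_id)
            src.attrs["node_population"] = pop.source_population
            tgt = _write_column(grp, "target_node_id", pop.target_node_id)
            tgt.attrs["node_population"] = pop.target_population
            _write_column(grp, "edge_type_id", pop.edge_type_id)
            _write_column(grp, "edge_group_id", pop.group_id)
            _write_column(grp, "edge_group_index", pop.group_index)
            for gid, group in sorted(pop.groups.items()):
                ggrp = grp.create_group(str(gid))
                ggrp.attrs["size"] = group.size
                for name, col in group.attributes.items():
                    _write_column(ggrp, name, col)
            if pop.indices:
                idx_root = grp.create_group("indices")
                for direction, index in sorted(pop.indices.items()):
                    _write_index(idx_root, index)


def _write_index(idx_root: h5py.Group, index: RangeIndex) -> None:
    grp = idx_root.create_group(_INDEX_GROUP[index.direction])
    max_node = max(index.ranges, default=-1)
    node_to_ranges = np.zeros((max_node + 1, 2), dtype=np.int64)
    range_list: list[tuple[int, int]] = []
    for nid in range(max_node + 1):
        spans = index.ranges.get(nid, [])
        node_to_ranges[nid, 0] = len(range_list)
        range_list.extend(spans)
        node_to_ranges[nid, 1] = len(range_list)
    grp.create_dataset("node_id_to_ranges", data=node_to_ranges)
    grp.create_dataset(
        "range_to_edge_id",
        data=np.asarray(range_list, dtype=np.int64).reshape(-1, 2),
    )


def _read_index(idx_root: h5py.Group, direction: str) -> RangeIndex | None:
    name = _INDEX_GROUP[direction]
    if name not in idx_root:
        return None
    grp = idx_root[name]
    node_to_ranges = grp["node_id_to_ranges"][...]
    range_list = grp["range_to_edge_id"][...]
    ranges: dict[int, list[tuple[int, int]]] = {}
    for nid in range(len(node_to_ranges)):
        a, b = node_to_ranges[nid]
        if b > a:
            ranges[nid] = [(int(s), int(e)) for s, e in range_list[a:b]]
    return RangeIndex(direction=direction, ranges=ranges)


def read_edges(path: str | os.PathLike) -> list[EdgePopulation]:
    """Read all edge populations (with indices) from an HDF5 file."""
    populations = []
    with h5py.File(path, "r") as fh:
        if "edges" not in fh:
            raise FormatError(f"{path}: missing /edges root group")
        root = fh["edges"]
        for name in sorted(root):
            grp = root[name]
            for required in ("source_node_id", "target_node_id", "edge_type_id"):
                if required not in grp:
                    raise FormatError(
                        f"{path}: population {name!r} lacks {required}"
                    )
            source = grp["source_node_id"][...]
            target = grp["target_node_id"][...]
            etype = grp["edge_type_id"][...]
            n = len(etype)
            if len(source) != n or len(target) != n:
                raise FormatError(
                    f"{path}: population {name!r} has mismatched column lengths"
                )
            group_id = (
                grp["edge_group_id"][...]
                if "edge_group_id" in grp
                else np.zeros(n, dtype=np.int64)
            )
            group_index = (
                grp["edge_group_index"][...]
                if "edge_group_index" in grp
                else np.arange(n, dtype=np.int64)
            )
            src_pop = grp["source_node_id"].attrs.get("node_population", "")
            tgt_pop = grp["target_node_id"].attrs.get("node_population", "")
            groups = _read_groups(grp, group_id, group_index, path, name)
            indices: dict[str, RangeIndex] = {}
            if "indices" in grp:
                for direction in ("by_target", "by_source"):
                    index = _read_index(grp["indices"], direction)
                    if index is not None:
                        indices[direction] = index
            populations.append(
                EdgePopulation(
                    name=name,
                    source_population=str(src_pop),
                    target_population=str(tgt_pop),
                    source_node_id=source,
                    target_node_id=target,
                    edge_type_id=etype,
                    group_id=group_id,
                    group_index=group_index,
                    groups=groups,
                    indices=indices,
                )
            )
    return populations


# ---------------------------------------------------------------------------
# Orderings and range indices
# ---------------------------------------------------------------------------

@dataclass
class Ordering:
    """Edge-array sort order.

    ``kind`` is one of ``target_major``, ``source_major`` or ``hybrid``.
    Hybrid ordering tiles the connectivity matrix into ``block_size`` x
    ``block_size`` blocks: edge ``(s, t)`` belongs to block
    ``(t // B, s // B)``; blocks are traversed in row-major order and
    the within-block order alternates by block parity (even = target
    major, odd = source major).
    """

    kind: str
    block_size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("target_major", "source_major", "hybrid"):
            raise ValueError(f"unknown ordering kind {self.kind!r}")
        if self.kind == "hybrid":
            if self.block_size is None or self.block_size < 1:
                raise ValueError("hybrid ordering requires block_size >= 1")


def sort_permutation(population: EdgePopulation, ordering: Ordering) -> np.ndarray:
    """Return the permutation that puts the edge arrays in ``ordering``."""
    src = population.source_node_id
    tgt = population.target_node_id
    if ordering.kind == "target_major":
        return np.lexsort((src, tgt))
    if ordering.kind == "source_major":
        return np.lexsort((tgt, src))
    B = int(ordering.block_size)  # hybrid
    bi = tgt // B
    bj = src // B
    even = (bi + bj) % 2 == 0
    k1 = np.where(even, tgt, src)
    k2 = np.where(even, src, tgt)
    return np.lexsort((k2, k1, bj, bi))


def sort_edges(population: EdgePopulation, ordering: Ordering) -> EdgePopulation:
    """Return a copy of ``population`` with permuted edge arrays.

    Groups are shared with the input (group_id/group_index travel with
    each edge).  Any attached range indices are dropped since they
    refer to the old order.
    """
    perm = sort_permutation(population, ordering)
    return EdgePopulation(
        name=population.name,
        source_population=population.source_population,
        target_population=population.target_population,
        source_node_id=population.source_node_id[perm],
        target_node_id=population.target_node_id[perm],
        edge_type_id=population.edge_type_id[perm],
        group_id=population.group_id[perm],
        group_index=population.group_index[perm],
        groups=population.groups,
        indices={},
    )


def build_edge_index(population: EdgePopulation, direction: str) -> RangeIndex:
    """Build a range index over the source or target id column.

    For every node ``n`` the concatenated ranges enumerate exactly the
    edge indices ``i`` with ``column[i] == n``, ascending.
    """
    if direction not in _INDEX_COLUMN:
        raise ValueError(f"bad index direction {direction!r}")
    column = getattr(
        population,
        "target_node_id" if direction == "by_target" else "source_node_id",
    )
    ranges: dict[int, list[tuple[int, int]]] = {}
    n = len(column)
    if n:
        boundaries = np.flatnonzero(np.diff(column) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        for a, b in zip(starts, ends):
            ranges.setdefault(int(column[a]), []).append((int(a), int(b)))
    return RangeIndex(direction=direction, ranges=ranges)


def query_edges(
    population: EdgePopulation, index: RangeIndex, node_id: int
) -> np.ndarray:
    """Edge indices incident to ``node_id`` on the indexed side, ascending."""
    result = index.edge_indices(node_id)
    if len(result) and result[-1] >= len(population):
        raise FormatError("range index refers past the end of the edge arrays")
    return result


# ---------------------------------------------------------------------------
# Whole-circuit convenience
# ---------------------------------------------------------------------------

def write_circuit(
    circuit: Circuit,
    nodes_path: str | os.PathLike,
    edges_path: str | os.PathLike,
    node_types_path: str | os.PathLike,
    edge_types_path: str | os.PathLike,
) -> None:
    """Write all four circuit files."""
    write_type_table(circuit.node_types, node_types_path)
    write_type_table(circuit.edge_types, edge_types_path)
    write_nodes(circuit.nodes.values(), nodes_path)
    write_edges(circuit.edges.values(), edges_path)


def read_circuit(
    nodes_path: str | os.PathLike,
    edges_path: str | os.PathLike,
    node_types_path: str | os.PathLike,
    edge_types_path: str | os.PathLike,
) -> Circuit:
    """Read a circuit from its four files."""
    circuit = Circuit(
        node_types=read_type_table(node_types_path, "node"),
        edge_types=read_type_table(edge_types_path, "edge"),
    )
    for pop in read_nodes(nodes_path):
        circuit.nodes[pop.name] = pop
    for pop in read_edges(edges_path):
        circuit.edges[pop.name] = pop
    return circuit
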