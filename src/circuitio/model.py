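"""In-memory data model for hybrid network circuits.

A circuit is a set of node populations and edge populations plus two
type tables (one for nodes, one for edges).  Attributes shared by many
instances live in a type-table row keyed by an integer type id;
per-instance attributes live in homogeneous *groups* inside each
population.  Resolving a node or edge overlays its type row with its
group attributes, instance values shadowing type values of the same
name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

#: Text token denoting an absent value in CSV type tables (case-sensitive).
NULL_TOKEN = "NONE"

#: Reserved values for the node-type column ``model_type``.
MODEL_TYPES = ("biophysical", "point_neuron", "single compartment", "virtual")

#: Provenance flags attached to resolved attributes.
PROVENANCE_TYPE = "type"
PROVENANCE_INSTANCE = "instance"


class CircuitError(Exception):
    """Base class for all circuit-model errors."""


class UnknownPopulationError(CircuitError):
    """A population name does not exist in the circuit."""


class UnknownNodeError(CircuitError):
    """A node id is not present in the addressed population."""


class UnknownEdgeError(CircuitError):
    """An edge index is out of range for the addressed population."""


class DanglingTypeError(CircuitError):
    """A node/edge references a type id absent from the type table."""


class NodeSetError(CircuitError):
    """A node-set expression is malformed."""


def _as_python(value: Any) -> Any:
    """Convert numpy scalars / bytes to plain Python values."""
    if isinstance(value, bytes):
        return value.decode("utf-8")
    if isinstance(value, np.generic):
        return value.item()
    return value


@dataclass
class TypeTable:
    """CSV-backed table mapping a type id to shared attribute values.

    Parameters
    ----------
    role:
        ``"node"`` or ``"edge"``; determines the id column name
        (``node_type_id`` / ``edge_type_id``) used on disk.
    columns:
        Ordered attribute names (excluding the id column).
    rows:
        Mapping ``type_id -> {attribute: value}``.  Absent (``NONE``)
        values are simply missing from the row mapping.
    """

    role: str
    columns: list[str] = field(default_factory=list)
    rows: dict[int, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("node", "edge"):
            raise ValueError(f"role must be 'node' or 'edge', got {self.role!r}")

    @property
    def id_column(self) -> str:
        return f"{self.role}_type_id"

    def row(self, type_id: int) -> dict[str, Any]:
        """Return the attribute map of ``type_id`` (without NONE entries)."""
        try:
            return self.rows[int(type_id)]
        except KeyError:
            raise DanglingTypeError(
                f"{self.id_column} {type_id} not present in type table"
            ) from None

    def add_row(self, type_id: int, attributes: Mapping[str, Any]) -> None:
        """Add a row, extending ``columns`` with any new attribute names."""
        type_id = int(type_id)
        if type_id < 0:
            raise ValueError("type ids must be non-negative")
        if type_id in self.rows:
            raise ValueError(f"duplicate {self.id_column} {type_id}")
        clean = {
            k: _as_python(v)
            for k, v in attributes.items()
            if v is not None and v != NULL_TOKEN
        }
        for name in attributes:
            if name not in self.columns:
                self.columns.append(name)
        self.rows[type_id] = clean

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypeTable):
            return NotImplemented
        return (
            self.role == other.role
            and self.columns == other.columns
            and self.rows == other.rows
        )


@dataclass
class NodeGroup:
    """Homogeneous collection of per-instance attribute columns.

    All attribute columns must have the same length, which is the group
    size.  A group may have no attribute columns at all, in which case
    ``size`` must be given explicitly.
    """

    group_id: int
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    size: int | None = None

    def __post_init__(self) -> None:
        self.attributes = {k: np.asarray(v) for k, v in self.attributes.items()}
        if self.size is None:
            if not self.attributes:
                self.size = 0
            else:
                self.size = len(next(iter(self.attributes.values())))

    def is_homogeneous(self) -> bool:
        """True iff all attribute columns have length == size."""
        return all(len(col) == self.size for col in self.attributes.values())

    def row(self, index: int) -> dict[str, Any]:
        """Per-instance attribute values at ``index`` as plain Python."""
        return {name: _as_python(col[index]) for name, col in self.attributes.items()}


# Edge groups share the node-group structure exactly.
EdgeGroup = NodeGroup


@dataclass
class NodePopulation:
    """Named, flat collection of nodes partitioned into groups."""

    name: str
    node_id: np.ndarray
    node_type_id: np.ndarray
    group_id: np.ndarray
    group_index: np.ndarray
    groups: dict[int, NodeGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=np.int64)
        self.node_type_id = np.asarray(self.node_type_id, dtype=np.int64)
        self.group_id = np.asarray(self.group_id, dtype=np.int64)
        self.group_index = np.asarray(self.group_index, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.node_id)

    def index_of(self, node_id: int) -> int:
        """Positional index of ``node_id`` within the population arrays."""
        hits = np.flatnonzero(self.node_id == node_id)
        if hits.size == 0:
            raise UnknownNodeError(
                f"node_id {node_id} not in population {self.name!r}"
            )
        return int(hits[0])


@dataclass
class RangeIndex:
    """Per-node lists of contiguous half-open ranges into the edge arrays."""

    direction: str  # "by_target" | "by_source"
    ranges: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.direction not in ("by_target", "by_source"):
            raise ValueError(f"bad index direction {self.direction!r}")

    def edge_indices(self, node_id: int) -> np.ndarray:
        """All edge indices for ``node_id``, ascending; empty if absent."""
        spans = self.ranges.get(int(node_id), [])
        if not spans:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([np.arange(a, b, dtype=np.int64) for a, b in spans])

    def total_length(self) -> int:
        return sum(b - a for spans in self.ranges.values() for a, b in spans)


@dataclass
class EdgePopulation:
    """Directed edges between a source and a target node population."""

    name: str
    source_population: str
    target_population: str
    source_node_id: np.ndarray
    target_node_id: np.ndarray
    edge_type_id: np.ndarray
    group_id: np.ndarray
    group_index: np.ndarray
    groups: dict[int, EdgeGroup] = field(default_factory=dict)
    indices: dict[str, RangeIndex] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for attr in (
            "source_node_id",
            "target_node_id",
            "edge_type_id",
            "group_id",
            "group_index",
        ):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=np.int64))

    def __len__(self) -> int:
        return len(self.source_node_id)


@dataclass
class Circuit:
    """Container of node/edge populations plus their type tables."""

    node_types: TypeTable = field(default_factory=lambda: TypeTable("node"))
    edge_types: TypeTable = field(default_factory=lambda: TypeTable("edge"))
    nodes: dict[str, NodePopulation] = field(default_factory=dict)
    edges: dict[str, EdgePopulation] = field(default_factory=dict)

    def node_population(self, name: str) -> NodePopulation:
        try:
            return self.nodes[name]
        except KeyError:
            raise UnknownPopulationError(f"no node population {name!r}") from None

    def edge_population(self, name: str) -> EdgePopulation:
        try:
            return self.edges[name]
        except KeyError:
            raise UnknownPopulationError(f"no edge population {name!r}") from None

    def iter_node_addresses(self) -> Iterable[tuple[str, int]]:
        """Yield every ``(population, node_id)`` in deterministic order."""
        for name in sorted(self.nodes):
            for nid in np.sort(self.nodes[name].node_id):
                yield name, int(nid)


@dataclass
class ResolvedNode:
    """A node with its type-level and instance-level attributes merged."""

    population: str
    node_id: int
    type_id: int
    attributes: dict[str, Any]
    provenance: dict[str, str]


@dataclass
class ResolvedEdge:
    """An edge with merged attributes plus its endpoints."""

    population: str
    edge_index: int
    type_id: int
    source_population: str
    source_node_id: int
    target_population: str
    target_node_id: int
    attributes: dict[str, Any]
    provenance: dict[str, str]


def _overlay(
    type_row: Mapping[str, Any], instance: Mapping[str, Any]
) -> tuple[dict[str, Any], dict[str, str]]:
    """Merge a type row with instance attributes; instance wins on conflict."""
    attributes = dict(type_row)
    provenance = {name: PROVENANCE_TYPE for name in type_row}
    for name, value in instance.items():
        attributes[name] = value
        provenance[name] = PROVENANCE_INSTANCE
    return attributes, provenance


def resolve_node(circuit: Circuit, population_name: str, node_id: int) -> ResolvedNode:
    """Resolve the full attribute map of one node.

    The node's type-table row is overlaid with its group's per-instance
    attributes; instance values shadow type values of the same name, and
    ``NONE``-valued type entries never appear.
    """
    pop = circuit.node_population(population_name)
    pos = pop.index_of(node_id)
    type_id = int(pop.node_type_id[pos])
    type_row = circuit.node_types.row(type_id)
    gid = int(pop.group_id[pos])
    gidx = int(pop.group_index[pos])
    group = pop.groups.get(gid)
    instance = group.row(gidx) if group is not None else {}
    attributes, provenance = _overlay(type_row, instance)
    return ResolvedNode(
        population=population_name,
        node_id=int(node_id),
        type_id=type_id,
        attributes=attributes,
        provenance=provenance,
    )


def resolve_edge(circuit: Circuit, population_name: str, edge_index: int) -> ResolvedEdge:
    """Resolve the full attribute map of the edge at ``edge_index``."""
    pop = circuit.edge_population(population_name)
    if not 0 <= edge_index < len(pop):
        raise UnknownEdgeError(
            f"edge index {edge_index} out of range for population "
            f"{population_name!r} of size {len(pop)}"
        )
    type_id = int(pop.edge_type_id[edge_index])
    type_row = circuit.edge_types.row(type_id)
    gid = int(pop.group_id[edge_index])
    gidx = int(pop.group_index[edge_index])
    group = pop.groups.get(gid)
    instance = group.row(gidx) if group is not None else {}
    attributes, provenance = _overlay(type_row, instance)
    return ResolvedEdge(
        population=population_name,
        edge_index=int(edge_index),
        type_id=type_id,
        source_population=pop.source_population,
        source_node_id=int(pop.source_node_id[edge_index]),
        target_population=pop.target_population,
        target_node_id=int(pop.target_node_id[edge_index]),
        attributes=attributes,
        provenance=provenance,
    )


def _matches(actual: Any, wanted: Any) -> bool:
    if isinstance(wanted, (list, tuple, set)):
        return any(_matches(actual, w) for w in wanted)
    return actual == wanted


def evaluate_node_set(
    circuit: Circuit,
    expression: Mapping[str, Any] | Sequence[tuple[str, int]],
) -> list[tuple[str, int]]:
    """Evaluate a node-set expression to a sorted node selection.

    ``expression`` is either an explicit sequence of ``(population,
    node_id)`` pairs or a predicate mapping attribute names to a
    required value (or list of allowed values).  The reserved keys
    ``"population"`` and ``"node_id"`` match the node's address rather
    than a resolved attribute.  Multiple keys combine conjunctively;
    list values are disjunctive within their key.  Evaluation is a pure
    filter over the circuit's nodes; the result is ordered by
    population name, then node id.
    """
    if isinstance(expression, Mapping):
        for key in expression:
            if not isinstance(key, str):
                raise NodeSetError(f"predicate keys must be strings, got {key!r}")
        selected = []
        for pop_name, node_id in circuit.iter_node_addresses():
            resolved: ResolvedNode | None = None
            ok = True
            for key, wanted in expression.items():
                if key == "population":
                    actual: Any = pop_name
                elif key == "node_id":
                    actual = node_id
                else:
                    if resolved is None:
                        resolved = resolve_node(circuit, pop_name, node_id)
                    if key not in resolved.attributes:
                        ok = False
                        break
                    actual = resolved.attributes[key]
                if not _matches(actual, wanted):
                    ok = False
                    break
            if ok:
                selected.append((pop_name, node_id))
        return selected

    if isinstance(expression, Sequence):
        wanted_pairs = set()
        for entry in expression:
            if len(entry) != 2:
                raise NodeSetError(f"explicit entries must be pairs, got {entry!r}")
            pop_name, node_id = entry
            if pop_name not in circuit.nodes:
                raise UnknownPopulationError(f"no node population {pop_name!r}")
            wanted_pairs.add((pop_name, int(node_id)))
        return [
            addr for addr in circuit.iter_node_addresses() if addr in wanted_pairs
        ]

    raise NodeSetError(f"unsupported node-set expression: {expression!r}")
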