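"""Cross-file structural validation of circuits and activity files.

Every check emits a :class:`Finding` rather than raising, so a single
pass reports all problems.  Findings are deterministic and sorted by
location then code.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Any

import h5py
import numpy as np

from . import io as cio
from .config import ConfigBundle
from .model import MODEL_TYPES, Circuit, EdgePopulation, NodePopulation, RangeIndex

ERROR = "error"
WARNING = "warning"


@dataclass(frozen=True)
class Finding:
    severity: str
    code: str
    location: str
    message: str

    def to_dict(self) -> dict[str, str]:
        return {
            "severity": self.severity,
            "code": self.code,
            "location": self.location,
            "message": self.message,
        }

    def __str__(self) -> str:
        return f"{self.severity}: [{self.code}] {self.location}: {self.message}"


def _sorted(findings: list[Finding]) -> list[Finding]:
    return sorted(findings, key=lambda f: (f.location, f.code, f.message))


def validate_circuit(target: Circuit | ConfigBundle | str | os.PathLike) -> list[Finding]:
    """Validate a circuit given in memory, as a config bundle, or by path.

    Checks: type-id resolution, group references and index ranges,
    group homogeneity, edge endpoint existence, reserved ``model_type``
    values, and range-index completeness.  An unreadable file becomes
    an error finding, not an exception.
    """
    if isinstance(target, Circuit):
        return _sorted(_validate_circuit_object(target))
    if isinstance(target, (str, os.PathLike)):
        from .config import load_config

        try:
            target = load_config(os.fspath(target))
        except Exception as exc:  # noqa: BLE001 - reported as a finding
            return [Finding(ERROR, "unreadable", os.fspath(target), str(exc))]
    findings: list[Finding] = []
    circuit = Circuit()
    cc = target.circuit
    if cc is None:
        return [Finding(ERROR, "missing_circuit", "<bundle>", "bundle has no circuit half")]
    for entry in cc.nodes:
        types_file = entry.get("node_types_file")
        nodes_file = entry.get("nodes_file")
        if types_file:
            try:
                table = cio.read_type_table(types_file, "node")
                for tid, row in table.rows.items():
                    if tid not in circuit.node_types.rows:
                        circuit.node_types.add_row(tid, row)
            except Exception as exc:  # noqa: BLE001
                findings.append(Finding(ERROR, "unreadable", str(types_file), str(exc)))
        if nodes_file:
            try:
                for pop in cio.read_nodes(nodes_file):
                    circuit.nodes[pop.name] = pop
            except Exception as exc:  # noqa: BLE001
                findings.append(Finding(ERROR, "unreadable", str(nodes_file), str(exc)))
    for entry in cc.edges:
        types_file = entry.get("edge_types_file")
        edges_file = entry.get("edges_file")
        if types_file:
            try:
                table = cio.read_type_table(types_file, "edge")
                for tid, row in table.rows.items():
                    if tid not in circuit.edge_types.rows:
                        circuit.edge_types.add_row(tid, row)
            except Exception as exc:  # noqa: BLE001
                findings.append(Finding(ERROR, "unreadable", str(types_file), str(exc)))
        if edges_file:
            try:
                for pop in cio.read_edges(edges_file):
                    circuit.edges[pop.name] = pop
            except Exception as exc:  # noqa: BLE001
                findings.append(Finding(ERROR, "unreadable", str(edges_file), str(exc)))
    findings.extend(_validate_circuit_object(circuit))
    return _sorted(findings)


def _validate_circuit_object(circuit: Circuit) -> list[Finding]:
    findings: list[Finding] = []
    findings.extend(_check_node_types(circuit))
    for name in sorted(circuit.nodes):
        findings.extend(_check_node_population(circuit, circuit.nodes[name]))
    for name in sorted(circuit.edges):
        findings.extend(_check_edge_population(circuit, circuit.edges[name]))
    return findings


def _check_node_types(circuit: Circuit) -> list[Finding]:
    findings = []
    table = circuit.node_types
    if table.rows and "model_type" not in table.columns:
        findings.append(
            Finding(
                ERROR,
                "model_type_missing",
                "node_types",
                "node type table lacks the reserved model_type column",
            )
        )
    for tid, row in sorted(table.rows.items()):
        mt = row.get("model_type")
        if mt is None:
            findings.append(
                Finding(
                    ERROR,
                    "model_type_missing",
                    f"node_types/{tid}",
                    f"node type {tid} has no model_type value",
                )
            )
        elif mt not in MODEL_TYPES:
            findings.append(
                Finding(
                    ERROR,
                    "model_type_value",
                    f"node_types/{tid}",
                    f"model_type {mt!r} is not one of {MODEL_TYPES}",
                )
            )
    return findings


def _check_groups(
    groups: dict[int, Any], group_id: np.ndarray, group_index: np.ndarray, where: str
) -> list[Finding]:
    findings = []
    for gid, group in sorted(groups.items()):
        if not group.is_homogeneous():
            lengths = sorted({len(c) for c in group.attributes.values()})
            findings.append(
                Finding(
                    ERROR,
                    "ragged_group",
                    f"{where}/{gid}",
                    f"group {gid} attribute columns have lengths {lengths}, "
                    f"size is {group.size}",
                )
            )
    for gid in np.unique(group_id) if len(group_id) else []:
        gid = int(gid)
        if gid not in groups:
            findings.append(
                Finding(
                    ERROR,
                    "group_unknown",
                    where,
                    f"group_id {gid} names no existing group",
                )
            )
            continue
        members = group_index[group_id == gid]
        size = groups[gid].size
        if members.size and (members.min() < 0 or members.max() >= size):
            findings.append(
                Finding(
                    ERROR,
                    "group_index_range",
                    f"{where}/{gid}",
                    f"group_index out of range [0, {size}) for group {gid}",
                )
            )
    return findings


def _check_node_population(circuit: Circuit, pop: NodePopulation) -> list[Finding]:
    findings = []
    where = f"nodes/{pop.name}"
    n = len(pop)
    for col_name in ("node_id", "node_type_id", "group_id", "group_index"):
        if len(getattr(pop, col_name)) != n:
            findings.append(
                Finding(
                    ERROR,
                    "column_length",
                    f"{where}/{col_name}",
                    f"column length {len(getattr(pop, col_name))} != {n}",
                )
            )
            return findings
    if len(np.unique(pop.node_id)) != n:
        findings.append(
            Finding(ERROR, "duplicate_node_id", where, "node_id values are not unique")
        )
    for tid in sorted(set(np.unique(pop.node_type_id)) - set(circuit.node_types.rows)):
        findings.append(
            Finding(
                ERROR,
                "dangling_node_type",
                where,
                f"node_type_id {int(tid)} absent from the node type table",
            )
        )
    findings.extend(_check_groups(pop.groups, pop.group_id, pop.group_index, where))
    return findings


def _check_edge_population(circuit: Circuit, pop: EdgePopulation) -> list[Finding]:
    findings = []
    where = f"edges/{pop.name}"
    n = len(pop)
    for col_name in (
        "source_node_id",
        "target_node_id",
        "edge_type_id",
        "group_id",
        "group_index",
    ):
        if len(getattr(pop, col_name)) != n:
            findings.append(
                Finding(
                    ERROR,
                    "column_length",
                    f"{where}/{col_name}",
                    f"column length {len(getattr(pop, col_name))} != {n}",
                )
            )
            return findings
    for tid in sorted(set(np.unique(pop.edge_type_id)) - set(circuit.edge_types.rows)):
        findings.append(
            Finding(
                ERROR,
                "dangling_edge_type",
                where,
                f"edge_type_id {int(tid)} absent from the edge type table",
            )
        )
    for side, pop_name, column in (
        ("source", pop.source_population, pop.source_node_id),
        ("target", pop.target_population, pop.target_node_id),
    ):
        if pop_name not in circuit.nodes:
            findings.append(
                Finding(
                    ERROR,
                    "unknown_population",
                    where,
                    f"{side} population {pop_name!r} not present in circuit",
                )
            )
            continue
        known = set(circuit.nodes[pop_name].node_id.tolist())
        missing = sorted(set(column.tolist()) - known)
        for nid in missing:
            findings.append(
                Finding(
                    ERROR,
                    "dangling_endpoint",
                    where,
                    f"{side}_node_id {nid} not present in population {pop_name!r}",
                )
            )
    findings.extend(_check_groups(pop.groups, pop.group_id, pop.group_index, where))
    for direction in sorted(pop.indices):
        findings.extend(
            _check_index(pop, pop.indices[direction], f"{where}/indices/{direction}")
        )
    return findings


def _check_index(pop: EdgePopulation, index: RangeIndex, where: str) -> list[Finding]:
    findings = []
    covered = np.zeros(len(pop), dtype=bool)
    column = (
        pop.target_node_id if index.direction == "by_target" else pop.source_node_id
    )
    ok = True
    for nid, spans in sorted(index.ranges.items()):
        prev_end = -1
        for a, b in spans:
            if not (0 <= a < b <= len(pop)) or a < prev_end:
                ok = False
                break
            prev_end = b
            if covered[a:b].any():
                ok = False
                break
            covered[a:b] = True
            if not np.all(column[a:b] == nid):
                findings.append(
                    Finding(
                        ERROR,
                        "index_corrupt",
                        where,
                        f"range [{a}, {b}) of node {nid} covers foreign edges",
                    )
                )
        if not ok:
            break
    if not ok or not covered.all():
        findings.append(
            Finding(
                ERROR,
                "index_incomplete",
                where,
                "index ranges do not partition the edge arrays exactly once",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def validate_activity(path: str | os.PathLike, circuit: Circuit) -> list[Finding]:
    """Validate a spikes or element-report file against a circuit."""
    path = os.fspath(path)
    findings: list[Finding] = []
    try:
        fh = h5py.File(path, "r")
    except Exception as exc:  # noqa: BLE001
        return [Finding(ERROR, "unreadable", path, str(exc))]
    with fh:
        if "spikes" in fh:
            findings.extend(_check_spike_file(fh["spikes"], circuit, path))
        if "report" in fh:
            findings.extend(_check_report_file(fh["report"], circuit, path))
        if "spikes" not in fh and "report" not in fh:
            findings.append(
                Finding(ERROR, "unreadable", path, "neither /spikes nor /report found")
            )
    return _sorted(findings)


def _known_node_ids(circuit: Circuit, population: str) -> set[int] | None:
    if population in circuit.nodes:
        return set(circuit.nodes[population].node_id.tolist())
    return None


def _check_spike_file(root: h5py.Group, circuit: Circuit, path: str) -> list[Finding]:
    findings = []
    for name in sorted(root):
        grp = root[name]
        where = f"{path}:/spikes/{name}"
        timestamps = grp["timestamps"][...] if "timestamps" in grp else None
        node_ids = grp["node_ids"][...] if "node_ids" in grp else None
        if timestamps is None or node_ids is None:
            findings.append(
                Finding(ERROR, "column_length", where, "missing timestamps or node_ids")
            )
            continue
        if len(timestamps) != len(node_ids):
            findings.append(
                Finding(
                    ERROR,
                    "column_length",
                    where,
                    f"{len(node_ids)} node_ids vs {len(timestamps)} timestamps",
                )
            )
            continue
        if len(timestamps) and timestamps.min() < 0:
            findings.append(
                Finding(ERROR, "negative_time", where, "negative spike timestamp")
            )
        sorting = str(grp.attrs.get("sorting", "none"))
        if sorting not in ("none", "by_time", "by_id"):
            findings.append(
                Finding(ERROR, "bad_sorting", where, f"unknown sorting {sorting!r}")
            )
        elif sorting == "by_time" and len(timestamps) > 1:
            if np.any(np.diff(timestamps) < 0):
                findings.append(
                    Finding(
                        ERROR,
                        "sorting_violated",
                        where,
                        "sorting=by_time but timestamps decrease",
                    )
                )
        elif sorting == "none" and len(timestamps) > 1:
            if not np.any(np.diff(timestamps) < 0):
                findings.append(
                    Finding(
                        WARNING,
                        "sorting_unmarked",
                        where,
                        "timestamps are time-sorted but sorting is 'none'",
                    )
                )
        known = _known_node_ids(circuit, name)
        if known is None:
            findings.append(
                Finding(
                    ERROR,
                    "unknown_population",
                    where,
                    f"population {name!r} not present in circuit",
                )
            )
        else:
            for nid in sorted(set(node_ids.tolist()) - known):
                findings.append(
                    Finding(
                        ERROR,
                        "dangling_node",
                        where,
                        f"spike node_id {nid} not present in population {name!r}",
                    )
                )
    return findings


def _check_report_file(root: h5py.Group, circuit: Circuit, path: str) -> list[Finding]:
    findings = []
    for name in sorted(root):
        grp = root[name]
        where = f"{path}:/report/{name}"
        if "data" not in grp or "mapping" not in grp:
            findings.append(
                Finding(ERROR, "mapping_corrupt", where, "missing data or mapping")
            )
            continue
        mgrp = grp["mapping"]
        data = grp["data"]
        node_ids = mgrp["node_ids"][...] if "node_ids" in mgrp else np.empty(0, int)
        offsets = mgrp["index_pointer"][...] if "index_pointer" in mgrp else None
        element_ids = mgrp["element_ids"][...] if "element_ids" in mgrp else None
        n_cols = data.shape[1] if data.ndim == 2 else -1
        if (
            offsets is None
            or len(offsets) != len(node_ids) + 1
            or len(offsets) == 0
            or offsets[0] != 0
            or np.any(np.diff(offsets) <= 0)
            or offsets[-1] != n_cols
        ):
            findings.append(
                Finding(
                    ERROR,
                    "mapping_corrupt",
                    where,
                    "index_pointer is not a strictly increasing 0..M offset array",
                )
            )
        if element_ids is not None and n_cols >= 0 and len(element_ids) != n_cols:
            findings.append(
                Finding(
                    ERROR,
                    "mapping_corrupt",
                    where,
                    f"{len(element_ids)} element_ids vs {n_cols} data columns",
                )
            )
        if "time" in mgrp and len(mgrp["time"]) == 3:
            tstart, tstop, dt = (float(x) for x in mgrp["time"][...])
            if dt <= 0 or tstop <= tstart:
                findings.append(
                    Finding(ERROR, "shape_mismatch", where, "bad time block")
                )
            else:
                n = int(round((tstop - tstart) / dt))
                if data.shape[0] != n:
                    findings.append(
                        Finding(
                            ERROR,
                            "shape_mismatch",
                            where,
                            f"{data.shape[0]} frames but time block implies {n}",
                        )
                    )
        else:
            findings.append(
                Finding(ERROR, "shape_mismatch", where, "missing [tstart, tstop, dt]")
            )
        # Report node ids must exist in the circuit; the report population
        # name may differ from the node population, so check all of them.
        all_known: set[int] = set()
        for pop in circuit.nodes.values():
            all_known.update(pop.node_id.tolist())
        known = _known_node_ids(circuit, name)
        lookup = known if known is not None else all_known
        for nid in sorted(set(node_ids.tolist()) - lookup):
            findings.append(
                Finding(
                    ERROR,
                    "dangling_node",
                    where,
                    f"report node_id {nid} not present in circuit",
                )
            )
    return findings
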