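"""Synthetic circuit and activity generators.

Produces self-contained fixtures: hybrid circuits (a biophysical-style
core, a point-neuron annulus and virtual input nodes wired by
probabilistic rules), Poisson spike trains, and smooth per-element
trace reports.  Every generator takes an explicit seed and owns a
single RNG stream; nothing touches global random state.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from . import io as cio
from . import reports
from .config import ConfigBundle, CircuitConfig, SimulationConfig, write_config
from .model import Circuit, EdgeGroup, EdgePopulation, NodeGroup, NodePopulation
from .reports import ElementMapping, ElementReport, SpikeReport


class SpecError(ValueError):
    """An invalid synthetic-circuit specification."""


@dataclass
class NodeTypeSpec:
    """One node type and how many instances of it to create."""

    type_id: int
    count: int
    attributes: dict[str, Any]


@dataclass
class PopulationSpec:
    name: str
    types: list[NodeTypeSpec]
    with_positions: bool = True

    @property
    def count(self) -> int:
        return sum(t.count for t in self.types)


@dataclass
class ConnectionRule:
    """Probabilistic all-pairs wiring between two populations.

    Each ordered (source, target) pair passing the type filters is
    connected independently with probability ``p``; a connected pair
    draws ``nsyn`` edges (``nsyn`` is either a fixed count or an
    inclusive ``(low, high)`` uniform integer range).  ``rich_group``
    adds placeholder afferent section/position attributes alongside
    ``syn_weight``, as used for edges onto compartmental targets.
    """

    source: str
    target: str
    p: float
    edge_type_id: int
    nsyn: int | tuple[int, int] = 1
    source_type_ids: Sequence[int] | None = None
    target_type_ids: Sequence[int] | None = None
    rich_group: bool = False
    weight_range: tuple[float, float] = (1e-4, 1e-2)
    section_range: tuple[int, int] = (0, 10)

    def validate(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise SpecError(f"connection probability must be in [0, 1], got {self.p}")
        if isinstance(self.nsyn, tuple):
            lo, hi = self.nsyn
            if lo < 1 or hi < lo:
                raise SpecError(f"bad nsyn range {self.nsyn}")
        elif self.nsyn < 1:
            raise SpecError(f"nsyn must be >= 1, got {self.nsyn}")


@dataclass
class CircuitSpec:
    """Full description of a synthetic circuit."""

    populations: list[PopulationSpec] = field(default_factory=list)
    rules: list[ConnectionRule] = field(default_factory=list)
    edge_types: dict[int, dict[str, Any]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise SpecError("duplicate population names")
        for pop in self.populations:
            for t in pop.types:
                if t.count < 0:
                    raise SpecError(f"negative count for type {t.type_id}")
        for rule in self.rules:
            rule.validate()
            if rule.source not in names or rule.target not in names:
                raise SpecError(
                    f"rule references unknown population "
                    f"{rule.source!r} or {rule.target!r}"
                )
            if rule.edge_type_id not in self.edge_types:
                raise SpecError(f"rule uses undefined edge type {rule.edge_type_id}")


def generate_circuit(spec: CircuitSpec) -> Circuit:
    """Instantiate a circuit from ``spec``, deterministically in its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    circuit = Circuit()

    seen_node_types: set[int] = set()
    for pop_spec in spec.populations:
        for t in pop_spec.types:
            if t.type_id not in seen_node_types:
                circuit.node_types.add_row(t.type_id, t.attributes)
                seen_node_types.add(t.type_id)
        n = pop_spec.count
        type_ids = np.concatenate(
            [np.full(t.count, t.type_id, dtype=np.int64) for t in pop_spec.types]
        ) if n else np.empty(0, dtype=np.int64)
        attributes: dict[str, np.ndarray] = {}
        if pop_spec.with_positions and n:
            attributes = {
                "x": rng.uniform(-400.0, 400.0, n),
                "y": rng.uniform(-400.0, 400.0, n),
                "z": rng.uniform(-400.0, 400.0, n),
            }
        group = NodeGroup(group_id=0, attributes=attributes, size=n)
        circuit.nodes[pop_spec.name] = NodePopulation(
            name=pop_spec.name,
            node_id=np.arange(n),
            node_type_id=type_ids,
            group_id=np.zeros(n, dtype=np.int64),
            group_index=np.arange(n),
            groups={0: group},
        )

    for tid, attrs in spec.edge_types.items():
        circuit.edge_types.add_row(tid, attrs)

    # Pre-compute node type lookup per population for rule filters.
    by_pair: dict[tuple[str, str], list[ConnectionRule]] = {}
    for rule in spec.rules:
        by_pair.setdefault((rule.source, rule.target), []).append(rule)

    for (src_name, tgt_name), rules in by_pair.items():
        name = f"{src_name}_to_{tgt_name}"
        circuit.edges[name] = _generate_edge_population(
            name, circuit, src_name, tgt_name, rules, rng
        )
    return circuit


def _rule_endpoint_ids(
    pop: NodePopulation, type_filter: Sequence[int] | None
) -> np.ndarray:
    if type_filter is None:
        return pop.node_id
    mask = np.isin(pop.node_type_id, np.asarray(list(type_filter)))
    return pop.node_id[mask]


def _generate_edge_population(
    name: str,
    circuit: Circuit,
    src_name: str,
    tgt_name: str,
    rules: Sequence[ConnectionRule],
    rng: np.random.Generator,
) -> EdgePopulation:
    src_pop = circuit.nodes[src_name]
    tgt_pop = circuit.nodes[tgt_name]
    sources: list[np.ndarray] = []
    targets: list[np.ndarray] = []
    etypes: list[np.ndarray] = []
    rich_flags: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    sections: list[np.ndarray] = []
    positions: list[np.ndarray] = []

    for rule in rules:
        src_ids = _rule_endpoint_ids(src_pop, rule.source_type_ids)
        tgt_ids = _rule_endpoint_ids(tgt_pop, rule.target_type_ids)
        if len(src_ids) == 0 or len(tgt_ids) == 0 or rule.p == 0.0:
            continue
        connected = rng.random((len(src_ids), len(tgt_ids))) < rule.p
        si, ti = np.nonzero(connected)
        if si.size == 0:
            continue
        if isinstance(rule.nsyn, tuple):
            nsyn = rng.integers(rule.nsyn[0], rule.nsyn[1] + 1, si.size)
        else:
            nsyn = np.full(si.size, int(rule.nsyn))
        s = np.repeat(src_ids[si], nsyn)
        t = np.repeat(tgt_ids[ti], nsyn)
        k = len(s)
        sources.append(s)
        targets.append(t)
        etypes.append(np.full(k, rule.edge_type_id, dtype=np.int64))
        rich_flags.append(np.full(k, rule.rich_group))
        lo, hi = rule.weight_range
        weights.append(rng.uniform(lo, hi, k))
        sections.append(rng.integers(rule.section_range[0], rule.section_range[1] + 1, k))
        positions.append(rng.uniform(0.0, 1.0, k))

    if sources:
        source = np.concatenate(sources)
        target = np.concatenate(targets)
        etype = np.concatenate(etypes)
        rich = np.concatenate(rich_flags)
        weight = np.concatenate(weights)
        section = np.concatenate(sections)
        position = np.concatenate(positions)
    else:
        source = target = etype = np.empty(0, dtype=np.int64)
        rich = np.empty(0, dtype=bool)
        weight = section = position = np.empty(0)

    n = len(source)
    group_id = np.where(rich, 0, 1)
    group_index = np.zeros(n, dtype=np.int64)
    group_index[rich] = np.arange(int(rich.sum()))
    group_index[~rich] = np.arange(n - int(rich.sum()))
    groups = {
        0: EdgeGroup(
            group_id=0,
            attributes={
                "syn_weight": weight[rich],
                "afferent_section_id": section[rich],
                "afferent_section_pos": position[rich],
            },
            size=int(rich.sum()),
        ),
        1: EdgeGroup(
            group_id=1,
            attributes={"syn_weight": weight[~rich]},
            size=n - int(rich.sum()),
        ),
    }
    return EdgePopulation(
        name=name,
        source_population=src_name,
        target_population=tgt_name,
        source_node_id=source,
        target_node_id=target,
        edge_type_id=etype,
        group_id=group_id,
        group_index=group_index,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# A hybrid core/annulus/virtual spec
# ---------------------------------------------------------------------------

#: Full-scale population sizes for :func:`l4_like_spec`.
L4_CORE = 10_000
L4_ANNULUS = 35_000
L4_VIRTUAL = 10_000


def l4_like_spec(scale: float, seed: int = 0) -> CircuitSpec:
    """A hybrid circuit spec: compartmental core, point-neuron annulus
    and virtual inputs, scaled by ``scale`` (ceiling per population).

    Edges onto the core carry a rich attribute group (weight + afferent
    section/position); edges onto the annulus carry weight only.
    Connection probabilities shrink with scale so edge counts stay
    roughly linear in the node count.
    """
    if not 0.0 < scale <= 1.0:
        raise SpecError(f"scale must be in (0, 1], got {scale}")
    n_core = math.ceil(scale * L4_CORE)
    n_annulus = math.ceil(scale * L4_ANNULUS)
    n_virtual = math.ceil(scale * L4_VIRTUAL)

    node_types = {
        0: {"model_type": "biophysical", "model_template": "ctdb:Biophys1.hoc",
            "morphology": "exc_m.swc", "dynamics_params": "exc_fit.json"},
        1: {"model_type": "biophysical", "model_template": "ctdb:Biophys1.hoc",
            "morphology": "inh_m.swc", "dynamics_params": "inh_fit.json"},
        2: {"model_type": "point_neuron", "model_template": "nrn:IntFire1",
            "dynamics_params": "if1_exc.json"},
        3: {"model_type": "point_neuron", "model_template": "nrn:IntFire1",
            "dynamics_params": "if1_inh.json"},
        4: {"model_type": "virtual"},
    }
    n_core_exc = math.ceil(0.85 * n_core)
    n_ann_exc = math.ceil(0.85 * n_annulus)
    populations = [
        PopulationSpec(
            name="core",
            types=[
                NodeTypeSpec(0, n_core_exc, node_types[0]),
                NodeTypeSpec(1, n_core - n_core_exc, node_types[1]),
            ],
        ),
        PopulationSpec(
            name="annulus",
            types=[
                NodeTypeSpec(2, n_ann_exc, node_types[2]),
                NodeTypeSpec(3, n_annulus - n_ann_exc, node_types[3]),
            ],
        ),
        PopulationSpec(
            name="virtual",
            types=[NodeTypeSpec(4, n_virtual, node_types[4])],
            with_positions=False,
        ),
    ]
    edge_types = {
        0: {"model_template": "exp2syn", "dynamics_params": "syn_exc.json",
            "delay": 2.0},
        1: {"model_template": "exp2syn", "dynamics_params": "syn_inh.json",
            "delay": 2.0},
    }
    # Aim for ~ tens of inputs per target regardless of scale.
    n_total = n_core + n_annulus
    p_rec = min(1.0, 20.0 / max(n_total, 1))
    p_ext = min(1.0, 20.0 / max(n_virtual, 1))
    rules = [
        ConnectionRule("core", "core", p_rec, 0, nsyn=(1, 3), rich_group=True),
        ConnectionRule("core", "annulus", p_rec, 0),
        ConnectionRule("annulus", "core", p_rec, 1, nsyn=(1, 2), rich_group=True),
        ConnectionRule("annulus", "annulus", p_rec, 1),
        ConnectionRule("virtual", "core", p_ext, 0, rich_group=True),
        ConnectionRule("virtual", "annulus", p_ext, 0),
    ]
    return CircuitSpec(
        populations=populations, rules=rules, edge_types=edge_types, seed=seed
    )


# ---------------------------------------------------------------------------
# Activity generators
# ---------------------------------------------------------------------------

def generate_poisson_spikes(
    node_ids: Sequence[int],
    rate_hz: float,
    duration_ms: float,
    seed: int = 0,
    population: str = "virtual",
) -> SpikeReport:
    """Independent homogeneous Poisson spike trains, time-sorted.

    Each node fires at ``rate_hz`` over ``[0, duration_ms)``.
    """
    if rate_hz < 0:
        raise SpecError(f"rate must be >= 0, got {rate_hz}")
    if duration_ms < 0:
        raise SpecError(f"duration must be >= 0, got {duration_ms}")
    rng = np.random.default_rng(seed)
    node_ids = np.asarray(list(node_ids), dtype=np.int64)
    mean = rate_hz * duration_ms / 1000.0
    counts = rng.poisson(mean, len(node_ids))
    ids = np.repeat(node_ids, counts)
    times = rng.uniform(0.0, duration_ms, int(counts.sum()))
    order = np.argsort(times, kind="stable")
    return SpikeReport(
        population=population,
        node_ids=ids[order],
        timestamps=times[order],
        sorting="by_time",
    )


def generate_report_traces(
    mapping: ElementMapping,
    tstart: float,
    tstop: float,
    dt: float,
    model: tuple,
    seed: int = 0,
    population: str = "default",
    variable: str = "v",
    units: str = "mV",
) -> ElementReport:
    """Generate a fully populated element report.

    ``model`` selects the per-trace time-series model:

    * ``("constant", c)`` — every entry equals ``c``;
    * ``("sinusoid", amplitude, freq_hz)`` — one phase drawn uniformly
      per trace;
    * ``("ar1", rho, sigma)`` — a first-order autoregressive walk.
    """
    rng = np.random.default_rng(seed)
    n = reports.frame_count(tstart, tstop, dt)
    m = mapping.n_elements
    kind = model[0]
    if kind == "constant":
        data = np.full((n, m), float(model[1]))
    elif kind == "sinusoid":
        amplitude, freq_hz = float(model[1]), float(model[2])
        t = (tstart + dt * np.arange(n))[:, None] / 1000.0  # seconds
        phase = rng.uniform(0.0, 2 * np.pi, m)[None, :]
        data = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    elif kind == "ar1":
        rho, sigma = float(model[1]), float(model[2])
        noise = rng.normal(0.0, sigma, (n, m))
        data = np.empty((n, m))
        prev = np.zeros(m)
        for r in range(n):
            prev = rho * prev + noise[r]
            data[r] = prev
    else:
        raise SpecError(f"unknown trace model {kind!r}")
    return ElementReport(
        mapping=mapping,
        tstart=tstart,
        tstop=tstop,
        dt=dt,
        data=data,
        variable=variable,
        units=units,
        population=population,
    )


# ---------------------------------------------------------------------------
# Whole-bundle fixture
# ---------------------------------------------------------------------------

def write_bundle(
    directory: str | os.PathLike,
    scale: float = 0.01,
    seed: int = 0,
    input_rate_hz: float = 10.0,
    tstop: float = 100.0,
    dt: float = 1.0,
) -> str:
    """Write a complete circuit + config + activity fixture bundle.

    Layout: ``network/`` (nodes, edges, type tables), ``inputs/``
    (Poisson spikes from the virtual nodes), ``output/`` (a somatic
    trace report over the core population) and the three config files.
    Returns the path of the primary config.
    """
    directory = os.fspath(directory)
    net_dir = os.path.join(directory, "network")
    in_dir = os.path.join(directory, "inputs")
    out_dir = os.path.join(directory, "output")
    for d in (net_dir, in_dir, out_dir):
        os.makedirs(d, exist_ok=True)

    circuit = generate_circuit(l4_like_spec(scale, seed=seed))
    paths = {
        "nodes": os.path.join(net_dir, "nodes.h5"),
        "edges": os.path.join(net_dir, "edges.h5"),
        "node_types": os.path.join(net_dir, "node_types.csv"),
        "edge_types": os.path.join(net_dir, "edge_types.csv"),
    }
    cio.write_circuit(
        circuit, paths["nodes"], paths["edges"], paths["node_types"], paths["edge_types"]
    )

    spikes = generate_poisson_spikes(
        circuit.nodes["virtual"].node_id,
        rate_hz=input_rate_hz,
        duration_ms=tstop,
        seed=seed + 1,
        population="virtual",
    )
    spikes_path = os.path.join(in_dir, "input_spikes.h5")
    reports.write_spikes(spikes, spikes_path)

    core_ids = circuit.nodes["core"].node_id[: min(10, len(circuit.nodes["core"]))]
    mapping = reports.build_mapping([(int(nid), [(0, None)]) for nid in core_ids])
    trace_report = generate_report_traces(
        mapping, 0.0, tstop, dt, ("constant", -65.0), seed=seed + 2, population="core"
    )
    report_path = os.path.join(out_dir, "soma_report.h5")
    reports.write_element_report(trace_report, report_path)

    # Configs carry paths relative to the bundle directory so the whole
    # tree stays relocatable; write_config stores the raw documents.
    rel = {k: os.path.relpath(v, directory) for k, v in paths.items()}
    circuit_cfg = CircuitConfig(
        components={},
        nodes=[{
            "nodes_file": rel["nodes"],
            "node_types_file": rel["node_types"],
        }],
        edges=[{
            "edges_file": rel["edges"],
            "edge_types_file": rel["edge_types"],
        }],
    )
    circuit_cfg.raw = circuit_cfg.to_dict()
    bundle = ConfigBundle(
        circuit=circuit_cfg,
        simulation=_make_sim_config(
            tstop=tstop,
            dt=dt,
            seed=seed,
            spikes_file=os.path.relpath(spikes_path, directory),
            output_dir=os.path.relpath(out_dir, directory),
        ),
    )
    return write_config(bundle, directory)


def _make_sim_config(tstop, dt, seed, spikes_file, output_dir) -> SimulationConfig:
    cfg = SimulationConfig(
            tstop=tstop,
            dt=dt,
            seed=seed,
            node_sets={
                "core": {"population": "core"},
                "biophysical": {"model_type": "biophysical"},
            },
            inputs={
                "virtual_spikes": {
                    "input_type": "spikes",
                    "node_set": {"population": "virtual"},
                    "input_file": spikes_file,
                }
            },
            output={"output_dir": output_dir, "overwrite": True},
            reports={
                "soma_v": {
                    "variable": "v",
                    "cells": "core",
                    "start": 0.0,
                    "end": tstop,
                }
            },
    )
    cfg.raw = cfg.to_dict()
    return cfg
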