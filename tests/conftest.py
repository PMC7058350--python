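import numpy as np
import pytest

from circuitio.examples import demo_circuit
from circuitio.model import (
    Circuit,
    EdgeGroup,
    EdgePopulation,
    NodeGroup,
    NodePopulation,
)

MODEL_TYPE_CHOICES = ("biophysical", "point_neuron", "single compartment", "virtual")


@pytest.fixture
def demo():
    return demo_circuit()


def make_random_circuit(
    rng: np.random.Generator,
    max_nodes: int = 50,
    max_edges: int = 200,
    max_groups: int = 3,
    n_populations: int = 1,
) -> Circuit:
    """Random but always-valid circuit for round-trip / property tests."""
    circuit = Circuit()
    n_types = int(rng.integers(1, 5))
    for tid in range(n_types):
        attrs = {"model_type": MODEL_TYPE_CHOICES[rng.integers(len(MODEL_TYPE_CHOICES))]}
        if rng.random() < 0.7:
            attrs["model_template"] = f"tmpl:{tid}"
        if rng.random() < 0.5:
            attrs["tau"] = float(rng.uniform(0.1, 30.0))
        circuit.node_types.add_row(tid, attrs)
    n_edge_types = int(rng.integers(1, 4))
    for tid in range(n_edge_types):
        circuit.edge_types.add_row(
            tid, {"delay": float(rng.uniform(0.5, 5.0)), "model_template": "exp2syn"}
        )

    pop_names = [f"pop{i}" for i in range(n_populations)]
    for name in pop_names:
        n = int(rng.integers(1, max_nodes + 1))
        n_groups = int(rng.integers(1, max_groups + 1))
        group_id = rng.integers(0, n_groups, n)
        group_index = np.zeros(n, dtype=np.int64)
        groups = {}
        for gid in range(n_groups):
            members = np.flatnonzero(group_id == gid)
            group_index[members] = np.arange(len(members))
            attrs = {}
            if rng.random() < 0.8:
                attrs["x"] = rng.normal(size=len(members))
            if rng.random() < 0.4:
                attrs["label"] = np.array(
                    [f"cell_{gid}_{i}" for i in range(len(members))], dtype=object
                )
            groups[gid] = NodeGroup(group_id=gid, attributes=attrs, size=len(members))
        circuit.nodes[name] = NodePopulation(
            name=name,
            node_id=np.arange(n),
            node_type_id=rng.integers(0, n_types, n),
            group_id=group_id,
            group_index=group_index,
            groups=groups,
        )

    src_name = pop_names[0]
    tgt_name = pop_names[-1]
    n_src = len(circuit.nodes[src_name])
    n_tgt = len(circuit.nodes[tgt_name])
    m = int(rng.integers(0, max_edges + 1))
    e_group_id = rng.integers(0, 2, m)
    e_group_index = np.zeros(m, dtype=np.int64)
    e_groups = {}
    for gid in range(2):
        members = np.flatnonzero(e_group_id == gid)
        e_group_index[members] = np.arange(len(members))
        attrs = {"syn_weight": rng.uniform(0, 1, len(members))}
        if gid == 0:
            attrs["afferent_section_id"] = rng.integers(0, 10, len(members))
        e_groups[gid] = EdgeGroup(group_id=gid, attributes=attrs, size=len(members))
    circuit.edges["conn"] = EdgePopulation(
        name="conn",
        source_population=src_name,
        target_population=tgt_name,
        source_node_id=rng.integers(0, n_src, m),
        target_node_id=rng.integers(0, n_tgt, m),
        edge_type_id=rng.integers(0, n_edge_types, m),
        group_id=e_group_id,
        group_index=e_group_index,
        groups=e_groups,
    )
    return circuit


@pytest.fixture
def random_circuit_factory():
    return make_random_circuit


def assert_circuits_equal(a: Circuit, b: Circuit) -> None:
    assert a.node_types == b.node_types
    assert a.edge_types == b.edge_types
    assert sorted(a.nodes) == sorted(b.nodes)
    for name in a.nodes:
        pa, pb = a.nodes[name], b.nodes[name]
        np.testing.assert_array_equal(pa.node_id, pb.node_id)
        np.testing.assert_array_equal(pa.node_type_id, pb.node_type_id)
        np.testing.assert_array_equal(pa.group_id, pb.group_id)
        np.testing.assert_array_equal(pa.group_index, pb.group_index)
        assert_groups_equal(pa.groups, pb.groups)
    assert sorted(a.edges) == sorted(b.edges)
    for name in a.edges:
        ea, eb = a.edges[name], b.edges[name]
        assert ea.source_population == eb.source_population
        assert ea.target_population == eb.target_population
        for col in ("source_node_id", "target_node_id", "edge_type_id",
                    "group_id", "group_index"):
            np.testing.assert_array_equal(getattr(ea, col), getattr(eb, col))
        assert_groups_equal(ea.groups, eb.groups)


def assert_groups_equal(ga, gb) -> None:
    assert sorted(ga) == sorted(gb)
    for gid in ga:
        assert ga[gid].size == gb[gid].size
        assert sorted(ga[gid].attributes) == sorted(gb[gid].attributes)
        for attr in ga[gid].attributes:
            ca = np.asarray(ga[gid].attributes[attr])
            cb = np.asarray(gb[gid].attributes[attr])
            if ca.dtype.kind in ("U", "O") or cb.dtype.kind in ("U", "O"):
                assert [str(v) for v in ca] == [str(v) for v in cb]
            else:
                np.testing.assert_array_equal(ca, cb)
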