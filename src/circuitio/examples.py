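"""A tiny built-in example circuit.

Five node types (three compartmental, two integrate-and-fire) and four
synapse types, with one node instantiated per node type.  Used by the
documentation and as a minimal smoke-test fixture.
"""

from __future__ import annotations

import io as _stdio

import numpy as np

from .io import read_type_table
from .model import Circuit, EdgeGroup, EdgePopulation, NodeGroup, NodePopulation, TypeTable

NODE_TYPES_CSV = """\
node_type_id model_type model_template morphology dynamics_params
0 biophysical ctdb:Biophys1.hoc scnn1a_m.swc 472363762_fit.json
1 biophysical ctdb:Biophys1.hoc rorb_m.swc 473863510_fit.json
2 biophysical nml:PV1.nml.xml pv1_m.swc NONE
3 point_neuron nrn:IntFire1 NONE if1_exc.json
4 point_neuron nrn:IntFire1 NONE if1_inh.json
"""

EDGE_TYPES_CSV = """\
edge_type_id model_template dynamics_params delay
0 exp2syn biophys_exc.json 2.0
1 exp2syn biophys_inh.json 2.0
2 NONE Instantaneous_exc.json 2.0
3 NONE Instantaneous_inh.json 2.0
"""


def demo_node_types() -> TypeTable:
    """The example node-type table, parsed."""
    return read_type_table(_stdio.StringIO(NODE_TYPES_CSV), "node")


def demo_edge_types() -> TypeTable:
    """The example edge-type table, parsed."""
    return read_type_table(_stdio.StringIO(EDGE_TYPES_CSV), "edge")


def demo_circuit() -> Circuit:
    """A 5-node, 4-edge circuit with one node per demo node type."""
    n = 5
    nodes = NodePopulation(
        name="demo",
        node_id=np.arange(n),
        node_type_id=np.arange(n),
        group_id=np.zeros(n, dtype=np.int64),
        group_index=np.arange(n),
        groups={
            0: NodeGroup(
                group_id=0,
                attributes={
                    "x": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                    "y": np.array([2.0, 3.0, 4.0, 5.0, 6.0]),
                    "z": np.array([3.0, 4.0, 5.0, 6.0, 7.0]),
                },
            )
        },
    )
    m = 4
    edges = EdgePopulation(
        name="demo_edges",
        source_population="demo",
        target_population="demo",
        source_node_id=np.array([0, 1, 3, 4]),
        target_node_id=np.array([3, 4, 0, 1]),
        edge_type_id=np.arange(m),
        group_id=np.zeros(m, dtype=np.int64),
        group_index=np.arange(m),
        groups={0: EdgeGroup(group_id=0, attributes={}, size=m)},
    )
    return Circuit(
        node_types=demo_node_types(),
        edge_types=demo_edge_types(),
        nodes={"demo": nodes},
        edges={"demo_edges": edges},
    )
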