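"""Fault-injection harness: every validator check fires on exactly one
seeded corruption and stays silent on clean generated output."""

import copy

import h5py
import numpy as np
import pytest

from circuitio import io as cio
from circuitio import reports as crep
from circuitio.model import Circuit, RangeIndex
from circuitio.synth import generate_circuit, generate_poisson_spikes, l4_like_spec
from circuitio.validate import ERROR, validate_activity, validate_circuit


@pytest.fixture(scope="module")
def clean_circuit():
    return generate_circuit(l4_like_spec(0.002, seed=42))


def errors(findings):
    return [f for f in findings if f.severity == ERROR]


class TestValidateCircuit:
    def test_clean_circuit_has_no_findings(self, clean_circuit):
        assert validate_circuit(clean_circuit) == []

    def test_dangling_node_type(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        circuit.nodes["core"].node_type_id[0] = 99
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "dangling_node_type"

    def test_dangling_edge_type(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        circuit.edges["core_to_core"].edge_type_id[0] = 55
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "dangling_edge_type"

    def test_dangling_endpoint(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        pop = circuit.edges["core_to_core"]
        pop.target_node_id[0] = len(circuit.nodes["core"]) + 10
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "dangling_endpoint"

    def test_unknown_edge_population_reference(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        circuit.edges["core_to_core"].source_population = "ghost"
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "unknown_population"

    def test_group_unknown(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        circuit.nodes["core"].group_id[0] = 7
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "group_unknown"

    def test_group_index_range(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        pop = circuit.nodes["core"]
        pop.group_index[0] = pop.groups[0].size + 5
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "group_index_range"

    def test_ragged_group(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        group = circuit.nodes["core"].groups[0]
        group.attributes["x"] = group.attributes["x"][:-1]
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "ragged_group"

    def test_duplicate_node_id(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        circuit.nodes["virtual"].node_id[1] = circuit.nodes["virtual"].node_id[0]
        codes = {f.code for f in errors(validate_circuit(circuit))}
        assert "duplicate_node_id" in codes

    def test_column_length_mismatch(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        pop = circuit.nodes["core"]
        pop.node_type_id = pop.node_type_id[:-1]
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "column_length"

    def test_bad_model_type(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        circuit.node_types.rows[0]["model_type"] = "quantum"
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "model_type_value"

    def test_missing_model_type(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        del circuit.node_types.rows[4]["model_type"]
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "model_type_missing"

    def test_index_valid_then_corrupted(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        pop = cio.sort_edges(circuit.edges["core_to_core"], cio.Ordering("target_major"))
        pop.indices["by_target"] = cio.build_edge_index(pop, "by_target")
        circuit.edges["core_to_core"] = pop
        assert validate_circuit(circuit) == []
        # drop one range -> incomplete coverage
        first = next(iter(pop.indices["by_target"].ranges))
        del pop.indices["by_target"].ranges[first]
        findings = errors(validate_circuit(circuit))
        assert len(findings) == 1
        assert findings[0].code == "index_incomplete"

    def test_index_pointing_at_foreign_edges(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        pop = cio.sort_edges(circuit.edges["core_to_core"], cio.Ordering("target_major"))
        index = cio.build_edge_index(pop, "by_target")
        # swap two nodes' range lists
        keys = sorted(index.ranges)[:2]
        index.ranges[keys[0]], index.ranges[keys[1]] = (
            index.ranges[keys[1]],
            index.ranges[keys[0]],
        )
        pop.indices["by_target"] = index
        circuit.edges["core_to_core"] = pop
        codes = {f.code for f in errors(validate_circuit(circuit))}
        assert "index_corrupt" in codes

    def test_unreadable_path(self, tmp_path):
        findings = validate_circuit(tmp_path / "nope.json")
        assert len(findings) == 1
        assert findings[0].code == "unreadable"

    def test_findings_deterministic_order(self, clean_circuit):
        circuit = copy.deepcopy(clean_circuit)
        circuit.nodes["core"].node_type_id[0] = 99
        circuit.edges["core_to_core"].edge_type_id[0] = 55
        a = validate_circuit(circuit)
        b = validate_circuit(circuit)
        assert a == b
        assert [f.location for f in a] == sorted(f.location for f in a)

    def test_file_based_validation(self, clean_circuit, tmp_path):
        from circuitio.config import CircuitConfig, ConfigBundle

        paths = {
            "nodes_file": str(tmp_path / "n.h5"),
            "node_types_file": str(tmp_path / "nt.csv"),
        }
        epaths = {
            "edges_file": str(tmp_path / "e.h5"),
            "edge_types_file": str(tmp_path / "et.csv"),
        }
        cio.write_circuit(
            clean_circuit,
            paths["nodes_file"],
            epaths["edges_file"],
            paths["node_types_file"],
            epaths["edge_types_file"],
        )
        bundle = ConfigBundle(
            circuit=CircuitConfig(nodes=[paths], edges=[epaths])
        )
        assert validate_circuit(bundle) == []


@pytest.fixture(scope="module")
def spike_path_factory(tmp_path_factory, clean_circuit):
    def make(mutate=None, name="s.h5"):
        d = tmp_path_factory.mktemp("activity")
        path = str(d / name)
        report = generate_poisson_spikes(
            clean_circuit.nodes["virtual"].node_id, 20.0, 500.0, seed=7
        )
        crep.write_spikes(report, path)
        if mutate is not None:
            with h5py.File(path, "a") as fh:
                mutate(fh)
        return path

    return make


class TestValidateActivity:
    def test_clean_spikes(self, clean_circuit, spike_path_factory):
        assert validate_activity(spike_path_factory(), clean_circuit) == []

    def test_dangling_spike_node(self, clean_circuit, spike_path_factory):
        def mutate(fh):
            ids = fh["spikes/virtual/node_ids"]
            ids[0] = 10_000

        findings = errors(validate_activity(spike_path_factory(mutate), clean_circuit))
        assert len(findings) == 1
        assert findings[0].code == "dangling_node"

    def test_unknown_spike_population(self, clean_circuit, spike_path_factory):
        def mutate(fh):
            fh["spikes"].move("virtual", "ghost")

        findings = errors(validate_activity(spike_path_factory(mutate), clean_circuit))
        assert len(findings) == 1
        assert findings[0].code == "unknown_population"

    def test_negative_timestamp(self, clean_circuit, spike_path_factory):
        def mutate(fh):
            fh["spikes/virtual/timestamps"][0] = -5.0

        codes = {
            f.code
            for f in errors(validate_activity(spike_path_factory(mutate), clean_circuit))
        }
        assert "negative_time" in codes

    def test_sorting_violated(self, clean_circuit, spike_path_factory):
        def mutate(fh):
            ts = fh["spikes/virtual/timestamps"]
            if len(ts) > 1:
                ts[0] = ts[-1] + 100.0

        findings = errors(validate_activity(spike_path_factory(mutate), clean_circuit))
        assert len(findings) == 1
        assert findings[0].code == "sorting_violated"

    def test_spike_column_mismatch(self, clean_circuit, spike_path_factory):
        def mutate(fh):
            ids = fh["spikes/virtual/node_ids"][...]
            del fh["spikes/virtual/node_ids"]
            fh["spikes/virtual"].create_dataset("node_ids", data=ids[:-1])

        findings = errors(validate_activity(spike_path_factory(mutate), clean_circuit))
        assert len(findings) == 1
        assert findings[0].code == "column_length"

    def _report_path(self, tmp_path, clean_circuit, mutate=None):
        ids = clean_circuit.nodes["core"].node_id[:5]
        mapping = crep.build_mapping([(int(n), [(0, None)]) for n in ids])
        path = str(tmp_path / "r.h5")
        with crep.create_element_report(
            path, mapping, 0.0, 1.0, 0.1, population="core"
        ) as writer:
            writer.append_frames(np.zeros((10, 5)))
        if mutate is not None:
            with h5py.File(path, "a") as fh:
                mutate(fh)
        return path

    def test_clean_report(self, clean_circuit, tmp_path):
        path = self._report_path(tmp_path, clean_circuit)
        assert validate_activity(path, clean_circuit) == []

    def test_nonmonotone_offsets(self, clean_circuit, tmp_path):
        def mutate(fh):
            ptr = fh["report/core/mapping/index_pointer"]
            ptr[2] = ptr[1]  # no longer strictly increasing

        path = self._report_path(tmp_path, clean_circuit, mutate)
        findings = errors(validate_activity(path, clean_circuit))
        assert len(findings) == 1
        assert findings[0].code == "mapping_corrupt"

    def test_dangling_report_node(self, clean_circuit, tmp_path):
        def mutate(fh):
            fh["report/core/mapping/node_ids"][0] = 77_777

        path = self._report_path(tmp_path, clean_circuit, mutate)
        findings = errors(validate_activity(path, clean_circuit))
        assert len(findings) == 1
        assert findings[0].code == "dangling_node"

    def test_frame_count_mismatch(self, clean_circuit, tmp_path):
        def mutate(fh):
            fh["report/core/mapping/time"][1] = 2.0  # doubles implied N

        path = self._report_path(tmp_path, clean_circuit, mutate)
        findings = errors(validate_activity(path, clean_circuit))
        assert len(findings) == 1
        assert findings[0].code == "shape_mismatch"

    def test_unreadable_activity(self, clean_circuit, tmp_path):
        path = tmp_path / "junk.h5"
        path.write_text("not hdf5")
        findings = validate_activity(path, clean_circuit)
        assert len(findings) == 1
        assert findings[0].code == "unreadable"
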