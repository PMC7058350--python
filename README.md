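# circuitio

Read, write, validate and synthesize hybrid neuronal-network circuit
files and simulation activity reports.

A circuit is described by four files: two space-separated CSV *type
tables* (shared node/edge attributes keyed by an integer type id) and
two HDF5 *instance tables* (per-node and per-edge attributes, split
into populations and homogeneous groups). JSON configuration files tie
the pieces together; HDF5 activity files carry spike trains and
frame/trace element reports. `circuitio` implements all of these plus
edge orderings with range indices, a structural validator, and a
synthetic generator so everything is testable without external data.

## Library overview

| module | contents |
| --- | --- |
| `circuitio.model` | in-memory circuit model; `resolve_node` / `resolve_edge` overlay type-level and instance-level attributes (instance wins), `evaluate_node_set` filters nodes by predicate |
| `circuitio.io` | CSV type tables, HDF5 node/edge files, `sort_edges` (target-major / source-major / hybrid block ordering), `build_edge_index` / `query_edges` range indices |
| `circuitio.config` | primary/circuit/simulation JSON configs, `$VAR` manifest substitution, relative-path resolution |
| `circuitio.reports` | spike reports and chunked N×M element reports (rows = frames, columns = traces) with mapping metadata, frame/trace/filtered reads |
| `circuitio.validate` | structural validation of circuits and activity files, returning ordered `Finding` lists |
| `circuitio.synth` | deterministic synthetic circuits (`l4_like_spec`, `generate_circuit`), Poisson spike trains, trace generators, `write_bundle` fixtures |

```python
import circuitio as cio

circuit = cio.generate_circuit(cio.l4_like_spec(0.01, seed=1))
assert cio.validate_circuit(circuit) == []
node = cio.resolve_node(circuit, "core", 0)
print(node.attributes["model_type"])   # "biophysical"
```

## CLI

```sh
circuitio synth --scale 0.01 --seed 1 --out bundle/   # write a fixture bundle
circuitio info bundle/config.json                     # population / type counts
circuitio validate bundle/config.json                 # exit 0 clean, 1 on errors
circuitio sort-edges bundle/network/edges.h5 --order target
circuitio index-edges bundle/network/edges.h5 --by target --by source
circuitio spikes to-csv bundle/inputs/input_spikes.h5 spikes.csv
circuitio report slice bundle/output/soma_report.h5 out.csv --window 0 10
```

Exit codes: 0 success / no validation errors, 1 validation errors
found, 2 usage or I/O failure.

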