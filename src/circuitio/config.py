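"""Hierarchical JSON configuration: primary, circuit and simulation configs.

A *primary* config points at a circuit config and a simulation config.
The circuit config lists component directories and the network files
(nodes/edges HDF5 plus their CSV type tables); the simulation config
holds run parameters, node sets, inputs, output location and report
definitions.  Each file may carry a ``manifest`` block defining path
variables (``$NAME`` or ``${NAME}``) substituted throughout that file;
relative paths are resolved against the file's own directory.
"""

from __future__ import annotations

import copy
import json
import os
import re
from dataclasses import dataclass, field
from typing import Any, Mapping

VARIABLE_RE = re.compile(r"\$\{([A-Za-z_][A-Za-z0-9_]*)\}|\$([A-Za-z_][A-Za-z0-9_]*)")

#: String keys whose values are treated as filesystem paths.
_PATH_KEY_SUFFIXES = ("_file", "_dir")


class ConfigError(Exception):
    """Base class for configuration errors."""


class ManifestError(ConfigError):
    """Undefined variable or substitution cycle in a manifest."""


def _substitute(text: str, variables: Mapping[str, str]) -> str:
    def repl(match: re.Match) -> str:
        name = match.group(1) or match.group(2)
        if name not in variables:
            raise ManifestError(f"undefined manifest variable ${name}")
        return variables[name]

    return VARIABLE_RE.sub(repl, text)


def resolve_manifest_variables(manifest: Mapping[str, str]) -> dict[str, str]:
    """Resolve inter-variable references within a manifest.

    Raises :class:`ManifestError` on cycles or undefined variables.
    """
    resolved: dict[str, str] = {}
    visiting: set[str] = set()

    def resolve(name: str) -> str:
        if name in resolved:
            return resolved[name]
        if name not in manifest:
            raise ManifestError(f"undefined manifest variable ${name}")
        if name in visiting:
            raise ManifestError(f"manifest substitution cycle through ${name}")
        visiting.add(name)
        text = manifest[name]
        while VARIABLE_RE.search(text):
            def repl(match: re.Match) -> str:
                return resolve(match.group(1) or match.group(2))

            text = VARIABLE_RE.sub(repl, text)
        visiting.discard(name)
        resolved[name] = text
        return text

    for name in manifest:
        resolve(name)
    return resolved


def resolve_manifest(
    manifest: Mapping[str, str],
    values: Mapping[str, str],
    base_dir: str | os.PathLike,
) -> dict[str, str]:
    """Substitute manifest variables into path values and absolutize.

    Every ``$NAME``/``${NAME}`` occurrence in each value is replaced
    (recursively, until no variable remains); relative results are then
    joined to ``base_dir``.
    """
    variables = resolve_manifest_variables(manifest)
    out = {}
    for key, text in values.items():
        text = _substitute(text, variables)
        out[key] = os.path.normpath(os.path.join(os.fspath(base_dir), text))
    return out


def _walk_substitute(obj: Any, variables: Mapping[str, str]) -> Any:
    if isinstance(obj, str):
        return _substitute(obj, variables)
    if isinstance(obj, dict):
        return {k: _walk_substitute(v, variables) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_walk_substitute(v, variables) for v in obj]
    return obj


def _walk_absolutize(obj: Any, base_dir: str, force: bool = False) -> Any:
    if isinstance(obj, dict):
        out = {}
        for key, value in obj.items():
            if isinstance(value, str) and (
                force or any(key.endswith(sfx) for sfx in _PATH_KEY_SUFFIXES)
            ):
                out[key] = os.path.normpath(os.path.join(base_dir, value))
            elif key == "components" and isinstance(value, dict):
                out[key] = _walk_absolutize(value, base_dir, force=True)
            else:
                out[key] = _walk_absolutize(value, base_dir, force=force and not isinstance(value, str))
        return out
    if isinstance(obj, list):
        return [_walk_absolutize(v, base_dir, force=force) for v in obj]
    return obj


def _load_and_resolve(path: str) -> dict:
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a JSON object")
    base_dir = os.path.dirname(os.path.abspath(path))
    variables = resolve_manifest_variables(raw.get("manifest", {}))
    resolved = {
        k: _walk_substitute(v, variables) for k, v in raw.items() if k != "manifest"
    }
    return _walk_absolutize(resolved, base_dir)


@dataclass
class CircuitConfig:
    """Resolved circuit half of a configuration bundle."""

    components: dict[str, str] = field(default_factory=dict)
    nodes: list[dict[str, str]] = field(default_factory=list)
    edges: list[dict[str, str]] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)
    path: str | None = None
    raw: dict | None = None

    @classmethod
    def from_dict(cls, doc: dict, path: str | None = None, raw: dict | None = None) -> "CircuitConfig":
        networks = doc.get("networks", {})
        if not isinstance(networks, dict):
            raise ConfigError("circuit config: 'networks' must be an object")
        known = {"components", "networks"}
        return cls(
            components=dict(doc.get("components", {})),
            nodes=list(networks.get("nodes", [])),
            edges=list(networks.get("edges", [])),
            extras={k: v for k, v in doc.items() if k not in known},
            path=path,
            raw=raw,
        )

    def to_dict(self) -> dict:
        doc: dict[str, Any] = dict(self.extras)
        if self.components:
            doc["components"] = dict(self.components)
        doc["networks"] = {"nodes": list(self.nodes), "edges": list(self.edges)}
        return doc


@dataclass
class SimulationConfig:
    """Resolved simulation half of a configuration bundle."""

    tstop: float = 0.0
    dt: float = 0.0
    seed: int | None = None
    run_extras: dict[str, Any] = field(default_factory=dict)
    conditions: dict[str, Any] = field(default_factory=dict)
    node_sets: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, Any] = field(default_factory=dict)
    output: dict[str, Any] = field(default_factory=dict)
    reports: dict[str, Any] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)
    path: str | None = None
    raw: dict | None = None

    @classmethod
    def from_dict(cls, doc: dict, path: str | None = None, raw: dict | None = None) -> "SimulationConfig":
        run = dict(doc.get("run", {}))
        if "tstop" in run:
            tstop = run.pop("tstop")
        elif "duration" in run:
            tstop = run.pop("duration")
        else:
            raise ConfigError("simulation config: run block lacks tstop/duration")
        if "dt" not in run:
            raise ConfigError("simulation config: run block lacks dt")
        dt = run.pop("dt")
        seed = run.pop("seed", None)
        known = {"run", "conditions", "node_sets", "inputs", "output", "reports"}
        cfg = cls(
            tstop=float(tstop),
            dt=float(dt),
            seed=None if seed is None else int(seed),
            run_extras=run,
            conditions=dict(doc.get("conditions", {})),
            node_sets=dict(doc.get("node_sets", {})),
            inputs=dict(doc.get("inputs", {})),
            output=dict(doc.get("output", {})),
            reports=dict(doc.get("reports", {})),
            extras={k: v for k, v in doc.items() if k not in known},
            path=path,
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.tstop > 0:
            raise ConfigError(f"run.tstop must be positive, got {self.tstop}")
        if not self.dt > 0:
            raise ConfigError(f"run.dt must be positive, got {self.dt}")
        for name, report in self.reports.items():
            cells = report.get("cells")
            if isinstance(cells, str) and cells not in self.node_sets:
                raise ConfigError(
                    f"report {name!r} references undefined node set {cells!r}"
                )

    @property
    def n_timesteps(self) -> int:
        """Number of simulation frames, round(tstop / dt)."""
        return int(round(self.tstop / self.dt))

    def to_dict(self) -> dict:
        run: dict[str, Any] = {"tstop": self.tstop, "dt": self.dt}
        if self.seed is not None:
            run["seed"] = self.seed
        run.update(self.run_extras)
        doc: dict[str, Any] = dict(self.extras)
        doc["run"] = run
        doc["conditions"] = dict(self.conditions)
        doc["node_sets"] = dict(self.node_sets)
        doc["inputs"] = dict(self.inputs)
        doc["output"] = dict(self.output)
        doc["reports"] = dict(self.reports)
        return doc


@dataclass
class ConfigBundle:
    """A resolved circuit + simulation configuration pair."""

    circuit: CircuitConfig | None = None
    simulation: SimulationConfig | None = None
    provenance: list[str] = field(default_factory=list)


def _classify(doc: dict) -> str:
    if "networks" in doc or "components" in doc:
        return "circuit"
    if "run" in doc or "reports" in doc or "inputs" in doc:
        return "simulation"
    if isinstance(doc.get("network"), str) or isinstance(doc.get("simulation"), str):
        return "primary"
    raise ConfigError("cannot classify config file (not primary/circuit/simulation)")


def load_config(path: str | os.PathLike) -> ConfigBundle:
    """Load a primary config (or a lone circuit/simulation config).

    Manifest variables are applied per file, paths are absolutized
    relative to each file's own directory, and simulation invariants
    are checked.  A lone circuit or simulation config yields a bundle
    with the other half set to ``None``.
    """
    path = os.path.abspath(os.fspath(path))
    doc = _load_and_resolve(path)
    kind = _classify(doc)
    bundle = ConfigBundle(provenance=[path])
    if kind == "primary":
        base_dir = os.path.dirname(path)
        for key, setter in (("network", "circuit"), ("simulation", "simulation")):
            if key not in doc:
                raise ConfigError(f"primary config lacks {key!r} key")
            child = os.path.normpath(os.path.join(base_dir, doc[key]))
            sub = load_config(child)
            if setter == "circuit":
                bundle.circuit = sub.circuit
            else:
                bundle.simulation = sub.simulation
            bundle.provenance.extend(sub.provenance)
        return bundle
    raw = json.load(open(path))
    if kind == "circuit":
        bundle.circuit = CircuitConfig.from_dict(doc, path=path, raw=raw)
    else:
        bundle.simulation = SimulationConfig.from_dict(doc, path=path, raw=raw)
    return bundle


def load_config_pair(
    circuit_path: str | os.PathLike, simulation_path: str | os.PathLike
) -> ConfigBundle:
    """Load a circuit config and a simulation config as one bundle."""
    circuit = load_config(circuit_path)
    simulation = load_config(simulation_path)
    if circuit.circuit is None:
        raise ConfigError(f"{circuit_path} is not a circuit config")
    if simulation.simulation is None:
        raise ConfigError(f"{simulation_path} is not a simulation config")
    return ConfigBundle(
        circuit=circuit.circuit,
        simulation=simulation.simulation,
        provenance=circuit.provenance + simulation.provenance,
    )


def write_config(bundle: ConfigBundle, directory: str | os.PathLike) -> str:
    """Write ``bundle`` as circuit.json + simulation.json + config.json.

    If a half still carries its raw (unresolved) document, that is
    written verbatim so manifest variables survive the round trip.
    Returns the path of the primary config.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    if bundle.circuit is None or bundle.simulation is None:
        raise ConfigError("write_config requires both bundle halves")
    circuit_doc = (
        copy.deepcopy(bundle.circuit.raw)
        if bundle.circuit.raw is not None
        else bundle.circuit.to_dict()
    )
    simulation_doc = (
        copy.deepcopy(bundle.simulation.raw)
        if bundle.simulation.raw is not None
        else bundle.simulation.to_dict()
    )
    paths = {}
    for name, doc in (("circuit", circuit_doc), ("simulation", simulation_doc)):
        paths[name] = os.path.join(directory, f"{name}.json")
        with open(paths[name], "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    primary = os.path.join(directory, "config.json")
    with open(primary, "w") as fh:
        json.dump({"network": "circuit.json", "simulation": "simulation.json"}, fh, indent=2)
        fh.write("\n")
    return primary
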