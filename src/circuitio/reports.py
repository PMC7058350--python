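"""Activity I/O: spike-train reports and element (frame/trace) reports.

Spike files store, per population, two equal-length datasets under
``/spikes/<population>/``: ``timestamps`` (ms) and ``node_ids``, with a
``sorting`` attribute in {none, by_time, by_id}.

Element reports store a chunked ``N x M`` matrix under
``/report/<population>/data`` — rows are *frames* (all values at one
timestamp), columns are *traces* (one element's time series) — plus a
``mapping`` group with ``node_ids`` (order of appearance, not
necessarily sorted), ``index_pointer`` (each node's first column, with
a terminal ``M``), ``element_ids``, optional ``element_pos`` and
``time = [tstart, tstop, dt]``.  All elements of one node occupy
contiguous columns.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import h5py
import numpy as np

from .model import CircuitError

SORTINGS = ("none", "by_time", "by_id")

#: Relative tolerance used when deriving the frame count from tstop/dt.
_FRAME_RTOL = 1e-9


class ReportError(CircuitError):
    """Invalid report structure or access."""


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

@dataclass
class SpikeReport:
    """Paired (node id, spike time) event lists for one population."""

    population: str
    node_ids: np.ndarray
    timestamps: np.ndarray
    sorting: str = "none"

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.timestamps)

    def validate(self) -> None:
        if self.sorting not in SORTINGS:
            raise ReportError(f"unknown sorting mode {self.sorting!r}")
        if len(self.node_ids) != len(self.timestamps):
            raise ReportError(
                f"node_ids/timestamps length mismatch: "
                f"{len(self.node_ids)} != {len(self.timestamps)}"
            )
        if len(self.timestamps) and self.timestamps.min() < 0:
            raise ReportError("negative spike timestamp")
        if self.sorting == "by_time" and len(self) > 1:
            if np.any(np.diff(self.timestamps) < 0):
                raise ReportError("sorting=by_time but timestamps decrease")


def write_spikes(
    reports: SpikeReport | Iterable[SpikeReport], path: str | os.PathLike
) -> None:
    """Write one or more spike reports to an HDF5 file (overwrites)."""
    if isinstance(reports, SpikeReport):
        reports = [reports]
    with h5py.File(path, "w") as fh:
        root = fh.create_group("spikes")
        for report in reports:
            report.validate()
            grp = root.create_group(report.population)
            grp.attrs["sorting"] = report.sorting
            grp.create_dataset("timestamps", data=report.timestamps)
            grp.create_dataset("node_ids", data=report.node_ids)


def read_spikes(
    path: str | os.PathLike,
    population: str | None = None,
    node_ids: Sequence[int] | None = None,
    window: tuple[float, float] | None = None,
) -> SpikeReport:
    """Read one population's spikes, optionally filtered.

    ``node_ids`` keeps only events of those nodes; ``window=(t0, t1)``
    keeps events with ``t0 <= t < t1``.  With a single population in
    the file, ``population`` may be omitted.
    """
    with h5py.File(path, "r") as fh:
        if "spikes" not in fh:
            raise ReportError(f"{path}: missing /spikes root group")
        root = fh["spikes"]
        names = sorted(root)
        if population is None:
            if len(names) != 1:
                raise ReportError(
                    f"{path}: {len(names)} populations present, name one of {names}"
                )
            population = names[0]
        if population not in root:
            raise ReportError(f"{path}: no spike population {population!r}")
        grp = root[population]
        timestamps = grp["timestamps"][...]
        ids = grp["node_ids"][...]
        if len(timestamps) != len(ids):
            raise ReportError(f"{path}: spike column length mismatch")
        sorting = str(grp.attrs.get("sorting", "none"))
    mask = np.ones(len(timestamps), dtype=bool)
    if node_ids is not None:
        mask &= np.isin(ids, np.asarray(list(node_ids)))
    if window is not None:
        t0, t1 = window
        mask &= (timestamps >= t0) & (timestamps < t1)
    return SpikeReport(
        population=population,
        node_ids=ids[mask],
        timestamps=timestamps[mask],
        sorting=sorting,
    )


def spikes_to_csv(report: SpikeReport, path: str | os.PathLike) -> None:
    """Export spikes as ``node_id time`` lines (space-separated, header)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=" ", lineterminator="\n")
        writer.writerow(["node_id", "time"])
        for nid, t in zip(report.node_ids, report.timestamps):
            writer.writerow([int(nid), repr(float(t))])


def spikes_from_csv(path: str | os.PathLike, population: str) -> SpikeReport:
    """Import spikes from the CSV layout written by :func:`spikes_to_csv`."""
    node_ids, times = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=" ")
        header = next(reader, None)
        if header is None or header[:2] != ["node_id", "time"]:
            raise ReportError(f"{path}: expected 'node_id time' header")
        for row in reader:
            if not row:
                continue
            node_ids.append(int(row[0]))
            times.append(float(row[1]))
    return SpikeReport(population=population, node_ids=node_ids, timestamps=times)


# ---------------------------------------------------------------------------
# Element mapping
# ---------------------------------------------------------------------------

@dataclass
class ElementMapping:
    """Column mapping of an element report.

    ``node_ids`` lists recorded nodes in order of appearance;
    ``offsets`` has one more entry, giving each node's first column and
    a terminal total ``M``.  ``element_ids`` (length ``M``) identifies
    each element within its node; ``element_pos``, when present, aligns
    1:1 with ``element_ids``.
    """

    node_ids: np.ndarray
    offsets: np.ndarray
    element_ids: np.ndarray
    element_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.offsets = np.asarray(self.offsets, dtype=np.int64)
        self.element_ids = np.asarray(self.element_ids, dtype=np.int64)
        if self.element_pos is not None:
            self.element_pos = np.asarray(self.element_pos, dtype=np.float64)

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)

    def validate(self) -> None:
        if len(self.offsets) != len(self.node_ids) + 1:
            raise ReportError("offsets must have len(node_ids)+1 entries")
        if len(self.offsets) == 0 or self.offsets[0] != 0:
            raise ReportError("offsets must start at 0")
        if np.any(np.diff(self.offsets) <= 0):
            raise ReportError("offsets must be strictly increasing")
        if self.offsets[-1] != self.n_elements:
            raise ReportError("offsets must end at the total element count")
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ReportError("duplicate node id in mapping")
        if self.element_pos is not None and len(self.element_pos) != self.n_elements:
            raise ReportError("element_pos must align 1:1 with element_ids")


def build_mapping(
    per_node_elements: Sequence[tuple[int, Sequence[tuple[int, float | None]]]],
) -> ElementMapping:
    """Build a mapping from an ordered per-node element listing.

    ``per_node_elements`` is a sequence of ``(node_id, elements)``
    where ``elements`` is a non-empty sequence of ``(element_id,
    element_pos_or_None)``.  Node order is preserved as given.  Either
    all positions are given or none are.
    """
    node_ids: list[int] = []
    offsets = [0]
    element_ids: list[int] = []
    element_pos: list[float] = []
    have_pos = None
    for node_id, elements in per_node_elements:
        if node_id in node_ids:
            raise ReportError(f"duplicate node {node_id} in mapping input")
        if len(elements) == 0:
            raise ReportError(f"node {node_id} has zero elements")
        node_ids.append(int(node_id))
        for element_id, pos in elements:
            element_ids.append(int(element_id))
            this_pos = pos is not None
            if have_pos is None:
                have_pos = this_pos
            elif have_pos != this_pos:
                raise ReportError("element_pos must be given for all elements or none")
            if this_pos:
                element_pos.append(float(pos))
        offsets.append(len(element_ids))
    mapping = ElementMapping(
        node_ids=np.asarray(node_ids, dtype=np.int64),
        offsets=np.asarray(offsets, dtype=np.int64),
        element_ids=np.asarray(element_ids, dtype=np.int64),
        element_pos=np.asarray(element_pos) if have_pos else None,
    )
    mapping.validate()
    return mapping


def columns_for_node(mapping: ElementMapping, node_id: int) -> tuple[int, int]:
    """Half-open column interval holding ``node_id``'s elements."""
    hits = np.flatnonzero(mapping.node_ids == node_id)
    if hits.size == 0:
        raise ReportError(f"node {node_id} not present in mapping")
    k = int(hits[0])
    return int(mapping.offsets[k]), int(mapping.offsets[k + 1])


# ---------------------------------------------------------------------------
# Element reports
# ---------------------------------------------------------------------------

def frame_count(tstart: float, tstop: float, dt: float) -> int:
    """Number of frames, round((tstop - tstart) / dt) with 1e-9 rtol."""
    if dt <= 0:
        raise ReportError(f"dt must be positive, got {dt}")
    if tstop <= tstart:
        raise ReportError(f"empty time range [{tstart}, {tstop}]")
    exact = (tstop - tstart) / dt
    n = int(round(exact))
    if n < 1 or abs(exact - n) > _FRAME_RTOL * max(1.0, abs(exact)):
        n = int(np.ceil(exact - _FRAME_RTOL))
    return max(n, 1)


@dataclass
class ElementReport:
    """In-memory element report: mapping + time block + N x M matrix."""

    mapping: ElementMapping
    tstart: float
    tstop: float
    dt: float
    data: np.ndarray
    variable: str = "v"
    units: str = ""
    population: str = "default"

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame_time(self, row: int) -> float:
        return self.tstart + row * self.dt


class ElementReportWriter:
    """Writable handle over a freshly created element-report file.

    Frames are appended in order; the cursor advances by the number of
    rows written.  Use as a context manager or call :meth:`close`.
    """

    def __init__(
        self,
        path: str | os.PathLike,
        mapping: ElementMapping,
        tstart: float,
        tstop: float,
        dt: float,
        chunk_shape: tuple[int, int] | None = None,
        population: str = "default",
        variable: str = "v",
        units: str = "",
    ):
        mapping.validate()
        self.n_frames = frame_count(tstart, tstop, dt)
        self.n_elements = mapping.n_elements
        if chunk_shape is None:
            chunk_shape = (min(self.n_frames, 1024), min(self.n_elements, 512))
        c0, c1 = int(chunk_shape[0]), int(chunk_shape[1])
        if c0 < 1 or c1 < 1:
            raise ReportError(f"chunk dimensions must be >= 1, got {chunk_shape}")
        chunks: tuple[int, int] | None
        chunks = (min(c0, self.n_frames), min(c1, self.n_elements))
        if 0 in chunks:
            chunks = None
        self._cursor = 0
        self._fh = h5py.File(path, "w")
        grp = self._fh.create_group(f"report/{population}")
        self._data = grp.create_dataset(
            "data",
            shape=(self.n_frames, self.n_elements),
            dtype=np.float64,
            chunks=chunks,
        )
        self._data.attrs["variable"] = variable
        self._data.attrs["units"] = units
        mgrp = grp.create_group("mapping")
        mgrp.create_dataset("node_ids", data=mapping.node_ids)
        mgrp.create_dataset("index_pointer", data=mapping.offsets)
        mgrp.create_dataset("element_ids", data=mapping.element_ids)
        if mapping.element_pos is not None:
            mgrp.create_dataset("element_pos", data=mapping.element_pos)
        mgrp.create_dataset("time", data=np.asarray([tstart, tstop, dt], dtype=np.float64))

    def append_frames(self, block: np.ndarray) -> None:
        """Append a (k, M) block of frames at the write cursor."""
        block = np.asarray(block, dtype=np.float64)
        if block.ndim == 1:
            block = block.reshape(1, -1)
        if block.size == 0 and block.shape[0] == 0:
            return
        if block.shape[1] != self.n_elements:
            raise ReportError(
                f"frame width {block.shape[1]} != {self.n_elements} elements"
            )
        if self._cursor + block.shape[0] > self.n_frames:
            raise ReportError(
                f"writing {block.shape[0]} frames at {self._cursor} overflows "
                f"{self.n_frames}"
            )
        self._data[self._cursor : self._cursor + block.shape[0]] = block
        self._cursor += block.shape[0]

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None

    def __enter__(self) -> "ElementReportWriter":
        return self

    def __exit__(self, *exc: Any) -> None:
        self.close()


def create_element_report(
    path: str | os.PathLike,
    mapping: ElementMapping,
    tstart: float,
    tstop: float,
    dt: float,
    chunk_shape: tuple[int, int] | None = None,
    population: str = "default",
    variable: str = "v",
    units: str = "",
) -> ElementReportWriter:
    """Create an element-report file and return its writable handle."""
    return ElementReportWriter(
        path, mapping, tstart, tstop, dt, chunk_shape, population, variable, units
    )


def write_element_report(
    report: ElementReport, path: str | os.PathLike,
    chunk_shape: tuple[int, int] | None = None,
) -> None:
    """Write a fully populated in-memory report in one go."""
    with create_element_report(
        path,
        report.mapping,
        report.tstart,
        report.tstop,
        report.dt,
        chunk_shape=chunk_shape,
        population=report.population,
        variable=report.variable,
        units=report.units,
    ) as writer:
        writer.append_frames(report.data)


def open_element_report(
    path: str | os.PathLike, population: str | None = None
) -> ElementReport:
    """Load an element report (data and mapping) into memory."""
    with h5py.File(path, "r") as fh:
        if "report" not in fh:
            raise ReportError(f"{path}: missing /report root group")
        root = fh["report"]
        names = sorted(root)
        if population is None:
            if len(names) != 1:
                raise ReportError(
                    f"{path}: {len(names)} report populations, name one of {names}"
                )
            population = names[0]
        if population not in root:
            raise ReportError(f"{path}: no report population {population!r}")
        grp = root[population]
        data = grp["data"][...]
        mgrp = grp["mapping"]
        tstart, tstop, dt = (float(x) for x in mgrp["time"][...])
        mapping = ElementMapping(
            node_ids=mgrp["node_ids"][...],
            offsets=mgrp["index_pointer"][...],
            element_ids=mgrp["element_ids"][...],
            element_pos=mgrp["element_pos"][...] if "element_pos" in mgrp else None,
        )
        return ElementReport(
            mapping=mapping,
            tstart=tstart,
            tstop=tstop,
            dt=dt,
            data=data,
            variable=str(grp["data"].attrs.get("variable", "")),
            units=str(grp["data"].attrs.get("units", "")),
            population=population,
        )


# ---------------------------------------------------------------------------
# Slicing
# ---------------------------------------------------------------------------

def _resolve_columns(
    mapping: ElementMapping,
    node_ids: Sequence[int] | None,
    element_ids: Sequence[int] | None,
    element_pos: tuple[float, float] | None,
) -> np.ndarray:
    """Columns selected by node membership and element filters, in
    stored (mapping) order."""
    if node_ids is None:
        wanted = mapping.node_ids
    else:
        wanted = list(node_ids)
    cols: list[int] = []
    for nid in wanted:
        start, end = columns_for_node(mapping, int(nid))
        for c in range(start, end):
            if element_ids is not None and mapping.element_ids[c] not in element_ids:
                continue
            if element_pos is not None:
                if mapping.element_pos is None:
                    raise ReportError("report has no element_pos to filter on")
                p0, p1 = element_pos
                if not (p0 <= mapping.element_pos[c] < p1):
                    continue
            cols.append(c)
    return np.asarray(cols, dtype=np.int64)


def _window_rows(
    report: ElementReport, window: tuple[float, float] | None
) -> tuple[int, int]:
    n = report.n_frames
    if window is None:
        return 0, n
    t0, t1 = window
    eps = _FRAME_RTOL
    r0 = int(np.ceil((t0 - report.tstart) / report.dt - eps))
    r1 = int(np.ceil((t1 - report.tstart) / report.dt - eps))
    return max(r0, 0), min(max(r1, 0), n)


def read_frames(
    report: ElementReport,
    window: tuple[float, float] | None = None,
    node_ids: Sequence[int] | None = None,
    element_ids: Sequence[int] | None = None,
    element_pos: tuple[float, float] | None = None,
) -> np.ndarray:
    """Read a submatrix of frames.

    Rows cover times ``t0 <= t < t1`` (all frames when ``window`` is
    None); columns are the elements of the selected nodes passing the
    element filters.  An empty window is legal and yields an empty
    result.
    """
    r0, r1 = _window_rows(report, window)
    cols = _resolve_columns(report.mapping, node_ids, element_ids, element_pos)
    return report.data[r0:r1][:, cols]


def read_trace(
    report: ElementReport,
    node_id: int,
    element_ids: Sequence[int] | None = None,
    element_pos: tuple[float, float] | None = None,
) -> np.ndarray:
    """Full time series (all frames) of one node's selected elements."""
    cols = _resolve_columns(report.mapping, [node_id], element_ids, element_pos)
    return report.data[:, cols]


@dataclass
class Selection:
    """A reusable read selection resolving to (row range, column set)."""

    node_ids: Sequence[int] | None = None
    element_ids: Sequence[int] | None = None
    element_pos: tuple[float, float] | None = None
    window: tuple[float, float] | None = None

    def resolve(self, report: ElementReport) -> tuple[tuple[int, int], np.ndarray]:
        rows = _window_rows(report, self.window)
        cols = _resolve_columns(
            report.mapping, self.node_ids, self.element_ids, self.element_pos
        )
        return rows, cols

    def apply(self, report: ElementReport) -> np.ndarray:
        (r0, r1), cols = self.resolve(report)
        return report.data[r0:r1][:, cols]
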