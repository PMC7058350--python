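import numpy as np
import pytest

from circuitio.reports import (
    ElementMapping,
    ReportError,
    Selection,
    SpikeReport,
    build_mapping,
    columns_for_node,
    create_element_report,
    frame_count,
    open_element_report,
    read_frames,
    read_spikes,
    read_trace,
    spikes_from_csv,
    spikes_to_csv,
    write_element_report,
    write_spikes,
)
from circuitio.reports import ElementReport


class TestSpikes:
    @pytest.mark.parametrize("sorting", ["none", "by_time", "by_id"])
    def test_three_event_roundtrip(self, tmp_path, sorting):
        report = SpikeReport("p", [3, 1, 2], [0.5, 1.5, 2.5], sorting=sorting)
        path = tmp_path / "spikes.h5"
        write_spikes(report, path)
        back = read_spikes(path)
        np.testing.assert_array_equal(back.node_ids, [3, 1, 2])
        np.testing.assert_array_equal(back.timestamps, [0.5, 1.5, 2.5])
        assert back.sorting == sorting
        assert back.population == "p"

    def test_empty_roundtrip(self, tmp_path):
        report = SpikeReport("p", [], [])
        path = tmp_path / "spikes.h5"
        write_spikes(report, path)
        back = read_spikes(path)
        assert len(back) == 0

    def test_negative_timestamp_rejected(self, tmp_path):
        report = SpikeReport("p", [0], [-1.0])
        with pytest.raises(ReportError):
            write_spikes(report, tmp_path / "s.h5")

    def test_by_time_must_be_sorted(self, tmp_path):
        report = SpikeReport("p", [0, 1], [2.0, 1.0], sorting="by_time")
        with pytest.raises(ReportError):
            write_spikes(report, tmp_path / "s.h5")

    def test_window_filter_matches_linear_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        times = rng.uniform(0, 1000, 10_000)
        ids = rng.integers(0, 50, 10_000)
        write_spikes(SpikeReport("p", ids, times), tmp_path / "s.h5")
        back = read_spikes(tmp_path / "s.h5", window=(100.0, 200.0))
        oracle = sum(1 for t in times if 100.0 <= t < 200.0)
        assert len(back) == oracle
        assert np.all((back.timestamps >= 100.0) & (back.timestamps < 200.0))

    def test_node_filter(self, tmp_path):
        rng = np.random.default_rng(1)
        times = rng.uniform(0, 100, 1000)
        ids = rng.integers(0, 10, 1000)
        write_spikes(SpikeReport("p", ids, times), tmp_path / "s.h5")
        back = read_spikes(tmp_path / "s.h5", node_ids=[2, 5])
        oracle = sum(1 for i in ids if i in (2, 5))
        assert len(back) == oracle

    def test_roundtrip_preserves_multiset(self, tmp_path):
        rng = np.random.default_rng(2)
        times = rng.uniform(0, 10, 500)
        ids = rng.integers(0, 20, 500)
        write_spikes(SpikeReport("p", ids, times), tmp_path / "s.h5")
        back = read_spikes(tmp_path / "s.h5")
        assert sorted(zip(back.node_ids, back.timestamps)) == sorted(zip(ids, times))

    def test_csv_roundtrip(self, tmp_path):
        report = SpikeReport("p", [4, 2, 9], [0.25, 7.5, 3.125])
        spikes_to_csv(report, tmp_path / "s.csv")
        back = spikes_from_csv(tmp_path / "s.csv", "p")
        np.testing.assert_array_equal(back.node_ids, report.node_ids)
        np.testing.assert_array_equal(back.timestamps, report.timestamps)


class TestMapping:
    def test_single_node_single_element(self):
        mapping = build_mapping([(7, [(0, None)])])
        assert mapping.n_elements == 1
        np.testing.assert_array_equal(mapping.offsets, [0, 1])

    def test_cumulative_sum_oracle(self):
        per_node = [(5, [(0, None), (1, None)]), (2, [(0, None), (1, None), (2, None)])]
        mapping = build_mapping(per_node)
        counts = [len(elems) for _, elems in per_node]
        oracle_offsets = [0] + list(np.cumsum(counts))
        np.testing.assert_array_equal(mapping.offsets, oracle_offsets)
        assert mapping.n_elements == 5
        np.testing.assert_array_equal(mapping.node_ids, [5, 2])  # order preserved

    def test_node_with_three_variables(self):
        mapping = build_mapping([(0, [(0, None), (1, None), (2, None)])])
        start, end = columns_for_node(mapping, 0)
        assert end - start == 3

    def test_duplicate_node_rejected(self):
        with pytest.raises(ReportError):
            build_mapping([(1, [(0, None)]), (1, [(0, None)])])

    def test_zero_elements_rejected(self):
        with pytest.raises(ReportError):
            build_mapping([(1, [])])

    def test_mixed_pos_rejected(self):
        with pytest.raises(ReportError):
            build_mapping([(1, [(0, 0.5), (1, None)])])

    def test_columns_for_node(self):
        mapping = build_mapping([(5, [(0, None), (1, None)]), (2, [(0, None)] * 3)])
        assert columns_for_node(mapping, 5) == (0, 2)
        assert columns_for_node(mapping, 2) == (2, 5)
        with pytest.raises(ReportError):
            columns_for_node(mapping, 99)

    def test_intervals_partition_columns(self):
        rng = np.random.default_rng(3)
        per_node = [
            (int(nid), [(int(e), None) for e in range(rng.integers(1, 5))])
            for nid in rng.permutation(20)
        ]
        mapping = build_mapping(per_node)
        total = sum(
            columns_for_node(mapping, nid)[1] - columns_for_node(mapping, nid)[0]
            for nid, _ in per_node
        )
        assert total == mapping.n_elements


def random_report(rng, n_nodes=5, max_elems=4, n_frames=20, with_pos=True):
    per_node = []
    for nid in rng.permutation(100)[:n_nodes]:
        k = int(rng.integers(1, max_elems + 1))
        per_node.append(
            (
                int(nid),
                [
                    (e, float(rng.uniform()) if with_pos else None)
                    for e in range(k)
                ],
            )
        )
    mapping = build_mapping(per_node)
    dt = 0.1
    data = rng.normal(size=(n_frames, mapping.n_elements))
    return ElementReport(
        mapping=mapping, tstart=0.0, tstop=n_frames * dt, dt=dt, data=data
    )


class TestElementReportIO:
    def test_frame_count_arithmetic(self):
        assert frame_count(0.0, 1.0, 0.1) == 10
        assert frame_count(5.0, 6.0, 0.25) == 4

    def test_empty_duration_rejected(self):
        with pytest.raises(ReportError):
            frame_count(1.0, 1.0, 0.1)
        with pytest.raises(ReportError):
            frame_count(0.0, 1.0, 0.0)

    def test_chunked_write_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        report = random_report(rng, n_frames=10)
        path = tmp_path / "r.h5"
        m = report.mapping.n_elements
        write_element_report(report, path, chunk_shape=(4, m))
        back = open_element_report(path)
        np.testing.assert_array_equal(back.data, report.data)
        np.testing.assert_array_equal(back.mapping.node_ids, report.mapping.node_ids)
        np.testing.assert_array_equal(back.mapping.offsets, report.mapping.offsets)
        np.testing.assert_array_equal(
            back.mapping.element_ids, report.mapping.element_ids
        )
        np.testing.assert_array_equal(
            back.mapping.element_pos, report.mapping.element_pos
        )
        assert (back.tstart, back.tstop, back.dt) == (0.0, 1.0, 0.1)

    def test_append_in_blocks(self, tmp_path):
        """10x4 matrix written as 4+4+2 rows reads back identically."""
        rng = np.random.default_rng(5)
        mapping = build_mapping([(0, [(e, None) for e in range(4)])])
        matrix = rng.normal(size=(10, 4))
        path = tmp_path / "r.h5"
        with create_element_report(path, mapping, 0.0, 1.0, 0.1) as writer:
            writer.append_frames(matrix[:4])
            writer.append_frames(matrix[4:8])
            writer.append_frames(matrix[8:])
        back = open_element_report(path)
        np.testing.assert_array_equal(back.data, matrix)

    def test_zero_row_block_noop(self, tmp_path):
        mapping = build_mapping([(0, [(0, None)])])
        path = tmp_path / "r.h5"
        with create_element_report(path, mapping, 0.0, 0.2, 0.1) as writer:
            writer.append_frames(np.empty((0, 1)))
            writer.append_frames(np.ones((2, 1)))

    def test_wrong_width_rejected(self, tmp_path):
        mapping = build_mapping([(0, [(0, None), (1, None)])])
        with create_element_report(tmp_path / "r.h5", mapping, 0.0, 1.0, 0.5) as w:
            with pytest.raises(ReportError):
                w.append_frames(np.ones((1, 3)))
            with pytest.raises(ReportError):
                w.append_frames(np.ones((1, 1)))

    def test_overflow_rejected(self, tmp_path):
        mapping = build_mapping([(0, [(0, None)])])
        with create_element_report(tmp_path / "r.h5", mapping, 0.0, 0.2, 0.1) as w:
            w.append_frames(np.ones((2, 1)))
            with pytest.raises(ReportError):
                w.append_frames(np.ones((1, 1)))

    def test_bad_chunk_shape(self, tmp_path):
        mapping = build_mapping([(0, [(0, None)])])
        with pytest.raises(ReportError):
            create_element_report(
                tmp_path / "r.h5", mapping, 0.0, 1.0, 0.1, chunk_shape=(0, 1)
            )


class TestSlicing:
    def test_full_window_all_nodes_is_identity(self, tmp_path):
        rng = np.random.default_rng(6)
        report = random_report(rng)
        np.testing.assert_array_equal(read_frames(report), report.data)

    def test_frame_slice_matches_dense_oracle(self, tmp_path):
        rng = np.random.default_rng(7)
        report = random_report(rng, n_nodes=7, n_frames=20)
        nid = int(report.mapping.node_ids[3])
        start, end = columns_for_node(report.mapping, nid)
        window = (3 * report.dt, 4 * report.dt)  # exactly frame 3
        got = read_frames(report, window=window, node_ids=[nid])
        np.testing.assert_array_equal(got, report.data[3:4, start:end])

    def test_trace_matches_dense_oracle(self):
        rng = np.random.default_rng(8)
        report = random_report(rng)
        nid = int(report.mapping.node_ids[0])
        start, end = columns_for_node(report.mapping, nid)
        np.testing.assert_array_equal(
            read_trace(report, nid), report.data[:, start:end]
        )

    def test_element_pos_filter(self):
        mapping = build_mapping([(1, [(0, 0.1), (1, 0.7)])])
        data = np.arange(10, dtype=float).reshape(5, 2)
        report = ElementReport(mapping=mapping, tstart=0, tstop=0.5, dt=0.1, data=data)
        got = read_trace(report, 1, element_pos=(0.0, 0.5))
        assert got.shape == (5, 1)
        np.testing.assert_array_equal(got[:, 0], data[:, 0])

    def test_element_id_filter(self):
        mapping = build_mapping([(1, [(0, None), (4, None), (9, None)])])
        data = np.arange(6, dtype=float).reshape(2, 3)
        report = ElementReport(mapping=mapping, tstart=0, tstop=0.2, dt=0.1, data=data)
        got = read_frames(report, node_ids=[1], element_ids=[4, 9])
        np.testing.assert_array_equal(got, data[:, 1:3])

    def test_empty_window_is_legal(self):
        rng = np.random.default_rng(9)
        report = random_report(rng)
        got = read_frames(report, window=(5.0, 5.0))
        assert got.shape[0] == 0

    def test_unknown_node_rejected(self):
        rng = np.random.default_rng(10)
        report = random_report(rng)
        with pytest.raises(ReportError):
            read_trace(report, 10_000)

    def test_selection_object(self):
        rng = np.random.default_rng(11)
        report = random_report(rng, n_frames=30)
        nid = int(report.mapping.node_ids[1])
        sel = Selection(node_ids=[nid], window=(0.5, 1.5))
        start, end = columns_for_node(report.mapping, nid)
        np.testing.assert_array_equal(
            sel.apply(report), report.data[5:15, start:end]
        )

    def test_chunk_invariance(self, tmp_path):
        """Reads are bit-identical across chunk shapes."""
        rng = np.random.default_rng(12)
        report = random_report(rng, n_nodes=6, n_frames=40)
        m = report.mapping.n_elements
        reference = None
        for chunk in [(1, 1), (40, m), (7, max(1, m // 2))]:
            path = tmp_path / f"r_{chunk[0]}_{chunk[1]}.h5"
            write_element_report(report, path, chunk_shape=chunk)
            back = open_element_report(path)
            got = read_frames(back, window=(0.5, 2.5))
            if reference is None:
                reference = got
            else:
                np.testing.assert_array_equal(got, reference)

    def test_order_preserved_without_pos(self):
        """Element order in reads is exactly the stored order."""
        rng = np.random.default_rng(13)
        report = random_report(rng, with_pos=False)
        assert report.mapping.element_pos is None
        for nid in report.mapping.node_ids:
            start, end = columns_for_node(report.mapping, int(nid))
            np.testing.assert_array_equal(
                read_trace(report, int(nid)), report.data[:, start:end]
            )
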