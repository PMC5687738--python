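import shutil

import numpy as np
import pytest

from mzvault import (
    BuildParams,
    MetadataStore,
    MsPoint,
    MzStore,
    PointCache,
    PointFile,
    QueryWindow,
    StoreConfig,
    cache_fetch,
    write_point_file,
)
from mzvault.storage import HEADER_SIZE, RECORD_WIDTH, CorruptionError
from mzvault.tree import iter_leaves

from conftest import point_key, scan_window, uniform_cloud


def mk_points(n, start=0):
    return [MsPoint(start + i, 100.0 + i, 10.0 * i, float(i + 1)) for i in range(n)]


class TestPointFile:
    def test_leaf_offsets_follow_record_arithmetic(self, tmp_path):
        path = tmp_path / "points.bin"
        _, blocks = write_point_file([mk_points(2), mk_points(2, 2)], path)
        assert blocks == [
            (HEADER_SIZE, 2),
            (HEADER_SIZE + 2 * RECORD_WIDTH, 2),
        ]

    def test_empty_leaf_list_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_point_file([], tmp_path / "points.bin")

    def test_round_trip_every_record(self, tmp_path):
        pts = mk_points(100)
        path = tmp_path / "points.bin"
        id_map, _ = write_point_file([pts[:37], pts[37:]], path)
        with PointFile(path) as pf:
            assert pf.count == 100
            for p in pts:
                got = pf.read_point(id_map[p.id])
                assert (got.mz, got.rt, got.intensity) == (p.mz, p.rt, p.intensity)

    def test_random_access_matches_in_memory_copy(self, tmp_path):
        pts = uniform_cloud(8, 10000)
        path = tmp_path / "points.bin"
        id_map, _ = write_point_file([pts], path)
        rng = np.random.default_rng(0)
        with PointFile(path) as pf:
            for i in rng.integers(0, 10000, 50):
                got = pf.read_point(int(i))
                src = pts[int(i)]  # single leaf: ids map to input order
                assert (got.mz, got.rt, got.intensity) == (src.mz, src.rt, src.intensity)

    def test_out_of_range_id_errors(self, tmp_path):
        path = tmp_path / "points.bin"
        write_point_file([mk_points(3)], path)
        with PointFile(path) as pf:
            with pytest.raises(IndexError):
                pf.read_point(3)
            with pytest.raises(IndexError):
                pf.read_point(-1)

    def test_block_read_equals_single_reads_and_conserves(self, tmp_path):
        pts = mk_points(50)
        leaves = [pts[:20], pts[20:45], pts[45:]]
        path = tmp_path / "points.bin"
        _, blocks = write_point_file(leaves, path)
        with PointFile(path) as pf:
            recovered = []
            for offset, count in blocks:
                first = (offset - HEADER_SIZE) // RECORD_WIDTH
                block = pf.read_block(offset, count, first)
                assert block == [pf.read_point(p.id) for p in block]
                recovered.extend(block)
            assert [(p.mz, p.rt, p.intensity) for p in recovered] == [
                (p.mz, p.rt, p.intensity) for p in pts
            ]

    def test_truncated_file_is_detected(self, tmp_path):
        path = tmp_path / "points.bin"
        write_point_file([mk_points(10)], path)
        whole = path.read_bytes()
        path.write_bytes(whole[: HEADER_SIZE + 5 * RECORD_WIDTH])
        with pytest.raises(CorruptionError):
            PointFile(path)

    def test_bad_block_range_is_detected(self, tmp_path):
        path = tmp_path / "points.bin"
        write_point_file([mk_points(4)], path)
        with PointFile(path) as pf:
            with pytest.raises(CorruptionError):
                pf.read_block(HEADER_SIZE, 10, 0)


class TestPointCache:
    def backing(self, tmp_path, n=10):
        path = tmp_path / "points.bin"
        write_point_file([mk_points(n)], path)
        return PointFile(path)

    def test_lru_eviction_by_hand(self, tmp_path):
        pf = self.backing(tmp_path)
        cache = PointCache(2 * RECORD_WIDTH)  # room for 2 points
        for i in (1, 2, 3):
            cache_fetch(cache, [i], pf)
        assert cache.misses == 3 and cache.hits == 0
        # 1 was least recently used, so it must have been evicted
        cache_fetch(cache, [1], pf)
        assert cache.misses == 4
        # 3 stayed resident
        cache_fetch(cache, [3], pf)
        assert cache.hits == 1

    def test_hit_returns_field_identical_point(self, tmp_path):
        pf = self.backing(tmp_path)
        cache = PointCache(10 * RECORD_WIDTH)
        first = cache_fetch(cache, [4], pf)[0]
        again = cache_fetch(cache, [4], pf)[0]
        assert cache.hits == 1
        assert first == again == pf.read_point(4)

    def test_zero_capacity_disables_caching_without_changing_results(self, tmp_path):
        pf = self.backing(tmp_path)
        cache = PointCache(0)
        out = cache_fetch(cache, [0, 5, 9, 5], pf)
        assert len(cache) == 0
        assert out == [pf.read_point(i) for i in (0, 5, 9, 5)]

    def test_resident_size_never_exceeds_budget(self, tmp_path):
        pf = self.backing(tmp_path, n=10)
        cache = PointCache(3 * RECORD_WIDTH)
        rng = np.random.default_rng(1)
        for i in rng.integers(0, 10, 200):
            cache_fetch(cache, [int(i)], pf)
            assert cache.resident_bytes <= cache.capacity_bytes


class TestMetadata:
    def test_assign_trace_visible_to_next_query(self, tiny_store):
        ids = [p.id for p in tiny_store.query(QueryWindow.covering(tiny_store.bounds))][:3]
        assert tiny_store.assign_trace(ids, 7) == 3
        got = {
            p.id: p.trace_id
            for p in tiny_store.query(QueryWindow.covering(tiny_store.bounds))
        }
        assert all(got[i] == 7 for i in ids)

    def test_reassignment_overwrites(self, tiny_store):
        tiny_store.assign_trace([0, 1], 7)
        tiny_store.assign_trace([1], 9)
        seg = tiny_store.meta.segmentation_for([0, 1])
        assert seg[0][0] == 7 and seg[1][0] == 9

    def test_trace_zero_clears(self, tiny_store):
        tiny_store.assign_trace([0, 1], 7)
        tiny_store.assign_trace([0, 1], 0)
        assert tiny_store.meta.segmentation_for([0, 1]) == {}

    def test_unknown_point_ids_listed(self, tiny_store):
        n = tiny_store.points.count
        with pytest.raises(KeyError, match=str(n + 5)):
            tiny_store.assign_trace([0, n + 5], 3)

    def test_envelope_inherited_through_trace(self, tiny_store):
        tiny_store.assign_trace([0, 1], 7)
        tiny_store.assign_trace([2], 8)
        assert tiny_store.assign_envelope([7, 8], 3) == 2
        seg = tiny_store.meta.segmentation_for([0, 1, 2])
        assert {v for v in seg.values()} == {(7, 3), (8, 3)}
        tiny_store.assign_envelope([7], 0)
        assert tiny_store.meta.segmentation_for([0])[0] == (7, 0)

    def test_unknown_trace_and_empty_list(self, tiny_store):
        with pytest.raises(KeyError):
            tiny_store.assign_envelope([12345], 1)
        assert tiny_store.assign_envelope([], 1) == 0

    def test_edits_never_alter_coordinates(self, tiny_store):
        before = [
            (p.mz, p.rt, p.intensity)
            for p in tiny_store.query(QueryWindow.covering(tiny_store.bounds))
        ]
        tiny_store.assign_trace(list(range(50)), 11)
        tiny_store.assign_envelope([11], 4)
        after = [
            (p.mz, p.rt, p.intensity)
            for p in tiny_store.query(QueryWindow.covering(tiny_store.bounds))
        ]
        assert before == after


class TestTreePersistence:
    def test_save_load_small_tree_is_structurally_equal(self, tmp_path):
        store = MzStore.build(
            mk_points(30), tmp_path / "s", BuildParams(leaf_capacity=10, branching=2)
        )
        reloaded = MetadataStore(tmp_path / "s" / "meta.sqlite").load_tree()

        def eq(a, b):
            assert a.node_id == b.node_id
            assert a.bounds == b.bounds
            assert a.point_ids == b.point_ids
            assert a.leaf_block == b.leaf_block
            assert len(a.children) == len(b.children)
            for ca, cb in zip(a.children, b.children):
                eq(ca, cb)

        eq(store.root, reloaded)
        store.close()

    def test_queries_identical_after_reopen(self, medium_cloud, medium_store, tmp_path):
        copy = tmp_path / "copy"
        shutil.copytree(medium_store.directory, copy)
        with MzStore.open(copy) as reopened:
            rng = np.random.default_rng(2)
            for _ in range(10):
                mz = sorted(rng.uniform(400, 1200, 2))
                rt = sorted(rng.uniform(0, 600, 2))
                for n in (None, 50):
                    w = QueryWindow(mz[0], mz[1], rt[0], rt[1], n)
                    assert medium_store.query(w) == reopened.query(w)

    def test_load_from_empty_store_errors(self, tmp_path):
        meta = MetadataStore(tmp_path / "empty.sqlite")
        with pytest.raises(RuntimeError):
            meta.load_tree()


class TestStoreQueries:
    def test_full_extent_recovers_generated_points_and_segmentation(
        self, medium_cloud, medium_store
    ):
        got = medium_store.query(QueryWindow.covering(medium_store.bounds))
        assert sorted(map(point_key, got)) == sorted(map(point_key, medium_cloud))

    def test_cache_transparency(self, medium_cloud, medium_store, tmp_path):
        """Results are identical with the cache enabled and disabled."""
        copy = tmp_path / "nocache"
        shutil.copytree(medium_store.directory, copy)
        with MzStore.open(copy, StoreConfig(use_cache=False)) as cold:
            assert cold.cache is None
            rng = np.random.default_rng(3)
            for _ in range(10):
                mz = sorted(rng.uniform(400, 1200, 2))
                rt = sorted(rng.uniform(0, 600, 2))
                for n in (None, 120):
                    w = QueryWindow(mz[0], mz[1], rt[0], rt[1], n)
                    assert medium_store.query(w) == cold.query(w)

    def test_unbudgeted_store_query_equals_linear_scan(self, medium_cloud, medium_store):
        w = QueryWindow(600.0, 900.0, 100.0, 400.0)
        got = medium_store.query(w)
        expected = scan_window(medium_cloud, w)
        assert sorted(map(point_key, got)) == sorted(map(point_key, expected))
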