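"""Local/global clustering behaviour, time tables, and site JSON round-trip."""

from __future__ import annotations

import numpy as np
import pytest

from tbsmap import (
    ContactMatrix,
    LocalCluster,
    global_cluster,
    local_cluster,
    load_table1_fixture,
    merge_sites_across_substrates,
    site_time_table,
    site_time_table_report,
)
from tbsmap.site_discovery import (
    read_sites_json,
    render_time_table,
    write_sites_json,
)


def _matrix(frames_by_residue, n_residues=10, n_frames=50, substrate="S", replica="r01"):
    return ContactMatrix(
        substrate_id=substrate,
        replica_id=replica,
        n_residues=n_residues,
        n_frames=n_frames,
        dt_ps=2.0,
        contacts={r: np.asarray(f) for r, f in frames_by_residue.items()},
    )


def _cluster(residues, times, substrate="S", replica="r01", cluster_time=None):
    per = dict(zip(residues, times))
    return LocalCluster(
        substrate_id=substrate,
        replica_id=replica,
        residues=frozenset(residues),
        per_residue_time_ns=per,
        cluster_time_ns=max(times) if cluster_time is None else cluster_time,
    )


class TestLocalCluster:
    def test_identical_triplet_survives_disjoint_singletons_dropped(self, small_matrix):
        clusters = local_cluster(small_matrix)
        assert len(clusters) == 1
        assert clusters[0].residues == frozenset({1, 2, 3})

    def test_all_identical_supports_one_cluster(self):
        m = _matrix({r: [0, 1, 2] for r in range(1, 6)})
        clusters = local_cluster(m)
        assert len(clusters) == 1
        assert clusters[0].residues == frozenset(range(1, 6))

    def test_two_disjoint_triplet_groups(self):
        m = _matrix(
            {1: [0, 1], 2: [0, 1], 3: [0, 1], 7: [30, 31], 8: [30, 31], 9: [30, 31]}
        )
        clusters = local_cluster(m)
        assert [sorted(c.residues) for c in clusters] == [[1, 2, 3], [7, 8, 9]]

    def test_empty_matrix_yields_empty_list(self):
        m = _matrix({1: [0]})
        m.contacts = {}
        assert local_cluster(m) == []

    def test_partition_before_size_filter(self, rng):
        """No residue appears in two local clusters (min size 1 keeps all)."""
        for _ in range(10):
            dense = rng.random((12, 60)) < 0.15
            contacts = {
                r + 1: np.flatnonzero(dense[r]) for r in range(12) if dense[r].any()
            }
            if not contacts:
                continue
            m = _matrix(contacts, n_residues=12, n_frames=60)
            clusters = local_cluster(m, min_cluster_size=1)
            seen = [r for c in clusters for r in c.residues]
            assert len(seen) == len(set(seen))
            assert set(seen) == set(contacts)

    def test_time_invariants(self, small_matrix):
        """max per-residue time <= cluster occupancy time <= sum of times."""
        for c in local_cluster(small_matrix):
            times = list(c.per_residue_time_ns.values())
            assert max(times) - 1e-12 <= c.cluster_time_ns <= sum(times) + 1e-12


class TestGlobalCluster:
    def test_identical_sets_across_replicas_merge(self):
        locals_ = [
            _cluster([1, 2, 3], [1.0, 2.0, 3.0], replica=f"r{i:02d}")
            for i in range(10)
        ]
        sites = global_cluster(locals_)
        assert len(sites) == 1
        assert sites[0].residues == frozenset({1, 2, 3})

    def test_singleton_local_cluster(self):
        lc = _cluster([4, 5, 6], [1.0, 1.5, 2.0], cluster_time=2.5)
        (site,) = global_cluster([lc])
        assert site.residues == lc.residues
        assert site.time_table == {"S": pytest.approx(2.5)}

    def test_disjoint_families_stay_separate(self):
        locals_ = [
            _cluster([1, 2, 3], [1.0, 1.0, 1.0], replica="r01"),
            _cluster([1, 2, 3], [2.0, 2.0, 2.0], replica="r02"),
            _cluster([7, 8, 9], [1.0, 1.0, 1.0], replica="r01"),
            _cluster([7, 8, 9], [3.0, 3.0, 3.0], replica="r02"),
        ]
        sites = global_cluster(locals_)
        assert [sorted(s.residues) for s in sites] == [[1, 2, 3], [7, 8, 9]]

    def test_median_aggregator_between_min_and_max(self):
        locals_ = [
            _cluster([1, 2, 3], [1.0, 1.0, t], cluster_time=t, replica=f"r{i}")
            for i, t in enumerate([2.0, 5.0, 11.0])
        ]
        (site,) = global_cluster(locals_, aggregator="median")
        assert 2.0 <= site.time_table["S"] <= 11.0
        assert site.time_table["S"] == pytest.approx(5.0)
        (site_sum,) = global_cluster(locals_, aggregator="sum")
        assert site_sum.time_table["S"] == pytest.approx(18.0)

    def test_mixed_substrates_rejected(self):
        locals_ = [
            _cluster([1, 2, 3], [1.0] * 3, substrate="A"),
            _cluster([1, 2, 3], [1.0] * 3, substrate="B"),
        ]
        with pytest.raises(ValueError):
            global_cluster(locals_)


class TestMergeAcrossSubstrates:
    def _site(self, residues, time, substrate):
        lc = _cluster(sorted(residues), [time] * len(residues),
                      substrate=substrate, cluster_time=time)
        (site,) = global_cluster([lc])
        return site

    def test_same_residue_set_two_substrates(self):
        s1 = self._site({1, 2, 3}, 10.0, "A")
        s2 = self._site({1, 2, 3}, 20.0, "B")
        merged = merge_sites_across_substrates({"A": [s1], "B": [s2]})
        assert len(merged) == 1
        assert merged[0].time_table == {"A": 10.0, "B": 20.0}
        assert merged[0].site_id == 1

    def test_disjoint_sets_stay_separate_with_single_entry_tables(self):
        s1 = self._site({1, 2, 3}, 10.0, "A")
        s2 = self._site({7, 8, 9}, 20.0, "B")
        merged = merge_sites_across_substrates({"A": [s1], "B": [s2]})
        assert len(merged) == 2
        # ids in descending total time
        assert merged[0].time_table == {"B": 20.0}
        assert merged[1].time_table == {"A": 10.0}
        assert [m.site_id for m in merged] == [1, 2]


class TestTimeTableReport:
    def test_packaged_table_round_trips_byte_identically(self):
        from importlib.resources import files

        frame = load_table1_fixture()
        raw = files("tbsmap").joinpath("data/table1.tsv").read_text("utf-8")
        assert render_time_table(frame) == raw

    def test_single_site_single_substrate(self):
        lc = _cluster([1, 2, 3], [1.0, 1.0, 1.0], substrate="A", cluster_time=1.0)
        (site,) = global_cluster([lc])
        merged = merge_sites_across_substrates({"A": [site]})
        report = site_time_table_report(merged)
        assert report == "site\tA\n1\t1.0\n"

    def test_absent_pair_rendered_as_dash(self):
        s1 = self._sites_two_substrates()
        report = site_time_table_report(s1)
        lines = report.strip().split("\n")
        assert lines[0] == "site\tA\tB"
        assert any("\t-" in line for line in lines[1:])

    def _sites_two_substrates(self):
        a = _cluster([1, 2, 3], [1.0] * 3, substrate="A", cluster_time=2.5)
        b = _cluster([7, 8, 9], [1.0] * 3, substrate="B", cluster_time=2.0)
        (sa,) = global_cluster([a])
        (sb,) = global_cluster([b])
        return merge_sites_across_substrates({"A": [sa], "B": [sb]})


def test_sites_json_round_trip(tmp_path):
    a = _cluster([1, 2, 3], [1.0, 2.0, 3.0], substrate="A", cluster_time=3.5)
    (site,) = global_cluster([a])
    merged = merge_sites_across_substrates({"A": [site]})
    path = tmp_path / "sites.json"
    write_sites_json(merged, path, config_hash="abc123")
    loaded = read_sites_json(path)
    assert len(loaded) == 1
    assert loaded[0].residues == merged[0].residues
    assert loaded[0].time_table == merged[0].time_table
    assert loaded[0].site_id == merged[0].site_id
    assert [c.per_residue_time_ns for c in loaded[0].members] == [
        dict(c.per_residue_time_ns) for c in merged[0].members
    ]
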