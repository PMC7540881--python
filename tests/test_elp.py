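import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from elnm.elp import (AccessibilityConfig, ELPRecord, RangeGrid,
                      accessibility_filter, diversity_summary,
                      geographic_overlap, identify_elps, elp_partition_labels)
from elnm.raster import Grid
from elnm.synthetic import load_published_elp_table


def range_grid(presence, gid="g"):
    presence = np.asarray(presence, bool)
    g = Grid(*presence.shape, 0.0, float(presence.shape[0]), 1.0)
    return RangeGrid(gid, g, presence)


class TestAccessibility:
    def test_single_component_is_unchanged(self):
        presence = np.zeros((6, 6), bool)
        presence[1:4, 1:4] = True
        rng_grid = range_grid(presence)
        poly = box(1.5, 2.5, 3.0, 4.0)  # overlaps the blob
        out = accessibility_filter(rng_grid, poly)
        assert np.array_equal(out.presence, presence)

    def test_disjoint_inland_component_removed(self):
        presence = np.zeros((8, 8), bool)
        presence[1:3, 1:3] = True     # connected to the territory
        presence[6:8, 6:8] = True     # far-away blob
        poly = box(1.0, 5.0, 3.0, 7.0)
        out = accessibility_filter(range_grid(presence), poly,
                                   AccessibilityConfig(maritime=False))
        assert out.presence[1:3, 1:3].all()
        assert not out.presence[6:8, 6:8].any()

    def test_maritime_keeps_island_touching_sea(self):
        presence = np.zeros((8, 8), bool)
        presence[1:3, 1:3] = True
        presence[6:8, 6:8] = True     # island component adjacent to sea
        sea = np.zeros((8, 8), bool)
        sea[5, 5:8] = True            # sea cells border the island blob
        poly = box(1.0, 5.0, 3.0, 7.0)
        out = accessibility_filter(range_grid(presence), poly,
                                   AccessibilityConfig(maritime=True),
                                   sea_mask=sea)
        assert out.presence[6:8, 6:8].all()


class TestGeographicOverlap:
    def test_identical_is_one(self):
        p = np.random.default_rng(0).random((5, 5)) > 0.5
        assert geographic_overlap(range_grid(p), range_grid(p)) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4), bool); a[0] = True
        b = np.zeros((4, 4), bool); b[3] = True
        assert geographic_overlap(range_grid(a), range_grid(b)) == 0.0

    def test_counting_example(self):
        a = np.zeros((4, 5), bool); a.ravel()[:10] = True
        b = np.zeros((4, 5), bool); b.ravel()[5:15] = True
        assert geographic_overlap(range_grid(a), range_grid(b)) == pytest.approx(5 / 15)


def matrices(ids, geo_pairs, d_pairs):
    geo = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    dd = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for (a, b), v in geo_pairs.items():
        geo.loc[a, b] = geo.loc[b, a] = v
    for (a, b), v in d_pairs.items():
        dd.loc[a, b] = dd.loc[b, a] = v
    return geo, dd


class TestIdentifyELPs:
    def test_no_edges_gives_singletons(self):
        ids = ["a", "b", "c"]
        geo, dd = matrices(ids, {}, {})
        records = identify_elps(ids, geo, dd, g_min=0.4, d_min=0.6)
        assert [r.n_groups for r in records] == [1, 1, 1]

    def test_chain_closes_transitively(self):
        ids = ["a", "b", "c"]
        geo, dd = matrices(ids, {("a", "b"): 0.9, ("b", "c"): 0.9},
                           {("a", "b"): 0.9, ("b", "c"): 0.9})
        records = identify_elps(ids, geo, dd)
        assert records[0].member_ids == ["a", "b", "c"]

    def test_both_conditions_required(self):
        ids = ["a", "b"]
        geo, dd = matrices(ids, {("a", "b"): 0.9}, {("a", "b"): 0.1})
        assert len(identify_elps(ids, geo, dd)) == 2

    def test_raising_thresholds_only_refines(self, rng):
        ids = [f"g{i}" for i in range(6)]
        geo = rng.random((6, 6)); geo = (geo + geo.T) / 2; np.fill_diagonal(geo, 1)
        dd = rng.random((6, 6)); dd = (dd + dd.T) / 2; np.fill_diagonal(dd, 1)
        geo = pd.DataFrame(geo, index=ids, columns=ids)
        dd = pd.DataFrame(dd, index=ids, columns=ids)
        loose = identify_elps(ids, geo, dd, g_min=0.2, d_min=0.2)
        tight = identify_elps(ids, geo, dd, g_min=0.6, d_min=0.6)
        loose_labels = elp_partition_labels(loose, ids)
        tight_labels = elp_partition_labels(tight, ids)
        assert len(tight) >= len(loose)
        # refinement: every tight cluster sits inside one loose cluster
        for k in set(tight_labels):
            parents = set(loose_labels[tight_labels == k])
            assert len(parents) == 1

    def test_partition_covers_every_group_once(self, rng):
        ids = [f"g{i}" for i in range(5)]
        geo, dd = matrices(ids, {("g0", "g1"): 0.9}, {("g0", "g1"): 0.9})
        records = identify_elps(ids, geo, dd)
        members = [m for r in records for m in r.member_ids]
        assert sorted(members) == sorted(ids)


class TestDiversitySummary:
    def test_counts_and_language_sums(self):
        records = [ELPRecord("ELP 1", ["a", "b"], ["TNG"], 2),
                   ELPRecord("ELP 2", ["c"], ["Austronesian"], 1)]
        meta = pd.DataFrame({"family": ["TNG", "TNG", "Austronesian"],
                             "n_languages": [4, 6, 9]},
                            index=["a", "b", "c"])
        table = diversity_summary(records, meta)
        assert list(table["n_groups"]) == [2, 1]
        assert list(table["n_languages"]) == [10, 9]

    def test_empty_input_gives_empty_table(self):
        assert diversity_summary([]).empty


class TestTable1Fixture:
    def test_membership_is_a_partition_of_29_groups(self):
        records, metadata = load_published_elp_table()
        members = [m for r in records for m in r.member_ids]
        assert len(members) == len(set(members)) == 29
        assert len(records) == 17

    def test_mixed_family_pattern(self):
        records, _ = load_published_elp_table()
        rec = next(r for r in records if sorted(r.member_ids) == ["23", "36", "37", "38"])
        assert sorted(rec.families) == ["Austronesian", "TNG"]

    def test_family_split_counts(self):
        _, metadata = load_published_elp_table()
        counts = metadata["family"].value_counts()
        assert counts["TNG"] == 20 and counts["Austronesian"] == 9

    def test_group_counts_recomputed_from_membership(self):
        records, metadata = load_published_elp_table()
        table = diversity_summary(records, metadata)
        # printed N Group(s) column, in table order
        assert list(table["n_groups"]) == [7, 2, 2, 4, 2] + [1] * 12
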