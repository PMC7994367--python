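"""Territory classification, heat maps, satellites and shared nodes."""

import numpy as np
import pandas as pd
import pytest

from sigsom import blsom, map_analysis


def make_assignment(I, J, members):
    """members: list of (i, j, species[, record_id]) tuples, one per window."""
    rows = []
    for n, m in enumerate(members):
        i, j, sp = m[:3]
        rid = m[3] if len(m) > 3 else f"{sp}_scaf"
        rows.append((f"w{n}", rid, sp, i, j))
    frame = pd.DataFrame(rows, columns=["window_id", "record_id", "species", "i", "j"])
    return blsom.NodeAssignment(I=I, J=J, frame=frame)


def make_grid(I, J, values_by_group):
    """Trivial grid whose weights hold given per-group per-node values."""
    labels = list(values_by_group)
    W = np.column_stack([np.asarray(values_by_group[g], float).ravel()
                         for g in labels])
    return blsom.BLSOMGrid(
        I=I, J=J, weights=W, group_labels=labels,
        x_av=W.mean(axis=0), b1=np.zeros(len(labels)), b2=np.zeros(len(labels)),
        sigma1=1.0, sigma2=1.0, radius_schedule=[1],
    )


class TestClassify:
    def test_majority_vs_pure_only(self):
        members = [(0, 0, "A")] * 6 + [(0, 0, "B")] * 4
        asn = make_assignment(2, 2, members)
        maj = map_analysis.classify_nodes(asn, "majority50").frame
        row = maj[(maj.i == 0) & (maj.j == 0)].iloc[0]
        assert row.klass == "majority"
        assert row.top_species == "A"
        assert row.top_fraction == pytest.approx(0.6)
        pure = map_analysis.classify_nodes(asn, "pure_only").frame
        assert pure[(pure.i == 0) & (pure.j == 0)].iloc[0].klass == "mixed"

    def test_exact_half_is_mixed(self):
        members = [(0, 0, "A")] * 5 + [(0, 0, "B")] * 5
        asn = make_assignment(2, 2, members)
        for mode in ("majority50", "pure_only"):
            frame = map_analysis.classify_nodes(asn, mode).frame
            assert frame[(frame.i == 0) & (frame.j == 0)].iloc[0].klass == "mixed"

    def test_empty_and_pure_nodes(self):
        asn = make_assignment(2, 2, [(1, 1, "A"), (1, 1, "A")])
        frame = map_analysis.classify_nodes(asn).frame
        assert frame[(frame.i == 0) & (frame.j == 0)].iloc[0].klass == "empty"
        assert frame[(frame.i == 1) & (frame.j == 1)].iloc[0].klass == "pure"

    def test_partition_covers_all_nodes(self):
        asn = make_assignment(3, 4, [(0, 0, "A"), (2, 3, "B"), (2, 3, "A")])
        frame = map_analysis.classify_nodes(asn).frame
        assert len(frame) == 12
        assert frame.klass.isin(["empty", "pure", "majority", "mixed"]).all()


class TestPurity:
    def test_pure_map(self):
        asn = make_assignment(2, 2, [(0, 0, "A")] * 5 + [(1, 1, "B")] * 5)
        assert map_analysis.territory_purity(asn) == 1.0

    def test_mixed_map(self):
        asn = make_assignment(2, 2, [(0, 0, "A")] * 5 + [(0, 0, "B")] * 5)
        assert map_analysis.territory_purity(asn) == 0.5

    def test_null_near_chance_for_exchangeable_labels(self, rng):
        members = [(int(i), int(j), sp)
                   for i, j, sp in zip(rng.integers(0, 5, 300),
                                       rng.integers(0, 5, 300),
                                       rng.choice(["A", "B", "C"], 300))]
        asn = make_assignment(5, 5, members)
        null = map_analysis.purity_null(asn, n_perm=10, seed=1)
        assert abs(map_analysis.territory_purity(asn) - null) < 0.1


class TestHeatmap:
    def test_tertile_rule_nine_nodes(self):
        vals = np.arange(1, 10, dtype=float).reshape(3, 3)
        grid = make_grid(3, 3, {"CG": vals})
        members = [(i, j, "A") for i in range(3) for j in range(3)]
        asn = make_assignment(3, 3, members)
        hm = map_analysis.contribution_heatmap(grid, asn, "CG")
        by_val = dict(zip(hm.frame.value, hm.frame.klass))
        assert {by_val[v] for v in (9.0, 8.0, 7.0)} == {"high"}
        assert {by_val[v] for v in (6.0, 5.0, 4.0)} == {"moderate"}
        assert {by_val[v] for v in (3.0, 2.0, 1.0)} == {"low"}

    def test_all_equal_values_all_high(self):
        grid = make_grid(2, 2, {"CG": np.ones(4)})
        asn = make_assignment(2, 2, [(i, j, "A") for i in range(2) for j in range(2)])
        hm = map_analysis.contribution_heatmap(grid, asn, "CG")
        assert (hm.frame.klass == "high").all()

    def test_empty_nodes_uncolored(self):
        grid = make_grid(2, 2, {"CG": np.arange(4.0)})
        asn = make_assignment(2, 2, [(0, 0, "A"), (1, 1, "A"), (0, 1, "A")])
        hm = map_analysis.contribution_heatmap(grid, asn, "CG")
        lattice = hm.klass_lattice()
        assert lattice[1, 0] is None
        assert len(hm.frame) == 3

    def test_species_relabel_invariance(self):
        grid = make_grid(2, 2, {"CG": np.arange(4.0)})
        a = make_assignment(2, 2, [(i, j, "A") for i in range(2) for j in range(2)])
        b = make_assignment(2, 2, [(i, j, "B") for i in range(2) for j in range(2)])
        ha = map_analysis.contribution_heatmap(grid, a, "CG")
        hb = map_analysis.contribution_heatmap(grid, b, "CG")
        assert ha.frame.klass.tolist() == hb.frame.klass.tolist()

    def test_unknown_label(self):
        grid = make_grid(2, 2, {"CG": np.arange(4.0)})
        asn = make_assignment(2, 2, [(0, 0, "A")])
        with pytest.raises(KeyError):
            map_analysis.contribution_heatmap(grid, asn, "ZZ")


class TestSatellites:
    def lattice_assignment(self):
        # species A: main blob (rows 0-5 x cols 0-5 -> 36 nodes), one
        # 3-node satellite at (9,0),(9,1),(8,1), one 2-node at (9,8),(9,9)
        members = []
        for i in range(6):
            for j in range(6):
                members.append((i, j, "A"))
        for i, j in [(9, 0), (9, 1), (8, 1)]:
            members.append((i, j, "A"))
        for i, j in [(9, 8), (9, 9)]:
            members.append((i, j, "A"))
        return make_assignment(10, 10, members)

    def test_component_rule(self):
        asn = self.lattice_assignment()
        tmap = map_analysis.classify_nodes(asn, "majority50")
        sats = map_analysis.extract_satellites(tmap, asn, "A", min_size=2,
                                               max_fraction_of_main=0.5)
        assert sorted(s.size for s in sats) == [2, 3]
        sats3 = map_analysis.extract_satellites(tmap, asn, "A", min_size=3,
                                                max_fraction_of_main=0.5)
        assert [s.size for s in sats3] == [3]

    def test_single_component_no_satellites(self):
        members = [(i, j, "A") for i in range(3) for j in range(3)]
        asn = make_assignment(4, 4, members)
        tmap = map_analysis.classify_nodes(asn, "majority50")
        assert map_analysis.extract_satellites(tmap, asn, "A") == []

    def test_diagonal_adjacency_merges(self):
        # (0,0) and (1,1) touch diagonally -> one Moore component
        asn = make_assignment(3, 3, [(0, 0, "A"), (1, 1, "A")])
        tmap = map_analysis.classify_nodes(asn, "majority50")
        assert map_analysis.extract_satellites(tmap, asn, "A", min_size=1) == []

    def test_absent_species_raises(self):
        asn = make_assignment(2, 2, [(0, 0, "A")])
        tmap = map_analysis.classify_nodes(asn, "majority50")
        with pytest.raises(ValueError):
            map_analysis.extract_satellites(tmap, asn, "Z")

    def test_satellite_carries_windows(self):
        asn = self.lattice_assignment()
        tmap = map_analysis.classify_nodes(asn, "majority50")
        sats = map_analysis.extract_satellites(tmap, asn, "A", min_size=3,
                                               max_fraction_of_main=0.5)
        assert len(sats[0].window_ids) == 3


class TestEnrichment:
    def comp_frame(self):
        return pd.DataFrame({
            "window_id": ["w0", "w1"],
            "record_id": ["r", "r"],
            "species": ["A", "A"],
            "start": [0, 100],
            "end": [100, 200],
            "total_count": [100, 100],
            "CG": [0.02, 0.02],
            "AT": [0.98, 0.98],
        })

    def test_simple_ratio(self):
        comp = self.comp_frame()
        sat = map_analysis.SatelliteTerritory("A", [(0, 0)], ["w0"], 1)
        genome = pd.Series({"CG": 0.01, "AT": 0.99})
        pairs = map_analysis.enrichment_ratios(sat, comp, genome, top_n=2)
        assert pairs[0] == ("CG", pytest.approx(2.0))

    def test_identity_when_satellite_is_genome(self):
        comp = self.comp_frame()
        sat = map_analysis.SatelliteTerritory("A", [(0, 0)], ["w0", "w1"], 1)
        genome = map_analysis.pooled_composition(comp)
        pairs = map_analysis.enrichment_ratios(sat, comp, genome, top_n=2)
        assert all(r == pytest.approx(1.0) for _, r in pairs)

    def test_zero_genome_freq_flagged_inf(self):
        comp = self.comp_frame()
        sat = map_analysis.SatelliteTerritory("A", [(0, 0)], ["w0"], 1)
        genome = pd.Series({"CG": 0.0, "AT": 1.0})
        with pytest.warns(UserWarning):
            pairs = map_analysis.enrichment_ratios(sat, comp, genome, top_n=1)
        assert np.isinf(pairs[0][1])

    def test_pooling_weights_by_total_count(self):
        comp = self.comp_frame()
        comp.loc[1, "total_count"] = 300
        comp.loc[1, "CG"] = 0.06
        pooled = map_analysis.pooled_composition(comp)
        assert pooled["CG"] == pytest.approx((0.02 * 100 + 0.06 * 300) / 400)


class TestSharedAndAdjacent:
    def test_disjoint_sets_empty(self):
        asn = make_assignment(3, 3, [(0, 0, "A"), (2, 2, "B")])
        out = map_analysis.shared_nodes(asn, {"species": "A"}, {"species": "B"})
        assert out.nodes == [] and out.a_record_ids == []

    def test_co_occupied_node_found(self):
        asn = make_assignment(3, 3, [(1, 1, "A", "scafA9"), (1, 1, "B", "scafB1"),
                                     (0, 0, "A", "scafA1")])
        out = map_analysis.shared_nodes(asn, {"species": "A"}, {"species": "B"})
        assert out.nodes == [(1, 1)]
        assert out.a_record_ids == ["scafA9"]

    def test_empty_filter_warns(self):
        asn = make_assignment(2, 2, [(0, 0, "A")])
        with pytest.warns(UserWarning):
            out = map_analysis.shared_nodes(asn, {"species": "A"}, {"species": "Z"})
        assert out.nodes == []

    def test_adjacent_distance_zero_is_co_occupancy(self):
        members = [(0, 0, "A")] * 3 + [(0, 0, "B"), (2, 2, "B")]
        asn = make_assignment(3, 3, members)
        nodes, wids = map_analysis.adjacent_nodes(asn, {"species": "B"}, "A", 0)
        assert nodes == [(0, 0)]
        assert len(wids) == 1

    def test_diagonal_within_distance_one(self):
        members = [(0, 0, "A")] * 3 + [(1, 1, "B"), (2, 2, "B")]
        asn = make_assignment(4, 4, members)
        nodes, _ = map_analysis.adjacent_nodes(asn, {"species": "B"}, "A", 1)
        assert nodes == [(1, 1)]

    def test_far_inside_own_territory_excluded(self):
        members = [(0, 0, "A")] * 3 + [(3, 3, "B")] * 3
        asn = make_assignment(4, 4, members)
        nodes, _ = map_analysis.adjacent_nodes(asn, {"species": "B"}, "A", 1)
        assert nodes == []
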