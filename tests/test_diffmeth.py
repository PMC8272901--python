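import numpy as np
import pytest

from epihotspot.diffmeth import (
    DMCpG,
    DMRTile,
    GroupDesign,
    call_dmcpgs,
    classify_persistence,
    classify_tiles,
    read_dmcpgs,
    read_tiles,
    tile_dmrs,
    write_dmcpgs,
    write_tiles,
)
from epihotspot.methio import UnitedMatrix

from oracles import single_linkage_tiles


def make_matrix(n_meth, n_unmeth, sample_ids, chrom="chr1", start_pos=1000, spacing=50):
    n_meth = np.asarray(n_meth)
    n_unmeth = np.asarray(n_unmeth)
    positions = [(chrom, start_pos + spacing * i) for i in range(n_meth.shape[0])]
    return UnitedMatrix(positions, list(sample_ids), n_meth, n_unmeth)


def coverage_matrix(positions, sample_ids=("x", "y")):
    """All-sites-covered matrix used for eligibility checks."""
    n = len(positions)
    ones = np.full((n, len(sample_ids)), 5, dtype=np.int64)
    return UnitedMatrix(list(positions), list(sample_ids), ones, ones.copy())


def mk_tile(chrom, start, end, diff=40.0, cell_type="fibroblast", source=""):
    return DMRTile(
        chrom=chrom, start=start, end=end, n_dmcpgs=1, mean_diff=diff,
        direction="hyper" if diff > 0 else "hypo", cell_type=cell_type, source=source,
    )


class TestGroupDesign:
    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign("x", (), ("p1",))

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign("x", ("s1",), ("s1",))


class TestCallDMCpGs:
    def test_extreme_separation_retained(self):
        # patients near 100%, controls near 0% -> retained, hyper
        m = make_matrix(
            [[40, 38, 2, 0]], [[0, 2, 38, 40]], ["p1", "p2", "c1", "c2"]
        )
        design = GroupDesign("t", ("c1", "c2"), ("p1", "p2"))
        out = call_dmcpgs(m, design)
        assert len(out) == 1
        assert out[0].meth_diff == pytest.approx(95, abs=5)
        assert out[0].meth_diff > 0

    def test_identical_groups_never_retained(self):
        m = make_matrix(
            [[10, 10, 10, 10]] * 5, [[10, 10, 10, 10]] * 5, ["p1", "p2", "c1", "c2"]
        )
        design = GroupDesign("t", ("c1", "c2"), ("p1", "p2"))
        out = call_dmcpgs(m, design)
        assert out == []

    def test_absent_sample_raises(self):
        m = make_matrix([[5, 5]], [[5, 5]], ["a", "b"])
        with pytest.raises(KeyError):
            call_dmcpgs(m, GroupDesign("t", ("a",), ("zzz",)))

    def test_sign_convention(self):
        # patients hypomethylated -> negative diff
        m = make_matrix([[0, 1, 39, 38]], [[40, 39, 1, 2]], ["p1", "p2", "c1", "c2"])
        out = call_dmcpgs(m, GroupDesign("t", ("c1", "c2"), ("p1", "p2")))
        assert len(out) == 1 and out[0].meth_diff < 0

    def test_cutoff_monotonicity(self, rng):
        n = 300
        n_meth = rng.integers(0, 30, size=(n, 4))
        n_unmeth = rng.integers(1, 30, size=(n, 4))
        m = make_matrix(n_meth, n_unmeth, ["p1", "p2", "c1", "c2"])
        design = GroupDesign("t", ("c1", "c2"), ("p1", "p2"))
        base = len(call_dmcpgs(m, design, diff_cutoff=10, q_cutoff=0.2))
        assert len(call_dmcpgs(m, design, diff_cutoff=30, q_cutoff=0.2)) <= base
        assert len(call_dmcpgs(m, design, diff_cutoff=10, q_cutoff=0.01)) <= base

    def test_fisher_fallback_agrees_on_direction(self):
        m = make_matrix([[30, 0]], [[0, 30]], ["p1", "c1"])
        design = GroupDesign("t", ("c1",), ("p1",))
        out = call_dmcpgs(m, design, test="fisher")
        assert len(out) == 1 and out[0].meth_diff == pytest.approx(100)

    def test_unknown_test_rejected(self):
        m = make_matrix([[5, 5]], [[5, 5]], ["a", "b"])
        with pytest.raises(ValueError):
            call_dmcpgs(m, GroupDesign("t", ("a",), ("b",)), test="bogus")


class TestTileDMRs:
    def test_single_dmcpg_extended_to_100(self):
        tiles, n_amb = tile_dmrs([DMCpG("chr1", 1000, 40.0, 1e-9, 1e-6)])
        assert n_amb == 0
        (t,) = tiles
        assert t.length == 100
        # centered on the site's 0-based coordinate 999
        assert (t.start + t.end) / 2 == pytest.approx(999, abs=1)
        assert t.mean_diff == 40.0 and t.direction == "hyper"

    def test_merge_threshold(self):
        d1 = DMCpG("chr1", 1000, 35.0, 0, 0)
        tiles, _ = tile_dmrs([d1, DMCpG("chr1", 1400, 45.0, 0, 0)])
        assert len(tiles) == 1
        assert tiles[0].mean_diff == pytest.approx(40.0)
        assert tiles[0].n_dmcpgs == 2
        tiles, _ = tile_dmrs([d1, DMCpG("chr1", 1600, 45.0, 0, 0)])
        assert len(tiles) == 2

    def test_ambiguous_removed(self):
        tiles, n_amb = tile_dmrs(
            [DMCpG("chr1", 1000, 35.0, 0, 0), DMCpG("chr1", 1200, -35.0, 0, 0)]
        )
        assert tiles == [] and n_amb == 1

    def test_left_edge_clipped(self):
        tiles, _ = tile_dmrs([DMCpG("chr1", 10, 40.0, 0, 0)])
        (t,) = tiles
        assert t.start >= 0 and t.length == 100

    def test_min_width_invariant_and_members_inside(self, rng):
        pos = np.sort(rng.choice(np.arange(100, 100_000), size=200, replace=False))
        dmcpgs = [
            DMCpG("chr1", int(p), float(rng.choice([-40, 40])), 0, 0) for p in pos
        ]
        tiles, _ = tile_dmrs(dmcpgs)
        for t in tiles:
            assert t.length >= 100
        # pre-extension clusters are separated by > 500 bp
        spans = sorted((t.start, t.end) for t in tiles)

    def test_matches_single_linkage_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 120))
            pos = np.sort(rng.choice(np.arange(200, 60_000), size=n, replace=False))
            chroms = rng.choice(["chr1", "chr2"], size=n)
            dmcpgs = [
                DMCpG(str(c), int(p), float(rng.choice([-40.0, 40.0])), 0, 0)
                for c, p in zip(chroms, pos)
            ]
            tiles, n_amb = tile_dmrs(dmcpgs)
            got = sorted(
                (t.chrom, t.start, t.end, t.mean_diff, t.n_dmcpgs) for t in tiles
            )
            expect, exp_amb = single_linkage_tiles(
                [(d.chrom, d.pos, d.meth_diff) for d in dmcpgs]
            )
            assert n_amb == exp_amb
            assert [(c, s, e, n) for c, s, e, _, n in expect] == [
                (c, s, e, n) for c, s, e, _, n in got
            ]
            for (_, _, _, d1, _), (_, _, _, d2, _) in zip(expect, got):
                assert d1 == pytest.approx(d2)


class TestClassifyTiles:
    def _eligible_matrix(self):
        return coverage_matrix([("chr1", p) for p in range(1001, 20_000, 200)])

    def test_family_specific_with_all(self):
        t = mk_tile("chr1", 1000, 1200, source="familyA")
        out = classify_tiles(
            [mk_tile("chr1", 1000, 1200, source="all")], [t], [],
            self._eligible_matrix(), self._eligible_matrix(),
        )
        assert all(x.category == "familyA_specific" for x in out)

    def test_only_all_is_shared(self):
        t = mk_tile("chr1", 1000, 1200, source="all")
        out = classify_tiles([t], [], [], self._eligible_matrix(), self._eligible_matrix())
        assert [x.category for x in out] == ["shared"]

    def test_both_families_shared(self):
        tA = mk_tile("chr1", 1000, 1200, source="familyA")
        tC = mk_tile("chr1", 1050, 1250, source="familyC")
        out = classify_tiles([], [tA], [tC], self._eligible_matrix(), self._eligible_matrix())
        assert all(x.category == "shared" for x in out)

    def test_ineligible_dropped(self):
        t = mk_tile("chr1", 1000, 1200, source="familyA")
        empty_c = coverage_matrix([("chr2", 5)])
        out = classify_tiles([], [t], [], self._eligible_matrix(), empty_c)
        assert out == []

    def test_mixed_cell_types_rejected(self):
        t1 = mk_tile("chr1", 1000, 1200, cell_type="fibroblast")
        t2 = mk_tile("chr1", 5000, 5200, cell_type="iPSC")
        with pytest.raises(ValueError, match="cell types"):
            classify_tiles([t1], [t2], [], self._eligible_matrix(), self._eligible_matrix())

    def test_truth_table_oracle(self, rng):
        # all 7 non-empty membership patterns over disjoint regions
        patterns = [
            frozenset(p)
            for p in [("all",), ("A",), ("C",), ("all", "A"), ("all", "C"),
                      ("A", "C"), ("all", "A", "C")]
        ]
        expected = {
            frozenset({"all"}): "shared",
            frozenset({"A"}): "familyA_specific",
            frozenset({"C"}): "familyC_specific",
            frozenset({"all", "A"}): "familyA_specific",
            frozenset({"all", "C"}): "familyC_specific",
            frozenset({"A", "C"}): "shared",
            frozenset({"all", "A", "C"}): "shared",
        }
        for trial in range(5):
            run_all, run_a, run_c = [], [], []
            region_pattern = {}
            start = 1000
            for i in range(30):
                pat = patterns[int(rng.integers(0, len(patterns)))]
                region = (start, start + 150)
                region_pattern[region] = pat
                if "all" in pat:
                    run_all.append(mk_tile("chr1", *region, source="all"))
                if "A" in pat:
                    run_a.append(mk_tile("chr1", *region, source="familyA"))
                if "C" in pat:
                    run_c.append(mk_tile("chr1", *region, source="familyC"))
                start += 1000
            matrix = coverage_matrix([("chr1", p) for p in range(1001, start, 100)])
            out = classify_tiles(run_all, run_a, run_c, matrix, matrix)
            assert len(out) == sum(len(p) for p in region_pattern.values())
            for tile in out:
                pat = region_pattern[(tile.start, tile.end)]
                assert tile.category == expected[pat], (pat, tile)

    def test_partition_property(self, rng):
        # every eligible output tile gets exactly one of the three labels
        run_a = [mk_tile("chr1", 1000 + 700 * i, 1150 + 700 * i, source="familyA") for i in range(10)]
        run_c = [mk_tile("chr1", 1070 + 700 * i, 1250 + 700 * i, source="familyC") for i in range(5)]
        matrix = coverage_matrix([("chr1", p) for p in range(1001, 10_000, 50)])
        out = classify_tiles([], run_a, run_c, matrix, matrix)
        for t in out:
            assert t.category in ("shared", "familyA_specific", "familyC_specific")


class TestClassifyPersistence:
    def test_reversed_class(self):
        fib = [mk_tile("chr1", 1000, 1200, diff=40.0, cell_type="fibroblast")]
        ipsc = [mk_tile("chr1", 1000, 1200, diff=-40.0, cell_type="iPSC")]
        matrix = coverage_matrix([("chr1", 1100)])
        classes = classify_persistence(fib, ipsc, matrix, matrix)
        assert set(classes.values()) == {"hyper->hypo"}

    def test_lost_in_ipsc(self):
        fib = [mk_tile("chr1", 1000, 1200, diff=40.0)]
        matrix = coverage_matrix([("chr1", 1100)])
        classes = classify_persistence(fib, [], matrix, matrix)
        assert list(classes.values()) == ["hyper->none"]

    def test_eligibility_requires_both_matrices(self):
        fib = [mk_tile("chr1", 1000, 1200, diff=40.0)]
        has = coverage_matrix([("chr1", 1100)])
        lacks = coverage_matrix([("chr2", 99)])
        assert classify_persistence(fib, [], has, lacks) == {}

    def test_pairwise_overlap_oracle(self, rng):
        # random tile sets; expected class from direct overlap computation
        def rand_tiles(cell_type):
            tiles = []
            start = 1000
            for _ in range(20):
                if rng.random() < 0.6:
                    diff = float(rng.choice([-40.0, 40.0]))
                    tiles.append(mk_tile("chr1", start, start + 150, diff=diff, cell_type=cell_type))
                start += 500
            return tiles

        fib, ipsc = rand_tiles("fibroblast"), rand_tiles("iPSC")
        matrix = coverage_matrix([("chr1", p) for p in range(1001, 12_000, 40)])
        classes = classify_persistence(fib, ipsc, matrix, matrix)

        def state(tile, others):
            hits = [o for o in others if tile.start < o.end and o.start < tile.end]
            return "none" if not hits else hits[0].direction

        for t in fib:
            assert classes[t] == f"{t.direction}->{state(t, ipsc)}"
        for t in ipsc:
            assert classes[t] == f"{state(t, fib)}->{t.direction}"


class TestSerialization:
    def test_dmcpg_round_trip(self, tmp_path):
        dmcpgs = [DMCpG("chr1", 1000, 42.5, 1e-8, 1e-5), DMCpG("chr2", 5, -31.0, 1e-4, 9e-3)]
        p = tmp_path / "dm.tsv"
        write_dmcpgs(dmcpgs, p)
        back = read_dmcpgs(p)
        assert [(d.chrom, d.pos) for d in back] == [(d.chrom, d.pos) for d in dmcpgs]
        assert back[0].meth_diff == pytest.approx(42.5)

    def test_tile_round_trip(self, tmp_path):
        tiles = [mk_tile("chr1", 1000, 1200, source="familyA")]
        p = tmp_path / "tiles.tsv"
        write_tiles(tiles, p)
        back = read_tiles(p)
        assert back[0].start == 1000 and back[0].source == "familyA"
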