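import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_lift_map, brute_force_runs, make_chain, random_chain_set
from synpi import intervals as iv
from synpi.io import GenomeInterval
from synpi.synteny import ChainIndex, build_window_map, lift_interval, tile_windows


def _windows(sizes, W=200_000):
    return tile_windows(sizes, W)


class TestTileWindows:
    def test_exact_tiling(self):
        w = _windows({"chr1": 1_000_000})
        assert len(w) == 5 and w["full"].all()
        assert list(w["start"]) == [0, 200_000, 400_000, 600_000, 800_000]

    def test_partial_tail_flagged(self):
        w = _windows({"chr1": 450_000})
        assert len(w) == 3
        assert list(w["full"]) == [True, True, False]
        assert w.iloc[-1]["end"] - w.iloc[-1]["start"] == 50_000

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            _windows({"chr1": 100}, W=0)
        with pytest.raises(ValueError):
            _windows({})


class TestLiftInterval:
    def test_identity_block(self):
        ch = make_chain(10, "chr1", 10_000, 0, "t1", 10_000, "+", 0, [(10_000, 0, 0)])
        runs = lift_interval(GenomeInterval("chr1", 1000, 2000), [ch])
        assert len(runs) == 1
        r = runs[0]
        assert r.lifted_bases == 1000
        assert (r.target.start, r.target.end) == (1000, 2000)

    def test_source_gap_inside_window_vs_per_base_oracle(self):
        # 200 kb window over a chain with a 10 kb source-side (dt) gap:
        # one run, 190 000 lifted bases, contiguous 190 kb target span
        W, gap = 200_000, 10_000
        half = (W - gap) // 2
        ch = make_chain(10, "chr1", W, 0, "t1", W, "+", 0,
                        [(half, gap, 0), (half, 0, 0)])
        runs = lift_interval(GenomeInterval("chr1", 0, W), [ch])
        assert len(runs) == 1
        assert runs[0].lifted_bases == W - gap
        assert runs[0].target.length == W - gap
        table = brute_force_lift_map([ch], "chr1", W)
        expect = brute_force_runs(table, 0, W)
        assert expect == [(runs[0].target.chrom, runs[0].target.start,
                           runs[0].target.end, runs[0].lifted_bases,
                           runs[0].target.strand)]

    def test_target_gap_extends_span_not_bases(self):
        ch = make_chain(10, "chr1", 1000, 0, "t1", 5000, "+", 0,
                        [(400, 0, 300), (600, 0, 0)])
        (run,) = lift_interval(GenomeInterval("chr1", 0, 1000), [ch])
        assert run.lifted_bases == 1000
        assert run.target.length == 1300

    def test_split_across_target_chromosomes(self):
        c1 = make_chain(10, "chr1", 1000, 0, "t1", 5000, "+", 0, [(500, 0, 0)])
        c2 = make_chain(10, "chr1", 1000, 500, "t2", 5000, "+", 100, [(500, 0, 0)])
        runs = lift_interval(GenomeInterval("chr1", 0, 1000), [c1, c2])
        assert [r.target.chrom for r in runs] == ["t1", "t2"]
        assert [r.lifted_bases for r in runs] == [500, 500]

    def test_unmapped_interval(self):
        ch = make_chain(10, "chr1", 10_000, 0, "t1", 10_000, "+", 0, [(100, 0, 0)])
        assert lift_interval(GenomeInterval("chr1", 5000, 6000), [ch]) == []

    @pytest.mark.parametrize("trial", range(12))
    def test_per_base_oracle_on_random_chains(self, trial):
        rng = np.random.default_rng(1000 + trial)
        chains = random_chain_set(rng, src_len=4000, n_chains=4)
        if not chains:
            pytest.skip("degenerate draw")
        index = ChainIndex(chains)
        table = brute_force_lift_map(chains, "src1", 4000)
        for _ in range(20):
            a = int(rng.integers(0, 3900))
            b = int(rng.integers(a + 1, 4001))
            got = [(r.target.chrom, r.target.start, r.target.end,
                    r.lifted_bases, r.target.strand)
                   for r in index.lift_interval(GenomeInterval("src1", a, b))]
            assert got == brute_force_runs(table, a, b)

    def test_position_lift_matches_table(self, rng):
        chains = random_chain_set(rng, src_len=4000, n_chains=4)
        index = ChainIndex(chains)
        table = brute_force_lift_map(chains, "src1", 4000)
        pos = np.arange(4000)
        ok, tchrom, tpos = index.lift_positions("src1", pos)
        for p in pos:
            if table[p] is None:
                assert not ok[p]
            else:
                _, chrom, _, t = table[p]
                assert ok[p] and tchrom[p] == chrom and tpos[p] == t


class TestBuildWindowMap:
    def _map(self, chains, sizes, **kw):
        return build_window_map(_windows(sizes), chains, **kw)

    def test_identity_genome_retains_everything(self):
        sizes = {"chr1": 1_000_000}
        ch = make_chain(10, "chr1", 1_000_000, 0, "chr1", 1_000_000, "+", 0,
                        [(1_000_000, 0, 0)])
        wmap = self._map([ch], sizes)
        assert (wmap["verdict"] == "retained").all()
        assert np.allclose(wmap["remap_fraction"], 1.0)

    def test_retention_rules(self):
        W = 200_000
        sizes = {"chr1": 3 * W}
        # w0: remap 0.85, span 190k -> retained
        c0 = make_chain(10, "chr1", 3 * W, 0, "t1", 10**6, "+", 0,
                        [(85_000, 30_000, 20_000), (85_000, 0, 0)])
        # w1: remap 0.79 -> rejected_low_remap (strict > 0.80)
        c1 = make_chain(10, "chr1", 3 * W, W, "t1", 10**6, "+", 400_000,
                        [(158_000, 42_000, 0)])
        # w2: remap 0.95, span 230k -> rejected_size
        c2 = make_chain(10, "chr1", 3 * W, 2 * W, "t1", 10**6, "+", 700_000,
                        [(95_000, 10_000, 40_000), (95_000, 0, 0)])
        wmap = self._map([c0, c1, c2], sizes)
        assert list(wmap["verdict"]) == ["retained", "rejected_low_remap", "rejected_size"]
        assert wmap.loc[1, "remap_fraction"] == pytest.approx(0.79)
        assert wmap.loc[2, "lifted_length"] == 230_000

    def test_exactly_80_percent_is_rejected(self):
        W = 200_000
        ch = make_chain(10, "chr1", W, 0, "t1", 10**6, "+", 0,
                        [(160_000, 40_000, 0)])
        wmap = self._map([ch], {"chr1": W})
        assert wmap.loc[0, "verdict"] == "rejected_low_remap"

    def test_split_verdict_needs_total_above_threshold(self):
        W = 200_000
        c1 = make_chain(10, "chr1", W, 0, "t1", 10**6, "+", 0, [(110_000, 0, 0)])
        c2 = make_chain(10, "chr1", W, 110_000, "t2", 10**6, "+", 0, [(90_000, 0, 0)])
        wmap = self._map([c1, c2], {"chr1": W})
        assert wmap.loc[0, "verdict"] == "rejected_split"

    def test_monotone_in_thresholds(self, rng):
        chains = random_chain_set(rng, src_len=10_000, n_chains=6)
        sizes = {"src1": 10_000}
        windows = tile_windows(sizes, 1000)
        base = build_window_map(windows, chains, min_remap=0.5, min_len=500, max_len=2000)
        stricter = build_window_map(windows, chains, min_remap=0.7, min_len=700, max_len=1500)
        assert (stricter["verdict"] == "retained").sum() <= (base["verdict"] == "retained").sum()

    def test_score_resolves_base_conflicts(self):
        low = make_chain(1, "chr1", 1000, 0, "t1", 5000, "+", 0, [(1000, 0, 0)])
        high = make_chain(99, "chr1", 1000, 200, "t2", 5000, "+", 0, [(300, 0, 0)])
        index = ChainIndex([low, high])
        runs = index.lift_interval(GenomeInterval("chr1", 0, 1000))
        assert [(r.target.chrom, r.lifted_bases) for r in runs] == \
            [("t1", 200), ("t2", 300), ("t1", 500)]


class TestMasking:
    def test_mask_base_counting(self):
        windows = pd.DataFrame({"window_id": ["w"], "chrom": ["chr1"],
                                "start": [0], "end": [200_000]})
        mask = iv.track_from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [10_000], "end": [11_000]}))
        assert iv.window_coverage(windows, mask)[0] == 1000
        empty = iv.track_from_frame(pd.DataFrame(columns=["chrom", "start", "end"]))
        assert iv.window_coverage(windows, empty)[0] == 0
        full = iv.track_from_frame(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [200_000]}))
        assert iv.window_coverage(windows, full)[0] == 200_000
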