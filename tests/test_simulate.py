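import filecmp
import math

import numpy as np
import pandas as pd
import pytest

from synpi.regress import spearman
from synpi.simulate import (SimulationConfig, coverage_pass_probability,
                            draw_landscapes, expected_pi, neutral_sfs_probs,
                            sample_population_pi, simulate_genome,
                            simulate_windows, watterson_a)


def _cfg(**kw):
    base = dict(seed=11, n_chromosomes=2, chrom_length=6_000_000)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            SimulationConfig()

    def test_sharing_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, s=1.5)

    def test_chrom_sizes_are_window_multiples(self):
        sizes = _cfg().chrom_sizes()
        W = 200_000
        assert all(v % W == 0 and v >= W for v in sizes.values())
        assert len(set(sizes.values())) > 1  # lengths vary across chromosomes


class TestLandscapes:
    def test_full_sharing_gives_identical_ranks(self):
        rng = np.random.default_rng(3)
        land = draw_landscapes(_cfg(s=1.0), rng)
        for f in ("rec", "cds", "repeat", "mut"):
            assert spearman(land.values["a"][f], land.values["b"][f]).rho == pytest.approx(1.0)

    def test_zero_sharing_decorrelates(self):
        rng = np.random.default_rng(4)
        land = draw_landscapes(_cfg(s=0.0, n_chromosomes=5,
                                    chrom_length=120_000_000), rng)
        for f in ("rec", "cds"):
            rho = spearman(land.values["a"][f], land.values["b"][f]).rho
            assert abs(rho) < 0.1  # 3000 windows: |rho| ~ 1/sqrt(n)

    def test_seed_reproducibility(self):
        l1 = draw_landscapes(_cfg(), np.random.default_rng(7))
        l2 = draw_landscapes(_cfg(), np.random.default_rng(7))
        for sp in ("a", "b"):
            for f, v in l1.values[sp].items():
                assert np.array_equal(v, l2.values[sp][f])

    def test_marginals_plausible(self):
        rng = np.random.default_rng(5)
        land = draw_landscapes(_cfg(n_chromosomes=5, chrom_length=60_000_000), rng)
        cds = land.values["a"]["cds"]
        assert 0.015 < cds.mean() < 0.025  # coding density averages ~2%
        assert (cds >= 0).all() and (cds <= 1).all()
        gc = land.values["a"]["gc"]
        r = np.corrcoef(gc, cds)[0, 1]
        assert 0.1 < r < 0.5  # GC weakly coupled to coding density


class TestExpectedPi:
    def test_background_selection_arithmetic(self):
        # d=0.1, r=0.9, k=2, eps=0.1 -> B = exp(-0.2)
        assert math.exp(-2.0 * 0.1 / (0.9 + 0.1)) == pytest.approx(0.81873075, abs=1e-8)
        cfg = _cfg(k=2.0, noise_sd=0.0)
        rng = np.random.default_rng(0)
        land = draw_landscapes(cfg, rng)
        B, Epi = expected_pi(cfg, land, rng)
        v = land.values["a"]
        assert np.allclose(B["a"], np.exp(-2.0 * v["cds"] / (v["rec"] + 0.1)))
        assert np.allclose(Epi["a"], 4 * cfg.ne_a * cfg.mu_a * v["mut"] * B["a"])

    def test_k_zero_is_neutral(self):
        cfg = _cfg(k=0.0, noise_sd=0.0)
        rng = np.random.default_rng(0)
        land = draw_landscapes(cfg, rng)
        B, Epi = expected_pi(cfg, land, rng)
        assert np.allclose(B["a"], 1.0)
        assert np.allclose(Epi["a"] / (4 * cfg.ne_a * cfg.mu_a), land.values["a"]["mut"])

    def test_zero_cds_means_no_reduction(self):
        cfg = _cfg(noise_sd=0.0)
        rng = np.random.default_rng(0)
        land = draw_landscapes(cfg, rng)
        land.values["a"]["cds"][:] = 0.0
        B, _ = expected_pi(cfg, land, rng)
        assert np.allclose(B["a"], 1.0)


class TestVariantRealisation:
    def test_watterson_and_sfs(self):
        assert watterson_a(2) == 1.0
        assert watterson_a(4) == pytest.approx(1 + 0.5 + 1 / 3)
        p = neutral_sfs_probs(30)
        assert p.sum() == pytest.approx(1.0)
        assert p[0] / p[9] == pytest.approx(10.0)  # P(1)/P(10) = 10

    def test_realised_pi_is_unbiased(self):
        # mean realised pi over replicate windows within 3 Monte-Carlo SEs
        rng = np.random.default_rng(123)
        n_rep, epi, acc = 400, 0.004, 200_000
        pi, _ = sample_population_pi(np.full(n_rep, epi),
                                     np.full(n_rep, acc), 30, rng)
        se = pi.std(ddof=1) / math.sqrt(n_rep)
        assert abs(pi.mean() - epi) < 3 * se

    def test_zero_expectation_zero_variants(self):
        rng = np.random.default_rng(1)
        pi, S = sample_population_pi(np.zeros(10), np.full(10, 1000), 30, rng)
        assert (S == 0).all() and (pi == 0).all()

    def test_coverage_pass_probability_high_at_depth_20(self):
        # Poisson(20) < 4 is vanishingly rare: >99% of sites pass for 15 diploids
        p = coverage_pass_probability(20.0, 4, 15)
        assert p > 0.99


class TestSimulateWindows:
    def test_truth_and_estimates_align(self):
        sw = simulate_windows(_cfg())
        assert len(sw.truth) == len(sw.windows)
        assert sw.truth["window_id"].is_unique
        # estimated pi regresses on truth with slope near 1
        from synpi.regress import ols

        res = ols(sw.pi["a"], pd.DataFrame({"truth": sw.truth["expected_pi_a"]}))
        assert 0.9 < res.coef("truth") < 1.1

    def test_low_site_windows_have_small_accessible_counts(self):
        sw = simulate_windows(_cfg(low_site_rate=0.2))
        low = (sw.truth["fate"] == "low_site").to_numpy()
        assert low.any()
        for sp in ("a", "b"):
            for acc in sw.accessible[sp]:
                assert (acc[low] < 10_000).all()
                assert (acc[~low] > 100_000).all()


class TestSimulateGenome:
    def test_outputs_complete_and_deterministic(self, tmp_path):
        cfg = _cfg(n_chromosomes=2, chrom_length=1_600_000, samples_per_pop=4)
        m1 = simulate_genome(cfg, tmp_path / "r1")
        simulate_genome(cfg, tmp_path / "r2")
        names = sorted(p.name for p in (tmp_path / "r1").iterdir())
        assert {"a2b.chain", "truth.tsv", "rec.tsv", "ds_a.tsv", "genes_a.gff3",
                "repeats_b.bed", "a.pop1.vcf", "b.pop2.vcf",
                "accessible_a.pop1.tsv"} <= set(names)
        for n in names:
            assert filecmp.cmp(tmp_path / "r1" / n, tmp_path / "r2" / n,
                               shallow=False), n
        # 2 chromosomes averaging 1.6 Mb with a 3x macro/micro spread:
        # 2.4 Mb + 0.8 Mb = 16 windows of 200 kb
        assert m1["n_windows"] == 16

    def test_truth_fates_round_trip_through_synteny(self, tiny_sim_dir):
        from synpi.io import read_chain_file, read_chrom_sizes
        from synpi.synteny import build_window_map, tile_windows

        sim_dir, cfg, _ = tiny_sim_dir
        truth = pd.read_csv(sim_dir / "truth.tsv", sep="\t")
        windows = tile_windows(read_chrom_sizes(sim_dir / "ref.sizes"), cfg.window_size)
        wmap = build_window_map(windows, read_chain_file(sim_dir / "a2b.chain"))
        merged = truth.merge(wmap[["window_id", "verdict"]], on="window_id")
        assert (merged["verdict"] == merged["expected_verdict"]).all()

    def test_annotations_realise_drawn_densities(self, tiny_sim_dir):
        from synpi.covariates import cds_density
        from synpi.io import read_gff_features

        sim_dir, cfg, _ = tiny_sim_dir
        truth = pd.read_csv(sim_dir / "truth.tsv", sep="\t")
        cds = read_gff_features(sim_dir / "genes_a.gff3", "CDS")
        windows = truth[["window_id", "chrom", "start", "end"]]
        d = cds_density(windows, cds)
        assert np.allclose(d, truth["cds_a"], atol=5e-5)

    def test_rearrangement_rate_zero_retains_all(self, tmp_path):
        cfg = _cfg(n_chromosomes=1, chrom_length=2_000_000, samples_per_pop=3,
                   rearrangement_rate=0.0, low_site_rate=0.0)
        simulate_genome(cfg, tmp_path / "r")
        truth = pd.read_csv(tmp_path / "r" / "truth.tsv", sep="\t")
        assert (truth["expected_verdict"] == "retained").all()
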