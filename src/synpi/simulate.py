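"""Synthetic two-species genomes with a shared linked-selection landscape.

The generator produces everything the pipeline consumes — chain files,
per-population VCFs, GFF3/BED annotations, covariate TSVs — plus a truth
table, for two "species" whose windowed diversity follows

    E[pi_s,w] = 4 * Ne_s * mu_s * m_w * B_w * exp(eta),   eta ~ N(0, noise_sd^2)

where m_w is a lognormal mutation-rate landscape, and the
background-selection factor is

    B_w = exp(-k * d_w / (r_w + eps))

with d_w the window's coding density and r_w its recombination rate (cM/Mb).
Landscapes are drawn once per window through a Gaussian copula whose latent
variable mixes a shared component z_w with a species-specific one, so the
sharing coefficient s in [0,1] tunes the cross-species landscape correlation.

Variant realisation is a windowed sufficient-statistic scheme rather than a
coalescent: per window the segregating-site count is Poisson with mean
E[pi]*sites*a_n (a_n the Watterson correction for the sampled allele copies)
and each site's alternate-allele count is drawn from the neutral site
frequency spectrum P(i) proportional to 1/i, which makes the realised window pi
an unbiased estimator of E[pi]. Both populations of a species resample one
panmictic pool (they share E[pi] but not individual variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st
import yaml

from .io import Chain, ChainBlock, GenomeInterval, write_chain_file
from .synteny import tile_windows

SPECIES = ("a", "b")
FATES = ("retained", "split", "inflate", "low_remap", "unmapped", "low_site")
FATE_TO_VERDICT = {
    "retained": "retained",
    "low_site": "retained",       # synteny keeps it; diversity QC drops it
    "split": "rejected_split",
    "inflate": "rejected_size",
    "low_remap": "rejected_low_remap",
    "unmapped": "unmapped",
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; every default is a study condition.

    Scales: chromosome lengths in bp, recombination in cM/Mb, depths in reads.
    Ne = 200 000 for both species with per-site mutation rates chosen so the
    genome-wide mean pi lands near 0.0039 (species a) and 0.0011 (species b)
    after the average background-selection reduction; coding density averages
    0.02 with range ~0-0.15; GC is weakly coupled to coding density
    (Pearson r ~ 0.28). A mandatory seed forbids silent nondeterminism.
    """

    n_chromosomes: int = 5
    chrom_length: int = 30_000_000  # mean length; actual lengths span ~3x around it
    window_size: int = 200_000
    ne_a: float = 200_000.0
    ne_b: float = 200_000.0
    mu_a: float = 5.5e-9
    mu_b: float = 1.55e-9
    rec_meanlog: float = math.log(2.0)
    rec_sdlog: float = 0.7
    cds_alpha: float = 0.55
    cds_beta: float = 27.0
    repeat_alpha: float = 2.0
    repeat_beta: float = 23.0
    gc_base: float = 0.40
    gc_cds_coupling: float = 0.35
    gc_sd: float = 0.025
    mut_sdlog: float = 0.25
    ds_scale: float = 0.12
    ds_gene_sdlog: float = 0.20
    ds_zero_fraction: float = 0.02
    ds_high_fraction: float = 0.005
    k: float = 2.0
    epsilon: float = 0.1
    s: float = 0.8
    noise_sd: float = 0.3
    samples_per_pop: int = 15
    n_pops: int = 2
    mean_depth: float = 20.0
    min_dp: int = 4
    rearrangement_rate: float = 0.05
    low_site_rate: float = 0.02
    inversion_rate: float = 0.10  # retained windows carried on a '-' strand chain
    seed: Optional[int] = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("SimulationConfig.seed is mandatory")
        if not (0.0 <= self.s <= 1.0):
            raise ValueError("landscape sharing s must be in [0, 1]")
        for name in ("mu_a", "mu_b", "k", "noise_sd", "rearrangement_rate",
                     "low_site_rate", "mean_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_copies(self) -> int:
        return 2 * self.samples_per_pop

    def chrom_sizes(self) -> dict[str, int]:
        """Declining chromosome lengths (macro -> micro), multiples of the
        window size, averaging ``chrom_length``."""
        n = self.n_chromosomes
        if n == 1:
            factors = np.array([1.0])
        else:
            factors = np.linspace(1.5, 0.5, n)
            factors = factors / factors.mean()
        W = self.window_size
        sizes = {}
        for i, f in enumerate(factors):
            sizes[f"chr{i + 1}"] = max(W, int(round(self.chrom_length * f / W)) * W)
        return sizes


def watterson_a(n: int) -> float:
    """Watterson's a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def neutral_sfs_probs(n: int) -> np.ndarray:
    """P(alt count = i) for i = 1..n-1 under the standard neutral SFS."""
    i = np.arange(1, n, dtype=np.float64)
    p = 1.0 / i
    return p / p.sum()


def coverage_pass_probability(mean_depth: float, min_dp: int, n_samples: int) -> float:
    """P(all samples have Poisson(mean_depth) depth >= min_dp)."""
    return float(st.poisson.sf(min_dp - 1, mean_depth) ** n_samples)


# ---------------------------------------------------------------------------
# landscapes and expectations
# ---------------------------------------------------------------------------


@dataclass
class Landscapes:
    windows: pd.DataFrame
    values: dict[str, dict[str, np.ndarray]]  # species -> field -> per-window array

    def frame(self, species: str) -> pd.DataFrame:
        df = self.windows.copy()
        for k, v in self.values[species].items():
            df[k] = v
        return df


def _copula_pair(rng: np.random.Generator, nwin: int, s: float):
    """Two latent N(0,1) vectors with a shared component weighted by s."""
    z = rng.standard_normal(nwin)
    ea = rng.standard_normal(nwin)
    eb = rng.standard_normal(nwin)
    norm = math.sqrt(s * s + (1.0 - s) * (1.0 - s))
    ua = (s * z + (1.0 - s) * ea) / norm
    ub = (s * z + (1.0 - s) * eb) / norm
    return ua, ub


def draw_landscapes(config: SimulationConfig, rng: np.random.Generator) -> Landscapes:
    """Per-window recombination, CDS density, repeat density, GC and mutation
    landscapes for both species, with cross-species sharing ``config.s``."""
    windows = tile_windows(config.chrom_sizes(), config.window_size)
    windows = windows[windows["full"]].reset_index(drop=True)
    nwin = len(windows)
    s = config.s
    vals = {sp: {} for sp in SPECIES}

    u_rec = _copula_pair(rng, nwin, s)
    u_cds = _copula_pair(rng, nwin, s)
    u_rep = _copula_pair(rng, nwin, s)
    u_mut = _copula_pair(rng, nwin, s)
    u_gc = _copula_pair(rng, nwin, s)
    for sp, ur, uc, up, um, ug in zip(SPECIES, u_rec, u_cds, u_rep, u_mut, u_gc):
        rec = np.exp(config.rec_meanlog + config.rec_sdlog * ur)
        cds = st.beta.ppf(st.norm.cdf(uc), config.cds_alpha, config.cds_beta)
        rep = st.beta.ppf(st.norm.cdf(up), config.repeat_alpha, config.repeat_beta)
        mut = np.exp(config.mut_sdlog * um - 0.5 * config.mut_sdlog ** 2)
        cds_mean = config.cds_alpha / (config.cds_alpha + config.cds_beta)
        gc = np.clip(config.gc_base + config.gc_cds_coupling * (cds - cds_mean)
                     + config.gc_sd * ug, 0.25, 0.75)
        vals[sp] = {"rec": rec, "cds": cds, "repeat": rep, "mut": mut, "gc": gc}
    return Landscapes(windows=windows, values=vals)


def expected_pi(config: SimulationConfig, land: Landscapes, rng: np.random.Generator):
    """Background-selection factor B_w and expected per-site pi per species."""
    out_B, out_pi = {}, {}
    for sp in SPECIES:
        v = land.values[sp]
        B = np.exp(-config.k * v["cds"] / (v["rec"] + config.epsilon))
        ne = config.ne_a if sp == "a" else config.ne_b
        mu = config.mu_a if sp == "a" else config.mu_b
        eta = rng.normal(0.0, config.noise_sd, len(B))
        out_B[sp] = B
        out_pi[sp] = 4.0 * ne * mu * v["mut"] * B * np.exp(eta)
    return out_B, out_pi


def assign_fates(config: SimulationConfig, nwin: int, rng: np.random.Generator) -> np.ndarray:
    """Per-window structural fate driving chain emission and the truth table."""
    fates = np.full(nwin, "retained", dtype=object)
    u = rng.random(nwin)
    rearranged = u < config.rearrangement_rate
    kinds = np.array(["split", "inflate", "low_remap", "unmapped"])
    fates[rearranged] = rng.choice(kinds, size=int(rearranged.sum()))
    v = rng.random(nwin)
    low = (~rearranged) & (v < config.low_site_rate)
    fates[low] = "low_site"
    return fates


# ---------------------------------------------------------------------------
# fast in-memory realisation (window summaries, no files)
# ---------------------------------------------------------------------------


def sample_population_pi(
    expected: np.ndarray,
    accessible: np.ndarray,
    n_copies: int,
    rng: np.random.Generator,
    unbiased: bool = True,
):
    """Realised window pi-hat for one population under the generator's model.

    Draws S_w ~ Poisson(E[pi]_w * accessible_w * a_n) segregating sites per
    window, alternate-allele counts from the neutral SFS, sums the unbiased
    per-site heterozygosity and divides by accessible_w. Returns (pi_hat,
    n_variable).
    """
    nwin = len(expected)
    a_n = watterson_a(n_copies)
    lam = np.maximum(expected, 0.0) * accessible * a_n
    S = rng.poisson(lam)
    total = int(S.sum())
    widx = np.repeat(np.arange(nwin), S)
    i = rng.choice(np.arange(1, n_copies), size=total, p=neutral_sfs_probs(n_copies))
    contrib = 2.0 * i * (n_copies - i) / (n_copies * (n_copies - 1.0))
    if not unbiased:
        contrib = 2.0 * i * (n_copies - i) / (n_copies * n_copies)
    num = np.bincount(widx, weights=contrib, minlength=nwin)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(accessible > 0, num / accessible, np.nan)
    return pi, S


@dataclass
class SimulatedWindows:
    """In-memory realisation: truth plus estimated window diversity."""

    config: SimulationConfig
    windows: pd.DataFrame
    truth: pd.DataFrame               # per window: landscapes, B, E[pi], fate
    pi: dict[str, np.ndarray]         # species -> species-mean pi-hat
    pi_pops: dict[str, list[np.ndarray]]
    accessible: dict[str, list[np.ndarray]]
    designed_rho: float


def simulate_windows(config: SimulationConfig,
                     sample_species: tuple[str, ...] = SPECIES) -> SimulatedWindows:
    """Fast path: landscapes -> expectations -> realised window pi, no files.

    This is the same statistical model the file emitter uses; it skips
    coordinates, genotypes and I/O, which the window-level statistics never
    see. ``sample_species`` limits variant realisation to the species a
    downstream analysis actually consumes (truth is always complete).
    """
    rng = np.random.default_rng(config.seed)
    land = draw_landscapes(config, rng)
    B, Epi = expected_pi(config, land, rng)
    nwin = len(land.windows)
    fates = assign_fates(config, nwin, rng)
    p_pass = coverage_pass_probability(config.mean_depth, config.min_dp,
                                       config.samples_per_pop)
    truth = land.windows[["window_id", "chrom", "start", "end"]].copy()
    for sp in SPECIES:
        for k, v in land.values[sp].items():
            truth[f"{k}_{sp}"] = v
        truth[f"B_{sp}"] = B[sp]
        truth[f"expected_pi_{sp}"] = Epi[sp]
        # window-level dS proxy: expected gene dS plus averaging noise
        truth[f"ds_{sp}"] = config.ds_scale * land.values[sp]["mut"] * np.exp(
            rng.normal(0.0, 0.08, nwin))
    truth["fate"] = fates

    pi_sp: dict[str, np.ndarray] = {}
    pi_pops: dict[str, list[np.ndarray]] = {}
    acc_all: dict[str, list[np.ndarray]] = {}
    W = config.window_size
    low_site = fates == "low_site"
    for sp in SPECIES:
        if sp not in sample_species:
            continue
        pops = []
        accs = []
        for _ in range(config.n_pops):
            acc = rng.binomial(W, p_pass, size=nwin).astype(np.int64)
            if low_site.any():
                acc[low_site] = rng.integers(2000, 9500, size=int(low_site.sum()))
            pi_hat, _ = sample_population_pi(Epi[sp], acc, config.n_copies, rng)
            pops.append(pi_hat)
            accs.append(acc)
        pi_sp[sp] = np.nanmean(np.vstack(pops), axis=0)
        pi_pops[sp] = pops
        acc_all[sp] = accs

    from .regress import spearman

    designed = spearman(Epi["a"], Epi["b"]).rho
    return SimulatedWindows(config=config, windows=land.windows, truth=truth,
                            pi=pi_sp, pi_pops=pi_pops, accessible=acc_all,
                            designed_rho=designed)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def _make_chain(score, src_chrom, src_size, src_start, tgt_chrom, tgt_size,
                tgt_strand, tgt_start_local, triples, chain_id) -> Chain:
    """Build a Chain from UCSC-style (size, dt, dq) triples (same arithmetic
    as the parser, so written files round-trip)."""
    spos, qpos = src_start, tgt_start_local
    blocks = []
    for size, dt, dq in triples:
        if tgt_strand == "+":
            tgt = GenomeInterval(tgt_chrom, qpos, qpos + size, "+")
        else:
            tgt = GenomeInterval(tgt_chrom, tgt_size - (qpos + size), tgt_size - qpos, "-")
        blocks.append(ChainBlock(GenomeInterval(src_chrom, spos, spos + size), tgt))
        spos += size + dt
        qpos += size + dq
    return Chain(score=score, src_chrom=src_chrom, src_size=src_size,
                 src_start=src_start, src_end=spos, tgt_chrom=tgt_chrom,
                 tgt_size=tgt_size, tgt_strand=tgt_strand,
                 tgt_start=tgt_start_local, tgt_end=qpos,
                 blocks=blocks, chain_id=chain_id)


def _emit_chains(config: SimulationConfig, windows: pd.DataFrame, fates,
                 rng: np.random.Generator):
    """Chains per window plus the per-window main target interval.

    Normal windows get a near-identity 4-block chain with <=120 bp gaps (and,
    at ``inversion_rate``, a reverse-strand target); fated windows get chains
    engineered to trip exactly one retention filter.
    """
    W = config.window_size
    n_chrom = config.n_chromosomes
    src_sizes = config.chrom_sizes()
    # target chromosomes: same names, source length + slack; split second
    # halves land in the slack region past the main layout
    tgt_sizes = {c: L + 7_000_000 for c, L in src_sizes.items()}
    chains: list[Chain] = []
    cursor = {c: 0 for c in src_sizes}
    split_cursor = {c: L + 1_000_000 for c, L in src_sizes.items()}
    target = {}  # window_id -> (tchrom, t0, t1) of the main lifted run
    cid = 1
    for row, fate in zip(windows.itertuples(index=False), fates):
        chrom, ws = row.chrom, row.start
        src_size = src_sizes[chrom]
        tchrom = chrom
        tgt_size = tgt_sizes[tchrom]
        t0 = cursor[chrom]
        score = 1000.0 + float(rng.integers(0, 100))
        if fate == "unmapped":
            target[row.window_id] = (tchrom, t0, t0 + W)
            cursor[chrom] = t0 + W + 1000
            cid += 1
            continue
        if fate == "split":
            half1 = int(0.55 * W)
            other = f"chr{(int(chrom[3:]) % n_chrom) + 1}"
            o0 = split_cursor[other]
            chains.append(_make_chain(score, chrom, src_size, ws, tchrom, tgt_size,
                                      "+", t0, [(half1, 0, 0)], cid))
            chains.append(_make_chain(score, chrom, src_size, ws + half1, other,
                                      tgt_sizes[other], "+", o0,
                                      [(W - half1, 0, 0)], cid + 1))
            split_cursor[other] = o0 + (W - half1) + 1000
            target[row.window_id] = (tchrom, t0, t0 + half1)
            cursor[chrom] = t0 + half1 + 1000
            cid += 2
            continue
        if fate == "inflate":
            sizes = (W // 2, W - W // 2)
            triples = [(sizes[0], 0, 30_000), (sizes[1], 0, 0)]
            span = W + 30_000
            strand = "+"
        elif fate == "low_remap":
            gap = W // 4
            sizes = ((W - gap) // 2, (W - gap) - (W - gap) // 2)
            triples = [(sizes[0], gap, 0), (sizes[1], 0, 0)]
            span = W - gap
            strand = "+"
        else:  # retained / low_site: near-identity with small gaps
            dts = rng.integers(0, 120, size=3)
            dqs = rng.integers(0, 120, size=3)
            body = W - int(dts.sum())
            cuts = np.sort(rng.integers(1, body, size=3))
            sizes = np.diff(np.concatenate([[0], cuts, [body]]))
            while (sizes <= 0).any():  # degenerate cut draw; redraw
                cuts = np.sort(rng.integers(1, body, size=3))
                sizes = np.diff(np.concatenate([[0], cuts, [body]]))
            triples = [(int(sizes[0]), int(dts[0]), int(dqs[0])),
                       (int(sizes[1]), int(dts[1]), int(dqs[1])),
                       (int(sizes[2]), int(dts[2]), int(dqs[2])),
                       (int(sizes[3]), 0, 0)]
            span = W - int(dts.sum()) + int(dqs.sum())
            strand = "-" if rng.random() < config.inversion_rate else "+"
        local = t0 if strand == "+" else tgt_size - (t0 + span)
        chains.append(_make_chain(score, chrom, src_size, ws, tchrom, tgt_size,
                                  strand, local, triples, cid))
        target[row.window_id] = (tchrom, t0, t0 + span)
        cursor[chrom] = t0 + span + 1000
        cid += 1
    return chains, target, tgt_sizes


def _place_intervals(total: int, region_start: int, region_len: int,
                     rng: np.random.Generator, min_len=150, max_len=2000):
    """Non-overlapping intervals of summed length ``total`` inside a region."""
    total = int(min(total, int(0.95 * region_len)))
    if total <= 0:
        return []
    lens = []
    remaining = total
    while remaining > 0:
        L = int(min(remaining, rng.integers(min_len, max_len + 1)))
        lens.append(L)
        remaining -= L
    free = region_len - total
    gaps = rng.multinomial(free, np.ones(len(lens) + 1) / (len(lens) + 1))
    out = []
    pos = region_start
    for g, L in zip(gaps[:-1], lens):
        pos += int(g)
        out.append((pos, pos + L))
        pos += L
    return out


def _genotype_fields(S, n_samples, alt_counts, mean_depth, rng):
    """Random assortment of alt copies into diploid genotypes + Poisson depths."""
    n_copies = 2 * n_samples
    U = rng.random((S, n_copies))
    ranks = np.argsort(np.argsort(U, axis=1), axis=1)
    alleles = ranks < alt_counts[:, None]
    codes = alleles[:, 0::2].astype(np.int8) + alleles[:, 1::2].astype(np.int8)
    depths = rng.poisson(mean_depth, size=(S, n_samples))
    return codes, depths


_GT = np.array(["0/0", "0/1", "1/1"])
_BASES = np.array(list("ACGT"))


def _write_vcf(path, chrom_records, samples, chrom_sizes):
    """chrom_records: {chrom: (pos0 sorted, ref, alt, codes, depths)}."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=synpi-simulate\n")
        for c, L in chrom_sizes.items():
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom in chrom_sizes:
            rec = chrom_records.get(chrom)
            if rec is None:
                continue
            pos0, ref, alt, codes, depths = rec
            if len(pos0) == 0:
                continue
            gt = _GT[codes]
            cols = np.char.add(np.char.add(gt.astype("U3"), ":"),
                               depths.astype("U6"))
            body = np.array(["\t".join(r) for r in cols])
            lead = np.array([
                f"{chrom}\t{p + 1}\t.\t{r}\t{a}\t.\tPASS\t.\tGT:DP\t"
                for p, r, a in zip(pos0, ref, alt)
            ])
            fh.write("\n".join(np.char.add(lead, body)))
            fh.write("\n")


def _distinct_positions(lo, hi, S, rng):
    """S distinct uniform positions in [lo, hi), sorted."""
    S = int(min(S, hi - lo))
    pos = np.unique(rng.integers(lo, hi, size=S))
    while len(pos) < S:
        extra = rng.integers(lo, hi, size=S - len(pos) + 8)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos[:S] if len(pos) == S else np.sort(rng.permutation(pos)[:S])


def _emit_population_vcf(path, config, windows_target, rng, samples, chrom_sizes):
    """One population's VCF: per window, Poisson site counts at the window's
    (possibly lifted) coordinates, SFS allele counts, random genotypes."""
    a_n = watterson_a(config.n_copies)
    sfs = neutral_sfs_probs(config.n_copies)
    per_chrom: dict[str, list] = {}
    for (chrom, lo, hi), e_pi, acc in windows_target:
        lam = max(e_pi, 0.0) * acc * a_n
        S = int(rng.poisson(lam))
        if S == 0:
            continue
        pos = _distinct_positions(lo, hi, S, rng)
        S = len(pos)
        i = rng.choice(np.arange(1, config.n_copies), size=S, p=sfs)
        ref_idx = rng.integers(0, 4, size=S)
        alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
        codes, depths = _genotype_fields(S, config.samples_per_pop, i,
                                         config.mean_depth, rng)
        per_chrom.setdefault(chrom, []).append(
            (pos, _BASES[ref_idx], _BASES[alt_idx], codes, depths))
    merged = {}
    for chrom, parts in per_chrom.items():
        pos = np.concatenate([p[0] for p in parts])
        order = np.argsort(pos, kind="stable")
        merged[chrom] = (
            pos[order],
            np.concatenate([p[1] for p in parts])[order],
            np.concatenate([p[2] for p in parts])[order],
            np.vstack([p[3] for p in parts])[order],
            np.vstack([p[4] for p in parts])[order],
        )
    _write_vcf(path, merged, samples, chrom_sizes)


def _write_gff3(path, rows):
    """rows: (chrom, start0, end0, gene_id) -> gene + CDS feature pairs."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, s, e, gid in rows:
            fh.write(f"{chrom}\tsynpi_sim\tgene\t{s + 1}\t{e}\t.\t+\t.\tID={gid}\n")
            fh.write(f"{chrom}\tsynpi_sim\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                     f"ID=cds-{gid};Parent={gid}\n")


def simulate_genome(config: SimulationConfig, out_dir) -> dict:
    """Emit the full synthetic dataset to ``out_dir``; returns a manifest.

    Files: ref.sizes / target.sizes, a2b.chain, genes_{a,b}.gff3,
    repeats_{a,b}.bed, rec.tsv, gc_{a,b}.tsv, ds_a.tsv,
    accessible_{sp}.pop{i}.tsv, {sp}.pop{i}.vcf, truth.tsv, sim_meta.yaml.
    Byte-identical for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    r_land, r_fate, r_chain, r_annot, r_acc, r_vcf = [
        np.random.default_rng(c) for c in ss.spawn(6)]

    land = draw_landscapes(config, r_land)
    B, Epi = expected_pi(config, land, r_land)
    windows = land.windows
    nwin = len(windows)
    fates = assign_fates(config, nwin, r_fate)
    chains, target, tgt_sizes = _emit_chains(config, windows, fates, r_chain)
    write_chain_file(chains, out / "a2b.chain")

    src_sizes = config.chrom_sizes()
    pd.DataFrame(src_sizes.items()).to_csv(out / "ref.sizes", sep="\t",
                                           header=False, index=False)
    pd.DataFrame(tgt_sizes.items()).to_csv(out / "target.sizes", sep="\t",
                                           header=False, index=False)

    # annotations + per-gene dS (species a) realising the drawn landscapes
    W = config.window_size
    gff_rows = {sp: [] for sp in SPECIES}
    bed_rows = {sp: [] for sp in SPECIES}
    ds_rows = []
    gid = 0
    for wi, row in enumerate(windows.itertuples(index=False)):
        tchrom, t0, t1 = target[row.window_id]
        regions = {"a": (row.chrom, row.start, W),
                   "b": (tchrom, t0, min(W, t1 - t0))}
        for sp in SPECIES:
            chrom, lo, rlen = regions[sp]
            cds_total = int(round(land.values[sp]["cds"][wi] * W))
            exons = _place_intervals(cds_total, lo, rlen, r_annot)
            for s0, e0 in exons:
                gid += 1
                gff_rows[sp].append((chrom, s0, e0, f"g{sp}{gid}"))
                if sp == "a":
                    u = r_annot.random()
                    if u < config.ds_zero_fraction:
                        ds = 0.0
                    elif u < config.ds_zero_fraction + config.ds_high_fraction:
                        ds = float(2.1 + 2.9 * r_annot.random())
                    else:
                        ds = float(config.ds_scale * land.values["a"]["mut"][wi]
                                   * np.exp(r_annot.normal(0.0, config.ds_gene_sdlog)))
                    ds_rows.append((chrom, s0, e0, f"ga{gid}", ds))
            rep_total = int(round(land.values[sp]["repeat"][wi] * W))
            for s0, e0 in _place_intervals(rep_total, lo, rlen, r_annot,
                                           min_len=100, max_len=5000):
                bed_rows[sp].append((chrom, s0, e0))
    for sp in SPECIES:
        _write_gff3(out / f"genes_{sp}.gff3", gff_rows[sp])
        pd.DataFrame(bed_rows[sp], columns=["chrom", "start", "end"]).to_csv(
            out / f"repeats_{sp}.bed", sep="\t", header=False, index=False)
    pd.DataFrame(ds_rows, columns=["chrom", "start", "end", "gene_id", "ds"]).to_csv(
        out / "ds_a.tsv", sep="\t", index=False)

    # per-window covariate TSVs
    base_cols = windows[["window_id", "chrom", "start", "end"]]
    rec_df = base_cols.copy()
    rec_df["rec_rate"] = land.values["a"]["rec"]
    rec_df.to_csv(out / "rec.tsv", sep="\t", index=False)
    for sp in SPECIES:
        gc_df = base_cols.copy()
        gc_df["gc"] = land.values[sp]["gc"]
        gc_df.to_csv(out / f"gc_{sp}.tsv", sep="\t", index=False)

    # accessibility + variants
    p_pass = coverage_pass_probability(config.mean_depth, config.min_dp,
                                       config.samples_per_pop)
    low_site = fates == "low_site"
    pop_names = [f"pop{i + 1}" for i in range(config.n_pops)]
    for sp in SPECIES:
        sizes = src_sizes if sp == "a" else tgt_sizes
        for pop in pop_names:
            acc = r_acc.binomial(W, p_pass, size=nwin).astype(np.int64)
            if low_site.any():
                acc[low_site] = r_acc.integers(2000, 9500, size=int(low_site.sum()))
            acc_df = base_cols.copy()
            acc_df["n_sites"] = acc
            acc_df.to_csv(out / f"accessible_{sp}.{pop}.tsv", sep="\t", index=False)
            wt = []
            for wi, row in enumerate(windows.itertuples(index=False)):
                if sp == "a":
                    region = (row.chrom, row.start, row.end)
                else:
                    tchrom, t0, t1 = target[row.window_id]
                    region = (tchrom, t0, t1)
                wt.append((region, Epi[sp][wi], acc[wi]))
            samples = [f"{sp}_{pop}_s{j + 1}" for j in range(config.samples_per_pop)]
            _emit_population_vcf(out / f"{sp}.{pop}.vcf", config, wt, r_vcf,
                                 samples, sizes)

    truth = base_cols.copy()
    for sp in SPECIES:
        for k, v in land.values[sp].items():
            truth[f"{k}_{sp}"] = v
        truth[f"B_{sp}"] = B[sp]
        truth[f"expected_pi_{sp}"] = Epi[sp]
    truth["fate"] = fates
    truth["expected_verdict"] = [FATE_TO_VERDICT[f] for f in fates]
    truth["target_chrom"] = [target[w][0] for w in windows["window_id"]]
    truth["target_start"] = [target[w][1] for w in windows["window_id"]]
    truth["target_end"] = [target[w][2] for w in windows["window_id"]]
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    from .regress import spearman

    meta = {
        "designed_rho_spearman": float(spearman(Epi["a"], Epi["b"]).rho),
        "n_windows": int(nwin),
        "coverage_pass_probability": p_pass,
        "config": {k: (v if not isinstance(v, float) else float(v))
                   for k, v in asdict(config).items()},
    }
    with open(out / "sim_meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return meta
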