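import numpy as np
import pytest

from synpi.io import Chain, ChainBlock, GenomeInterval
from synpi.simulate import _make_chain


def make_chain(score, src_chrom, src_size, src_start, tgt_chrom, tgt_size,
               tgt_strand, tgt_start_local, triples, chain_id=None) -> Chain:
    """Chain builder from UCSC (size, dt, dq) triples, shared by tests."""
    return _make_chain(score, src_chrom, src_size, src_start, tgt_chrom,
                       tgt_size, tgt_strand, tgt_start_local, triples, chain_id)


def brute_force_lift_map(chains, src_chrom, length):
    """Per-base lift table for positions 0..length-1 of one source chromosome.

    Independent of ChainIndex: scans every chain/block per position, resolving
    overlaps by (-score, chain order). Entry: None or
    (chain_idx, tgt_chrom, strand, tgt_pos).
    """
    table = [None] * length
    for pos in range(length):
        best = None
        for ci, ch in enumerate(chains):
            if ch.src_chrom != src_chrom:
                continue
            for blk in ch.blocks:
                if blk.source.start <= pos < blk.source.end:
                    key = (-ch.score, ci)
                    if best is None or key < best[0]:
                        if blk.target.strand == "+":
                            t = blk.target.start + (pos - blk.source.start)
                        else:
                            t = blk.target.end - 1 - (pos - blk.source.start)
                        best = (key, ci, blk.target.chrom, blk.target.strand, t)
        if best is not None:
            table[pos] = best[1:]
    return table


def brute_force_runs(table, start, end):
    """Group the per-base lift table into runs over [start, end).

    A run is a maximal source-ordered stretch of mapped bases sharing
    (chain, target chrom, strand); returns
    [(tgt_chrom, span_start, span_end, lifted_bases, strand), ...].
    """
    runs = []
    cur = None  # [sig, tmin, tmax, count]
    for pos in range(start, end):
        entry = table[pos]
        if entry is None:
            continue
        ci, chrom, strand, t = entry
        sig = (ci, chrom, strand)
        if cur is not None and cur[0] == sig:
            cur[1] = min(cur[1], t)
            cur[2] = max(cur[2], t)
            cur[3] += 1
        else:
            if cur is not None:
                runs.append((cur[0][1], cur[1], cur[2] + 1, cur[3], cur[0][2]))
            cur = [sig, t, t, 1]
    if cur is not None:
        runs.append((cur[0][1], cur[1], cur[2] + 1, cur[3], cur[0][2]))
    return runs


def random_chain_set(rng, src_len=10_000, n_chains=5):
    """Random, possibly overlapping chains on one small source chromosome."""
    chains = []
    for ci in range(n_chains):
        src_start = int(rng.integers(0, src_len - 500))
        tgt_chrom = f"t{int(rng.integers(1, 3))}"
        strand = "+" if rng.random() < 0.7 else "-"
        n_blocks = int(rng.integers(1, 5))
        triples = []
        src_pos = src_start
        for b in range(n_blocks):
            size = int(rng.integers(20, 400))
            dt = int(rng.integers(0, 200)) if b < n_blocks - 1 else 0
            dq = int(rng.integers(0, 200)) if b < n_blocks - 1 else 0
            if src_pos + size > src_len:
                size = src_len - src_pos
                if size <= 0:
                    break
                triples.append((size, 0, 0))
                break
            triples.append((size, dt, dq))
            src_pos += size + dt
        if not triples:
            continue
        triples[-1] = (triples[-1][0], 0, 0)
        tgt_start = int(rng.integers(0, 50_000))
        chains.append(make_chain(
            float(rng.integers(1, 5000)), "src1", src_len, src_start,
            tgt_chrom, 100_000, strand, tgt_start, triples, chain_id=ci + 1))
    return chains


@pytest.fixture
def rng():
    return np.random.default_rng(20170222)


@pytest.fixture(scope="session")
def tiny_sim_dir(tmp_path_factory):
    """Small file-based simulated dataset shared by pipeline-level tests."""
    from synpi.simulate import SimulationConfig, simulate_genome

    out = tmp_path_factory.mktemp("sim") / "tiny"
    cfg = SimulationConfig(seed=424242, n_chromosomes=2, chrom_length=6_000_000,
                           samples_per_pop=5, rearrangement_rate=0.15,
                           low_site_rate=0.1)
    meta = simulate_genome(cfg, out)
    return out, cfg, meta
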