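"""Readers and writers for the external formats the pipeline consumes.

All internal coordinates are 0-based half-open; the only places 1-based
coordinates exist are the VCF reader boundary (POS) and GFF3 ingestion
(delegated to pyranges, which converts on read). UCSC chain files are parsed
here because no installed library handles them; everything else goes through
cyvcf2 / pyranges / pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from cyvcf2 import VCF


# ---------------------------------------------------------------------------
# core coordinate types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChainBlock:
    """One gapless aligned block; source and target spans have equal length.

    Target coordinates are stored on the forward strand regardless of the
    chain's declared target strand; ``target.strand`` records orientation.
    """

    source: GenomeInterval
    target: GenomeInterval

    def __post_init__(self):
        if self.source.length != self.target.length:
            raise ValueError("chain block with unequal source/target lengths")


@dataclass
class Chain:
    score: float
    src_chrom: str
    src_size: int
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_size: int
    tgt_strand: str
    tgt_start: int  # strand-local, as in the file
    tgt_end: int
    blocks: list[ChainBlock] = field(default_factory=list)
    chain_id: Optional[int] = None


class ChainParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# UCSC chain format
# ---------------------------------------------------------------------------


def read_chain_file(path) -> list[Chain]:
    """Parse a UCSC chain file into Chain objects with forward-strand blocks.

    Header fields follow the UCSC convention
    ``chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart
    qEnd [id]`` where the t-side is the lift *source* and the q-side the
    *target*. Block lines are ``size dt dq`` triples (dt = gap on the source,
    dq = gap on the target), terminated by a bare ``size`` line. Block
    arithmetic must tile the declared spans exactly.
    """
    chains: list[Chain] = []
    cur: Optional[Chain] = None
    spos = qpos = 0
    expecting_blocks = False

    def finalize(line_no):
        nonlocal cur, expecting_blocks
        if cur is not None and expecting_blocks:
            raise ChainParseError(f"line {line_no}: chain not terminated by a bare size line")
        cur = None

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "chain":
                finalize(line_no)
                if len(tok) not in (12, 13):
                    raise ChainParseError(f"line {line_no}: malformed chain header")
                try:
                    score = float(tok[1])
                    t_size, t_start, t_end = int(tok[3]), int(tok[5]), int(tok[6])
                    q_size, q_start, q_end = int(tok[8]), int(tok[10]), int(tok[11])
                except ValueError as exc:
                    raise ChainParseError(f"line {line_no}: non-numeric header field") from exc
                if tok[4] != "+":
                    raise ChainParseError(f"line {line_no}: source strand must be '+'")
                if tok[9] not in ("+", "-"):
                    raise ChainParseError(f"line {line_no}: bad target strand {tok[9]!r}")
                cur = Chain(
                    score=score,
                    src_chrom=tok[2], src_size=t_size, src_start=t_start, src_end=t_end,
                    tgt_chrom=tok[7], tgt_size=q_size, tgt_strand=tok[9],
                    tgt_start=q_start, tgt_end=q_end,
                    chain_id=int(tok[12]) if len(tok) == 13 else None,
                )
                spos, qpos = t_start, q_start
                expecting_blocks = True
                chains.append(cur)
                continue
            if cur is None:
                raise ChainParseError(f"line {line_no}: block data before any chain header")
            if len(tok) not in (1, 3):
                raise ChainParseError(f"line {line_no}: expected 'size [dt dq]'")
            try:
                size = int(tok[0])
                dt = int(tok[1]) if len(tok) == 3 else 0
                dq = int(tok[2]) if len(tok) == 3 else 0
            except ValueError as exc:
                raise ChainParseError(f"line {line_no}: non-integer block field") from exc
            if size <= 0 or dt < 0 or dq < 0:
                raise ChainParseError(f"line {line_no}: bad block geometry")
            if cur.tgt_strand == "+":
                tgt = GenomeInterval(cur.tgt_chrom, qpos, qpos + size, "+")
            else:
                tgt = GenomeInterval(
                    cur.tgt_chrom, cur.tgt_size - (qpos + size), cur.tgt_size - qpos, "-"
                )
            cur.blocks.append(
                ChainBlock(GenomeInterval(cur.src_chrom, spos, spos + size), tgt)
            )
            spos += size + dt
            qpos += size + dq
            if spos > cur.src_end or qpos > cur.tgt_end:
                raise ChainParseError(
                    f"line {line_no}: block arithmetic overshoots declared chain span"
                )
            if len(tok) == 1:
                if spos != cur.src_end or qpos != cur.tgt_end:
                    raise ChainParseError(
                        f"line {line_no}: blocks do not tile the declared chain span"
                    )
                cur = None
                expecting_blocks = False
    finalize("EOF")
    return chains


def write_chain_file(chains: Sequence[Chain], path) -> None:
    """Inverse of :func:`read_chain_file`; round-trips block structure exactly."""
    with open(path, "w") as fh:
        for ch in chains:
            score = int(ch.score) if float(ch.score).is_integer() else ch.score
            head = (
                f"chain {score} {ch.src_chrom} {ch.src_size} + {ch.src_start} {ch.src_end}"
                f" {ch.tgt_chrom} {ch.tgt_size} {ch.tgt_strand} {ch.tgt_start} {ch.tgt_end}"
            )
            if ch.chain_id is not None:
                head += f" {ch.chain_id}"
            fh.write(head + "\n")
            for i, blk in enumerate(ch.blocks):
                size = blk.source.length
                if i + 1 < len(ch.blocks):
                    nxt = ch.blocks[i + 1]
                    dt = nxt.source.start - blk.source.end
                    if ch.tgt_strand == "+":
                        dq = nxt.target.start - blk.target.end
                    else:
                        dq = blk.target.start - nxt.target.end
                    fh.write(f"{size} {dt} {dq}\n")
                else:
                    fh.write(f"{size}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class SiteRecord:
    """One bi-allelic SNP: 1-based position, per-sample genotypes and depths.

    ``genotypes`` is an (n_samples, 2) int array of allele codes (0 ref,
    1 alt, -1 missing); ``depths`` an (n_samples,) int array.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    depths: np.ndarray


class SiteStream:
    """Stream of bi-allelic SNP records from a VCF restricted to a region.

    Converts VCF 1-based POS to the region's 0-based half-open frame for the
    inclusion test; multi-allelic and non-SNP records are skipped and counted
    in ``n_skipped_multiallelic`` / ``n_skipped_non_snp``.
    """

    def __init__(self, vcf_path, region: Optional[GenomeInterval] = None):
        self.vcf_path = str(vcf_path)
        self.region = region
        self.n_skipped_multiallelic = 0
        self.n_skipped_non_snp = 0
        self.samples: list[str] = list(VCF(self.vcf_path).samples)

    def __iter__(self) -> Iterator[SiteRecord]:
        vcf = VCF(self.vcf_path)
        last: tuple[str, int] | None = None
        seen_chroms: set[str] = set()
        for rec in vcf:
            if last is not None and rec.CHROM == last[0] and rec.POS < last[1]:
                raise ValueError(f"unsorted VCF {self.vcf_path}: {rec.CHROM}:{rec.POS}")
            if rec.CHROM != (last[0] if last else None):
                if rec.CHROM in seen_chroms:
                    raise ValueError(f"unsorted VCF {self.vcf_path}: chromosome {rec.CHROM} repeats")
                seen_chroms.add(rec.CHROM)
            last = (rec.CHROM, rec.POS)
            if self.region is not None:
                if rec.CHROM != self.region.chrom:
                    continue
                pos0 = rec.POS - 1
                if not (self.region.start <= pos0 < self.region.end):
                    continue
            if len(rec.ALT) > 1:
                self.n_skipped_multiallelic += 1
                continue
            if not rec.is_snp or len(rec.ALT) == 0:
                self.n_skipped_non_snp += 1
                continue
            try:
                dp = rec.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                raise ValueError(
                    f"{self.vcf_path}: per-sample DP FORMAT field is required for the "
                    "coverage filter but is absent"
                )
            gt = rec.genotype.array()[:, :2].astype(np.int16)
            yield SiteRecord(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                genotypes=gt, depths=dp.reshape(-1).astype(np.int64),
            )


def read_sites(vcf_path, region: Optional[GenomeInterval] = None) -> SiteStream:
    return SiteStream(vcf_path, region)


@dataclass
class PopulationSites:
    """Whole-VCF bi-allelic SNP summaries, per chromosome, for one population.

    Arrays per chromosome: ``pos0`` (0-based site positions, sorted),
    ``alt_count`` / ``called_count`` (allele copies), ``min_depth`` (minimum
    per-sample DP at the site), ``alt`` (alt base). Monomorphic records in an
    all-sites VCF are kept with alt_count 0 so they can enter the
    qualifying-site denominator.
    """

    samples: list[str]
    chroms: list[str]
    pos0: dict[str, np.ndarray]
    alt_count: dict[str, np.ndarray]
    called_count: dict[str, np.ndarray]
    min_depth: dict[str, np.ndarray]
    alt: dict[str, np.ndarray]
    n_skipped_multiallelic: int = 0
    n_skipped_non_snp: int = 0


def load_population_sites(vcf_path, keep_monomorphic: bool = True) -> PopulationSites:
    """Single streaming pass over a VCF into per-chromosome numpy arrays."""
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    acc: dict[str, list] = {}
    n_multi = n_nonsnp = 0
    last: tuple[str, int] | None = None
    for rec in vcf:
        if last is not None and rec.CHROM == last[0] and rec.POS < last[1]:
            raise ValueError(f"unsorted VCF {vcf_path}: {rec.CHROM}:{rec.POS}")
        last = (rec.CHROM, rec.POS)
        if len(rec.ALT) > 1:
            n_multi += 1
            continue
        monomorphic = len(rec.ALT) == 0
        if not monomorphic and not rec.is_snp:
            n_nonsnp += 1
            continue
        if monomorphic and not keep_monomorphic:
            continue
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            raise ValueError(
                f"{vcf_path}: per-sample DP FORMAT field is required for the coverage filter"
            )
        gt = rec.genotype.array()[:, :2]
        alt_ct = int((gt == 1).sum())
        called = int((gt >= 0).sum())
        acc.setdefault(rec.CHROM, []).append(
            (rec.POS - 1, alt_ct, called, int(dp.min()), rec.ALT[0] if rec.ALT else ".")
        )
    chroms = list(acc)
    pos0, altc, callc, mind, alts = {}, {}, {}, {}, {}
    for c, rows in acc.items():
        arr = np.array([r[:4] for r in rows], dtype=np.int64)
        pos0[c], altc[c], callc[c], mind[c] = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
        alts[c] = np.array([r[4] for r in rows])
    return PopulationSites(
        samples=samples, chroms=chroms, pos0=pos0, alt_count=altc,
        called_count=callc, min_depth=mind, alt=alts,
        n_skipped_multiallelic=n_multi, n_skipped_non_snp=n_nonsnp,
    )


# ---------------------------------------------------------------------------
# tables: chrom sizes, BED, GFF3, covariate TSVs
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={0: str})
    if df["chrom"].duplicated().any():
        raise ValueError(f"{path}: duplicate chromosome names")
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> frame with chrom/start/end."""
    gr = pr.read_bed(str(path))
    df = gr.df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    return df[["chrom", "start", "end"]].astype({"start": np.int64, "end": np.int64})


def read_gff_features(path, feature: str) -> pd.DataFrame:
    """GFF3 features of one type as 0-based half-open chrom/start/end rows."""
    gr = pr.read_gff3(str(path))
    df = gr.df
    df = df[df["Feature"] == feature]
    out = df.rename(columns={"Chromosome": "chrom", "Start": "start", "End": "end"})
    return out[["chrom", "start", "end"]].reset_index(drop=True).astype(
        {"start": np.int64, "end": np.int64}
    )


def read_tsv_covariate(path, key_columns: Sequence[str], value_column: str) -> dict:
    """Strict keyed covariate reader: window key tuple -> float (NaN = missing)."""
    df = pd.read_csv(path, sep="\t", dtype={k: str for k in key_columns})
    missing = [c for c in list(key_columns) + [value_column] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    keys = list(map(tuple, df[list(key_columns)].itertuples(index=False, name=None)))
    if len(set(keys)) != len(keys):
        dup = pd.Series(keys)[pd.Series(keys).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate window key {dup}")
    vals = pd.to_numeric(df[value_column], errors="coerce")
    out = {}
    for k, v in zip(keys, vals):
        out[k if len(k) > 1 else k[0]] = float(v) if pd.notna(v) else float("nan")
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
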