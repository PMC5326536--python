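"""Per-window genomic covariates and their variance-stabilising transforms.

Five predictors of windowed diversity: recombination rate (cM/Mb, from an
external linkage-map TSV), coding-sequence density (union of CDS bases per
window), gene-length-weighted synonymous substitution rate dS (a mutation-rate
proxy, with the standard exclusions), intergenic GC fraction and repeat
density; plus chromosome length. Skewed predictors are transformed —
sqrt for CDS density and dS, log10(x+1) for recombination rate.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import intervals as iv


def cds_density(windows: pd.DataFrame, cds: pd.DataFrame) -> np.ndarray:
    """Union of CDS bases per window / window length. Strand-agnostic;
    overlapping CDS records count once."""
    track = iv.track_from_frame(cds)
    cov = iv.window_coverage(windows, track)
    return cov / (windows["end"] - windows["start"]).to_numpy()


def repeat_density(windows: pd.DataFrame, repeats: pd.DataFrame) -> np.ndarray:
    track = iv.track_from_frame(repeats)
    cov = iv.window_coverage(windows, track)
    return cov / (windows["end"] - windows["start"]).to_numpy()


def windowed_gc(
    windows: pd.DataFrame,
    fasta=None,
    gc_by_window: Optional[Mapping[str, float]] = None,
    genes: Optional[pd.DataFrame] = None,
    min_bases: int = 1000,
) -> np.ndarray:
    """Intergenic GC fraction per window.

    Either precomputed (``gc_by_window``: window_id -> fraction) or computed
    from a FASTA over intergenic (complement of gene spans), non-N bases;
    missing (NaN) when fewer than ``min_bases`` such bases exist.
    """
    if gc_by_window is not None:
        return np.array([gc_by_window.get(w, np.nan) for w in windows["window_id"]])
    if fasta is None:
        raise ValueError("need either a FASTA or a per-window GC table")
    import pyfaidx

    fa = fasta if isinstance(fasta, pyfaidx.Fasta) else pyfaidx.Fasta(str(fasta))
    gene_track = iv.track_from_frame(genes) if genes is not None else {}
    out = np.full(len(windows), np.nan)
    for i, w in enumerate(windows.itertuples(index=False)):
        seq = str(fa[str(w.chrom)][w.start:w.end]).upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        keep = np.ones(len(arr), dtype=bool)
        ivs = gene_track.get(str(w.chrom))
        if ivs is not None:
            for s, e in zip(*ivs):
                s, e = max(s, w.start), min(e, w.end)
                if s < e:
                    keep[s - w.start:e - w.start] = False
        sub = arr[keep]
        acgt = np.isin(sub, np.frombuffer(b"ACGT", dtype=np.uint8))
        sub = sub[acgt]
        if len(sub) < min_bases:
            continue
        gc = np.isin(sub, np.frombuffer(b"GC", dtype=np.uint8)).sum()
        out[i] = gc / len(sub)
    return out


def weighted_ds(
    windows: pd.DataFrame,
    genes_ds: pd.DataFrame,
    exclude_zero: bool = True,
    max_gene_ds: float = 2.0,
    max_window_ds: float = 0.3,
    mode: str = "overlap",
) -> np.ndarray:
    """Length-weighted mean dS of the genes in each window.

    Genes with dS == 0 or dS > ``max_gene_ds`` are excluded before
    averaging; a window whose weighted mean exceeds ``max_window_ds`` — or
    that has no surviving genes — is missing. ``mode='overlap'`` weights each
    gene by its overlap with the window (genes spanning a border contribute
    proportionally); ``'midpoint'`` assigns the whole gene length to the
    window holding its midpoint.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError("mode must be 'overlap' or 'midpoint'")
    g = genes_ds.copy()
    if (g["ds"] < 0).any():
        raise ValueError("negative dS in gene table")
    keep = g["ds"] <= max_gene_ds
    if exclude_zero:
        keep &= g["ds"] > 0
    g = g[keep]
    out = np.full(len(windows), np.nan)
    by_chrom = {c: grp.sort_values("start") for c, grp in g.groupby("chrom", sort=False)}
    for i, w in enumerate(windows.itertuples(index=False)):
        grp = by_chrom.get(str(w.chrom))
        if grp is None:
            continue
        if mode == "overlap":
            s = np.maximum(grp["start"].to_numpy(), w.start)
            e = np.minimum(grp["end"].to_numpy(), w.end)
            weight = np.maximum(e - s, 0)
        else:
            mid = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            inside = (mid >= w.start) & (mid < w.end)
            weight = np.where(inside, grp["end"].to_numpy() - grp["start"].to_numpy(), 0)
        total = weight.sum()
        if total == 0:
            continue
        mean = float((grp["ds"].to_numpy() * weight).sum() / total)
        if mean <= max_window_ds:
            out[i] = mean
    return out


def transform_predictors(table: pd.DataFrame) -> pd.DataFrame:
    """Add transformed columns alongside the raw predictors.

    cds_sqrt = sqrt(cds_density); ds_sqrt = sqrt(ds);
    rec_log10 = log10(rec_rate + 1). GC and repeat density stay untransformed.
    Missing values propagate.
    """
    out = table.copy()
    if "cds_density" in out:
        out["cds_sqrt"] = np.sqrt(out["cds_density"])
    if "ds" in out:
        out["ds_sqrt"] = np.sqrt(out["ds"])
    if "rec_rate" in out:
        out["rec_log10"] = np.log10(out["rec_rate"] + 1.0)
    return out


def build_covariate_table(
    windows: pd.DataFrame,
    cds: pd.DataFrame,
    repeats: pd.DataFrame,
    genes_ds: pd.DataFrame,
    rec_by_window: Mapping[str, float],
    chrom_sizes: Mapping[str, int],
    gc_by_window: Optional[Mapping[str, float]] = None,
    fasta=None,
    genes: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assemble the full per-window predictor table (raw + transformed)."""
    t = windows[["window_id", "chrom", "start", "end"]].copy()
    t["cds_density"] = cds_density(windows, cds)
    t["repeat_density"] = repeat_density(windows, repeats)
    t["gc"] = windowed_gc(windows, fasta=fasta, gc_by_window=gc_by_window, genes=genes)
    t["ds"] = weighted_ds(windows, genes_ds)
    t["rec_rate"] = np.array([rec_by_window.get(w, np.nan) for w in windows["window_id"]])
    t["chrom_length"] = np.array([chrom_sizes[str(c)] for c in windows["chrom"]], dtype=np.int64)
    return transform_predictors(t)
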