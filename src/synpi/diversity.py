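"""Coverage-filtered windowed nucleotide diversity (π) and window QC.

π for a window is the sum over variable sites of the unbiased per-site
heterozygosity 2·p̂(1−p̂)·n/(n−1) (p̂ the alternate-allele frequency among
called allele copies, n the called copies) divided by the number of
*qualifying* sites — all sites, variable or not, at which every individual of
the population has depth ≥ min_dp. Because VCFs usually carry variants only,
the qualifying denominator comes from a per-window accessible-site count (or
an all-sites VCF). The estimator equals the mean pairwise difference per site
between sampled haplotypes and is phase-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import intervals as iv
from .io import PopulationSites, SiteRecord, load_population_sites


def site_passes_coverage(site, min_dp: int = 4) -> bool:
    """True iff every sample's depth is at least ``min_dp`` (inclusive)."""
    depths = site.depths if isinstance(site, SiteRecord) else np.asarray(site)
    if depths.size == 0:
        raise ValueError("coverage filter on an empty population")
    return bool(np.min(depths) >= min_dp)


def per_site_heterozygosity(alt_count, called_count, unbiased: bool = True) -> np.ndarray:
    """2p̂(1−p̂), optionally with the n/(n−1) small-sample correction.

    Sites with fewer than two called allele copies contribute 0.
    """
    alt = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(called_count, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / n, 0.0)
        h = 2.0 * p * (1.0 - p)
        if unbiased:
            h = np.where(n > 1, h * n / (n - 1.0), 0.0)
        else:
            h = np.where(n > 1, h, 0.0)
    return h


@dataclass
class WindowDiversity:
    window_id: str
    population: str
    pi: float  # NaN when no qualifying sites
    n_qualifying_sites: int
    n_variable_sites: int


def window_pi(
    alt_count,
    called_count,
    n_qualifying_sites: int,
    window_id: str = "",
    population: str = "",
    unbiased: bool = True,
) -> WindowDiversity:
    """π for one window from the allele counts of its passing variable sites.

    ``n_qualifying_sites`` must already count every coverage-passing site
    (variable + monomorphic). A window with no qualifying sites yields
    missing π (NaN), never 0.
    """
    alt = np.asarray(alt_count, dtype=np.int64)
    called = np.asarray(called_count, dtype=np.int64)
    variable = (alt > 0) & (alt < called)
    numerator = float(per_site_heterozygosity(alt[variable], called[variable], unbiased).sum())
    if n_qualifying_sites <= 0:
        pi = float("nan")
    else:
        pi = numerator / n_qualifying_sites
    return WindowDiversity(window_id, population, pi, int(n_qualifying_sites),
                           int(variable.sum()))


def pairwise_pi_oracle(haplotypes: np.ndarray) -> float:
    """Mean pairwise difference per site by explicit pair enumeration.

    ``haplotypes``: (n_haplotypes, n_sites) 0/1 matrix over *qualifying*
    sites. Independent brute-force reference for :func:`window_pi`.
    """
    h = np.asarray(haplotypes)
    n, L = h.shape
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(h[i] != h[j]))
            npairs += 1
    return total / npairs / L


def compute_windowed_pi(
    vcf_path,
    windows: pd.DataFrame,
    population: str,
    min_dp: int = 4,
    accessible: Optional[Mapping[str, int]] = None,
    mask=None,
    unbiased: bool = True,
    sites: Optional[PopulationSites] = None,
) -> pd.DataFrame:
    """Per-window π for one population.

    ``windows`` carries window_id/chrom/start/end (any genome frame — the
    VCF must be in the same frame). ``accessible`` maps window_id to the
    qualifying-site count; if None the VCF is treated as all-sites and
    qualifying sites are counted from its records. ``mask`` is a merged
    interval track (same frame): masked variant sites are dropped and the
    qualifying count is reduced by the masked fraction of the window
    (accessibility assumed uniform within a window).
    """
    pop = sites if sites is not None else load_population_sites(str(vcf_path))
    rows = []
    for w in windows.itertuples(index=False):
        wid = w.window_id
        chrom = str(w.chrom)
        pos = pop.pos0.get(chrom)
        if pos is None:
            sel = slice(0, 0)
            pos_sel = np.empty(0, dtype=np.int64)
            alt = called = mind = np.empty(0, dtype=np.int64)
        else:
            lo, hi = np.searchsorted(pos, [w.start, w.end])
            sel = slice(lo, hi)
            pos_sel = pos[sel]
            alt, called, mind = (pop.alt_count[chrom][sel], pop.called_count[chrom][sel],
                                 pop.min_depth[chrom][sel])
        passing = mind >= min_dp
        masked_fraction = 0.0
        if mask is not None:
            in_mask = iv.positions_in_track(chrom, pos_sel, mask)
            passing = passing & ~in_mask
            masked = iv.window_coverage(
                pd.DataFrame({"chrom": [chrom], "start": [w.start], "end": [w.end]}), mask
            )[0]
            masked_fraction = masked / (w.end - w.start)
        alt_p, called_p = alt[passing], called[passing]
        if accessible is not None:
            base_q = int(accessible.get(wid, 0))
            n_qual = int(round(base_q * (1.0 - masked_fraction)))
        else:
            n_qual = int(passing.sum())  # all-sites VCF: records are the site universe
        wd = window_pi(alt_p, called_p, n_qual, wid, population, unbiased)
        rows.append((wid, population, wd.pi, wd.n_qualifying_sites, wd.n_variable_sites))
    return pd.DataFrame(rows, columns=[
        "window_id", "population", "pi", "n_qualifying_sites", "n_variable_sites"
    ])


def apply_window_qc(
    pop_tables: list[pd.DataFrame],
    min_sites: int = 10_000,
    outlier_k: float = 10.0,
    drop_outliers: bool = False,
) -> pd.DataFrame:
    """Species-level window table: mean of the population π values + QC verdicts.

    A window is dropped when *any* population has fewer than ``min_sites``
    qualifying sites (strict <). Outliers — species π above Q3 + k·IQR of the
    surviving windows — are always flagged; they are dropped only when
    ``drop_outliers`` is set, mirroring a manual-exclusion step that should
    stay explicit.
    """
    if len(pop_tables) < 1:
        raise ValueError("need at least one population table")
    merged = pop_tables[0][["window_id", "pi", "n_qualifying_sites"]].rename(
        columns={"pi": "pi_0", "n_qualifying_sites": "q_0"})
    for i, t in enumerate(pop_tables[1:], start=1):
        merged = merged.merge(
            t[["window_id", "pi", "n_qualifying_sites"]].rename(
                columns={"pi": f"pi_{i}", "n_qualifying_sites": f"q_{i}"}),
            on="window_id", how="inner")
    pi_cols = [c for c in merged.columns if c.startswith("pi_")]
    q_cols = [c for c in merged.columns if c.startswith("q_")]
    merged["pi_species"] = merged[pi_cols].mean(axis=1)
    low = (merged[q_cols] < min_sites).any(axis=1) | merged[pi_cols].isna().any(axis=1)
    verdict = np.where(low, "dropped_low_sites", "kept").astype(object)
    ok = merged.loc[~low, "pi_species"]
    if len(ok) >= 4:
        q1, q3 = np.nanpercentile(ok, [25, 75])
        bound = q3 + outlier_k * (q3 - q1)
    else:
        bound = np.inf
    outlier = (~low) & (merged["pi_species"] > bound)
    if drop_outliers:
        verdict[outlier.to_numpy()] = "dropped_outlier"
    merged["outlier"] = outlier
    merged["qc_verdict"] = verdict
    return merged[["window_id", "pi_species", "qc_verdict", "outlier"] + pi_cols + q_cols]
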