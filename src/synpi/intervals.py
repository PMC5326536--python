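"""Plain-array interval arithmetic on 0-based half-open intervals.

Every genomic track the pipeline touches (CDS unions, repeat tracks, masks)
reduces to per-chromosome sorted, merged ``(starts, ends)`` integer arrays;
the helpers here are the single implementation of union, complement and
window-coverage used by the synteny, diversity and covariates modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals -> sorted, disjoint (starts, ends)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    if np.any(ends <= starts):
        raise ValueError("interval with end <= start")
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def complement_intervals(starts, ends, chrom_len: int):
    """Gaps of a merged interval set within [0, chrom_len)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    bounds_s, bounds_e = [], []
    prev = 0
    for s, e in zip(starts, ends):
        s, e = max(0, min(s, chrom_len)), max(0, min(e, chrom_len))
        if s > prev:
            bounds_s.append(prev)
            bounds_e.append(s)
        prev = max(prev, e)
    if prev < chrom_len:
        bounds_s.append(prev)
        bounds_e.append(chrom_len)
    return np.asarray(bounds_s, dtype=np.int64), np.asarray(bounds_e, dtype=np.int64)


def overlap_with_window(starts, ends, win_start: int, win_end: int) -> int:
    """Total bases of a *merged* interval set falling inside [win_start, win_end)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    s = np.clip(starts, win_start, win_end)
    e = np.clip(ends, win_start, win_end)
    return int(np.maximum(e - s, 0).sum())


def track_from_frame(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Collapse a chrom/start/end frame into merged per-chromosome arrays."""
    track: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if df is None or len(df) == 0:
        return track
    for chrom, grp in df.groupby("chrom", sort=False, observed=True):
        track[str(chrom)] = merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
    return track


def window_coverage(windows: pd.DataFrame, track) -> np.ndarray:
    """Per-window covered base count of a merged track.

    ``windows`` needs chrom/start/end columns; returns int64 array aligned to rows.
    """
    out = np.zeros(len(windows), dtype=np.int64)
    for i, (chrom, ws, we) in enumerate(
        zip(windows["chrom"], windows["start"], windows["end"])
    ):
        ivs = track.get(str(chrom))
        if ivs is None:
            continue
        out[i] = overlap_with_window(ivs[0], ivs[1], int(ws), int(we))
    return out


def positions_in_track(chrom: str, pos: np.ndarray, track) -> np.ndarray:
    """Boolean mask: which 0-based positions fall inside the merged track."""
    ivs = track.get(str(chrom))
    if ivs is None or ivs[0].size == 0:
        return np.zeros(len(pos), dtype=bool)
    starts, ends = ivs
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(len(pos), dtype=bool)
    inside[ok] = pos[ok] < ends[idx[ok]]
    return inside
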