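"""Windowed copy-number estimation from matched tumor/normal read depth.

Windows are defined on the *normal* sample: each window spans a fixed number
of consecutive normal-sample reads (default 10,000), so window width adapts
to capture density while the normal read count per window is constant by
construction.  The copy-number signal is

    LogR = log2( (tumor_reads / normal_reads) / s )

where ``s`` is the library-size factor (total tumor reads / total normal
reads).  After the ratio, LogR values are median-centered per sample so the
modal (diploid) state sits at 0.  A tumor window with zero reads is floored
at a 0.5-read pseudo-count and flagged rather than producing -inf.

Coordinates are 1-based inclusive; window bounds are the positions of the
first and last normal read assigned to the window, and reads are assigned to
windows purely by their index in the per-chromosome sorted read list (a read
on a shared boundary position belongs to the window its index falls in).

Variants are annotated with the LogR of their containing window; since the
window value summarizes the surrounding interval, it is a neighborhood mean
estimate rather than a per-base measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CopyWindow",
    "make_windows",
    "count_tumor_reads",
    "windows_from_table",
    "windows_to_table",
    "compute_logr",
    "assign_logr",
    "DEFAULT_WINDOW_SIZE",
]

DEFAULT_WINDOW_SIZE = 10_000
ZERO_TUMOR_PSEUDOCOUNT = 0.5


@dataclass
class CopyWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    normal_reads: int
    tumor_reads: int = 0
    logr: float = math.nan
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad window bounds {self.chrom}:{self.start}-{self.end}")
        if self.normal_reads <= 0:
            raise ValueError("normal_reads must be positive")
        if self.tumor_reads < 0:
            raise ValueError("tumor_reads must be non-negative")


def make_windows(
    normal_positions: Mapping[str, Sequence[int]],
    window_size: int = DEFAULT_WINDOW_SIZE,
) -> list[CopyWindow]:
    """Partition each chromosome's sorted normal-read positions into windows
    of ``window_size`` consecutive reads (the last window per chromosome may
    be short)."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    windows: list[CopyWindow] = []
    for chrom in normal_positions:
        pos = np.asarray(normal_positions[chrom], dtype=np.int64)
        if pos.size == 0:
            warnings.warn(f"chromosome {chrom}: no normal reads, no windows built")
            continue
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"chromosome {chrom}: read positions are not sorted")
        for i in range(0, pos.size, window_size):
            chunk = pos[i : i + window_size]
            windows.append(
                CopyWindow(
                    chrom=str(chrom),
                    start=int(chunk[0]),
                    end=int(chunk[-1]),
                    normal_reads=int(chunk.size),
                )
            )
    return windows


def count_tumor_reads(
    windows: list[CopyWindow], tumor_positions: Mapping[str, Sequence[int]]
) -> None:
    """Fill ``tumor_reads`` by assigning each tumor read to the window
    containing its position; reads falling outside all window bounds on a
    covered chromosome go to the nearest window."""
    by_chrom: dict[str, list[CopyWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.start)
        pos = np.sort(np.asarray(tumor_positions.get(chrom, ()), dtype=np.int64))
        if pos.size == 0:
            continue
        starts = np.array([w.start for w in ws])
        ends = np.array([w.end for w in ws])
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx = np.clip(idx, 0, len(ws) - 1)
        # reads past a window's end but before the next start: nearest bound
        past_end = pos > ends[idx]
        has_next = idx < len(ws) - 1
        move = past_end & has_next
        nxt = np.clip(idx + 1, 0, len(ws) - 1)
        dist_next = np.abs(starts[nxt] - pos)
        dist_prev = np.abs(pos - ends[idx])
        idx = np.where(move & (dist_next < dist_prev), nxt, idx)
        counts = np.bincount(idx, minlength=len(ws))
        for w, c in zip(ws, counts):
            w.tumor_reads += int(c)


def windows_from_table(df: pd.DataFrame) -> list[CopyWindow]:
    """Build windows from a pre-binned table (chrom, start, end,
    normal_reads, tumor_reads) — the alternative input dialect."""
    needed = {"chrom", "start", "end", "normal_reads", "tumor_reads"}
    if not needed.issubset(df.columns):
        raise ValueError(f"window table must have columns {sorted(needed)}")
    return [
        CopyWindow(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            normal_reads=int(r.normal_reads), tumor_reads=int(r.tumor_reads),
        )
        for r in df.itertuples()
    ]


def windows_to_table(windows: Sequence[CopyWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "normal_reads": [w.normal_reads for w in windows],
            "tumor_reads": [w.tumor_reads for w in windows],
            "logr": [w.logr for w in windows],
        }
    )


def compute_logr(
    windows: Sequence[CopyWindow],
    library_size_factor: float | None = None,
    center: str = "median",
) -> np.ndarray:
    """Compute LogR in place for every window and return the vector.

    ``library_size_factor`` defaults to total tumor reads / total normal
    reads.  ``center`` is ``"median"`` (per-sample median centering, the
    default, anchoring the modal diploid state at 0) or ``"none"``.
    """
    if not windows:
        return np.array([])
    tumor = np.array([w.tumor_reads for w in windows], dtype=float)
    normal = np.array([w.normal_reads for w in windows], dtype=float)
    if library_size_factor is None:
        library_size_factor = tumor.sum() / normal.sum()
    if library_size_factor <= 0:
        raise ValueError("library size factor must be positive")
    floored = tumor == 0
    tumor = np.where(floored, ZERO_TUMOR_PSEUDOCOUNT, tumor)
    logr = np.log2((tumor / normal) / library_size_factor)
    if center == "median":
        logr = logr - np.median(logr)
    elif center != "none":
        raise ValueError(f"unknown centering {center!r}")
    for w, v, fl in zip(windows, logr, floored):
        w.logr = float(v)
        if fl:
            w.flags.add("zero_tumor_floored")
    return logr


def assign_logr(
    variants: pd.DataFrame, windows: Sequence[CopyWindow]
) -> pd.DataFrame:
    """Attach each variant (rows with ``chrom``/``pos``) the LogR of its
    containing window.

    A position falling in the gap between two windows, or beyond the last
    window of a covered chromosome, receives the nearest window's value and
    the flag ``nearest``; a chromosome with no windows yields NaN and the
    flag ``no_windows``.  Returns a frame with columns ``logr`` and
    ``logr_flag`` aligned to ``variants``.
    """
    by_chrom: dict[str, list[CopyWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for ws in by_chrom.values():
        ws.sort(key=lambda w: w.start)
    logrs = np.full(len(variants), np.nan)
    flag = np.array([""] * len(variants), dtype=object)
    for i, (chrom, pos) in enumerate(zip(variants["chrom"], variants["pos"])):
        ws = by_chrom.get(str(chrom))
        if not ws:
            flag[i] = "no_windows"
            continue
        starts = [w.start for w in ws]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        j = max(j, 0)
        w = ws[j]
        if w.start <= pos <= w.end:
            logrs[i] = w.logr
        else:
            # gap or out of range: nearest window bound
            cand = [w]
            if j + 1 < len(ws):
                cand.append(ws[j + 1])
            nearest = min(cand, key=lambda c: min(abs(pos - c.start), abs(pos - c.end)))
            logrs[i] = nearest.logr
            flag[i] = "nearest"
    return pd.DataFrame({"logr": logrs, "logr_flag": flag}, index=variants.index)
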