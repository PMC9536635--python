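"""Centered window grids, strand-aware counting, RPKM, and smoothing.

A *window grid* expands each source region symmetrically about its integer
midpoint into ``window_num`` adjacent windows of ``interval_len`` bases,
dropping regions whose expanded spans overlap one another or run off a
chromosome; reads are then counted per window and strand with the
>=1-bp-overlap rule of ``bedtools intersect``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass
class WindowGrid:
    """Equal-length tiled spans centered on source regions.

    ``regions`` has one row per surviving source region with columns
    ``chrom, span_start, span_end, center, name, strand`` (strand of the
    source region, '.' when strandless). Window ``w`` (1-based, left to
    right) of region ``r`` is
    ``[span_start + (w-1)*window_len, span_start + w*window_len)``.
    """

    regions: pd.DataFrame
    window_len: int
    window_num: int

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def span_len(self) -> int:
        return self.window_len * self.window_num

    def window_bounds(self, region_idx: int, window: int) -> tuple[int, int]:
        s = int(self.regions["span_start"].iloc[region_idx]) + (window - 1) * self.window_len
        return s, s + self.window_len

    def window_offsets(self) -> np.ndarray:
        """Signed offset of each window's midpoint from the span center."""
        w = np.arange(1, self.window_num + 1)
        return (w - 1) * self.window_len + self.window_len / 2 - self.span_len / 2


@dataclass
class SignalMatrix:
    """Per-region x per-window x per-strand read counts on a grid.

    The strand axis is indexed (0: '+', 1: '-'). ``library_size`` is the
    total mapped-read count of the counted library (used by RPKM).
    """

    grid: WindowGrid
    counts: np.ndarray  # (n_regions, window_num, 2) int64
    library_size: int
    skipped_reads: int = 0
    values: np.ndarray | None = None

    def rpkm(self) -> np.ndarray:
        """Reads per kilobase of window per million mapped reads, per cell."""
        if self.library_size <= 0:
            raise ValueError("RPKM requires a positive library size")
        return self.counts * 1e9 / (self.grid.window_len * self.library_size)

    def total_counts(self) -> int:
        return int(self.counts.sum())


def make_centered_windows(
    regions: pd.DataFrame,
    interval_len: int,
    window_num: int,
    genome: Genome,
) -> WindowGrid:
    """Expand regions about their midpoints into a non-overlapping grid.

    The span start is ``int((start+end)/2 - a/2 - a*(b-1)/2)`` with
    ``a=interval_len``, ``b=window_num`` (integer truncation), the span end
    ``span_start + a*b``. Regions whose spans exceed chromosome bounds are
    dropped, and every member of any overlapping span pair is dropped
    (mutually), so that opposite-signal regions cannot cancel.
    """
    if interval_len < 1 or window_num < 1:
        raise ValueError("interval_len and window_num must be >= 1")
    req = {"chrom", "start", "end"}
    if not req.issubset(regions.columns):
        raise ValueError(f"regions must have columns {sorted(req)}")

    df = regions.reset_index(drop=True).copy()
    span = interval_len * window_num
    # (start+end)/2 - span/2, truncated: exact integer arithmetic in halves
    df["span_start"] = (df["start"].to_numpy(np.int64) + df["end"].to_numpy(np.int64) - span) // 2
    df["span_end"] = df["span_start"] + span
    df["center"] = df["span_start"] + span / 2
    if "name" not in df:
        df["name"] = [f"region_{i}" for i in range(len(df))]
    if "strand" not in df:
        df["strand"] = "."

    lengths = genome.chrom_lengths
    known = df["chrom"].isin(lengths)
    in_bounds = known.copy()
    if known.any():
        lens = df.loc[known, "chrom"].map(lengths).to_numpy(np.int64)
        ok = (df.loc[known, "span_start"].to_numpy() >= 0) & (
            df.loc[known, "span_end"].to_numpy() <= lens
        )
        in_bounds.loc[known] = ok
    df = df[in_bounds]

    # mutual overlap filter: spans are equal length, so after sorting any
    # overlap shows up between neighbours
    keep = np.ones(len(df), dtype=bool)
    df = df.sort_values(["chrom", "span_start"], kind="mergesort").reset_index(drop=True)
    for _, idx in df.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        starts = df.loc[idx, "span_start"].to_numpy()
        ends = df.loc[idx, "span_end"].to_numpy()
        if len(idx) > 1:
            ov = starts[1:] < ends[:-1]
            bad = np.zeros(len(idx), dtype=bool)
            bad[1:] |= ov
            bad[:-1] |= ov
            keep[idx] = ~bad
    df = df[keep].reset_index(drop=True)

    if df.empty:
        warnings.warn("no regions survive window expansion/filtering", stacklevel=2)
    core = ["chrom", "span_start", "span_end", "center", "name", "strand"]
    extras = [c for c in df.columns if c not in core + ["start", "end"]]
    return WindowGrid(regions=df[core + extras], window_len=interval_len, window_num=window_num)


def _per_chrom_index(grid: WindowGrid):
    """chrom -> (region row indices sorted by span_start, starts, ends)."""
    out = {}
    regs = grid.regions
    for chrom, idx in regs.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        starts = regs["span_start"].to_numpy()[idx]
        order = np.argsort(starts, kind="mergesort")
        idx = idx[order]
        out[chrom] = (idx, starts[order], starts[order] + grid.span_len)
    return out


def count_reads_in_windows(
    reads: pd.DataFrame,
    grid: WindowGrid,
    library_size: int | None = None,
) -> SignalMatrix:
    """Count stranded reads per window (>=1 bp overlap increments a window;
    a read overlapping k windows increments all k). Reads on chromosomes
    absent from the grid's regions are skipped and tallied."""
    counts = np.zeros((grid.n_regions, grid.window_num, 2), dtype=np.int64)
    n_skipped = 0
    index = _per_chrom_index(grid)
    L = grid.window_len

    for (chrom, strand), sub in reads.groupby(["chrom", "strand"], sort=False):
        s_ax = 0 if strand == "+" else 1
        if chrom not in index:
            n_skipped += len(sub)
            continue
        ridx, rstarts, rends = index[chrom]
        rs = sub["start"].to_numpy(np.int64)
        re = sub["end"].to_numpy(np.int64)
        j0 = np.searchsorted(rends, rs, side="right")
        j1 = np.searchsorted(rstarts, re, side="left")
        nov = j1 - j0
        # vectorised single-region case
        one = nov == 1
        if one.any():
            j = j0[one]
            reg = ridx[j]
            ss = rstarts[j]
            ov_s = np.maximum(rs[one], ss)
            ov_e = np.minimum(re[one], rends[j])
            w_lo = (ov_s - ss) // L
            w_hi = (ov_e - 1 - ss) // L
            span = int((w_hi - w_lo).max()) if len(w_lo) else 0
            for d in range(span + 1):
                m = w_lo + d <= w_hi
                np.add.at(counts, (reg[m], w_lo[m] + d, s_ax), 1)
        # rare multi-region case
        multi = nov > 1
        for a, b, lo, hi in zip(rs[multi], re[multi], j0[multi], j1[multi]):
            for j in range(lo, hi):
                ss, ee = rstarts[j], rends[j]
                ov_s, ov_e = max(a, ss), min(b, ee)
                counts[ridx[j], (ov_s - ss) // L : (ov_e - 1 - ss) // L + 1, s_ax] += 1

    if n_skipped:
        log.info("count_reads_in_windows: %d reads on unknown chromosomes skipped", n_skipped)
    lib = library_size if library_size is not None else len(reads)
    return SignalMatrix(grid=grid, counts=counts, library_size=lib, skipped_reads=n_skipped)


def count_reads_in_regions(
    reads: pd.DataFrame,
    regions: pd.DataFrame,
    library_size: int | None = None,
) -> pd.DataFrame:
    """Per-region per-strand read counts for arbitrary non-overlapping
    regions (>=1 bp overlap). Returns regions with added columns
    ``count_plus`` / ``count_minus``."""
    out = regions.reset_index(drop=True).copy()
    cp = np.zeros(len(out), dtype=np.int64)
    cm = np.zeros(len(out), dtype=np.int64)
    for chrom, idx in out.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        starts = out["start"].to_numpy()[idx]
        ends = out["end"].to_numpy()[idx]
        order = np.argsort(starts, kind="mergesort")
        idx, starts, ends = idx[order], starts[order], ends[order]
        sub = reads[reads["chrom"] == chrom]
        for strand, acc in (("+", cp), ("-", cm)):
            rr = sub[sub["strand"] == strand]
            if rr.empty:
                continue
            rs = rr["start"].to_numpy(np.int64)
            re = rr["end"].to_numpy(np.int64)
            j0 = np.searchsorted(ends, rs, side="right")
            j1 = np.searchsorted(starts, re, side="left")
            for lo, hi in ((j0, j1),):
                multi = hi - lo
                one = multi >= 1
                # increment every overlapped region
                for a, b, l, h in zip(rs[one], re[one], lo[one], hi[one]):
                    acc[idx[l:h]] += 1
    out["count_plus"] = cp
    out["count_minus"] = cm
    out.attrs["library_size"] = library_size if library_size is not None else len(reads)
    return out


def aggregate_profile(sm: SignalMatrix, normalize: str = "rpkm") -> pd.DataFrame:
    """Mean per-window per-strand signal over regions.

    With ``normalize='rpkm'`` each cell is RPKM-normalised
    (count * 1e9 / (window_len * library_size)) before averaging; with
    ``'none'`` raw counts are averaged.
    """
    if sm.grid.n_regions < 1:
        raise ValueError("signal matrix has no regions")
    if normalize == "rpkm":
        vals = sm.rpkm()
    elif normalize == "none":
        vals = sm.counts.astype(float)
    else:
        raise ValueError("normalize must be 'rpkm' or 'none'")
    mean = vals.mean(axis=0)  # (window_num, 2)
    return pd.DataFrame(
        {
            "window": np.arange(1, sm.grid.window_num + 1),
            "plus": mean[:, 0],
            "minus": mean[:, 1],
        }
    )


def moving_average(track: np.ndarray, k: int = 10) -> np.ndarray:
    """Centered simple moving average with window ``k``.

    Edges use the available (shorter) window; NaNs are ignored in each
    window's mean (all-NaN windows stay NaN). The window for index i covers
    ``[i - (k-1)//2, i + k//2]``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.asarray(track, dtype=float)
    if x.size == 0:
        return x.copy()
    if k == 1:
        return x.copy()
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    cnum = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    n = x.size
    i = np.arange(n)
    lo = np.maximum(i - (k - 1) // 2, 0)
    hi = np.minimum(i + k // 2, n - 1) + 1
    tot = csum[hi] - csum[lo]
    num = cnum[hi] - cnum[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(num > 0, tot / np.maximum(num, 1), np.nan)
    return out
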