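"""Replication timing from early/late S-phase nascent-DNA sequencing.

The timing signal is the log2 ratio of depth-normalised early to late
read counts in fixed bins (default 50 kb). Early (ERD) and late (LRD)
replication domains are called by smoothing the ratio with a simple
moving average, thresholding at zero, bridging short gaps, and discarding
short runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome
from .windows import moving_average


@dataclass
class TimingTrack:
    """Binned early/late replication signal.

    ``bins`` has columns chrom, start, end, early, late (raw counts),
    log2_ratio (on depth-normalised counts with pseudocount).
    """

    bins: pd.DataFrame
    bin_size: int
    pseudocount: float


def _bin_counts(reads: pd.DataFrame, genome: Genome, bin_size: int) -> dict[str, np.ndarray]:
    """Per-chromosome read counts by read-midpoint bin."""
    out = {}
    for chrom in genome.chrom_names:
        nbins = -(-genome.length(chrom) // bin_size)
        out[chrom] = np.zeros(nbins, dtype=np.int64)
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in out:
            continue
        mid = (sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2
        b = np.clip(mid // bin_size, 0, len(out[chrom]) - 1)
        np.add.at(out[chrom], b, 1)
    return out


def compute_timing_track(
    early_reads: pd.DataFrame,
    late_reads: pd.DataFrame,
    genome: Genome,
    bin_size: int = 50_000,
    pseudocount: float = 1.0,
) -> TimingTrack:
    """log2((early + psi) / (late + psi)) per bin, each library first
    depth-normalised to reads per bin per million mapped reads."""
    if early_reads.empty or late_reads.empty:
        raise ValueError("both early and late read sets must be non-empty")
    e_bins = _bin_counts(early_reads, genome, bin_size)
    l_bins = _bin_counts(late_reads, genome, bin_size)
    e_tot = max(len(early_reads), 1)
    l_tot = max(len(late_reads), 1)
    rows = []
    for chrom in genome.chrom_names:
        e = e_bins[chrom]
        l = l_bins[chrom]
        starts = np.arange(len(e), dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, genome.length(chrom))
        e_norm = e * 1e6 / e_tot
        l_norm = l * 1e6 / l_tot
        ratio = np.log2((e_norm + pseudocount) / (l_norm + pseudocount))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "early": e,
                    "late": l,
                    "log2_ratio": ratio,
                }
            )
        )
    return TimingTrack(bins=pd.concat(rows, ignore_index=True), bin_size=bin_size, pseudocount=pseudocount)


def call_domains(
    track: TimingTrack,
    smooth_bins: int = 10,
    min_bins: int = 4,
    merge_gap_bins: int = 1,
) -> pd.DataFrame:
    """Segment the timing track into ERDs (smoothed ratio > 0) and LRDs
    (< 0); same-label runs separated by gaps of <= ``merge_gap_bins`` bins
    are merged, runs shorter than ``min_bins`` discarded. Returns a BED-like
    frame with columns chrom, start, end, label, mean_log2_ratio."""
    domains = []
    for chrom, sub in track.bins.groupby("chrom", sort=False):
        ratio = sub["log2_ratio"].to_numpy()
        if len(ratio) < min_bins:
            continue
        sm = moving_average(ratio, smooth_bins)
        label = np.zeros(len(sm), dtype=np.int8)
        label[sm > 0] = 1
        label[sm < 0] = -1
        # a smoothed value of exactly zero (an even window straddling a
        # clean step) takes the sign of the raw ratio at that bin
        tie = (sm == 0) & np.isfinite(ratio)
        label[tie & (ratio > 0)] = 1
        label[tie & (ratio < 0)] = -1

        # run-length encode, then bridge short gaps between same-label runs
        runs = _rle(label)
        merged = True
        while merged:
            merged = False
            for i in range(1, len(runs) - 1):
                lab_p, lab_i, lab_n = runs[i - 1][0], runs[i][0], runs[i + 1][0]
                if (
                    lab_i != lab_p
                    and lab_p == lab_n
                    and lab_p != 0
                    and runs[i][2] - runs[i][1] <= merge_gap_bins
                ):
                    runs[i] = (lab_p, runs[i][1], runs[i][2])
                    runs = _rle_merge(runs)
                    merged = True
                    break

        # refine each ERD/LRD boundary by a least-squares change-point
        # fit on the raw ratio: the smoothed crossing jitters by about
        # half a bin of noise, the step fit by far less
        for i in range(len(runs) - 1):
            (lab_a, lo_a, hi_a), (lab_b, lo_b, hi_b) = runs[i], runs[i + 1]
            if lab_a == 0 or lab_b == 0 or lab_a == lab_b or hi_a != lo_b:
                continue
            radius = max(smooth_bins // 2, 1)
            w_lo = max(lo_a + 1, hi_a - radius)
            w_hi = min(hi_b - 1, hi_a + radius)
            if w_hi <= w_lo:
                continue
            mu_a = np.nanmean(ratio[lo_a:hi_a])
            mu_b = np.nanmean(ratio[lo_b:hi_b])
            cands = np.arange(w_lo, w_hi + 1)
            costs = []
            seg = np.nan_to_num(ratio[lo_a:hi_b], nan=0.0)
            for c in cands:
                left = seg[: c - lo_a] - mu_a
                right = seg[c - lo_a :] - mu_b
                costs.append(np.sum(left**2) + np.sum(right**2))
            best = int(cands[int(np.argmin(costs))])
            runs[i] = (lab_a, lo_a, best)
            runs[i + 1] = (lab_b, best, hi_b)

        bin_starts = sub["start"].to_numpy()
        bin_ends = sub["end"].to_numpy()
        for lab, lo, hi in runs:
            if lab == 0 or hi - lo < min_bins:
                continue
            domains.append(
                {
                    "chrom": chrom,
                    "start": int(bin_starts[lo]),
                    "end": int(bin_ends[hi - 1]),
                    "label": "ERD" if lab == 1 else "LRD",
                    "mean_log2_ratio": float(np.nanmean(ratio[lo:hi])),
                }
            )
    return pd.DataFrame(domains, columns=["chrom", "start", "end", "label", "mean_log2_ratio"])


def _rle(label: np.ndarray) -> list[tuple[int, int, int]]:
    runs = []
    start = 0
    for i in range(1, len(label) + 1):
        if i == len(label) or label[i] != label[start]:
            runs.append((int(label[start]), start, i))
            start = i
    return runs


def _rle_merge(runs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    out = [runs[0]]
    for lab, lo, hi in runs[1:]:
        plab, plo, phi = out[-1]
        if lab == plab and lo == phi:
            out[-1] = (plab, plo, hi)
        else:
            out.append((lab, lo, hi))
    return out


def assign_to_domains(
    regions: pd.DataFrame,
    domains: pd.DataFrame,
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Label each region with the domain covering >= ``min_overlap_fraction``
    of its length (ties: larger overlap, then leftmost domain). Unlabeled
    regions get a null label."""
    out = regions.reset_index(drop=True).copy()
    labels: list[object] = [None] * len(out)
    dom_by_chrom = {
        chrom: sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in domains.groupby("chrom", sort=False)
    }
    for i, (chrom, start, end) in enumerate(zip(out["chrom"], out["start"], out["end"])):
        sub = dom_by_chrom.get(chrom)
        if sub is None:
            continue
        ds = sub["start"].to_numpy(np.int64)
        de = sub["end"].to_numpy(np.int64)
        ov = np.minimum(de, end) - np.maximum(ds, start)
        ov = np.maximum(ov, 0)
        if ov.max(initial=0) <= 0:
            continue
        best = int(np.argmax(ov))  # argmax takes the leftmost on ties
        if ov[best] >= min_overlap_fraction * (end - start):
            labels[i] = sub["label"].iloc[best]
    out["domain"] = labels
    return out
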