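"""Okazaki-fragment strand ratios, initiation-zone calling, fork polarity.

Okazaki fragments map to the lagging nascent strand, so the per-bin
replication fork directionality RFD = (C - W)/(C + W) (Crick = minus,
Watson = plus mapped fragments) ascends across replication initiation
zones. Zones are called as valley-to-peak ascents of the smoothed RFD
with a minimum total rise; each zone is scored by its adjusted slope
(rise per kb of extent), the quantity used for quartile stratification.

Fork polarity convention at a zone center: windows right of the center
are replicated by a rightward-moving fork, for which the plus strand is
the lagging-strand template and the minus strand the leading-strand
template; the roles mirror on the left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .genome import Genome
from .windows import moving_average


@dataclass
class RfdTrack:
    """Binned Watson/Crick Okazaki counts and RFD; NaN where no coverage."""

    bins: pd.DataFrame  # chrom, start, end, watson, crick, rfd
    bin_size: int


def compute_rfd(ok_reads: pd.DataFrame, genome: Genome, bin_size: int = 1000) -> RfdTrack:
    """RFD = (C - W)/(C + W) per bin from stranded Okazaki fragments,
    counted by fragment midpoint; bins with no fragments are NaN."""
    rows = []
    for chrom in genome.chrom_names:
        nbins = -(-genome.length(chrom) // bin_size)
        w = np.zeros(nbins, dtype=np.int64)
        c = np.zeros(nbins, dtype=np.int64)
        sub = ok_reads[ok_reads["chrom"] == chrom]
        if not sub.empty:
            mid = (sub["start"].to_numpy(np.int64) + sub["end"].to_numpy(np.int64)) // 2
            b = np.clip(mid // bin_size, 0, nbins - 1)
            plus = (sub["strand"] == "+").to_numpy()
            np.add.at(w, b[plus], 1)
            np.add.at(c, b[~plus], 1)
        tot = w + c
        with np.errstate(invalid="ignore"):
            rfd = np.where(tot > 0, (c - w) / np.maximum(tot, 1), np.nan)
        starts = np.arange(nbins, dtype=np.int64) * bin_size
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size, genome.length(chrom)),
                    "watson": w,
                    "crick": c,
                    "rfd": rfd,
                }
            )
        )
    return RfdTrack(bins=pd.concat(rows, ignore_index=True), bin_size=bin_size)


def _alternating_extrema(v: np.ndarray, prominence: float):
    """Boundary-aware valley/peak indices, cleaned to alternate."""
    pad_lo = np.concatenate(([np.inf], v, [np.inf]))
    valleys = find_peaks(-pad_lo, prominence=prominence)[0] - 1
    pad_hi = np.concatenate(([-np.inf], v, [-np.inf]))
    peaks = find_peaks(pad_hi, prominence=prominence)[0] - 1
    events = sorted([(i, -1) for i in valleys] + [(i, +1) for i in peaks])
    cleaned: list[tuple[int, int]] = []
    for idx, kind in events:
        if cleaned and cleaned[-1][1] == kind:
            # keep the more extreme of two same-kind neighbours
            prev = cleaned[-1][0]
            better = v[idx] * kind > v[prev] * kind
            if better:
                cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))
    return cleaned


def call_initiation_zones(
    rfd: RfdTrack,
    min_delta: float = 0.5,
    max_extent: int = 150_000,
    smooth_bins: int = 5,
    trim_fraction: float = 0.05,
) -> pd.DataFrame:
    """Ascending RFD segments (valley -> next peak of the smoothed track)
    with total rise >= ``min_delta`` and extent <= ``max_extent``.

    Each ascent is delimited at the ``trim_fraction`` and
    ``1 - trim_fraction`` levels of its rise, so the reported endpoints
    lie on the steep part of the ascent, where sampling noise displaces
    them least (the raw valley/peak positions wander along the shallow
    inter-zone slopes). Returns chrom, start, end, center (ascent
    midpoint), score (the adjusted slope: rise per kb of extent).
    Uncovered (NaN) bins are linearly interpolated before smoothing;
    leading/trailing NaN stretches are ignored.
    """
    zones = []
    bsz = rfd.bin_size
    for chrom, sub in rfd.bins.groupby("chrom", sort=False):
        x = sub["rfd"].to_numpy(float)
        finite = np.isfinite(x)
        if finite.sum() < 10:
            continue
        lo, hi = np.flatnonzero(finite)[[0, -1]]
        seg = pd.Series(x[lo : hi + 1]).interpolate().to_numpy()
        v = moving_average(seg, smooth_bins)
        extrema = _alternating_extrema(v, prominence=min_delta / 2)
        starts = sub["start"].to_numpy(np.int64)
        for (i, k1), (j, k2) in zip(extrema, extrema[1:]):
            if k1 != -1 or k2 != 1:
                continue
            full_rise = v[j] - v[i]
            if full_rise < min_delta:
                continue
            lo_thr = v[i] + trim_fraction * full_rise
            hi_thr = v[j] - trim_fraction * full_rise
            i2 = i + int(np.argmax(v[i : j + 1] >= lo_thr))
            j2 = j - int(np.argmax(v[i : j + 1][::-1] <= hi_thr))
            rise = v[j2] - v[i2]
            extent = (j2 - i2) * bsz
            if extent <= 0 or extent > max_extent:
                continue
            # the mid-level crossing sits on the steepest stretch of the
            # ascent and is the most noise-stable center estimate; the
            # crossing is interpolated to sub-bin resolution
            mid = (v[i] + v[j]) / 2
            ic = i + int(np.argmax(v[i : j + 1] >= mid))
            if ic > i and v[ic] > v[ic - 1]:
                frac = (mid - v[ic - 1]) / (v[ic] - v[ic - 1])
                center = starts[lo + ic - 1] + bsz * (0.5 + frac)
            else:
                center = starts[lo + ic] + bsz * 0.5
            z_start = int(starts[lo + i2])
            z_end = int(starts[lo + j2]) + bsz
            zones.append(
                {
                    "chrom": chrom,
                    "start": z_start,
                    "end": z_end,
                    "center": float(center),
                    "score": float(rise / (extent / 1000.0)),
                }
            )
    out = pd.DataFrame(zones, columns=["chrom", "start", "end", "center", "score"])
    if not out.empty:
        out["name"] = [f"iz_{i}" for i in range(len(out))]
    else:
        out["name"] = pd.Series(dtype=object)
    return out


def quartile_by_score(izs: pd.DataFrame) -> pd.DataFrame:
    """Quartile labels 1 (lowest scores) .. 4 (highest); ties fall to the
    lower quartile (tied scores share their group's minimum rank)."""
    if len(izs) < 4:
        raise ValueError("need at least 4 zones to form quartiles")
    out = izs.reset_index(drop=True).copy()
    rank = out["score"].rank(method="min").to_numpy()
    out["quartile"] = np.ceil(4 * rank / len(out)).astype(int)
    return out


def _overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean per row of a: overlaps (>=1 bp) any interval of b."""
    res = np.zeros(len(a), dtype=bool)
    b_by_chrom = {c: s.sort_values("start") for c, s in b.groupby("chrom", sort=False)}
    a = a.reset_index(drop=True)
    for chrom, sub in a.groupby("chrom", sort=False):
        other = b_by_chrom.get(chrom)
        if other is None:
            continue
        bs = other["start"].to_numpy(np.int64)
        be = other["end"].to_numpy(np.int64)
        # sort intervals of b; overlap iff some b interval has start < a.end and end > a.start
        order = np.argsort(bs)
        bs, be = bs[order], be[order]
        cummax_end = np.maximum.accumulate(be)
        for i, (s, e) in zip(sub.index, zip(sub["start"], sub["end"])):
            j = np.searchsorted(bs, e, side="left")  # b intervals starting before a.end
            res[i] = j > 0 and cummax_end[j - 1] > s
    return res


def common_zones(
    iz_sets: list[pd.DataFrame], reference: int = 0
) -> tuple[pd.DataFrame, list[pd.DataFrame], pd.DataFrame]:
    """Split zones into common and per-set unique by >=1 bp overlap.

    A reference-set zone is *common* iff it overlaps at least one zone of
    every other set; a zone of any set is *unique* iff it overlaps no zone
    of any other set. Also returns the pairwise overlap count matrix.
    """
    if len(iz_sets) < 2:
        raise ValueError("need at least two zone sets")
    ref = iz_sets[reference].reset_index(drop=True)
    common_mask = np.ones(len(ref), dtype=bool)
    for i, other in enumerate(iz_sets):
        if i == reference:
            continue
        common_mask &= _overlaps_any(ref, other)
    common = ref[common_mask].reset_index(drop=True)

    uniques = []
    for i, zs in enumerate(iz_sets):
        zs = zs.reset_index(drop=True)
        hit = np.zeros(len(zs), dtype=bool)
        for j, other in enumerate(iz_sets):
            if j == i:
                continue
            hit |= _overlaps_any(zs, other)
        uniques.append(zs[~hit].reset_index(drop=True))

    n = len(iz_sets)
    pair = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            pair[i, j] = len(iz_sets[i]) if i == j else int(
                _overlaps_any(iz_sets[i].reset_index(drop=True), iz_sets[j]).sum()
            )
    pairwise = pd.DataFrame(pair)
    return common, uniques, pairwise


def template_role(side: str, strand: str) -> str:
    """Template-strand role of a genomic strand on one side of a zone
    center: right side + plus strand -> lagging; mirrored otherwise."""
    if side not in ("left", "right") or strand not in ("+", "-"):
        raise ValueError("side must be left/right, strand +/-")
    if side == "right":
        return "lagging" if strand == "+" else "leading"
    return "leading" if strand == "+" else "lagging"


def assign_fork_polarity(
    window_start: int, window_end: int, iz_center: float
) -> dict[str, str] | None:
    """Side and per-strand template roles of a window relative to a zone
    center; None (excluded) if the window straddles the center."""
    if window_start < iz_center < window_end:
        return None
    side = "left" if window_end <= iz_center else "right"
    return {
        "side": side,
        "+": template_role(side, "+"),
        "-": template_role(side, "-"),
    }
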