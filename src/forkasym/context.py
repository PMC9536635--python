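"""Strand-resolved k-mer composition around initiation zones.

Sequence percentages are counted on the forward strand; the percentage of
a k-mer on the reverse strand equals the forward percentage of its
reverse complement, so only one representative per complementary pair is
reported (the lexicographically smaller; palindromes once). The "net T"
family of statistics (net T = #T - #A, net TT = overlapping TT - AA,
net TC = TC - GA, net C = #C - #G, net CC = CC - GG) orders k-mers by
their strand imbalance potential.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .genome import Genome, reverse_complement
from .okseq import template_role
from .windows import WindowGrid

_KMER_CACHE: dict[int, list[str]] = {}


def all_kmers(k: int) -> list[str]:
    if k not in _KMER_CACHE:
        _KMER_CACHE[k] = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    return _KMER_CACHE[k]


def collapse_representative(kmer: str) -> str:
    """Lexicographically smaller of (kmer, reverse complement)."""
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def _overlapping_count(s: str, sub: str) -> int:
    count = start = 0
    while True:
        i = s.find(sub, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def net_statistics(kmer: str) -> dict[str, int]:
    """Exact net-skew statistics of one k-mer (length 1..5).

    Dinucleotide counts are overlapping (TTT contains two TTs), matching
    how dipyrimidine lesion sites are counted.
    """
    if not (1 <= len(kmer) <= 5) or set(kmer) - set("ACGT"):
        raise ValueError("kmer must be over ACGT with length 1..5")
    return {
        "net_T": kmer.count("T") - kmer.count("A"),
        "net_TT": _overlapping_count(kmer, "TT") - _overlapping_count(kmer, "AA"),
        "net_TC": _overlapping_count(kmer, "TC") - _overlapping_count(kmer, "GA"),
        "net_C": kmer.count("C") - kmer.count("G"),
        "net_CC": _overlapping_count(kmer, "CC") - _overlapping_count(kmer, "GG"),
    }


def _window_kmer_counts(
    grid: WindowGrid, genome: Genome, k: int, window_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """Forward-strand overlapping k-mer counts summed over the selected
    windows of every region, per region group handled by the caller.

    Returns (counts matrix of shape (n_regions, 4**k), n skipped k-mers
    containing N). K-mers are counted within windows (none span a window
    boundary)."""
    n_regions = grid.n_regions
    counts = np.zeros((n_regions, 4**k), dtype=np.int64)
    n_skipped = 0
    L = grid.window_len
    widx = np.flatnonzero(window_mask)
    regs = grid.regions
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for r, (chrom, span_start) in enumerate(zip(regs["chrom"], regs["span_start"])):
        arr = genome.encoded(chrom)
        for w in widx:
            s = int(span_start) + int(w) * L
            block = arr[s : s + L]
            if L < k:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(block, k)
            valid = (windows < 4).all(axis=1)
            n_skipped += int((~valid).sum())
            codes = (windows[valid].astype(np.int64) * weights).sum(axis=1)
            counts[r] += np.bincount(codes, minlength=4**k)
    return counts, n_skipped


def kmer_percentages(
    grid: WindowGrid,
    genome: Genome,
    k_range: range = range(1, 6),
    min_flank: int = 2000,
) -> pd.DataFrame:
    """Aggregated k-mer percentages on each side of zone centers.

    The grid must be centered on initiation zones; windows closer than
    ``min_flank`` to the center are excluded. For each k, side and
    (optional) domain label of the grid's regions, forward-strand
    overlapping k-mer counts are aggregated and converted to percentages
    of all k-mers; the minus-strand percentage of a k-mer is the plus
    percentage of its reverse complement. Positions containing N are
    skipped and tallied in ``result.attrs['n_skipped']``.
    """
    offs = grid.window_offsets()
    flank = np.abs(offs) >= min_flank
    sides = {"left": flank & (offs < 0), "right": flank & (offs > 0)}
    regs = grid.regions
    domains = regs["domain"].to_numpy() if "domain" in regs else np.array(["all"] * len(regs))
    rows = []
    n_skipped = 0
    for k in k_range:
        kmers = all_kmers(k)
        rc_index = np.array([kmers.index(reverse_complement(m)) for m in kmers])
        for side, wmask in sides.items():
            counts, skipped = _window_kmer_counts(grid, genome, k, wmask)
            n_skipped += skipped
            for dom in pd.unique(domains):
                dmask = domains == dom
                total = counts[dmask].sum()
                if total == 0:
                    continue
                fwd = counts[dmask].sum(axis=0)
                pct_plus = fwd / total * 100.0
                pct_minus = pct_plus[rc_index]
                for m, pp, pm in zip(kmers, pct_plus, pct_minus):
                    rows.append(
                        {
                            "k": k,
                            "kmer": m,
                            "side": side,
                            "domain": dom,
                            "pct_plus": pp,
                            "pct_minus": pm,
                        }
                    )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_skipped
    return out


def skew_vs_ratio(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lagging/leading occurrence ratios of collapsed k-mers vs their net
    statistics.

    Uses the fork-polarity convention (right of center: plus strand is the
    lagging template). Returns (per-k-mer points, per-net-value medians of
    the ratio). K-mers with zero leading-strand occurrence are excluded
    and tallied in ``points.attrs['n_excluded']``.
    """
    rows = []
    n_excluded = 0
    collapsed = table[table["kmer"] == table["kmer"].map(collapse_representative)]
    for _, rec in collapsed.iterrows():
        kmer = rec["kmer"]
        plus_is_lagging = template_role(rec["side"], "+") == "lagging"
        lagging = rec["pct_plus"] if plus_is_lagging else rec["pct_minus"]
        leading = rec["pct_minus"] if plus_is_lagging else rec["pct_plus"]
        if leading <= 0:
            n_excluded += 1
            continue
        nets = net_statistics(kmer)
        rows.append(
            {
                "k": rec["k"],
                "kmer": kmer,
                "side": rec["side"],
                "domain": rec["domain"],
                "ratio": lagging / leading,
                **nets,
            }
        )
    points = pd.DataFrame(rows)
    points.attrs["n_excluded"] = n_excluded
    if points.empty:
        return points, pd.DataFrame()
    medians = (
        points.groupby(["domain", "side", "net_T"])["ratio"].median().reset_index()
        .rename(columns={"ratio": "median_ratio"})
    )
    return points, medians


def at_content(regions: pd.DataFrame, genome: Genome) -> pd.Series:
    """A+T percentage of each region over its non-N bases (NaN if all N)."""
    vals = []
    for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
        arr = genome.encoded(chrom)[int(start) : int(end)]
        non_n = arr < 4
        denom = int(non_n.sum())
        if denom == 0:
            vals.append(np.nan)
            continue
        at = int(((arr == 0) | (arr == 3)).sum())
        vals.append(at / denom * 100.0)
    return pd.Series(vals, index=regions.index, name="at_percent")


def identify_at_rich(
    genome: Genome, slice_size: int = 50_000
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Genome-wide T-rich and A-rich slices by forward-strand T%/A%.

    The genome is sliced into ``slice_size`` pieces; per slice, relative
    T = T% / A% on the forward strand. Slices are split into quartiles of
    relative T (ties to the lower quartile); the top quartile is T-rich,
    the bottom A-rich. Slices with zero A are excluded and tallied.
    Returns (t_rich, a_rich, all slices with quartiles).
    """
    rows = []
    n_excluded = 0
    for chrom in genome.chrom_names:
        arr = genome.encoded(chrom)
        for s in range(0, len(arr), slice_size):
            block = arr[s : s + slice_size]
            a = int((block == 0).sum())
            t = int((block == 3).sum())
            if a == 0:
                n_excluded += 1
                continue
            rows.append(
                {"chrom": chrom, "start": s, "end": s + len(block), "rel_t": t / a}
            )
    slices = pd.DataFrame(rows)
    if slices.empty:
        raise ValueError("genome yielded no sliceable regions")
    rank = slices["rel_t"].rank(method="min").to_numpy()
    slices["quartile"] = np.ceil(4 * rank / len(slices)).astype(int)
    slices.attrs["n_excluded"] = n_excluded
    t_rich = slices[slices["quartile"] == 4].reset_index(drop=True)
    a_rich = slices[slices["quartile"] == 1].reset_index(drop=True)
    return t_rich, a_rich, slices
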