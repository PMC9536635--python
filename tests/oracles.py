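"""Independent brute-force oracles the implementation is checked against.

Everything here is written for clarity, not speed, and deliberately
avoids the package's own vectorised code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def awk_window_spans(regions: pd.DataFrame, a: int, b: int) -> list[tuple]:
    """Evaluate the centered-window arithmetic the way an awk one-liner
    would: float arithmetic, int() truncation, per region."""
    spans = []
    for _, r in regions.iterrows():
        mid_terms = (r["start"] + r["end"]) / 2 - a / 2 - a * (b - 1) / 2
        start = int(mid_terms)  # truncation toward zero, positive here
        end = int((r["start"] + r["end"]) / 2 + a / 2 + a * (b - 1) / 2)
        spans.append((r["chrom"], start, end))
    return spans


def filter_spans(spans: list[tuple], chrom_lengths: dict) -> list[tuple]:
    """Bounds filter then mutual pairwise overlap filter (O(n^2))."""
    in_bounds = [
        s for s in spans if s[0] in chrom_lengths and s[1] >= 0 and s[2] <= chrom_lengths[s[0]]
    ]
    keep = []
    for i, s in enumerate(in_bounds):
        clash = any(
            j != i and t[0] == s[0] and s[1] < t[2] and t[1] < s[2]
            for j, t in enumerate(in_bounds)
        )
        if not clash:
            keep.append(s)
    return keep


def brute_window_counts(reads: pd.DataFrame, grid) -> np.ndarray:
    """Per-base overlap check of every read against every window."""
    counts = np.zeros((grid.n_regions, grid.window_num, 2), dtype=np.int64)
    for _, rd in reads.iterrows():
        s_ax = 0 if rd["strand"] == "+" else 1
        read_bases = set(range(rd["start"], rd["end"]))
        for r in range(grid.n_regions):
            if grid.regions["chrom"].iloc[r] != rd["chrom"]:
                continue
            for w in range(1, grid.window_num + 1):
                ws, we = grid.window_bounds(r, w)
                if read_bases & set(range(ws, we)):
                    counts[r, w - 1, s_ax] += 1
    return counts


def brute_damage_site(chrom: str, start: int, end: int, strand: str, genome_seq: str):
    """Enumerate read-orientation positions 1..10 of the damage window
    from first principles: the lesion dinucleotide is the two bases
    immediately 5' of the read start (read orientation), placed at window
    positions 5-6. Returns (window_start, window_end, site) or None."""
    if strand == "+":
        lesion = [start - 2, start - 1]  # genomic, 5'->3'
        # window positions p=1..10 with p=5 at lesion[0]
        w_start = lesion[0] - 4
        w_end = w_start + 10
        if w_start < 0 or w_end > len(genome_seq):
            return None
        site = genome_seq[lesion[0]] + genome_seq[lesion[1]]
    else:
        # minus-strand read orientation runs right to left; two bases
        # upstream of its 5' end (at coordinate end-1) are end, end+1
        lesion = [end + 1, end]  # read orientation 5'->3' = genomic desc
        w_end = lesion[0] + 5
        w_start = w_end - 10
        if w_start < 0 or w_end > len(genome_seq):
            return None
        site = COMP[genome_seq[lesion[0]]] + COMP[genome_seq[lesion[1]]]
    return w_start, w_end, site


def brute_kmer_window_percentages(grid, genome, k: int, window_mask) -> dict:
    """Forward-strand overlapping k-mer percentages over the selected
    windows, by naive string scanning; keys are k-mers."""
    counts: dict[str, int] = {}
    total = 0
    for r in range(grid.n_regions):
        chrom = grid.regions["chrom"].iloc[r]
        for w in np.flatnonzero(window_mask):
            ws, we = grid.window_bounds(r, int(w) + 1)
            seq = genome.fetch(chrom, ws, we)
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if "N" in km:
                    continue
                counts[km] = counts.get(km, 0) + 1
                total += 1
    return {m: c / total * 100.0 for m, c in counts.items()}


def brute_net(kmer: str) -> dict:
    def over(s, sub):
        return sum(1 for i in range(len(s) - 1) if s[i : i + 2] == sub)

    return {
        "net_T": kmer.count("T") - kmer.count("A"),
        "net_TT": over(kmer, "TT") - over(kmer, "AA"),
        "net_TC": over(kmer, "TC") - over(kmer, "GA"),
        "net_C": kmer.count("C") - kmer.count("G"),
        "net_CC": over(kmer, "CC") - over(kmer, "GG"),
    }


def haldane_or(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)
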