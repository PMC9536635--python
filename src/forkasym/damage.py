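"""Strand-aware Damage-seq damage-site localisation and XR-seq profiling.

Damage-seq reads start two bases downstream of the UV lesion (the
polymerase stops right before the adduct), so the putative lesion
dinucleotide sits immediately 5' of the read start in read orientation.
Each read is converted to a 10-base window placing that dinucleotide at
read-orientation positions 5-6; reads whose site is not a dipyrimidine
(TT, TC, CT, CC) are discarded as damage-free.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import Genome, decode_sequence, make_reads

log = logging.getLogger(__name__)

DIPYRIMIDINES = frozenset({"TT", "TC", "CT", "CC"})

_DINUC_LOOKUP = np.array([x + y for x in "ACGTN" for y in "ACGTN"])


def _dinucleotides(codes1: np.ndarray, codes2: np.ndarray) -> np.ndarray:
    """Vectorised 2-mer strings from two uint8 base-code arrays."""
    return _DINUC_LOOKUP[codes1.astype(np.int64) * 5 + codes2]


def locate_damage_sites(reads: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Convert Damage-seq reads to 10-base damage windows.

    For a plus-strand read [s, e) the lesion dinucleotide is at genomic
    [s-2, s) and the window is [s-6, s+4); for a minus-strand read the
    lesion is at [e, e+2) (read orientation: two bases upstream of its 5'
    end) and the window is [e-4, e+6), with the site dinucleotide reported
    reverse-complemented (read orientation). Windows falling outside a
    chromosome are dropped and tallied (``result.attrs['n_dropped']``).
    """
    parts = []
    n_dropped = 0
    for (chrom, strand), sub in reads.groupby(["chrom", "strand"], sort=False):
        if chrom not in genome:
            n_dropped += len(sub)
            continue
        clen = genome.length(chrom)
        arr = genome.encoded(chrom)
        if strand == "+":
            ws = sub["start"].to_numpy(np.int64) - 6
        else:
            ws = sub["end"].to_numpy(np.int64) - 4
        we = ws + 10
        ok = (ws >= 0) & (we <= clen)
        n_dropped += int((~ok).sum())
        ws, we = ws[ok], we[ok]
        if len(ws) == 0:
            continue
        if strand == "+":
            site = _dinucleotides(arr[ws + 4], arr[ws + 5])
        else:
            # read-orientation positions 5-6 are genomic ws+5, ws+4 on the
            # reverse strand: complement and swap
            comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
            site = _dinucleotides(comp[arr[ws + 5]], comp[arr[ws + 4]])
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": ws,
                    "end": we,
                    "name": site,
                    "score": 0,
                    "strand": strand,
                }
            )
        )
    if parts:
        out = pd.concat(parts, ignore_index=True)
    else:
        out = make_reads([], [], [], [])
    if n_dropped:
        log.info("locate_damage_sites: %d reads dropped at chromosome edges", n_dropped)
    out.attrs["n_dropped"] = n_dropped
    return out


def filter_dipyrimidine(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the damage windows whose site dinucleotide (``name``)
    is TT, TC, CT, or CC."""
    out = records[records["name"].isin(DIPYRIMIDINES)].reset_index(drop=True)
    out.attrs["n_dropped"] = len(records) - len(out)
    return out


def deduplicate_by_position(reads: pd.DataFrame, include_strand: bool = True) -> pd.DataFrame:
    """Collapse reads sharing (chrom, start, end[, strand]) to one read,
    sorted by (chrom, start, end). The deduplication key includes strand by
    default because all downstream analyses are strand-resolved."""
    key = ["chrom", "start", "end"] + (["strand"] if include_strand else [])
    out = (
        reads.drop_duplicates(subset=key)
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def filter_common_chromosomes(
    reads: pd.DataFrame, allowed: list[str] | None = None
) -> pd.DataFrame:
    """Keep reads on an allow-list of chromosomes (default: autosomes + X,
    'chr1'..'chr22' and 'chrX')."""
    if allowed is None:
        allowed = default_common_chromosomes()
    if len(allowed) == 0:
        raise ValueError("chromosome allow-list must not be empty")
    return reads[reads["chrom"].isin(set(allowed))].reset_index(drop=True)


def default_common_chromosomes() -> list[str]:
    return [f"chr{i}" for i in range(1, 23)] + ["chrX"]


def read_length_histogram(reads: pd.DataFrame) -> tuple[pd.Series, int]:
    """Exact read-length histogram and median length (lower of the two
    middle values for even n)."""
    if reads.empty:
        raise ValueError("cannot compute a length histogram of zero reads")
    lengths = (reads["end"] - reads["start"]).to_numpy(np.int64)
    hist = pd.Series(lengths).value_counts().sort_index()
    lengths_sorted = np.sort(lengths)
    median = int(lengths_sorted[(len(lengths_sorted) - 1) // 2])
    return hist, median


def read_sequences_encoded(
    reads: pd.DataFrame, genome: Genome, read_length: int
) -> np.ndarray:
    """uint8 matrix (n_reads x read_length) of read-orientation sequences
    for the reads of exactly ``read_length``."""
    sel = reads[(reads["end"] - reads["start"]) == read_length]
    rows = []
    for (chrom, strand), sub in sel.groupby(["chrom", "strand"], sort=False):
        arr = genome.encoded(chrom)
        starts = sub["start"].to_numpy(np.int64)
        pos = starts[:, None] + np.arange(read_length)[None, :]
        block = arr[pos]
        if strand == "-":
            comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
            block = comp[block[:, ::-1]]
        rows.append(block)
    if not rows:
        return np.empty((0, read_length), dtype=np.uint8)
    return np.concatenate(rows, axis=0)


def positional_dinucleotide_profile(
    reads: pd.DataFrame, genome: Genome, read_length: int = 26
) -> pd.DataFrame:
    """Per-position 2-mer frequencies of reads of exactly ``read_length``.

    Rows are read-orientation start positions 1..read_length-1; columns the
    16 dinucleotides; each row sums to 1. Positions involving N are skipped
    in that read (frequencies renormalised over observed 2-mers).
    """
    mat = read_sequences_encoded(reads, genome, read_length)
    if mat.shape[0] == 0:
        raise ValueError(f"no reads of length {read_length}")
    dinucs = [a + b for a in "ACGT" for b in "ACGT"]
    table = np.zeros((read_length - 1, 16), dtype=float)
    for p in range(read_length - 1):
        c1, c2 = mat[:, p], mat[:, p + 1]
        ok = (c1 < 4) & (c2 < 4)
        codes = c1[ok].astype(np.int64) * 4 + c2[ok]
        counts = np.bincount(codes, minlength=16).astype(float)
        total = counts.sum()
        if total > 0:
            table[p] = counts / total
    out = pd.DataFrame(table, columns=dinucs)
    out.insert(0, "position", np.arange(1, read_length))
    return out


def read_sequences(reads: pd.DataFrame, genome: Genome) -> list[str]:
    """Read-orientation sequences (reverse-complemented for minus reads)."""
    seqs = []
    for chrom, start, end, strand in zip(
        reads["chrom"], reads["start"], reads["end"], reads["strand"]
    ):
        seqs.append(genome.fetch(chrom, int(start), int(end), strand))
    return seqs
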