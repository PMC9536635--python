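"""Reference-genome container and the plain-text genomic file formats.

All coordinates in this package are 0-based half-open (BED convention).
Inputs in 1-based conventions (e.g. mutation catalogs) are converted at
their parser boundary, never downstream.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# numeric encoding used for vectorised sequence work: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype="S1")

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class Genome:
    """In-memory reference genome with strand-aware sequence access.

    Parameters
    ----------
    sequences
        Ordered mapping of chromosome name to nucleotide string
        (alphabet ACGTN, any case; stored uppercase).
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        self._seqs: dict[str, str] = {}
        self._encoded: dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if len(seq) == 0:
                raise ValueError(f"chromosome {name!r} has zero length")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"chromosome {name!r} has invalid bases {bad}")
            self._seqs[name] = seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Uppercase sequence of [start, end); reverse-complemented for '-'."""
        seq = self._seqs[chrom]
        if not (0 <= start < end <= len(seq)):
            raise IndexError(
                f"request {chrom}:{start}-{end} outside [0, {len(seq)})"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    def encoded(self, chrom: str) -> np.ndarray:
        """Cached uint8 encoding of the forward strand of ``chrom``."""
        arr = self._encoded.get(chrom)
        if arr is None:
            arr = encode_sequence(self._seqs[chrom])
            arr.setflags(write=False)
            self._encoded[chrom] = arr
        return arr

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | os.PathLike, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_chrom_sizes(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f"{name}\t{len(seq)}\n")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes


def make_reads(
    chroms: Iterable[str],
    starts: Iterable[int],
    ends: Iterable[int],
    strands: Iterable[str],
    names: Iterable[str] | None = None,
    scores: Iterable | None = None,
) -> pd.DataFrame:
    """Assemble a BED6-shaped read table (the package's read container)."""
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype="string").astype(object),
            "start": np.asarray(list(starts), dtype=np.int64),
            "end": np.asarray(list(ends), dtype=np.int64),
        }
    )
    df["name"] = list(names) if names is not None else "."
    df["score"] = list(scores) if scores is not None else 0
    df["strand"] = list(strands)
    if len(df) and (df["start"] >= df["end"]).any():
        raise ValueError("reads must satisfy start < end")
    if len(df) and (~df["strand"].isin(["+", "-"])).any():
        raise ValueError("strand must be '+' or '-'")
    return df[BED6_COLUMNS]


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED6 file into the read table; '#'-prefixed headers skipped."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": object, "start": np.int64, "end": np.int64},
    )
    return df


def write_bed6(
    df: pd.DataFrame, path: str | os.PathLike, header_comments: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df[BED6_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def write_bedgraph(
    path: str | os.PathLike,
    chroms: Iterable[str],
    starts: Iterable[int],
    ends: Iterable[int],
    values: Iterable[float],
) -> None:
    pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "value": values}).to_csv(
        path, sep="\t", header=False, index=False
    )
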