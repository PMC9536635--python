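"""Sequence-context-matched random read simulation.

Damage and repair read counts are confounded by sequence composition
(lesions form only at dipyrimidines, excision fragments have strong
positional base biases). To normalise for this, real read sets are
profiled (per-position nucleotide frequencies and a length distribution,
in read orientation) and random genomic reads are drawn whose profiles
match, via rejection sampling: a candidate position/strand/length is
accepted with probability proportional to the background-corrected
likelihood ratio

    w(seq) = prod_i  p_i(seq_i) / q(seq_i)

(p_i the model's position-i frequencies, q the sampling space's base
composition) divided by its maximum attainable value. Under a
positionally independent background this matches the model's per-position
marginals in expectation; the plain likelihood would instead converge to
the product of background and model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .damage import DIPYRIMIDINES
from .genome import Genome, make_reads

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


@dataclass
class ReadProfileModel:
    """Empirical per-length positional nucleotide model of a read set.

    ``pos_freq[L]`` is an (L, 4) array of A/C/G/T frequencies at each
    read-orientation position; ``length_probs`` maps length -> probability.
    ``anchor`` optionally requires the 2-mer starting at a fixed 0-based
    read-orientation position to belong to a set (e.g. a dipyrimidine at
    positions 5-6 of a 10-base damage window -> ``(4, DIPYRIMIDINES)``).
    """

    pos_freq: dict[int, np.ndarray]
    length_probs: pd.Series
    anchor: tuple[int, frozenset[str]] | None = None
    n_excluded: int = 0

    def __post_init__(self):
        for L, f in self.pos_freq.items():
            if not np.allclose(f.sum(axis=1), 1.0):
                raise ValueError(f"position frequencies for length {L} must sum to 1")
        if not np.isclose(self.length_probs.sum(), 1.0):
            raise ValueError("length distribution must sum to 1")


def dipyrimidine_anchor(position: int = 4) -> tuple[int, frozenset[str]]:
    """Anchor requiring a dipyrimidine 2-mer at the given 0-based
    read-orientation position (negative positions count from the 3' end).

    Position 4 matches the lesion dinucleotide of 10-base damage windows;
    ``position=-6`` matches the excision-fragment lesion 5-6 nt from the
    3' end.
    """
    return (position, DIPYRIMIDINES)


def build_profile(
    reads: pd.DataFrame,
    genome: Genome,
    anchor: tuple[int, frozenset[str]] | None = None,
) -> ReadProfileModel:
    """Empirical per-position nucleotide frequencies and length
    distribution of a read set, in read orientation. Reads containing N
    are excluded from the profile and tallied."""
    from .damage import read_sequences_encoded

    if reads.empty:
        raise ValueError("cannot profile an empty read set")
    lengths = (reads["end"] - reads["start"]).to_numpy(np.int64)
    pos_freq: dict[int, np.ndarray] = {}
    length_counts: dict[int, int] = {}
    n_excluded = 0
    for L in np.unique(lengths):
        L = int(L)
        mat = read_sequences_encoded(reads, genome, L)
        clean = mat[(mat < 4).all(axis=1)]
        n_excluded += mat.shape[0] - clean.shape[0]
        if clean.shape[0] == 0:
            continue
        freq = np.stack(
            [np.bincount(clean[:, p], minlength=4)[:4] for p in range(L)]
        ).astype(float)
        pos_freq[L] = freq / freq.sum(axis=1, keepdims=True)
        length_counts[L] = clean.shape[0]
    if not length_counts:
        raise ValueError("no N-free reads to profile")
    lp = pd.Series(length_counts, dtype=float)
    lp /= lp.sum()
    return ReadProfileModel(
        pos_freq=pos_freq, length_probs=lp, anchor=anchor, n_excluded=n_excluded
    )


def _background_composition(genome: Genome, chroms: list[str]) -> np.ndarray:
    counts = np.zeros(4, dtype=np.int64)
    for c in chroms:
        counts += np.bincount(genome.encoded(c), minlength=5)[:4]
    total = counts.sum()
    if total == 0:
        raise ValueError("sampling space contains no A/C/G/T bases")
    return counts / total


def simulate_reads(
    model: ReadProfileModel,
    genome: Genome,
    n: int,
    seed: int,
    sampling_space: str = "genome",
    background_reads: pd.DataFrame | None = None,
    min_acceptance: float = 1e-4,
    burn_in: int = 20_000,
) -> pd.DataFrame:
    """Draw ``n`` frequency-matched random reads (deterministic per seed).

    ``sampling_space='genome'`` samples uniform positions and strands over
    the genome; ``'background_reads'`` samples sub-intervals of the
    supplied background fragment set (sequenced input DNA), so every
    simulated read lies within a background fragment. Candidates failing
    the model's anchor constraint are rejected outright; the rest are
    rejection-sampled against the background-corrected likelihood ratio.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if sampling_space == "background_reads":
        if background_reads is None or background_reads.empty:
            raise ValueError("background_reads required for that sampling space")
        bg = background_reads.reset_index(drop=True)
        chroms = sorted(set(bg["chrom"]))
    elif sampling_space == "genome":
        bg = None
        chroms = genome.chrom_names
    else:
        raise ValueError("sampling_space must be 'genome' or 'background_reads'")
    q = _background_composition(genome, chroms)

    lengths = model.length_probs.index.to_numpy(np.int64)
    length_p = model.length_probs.to_numpy()
    # per length: log(p/q) lookup and its max attainable sum
    logratio = {}
    max_logw = {}
    for L in lengths:
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.log(model.pos_freq[int(L)]) - np.log(q)[None, :]
        logratio[int(L)] = lr
        max_logw[int(L)] = np.max(lr, axis=1).sum()

    clens = np.array([genome.length(c) for c in chroms], dtype=np.int64)
    cprob = clens / clens.sum()

    out_chrom: list[np.ndarray] = []
    out_start: list[np.ndarray] = []
    out_len: list[np.ndarray] = []
    out_strand: list[np.ndarray] = []
    accepted = 0
    proposed = 0
    batch = max(4 * n, 10_000)
    anchor = model.anchor
    if anchor is not None:
        apos, aset = anchor
        acodes = {
            4 * "ACGT".index(s[0]) + "ACGT".index(s[1]) for s in aset
        }
        acode_mask = np.zeros(16, dtype=bool)
        for c in acodes:
            acode_mask[c] = True

    while accepted < n:
        Ls = rng.choice(lengths, size=batch, p=length_p)
        ci = rng.choice(len(chroms), size=batch, p=cprob)
        strands = rng.integers(0, 2, size=batch)  # 0 '+', 1 '-'
        if bg is None:
            maxstart = clens[ci] - Ls
            valid = maxstart >= 0
            starts = np.where(valid, (rng.random(batch) * np.maximum(maxstart + 1, 1)).astype(np.int64), -1)
        else:
            fi = rng.integers(0, len(bg), size=batch)
            fs = bg["start"].to_numpy(np.int64)[fi]
            fe = bg["end"].to_numpy(np.int64)[fi]
            ci = np.searchsorted(np.array(chroms, dtype=object), bg["chrom"].to_numpy()[fi])
            room = fe - fs - Ls
            valid = room >= 0
            starts = np.where(valid, fs + (rng.random(batch) * np.maximum(room + 1, 1)).astype(np.int64), -1)
        u = rng.random(batch)
        proposed += batch

        for L in np.unique(Ls):
            L = int(L)
            lr = logratio[L]
            mw = max_logw[L]
            sel = (Ls == L) & valid
            if not sel.any():
                continue
            sidx = np.flatnonzero(sel)
            # gather sequences per chromosome
            logw = np.full(len(sidx), -np.inf)
            seq_ok = np.zeros(len(sidx), dtype=bool)
            anchor_ok = np.ones(len(sidx), dtype=bool)
            for cix in np.unique(ci[sidx]):
                m = ci[sidx] == cix
                arr = genome.encoded(chroms[int(cix)])
                pos = starts[sidx[m], None] + np.arange(L)[None, :]
                block = arr[pos]
                minus = strands[sidx[m]] == 1
                if minus.any():
                    block[minus] = _COMP[block[minus, ::-1]]
                ok = (block < 4).all(axis=1)
                seq_ok[m] = ok
                pos_idx = np.arange(L)[None, :]
                lw = lr[pos_idx, np.minimum(block, 3).astype(np.int64)].sum(axis=1)
                logw[m] = np.where(ok, lw, -np.inf)
                if anchor is not None:
                    # negative anchor positions count from the 3' end
                    ap = apos if apos >= 0 else L + apos
                    if 0 <= ap < L - 1:
                        codes = block[:, ap].astype(np.int64) * 4 + block[:, ap + 1]
                        a_ok = ok & acode_mask[np.minimum(codes, 15)]
                        anchor_ok[m] = a_ok
                    else:
                        anchor_ok[m] = False
            acc = seq_ok & anchor_ok & (np.log(u[sidx] + 1e-300) < (logw - mw))
            aidx = sidx[acc]
            if len(aidx):
                out_chrom.append(np.array([chroms[int(c)] for c in ci[aidx]], dtype=object))
                out_start.append(starts[aidx])
                out_len.append(Ls[aidx])
                out_strand.append(strands[aidx])
                accepted += len(aidx)
        if proposed >= burn_in and accepted / proposed < min_acceptance:
            raise RuntimeError(
                f"simulation acceptance rate {accepted/proposed:.2e} below "
                f"{min_acceptance:.0e}; the profile model is too sharp for "
                "this sampling space -- consider a weaker model"
            )

    chrom = np.concatenate(out_chrom)[:n]
    start = np.concatenate(out_start)[:n]
    length = np.concatenate(out_len)[:n]
    strand = np.concatenate(out_strand)[:n]
    return make_reads(
        chrom,
        start,
        start + length,
        np.where(strand == 0, "+", "-"),
        names=[f"sim_{i}" for i in range(n)],
    )
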