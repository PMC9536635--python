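"""UV-signature somatic mutations and their strand asymmetry.

UV photoproducts at C-containing dipyrimidines give the skin-cancer
signature C>T change, read out strand-resolved: a forward-strand C>T
preceded by T is a TC>TT event on the plus strand; preceded by C it is
CC>CT; the mirror events appear as G>A followed by A (TC>TT, minus
strand) or G (CC>CT, minus strand). Everything else is "other".
Mutation catalogs are minimal TSVs (chrom, 1-based position, ref, alt,
sample), converted to 0-based on input.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genome import Genome
from .windows import WindowGrid

MUT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample"]


def read_mutation_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a (chrom, 1-based pos, ref, alt, sample) TSV; positions are
    converted to 0-based."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=MUT_COLUMNS,
                     dtype={"chrom": object, "pos": np.int64})
    df["pos"] = df["pos"] - 1
    return df


def write_mutation_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df[MUT_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", header=False, index=False)


def classify_uv_mutations(muts: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Attach UV-signature class and strand to single-base substitutions.

    Adds ``signature`` in {TC>TT, CC>CT, other} and ``strand`` in
    {+, -, .}. The catalog is assumed to report mutations on the forward
    strand. Context lookups that fall off a chromosome end leave the
    record unassigned (other/'.').
    """
    out = muts.reset_index(drop=True).copy()
    sig = np.full(len(out), "other", dtype=object)
    strand = np.full(len(out), ".", dtype=object)
    single = (
        out["ref"].str.len().eq(1)
        & out["alt"].str.len().eq(1)
        & (out["ref"] != out["alt"])
    )
    for chrom, idx in out.groupby("chrom", sort=False).indices.items():
        if chrom not in genome:
            continue
        arr = genome.encoded(chrom)
        clen = len(arr)
        pos = out["pos"].to_numpy(np.int64)[idx]
        ref = out["ref"].to_numpy()[idx]
        alt = out["alt"].to_numpy()[idx]
        ok = single.to_numpy()[idx] & (pos >= 0) & (pos < clen)

        ct = ok & (ref == "C") & (alt == "T") & (pos >= 1)
        if ct.any():
            prev = arr[np.maximum(pos - 1, 0)]
            tc = ct & (prev == 3)
            cc = ct & (prev == 1)
            sig[idx[tc]] = "TC>TT"
            strand[idx[tc]] = "+"
            sig[idx[cc]] = "CC>CT"
            strand[idx[cc]] = "+"
        ga = ok & (ref == "G") & (alt == "A") & (pos + 1 < clen)
        if ga.any():
            nxt = arr[np.minimum(pos + 1, clen - 1)]
            tc = ga & (nxt == 0)  # G>A followed by A = reverse-strand TC>TT
            cc = ga & (nxt == 2)  # followed by G = reverse-strand CC>CT
            sig[idx[tc]] = "TC>TT"
            strand[idx[tc]] = "-"
            sig[idx[cc]] = "CC>CT"
            strand[idx[cc]] = "-"
    out["signature"] = sig
    out["strand"] = strand
    return out


def _remove_in_genes(muts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    keep = np.ones(len(muts), dtype=bool)
    muts = muts.reset_index(drop=True)
    for chrom, sub in genes.groupby("chrom", sort=False):
        m = muts["chrom"] == chrom
        if not m.any():
            continue
        pos = muts.loc[m, "pos"].to_numpy(np.int64)
        gs = sub["start"].to_numpy(np.int64)
        ge = sub["end"].to_numpy(np.int64)
        order = np.argsort(gs)
        gs, ge = gs[order], ge[order]
        cummax = np.maximum.accumulate(ge)
        j = np.searchsorted(gs, pos, side="right")
        inside = (j > 0) & (cummax[np.maximum(j - 1, 0)] > pos)
        keep[np.flatnonzero(m)[inside]] = False
    return muts[keep].reset_index(drop=True)


def _strand_context_counts(grid: WindowGrid, genome: Genome) -> np.ndarray:
    """Overlapping TC+CC dinucleotide context counts per (region, window,
    strand). Plus-strand contexts are forward TC/CC; minus-strand contexts
    are forward GA/GG (their reverse complements)."""
    counts = np.zeros((grid.n_regions, grid.window_num, 2), dtype=np.int64)
    L = grid.window_len
    for r, (chrom, span_start) in enumerate(
        zip(grid.regions["chrom"], grid.regions["span_start"])
    ):
        arr = genome.encoded(chrom)
        for w in range(grid.window_num):
            s = int(span_start) + w * L
            block = arr[s : s + L]
            if len(block) < 2:
                continue
            c1 = block[:-1].astype(np.int64)
            c2 = block[1:]
            code = c1 * 5 + c2
            # forward TC = (3,1) -> 16 ; CC = (1,1) -> 6
            counts[r, w, 0] = int(np.sum(code == 16) + np.sum(code == 6))
            # forward GA = (2,0) -> 10 ; GG = (2,2) -> 12
            counts[r, w, 1] = int(np.sum(code == 10) + np.sum(code == 12))
    return counts


def _mutation_window_counts(
    muts: pd.DataFrame, grid: WindowGrid
) -> np.ndarray:
    """Signature-mutation counts per (region, window, strand)."""
    counts = np.zeros((grid.n_regions, grid.window_num, 2), dtype=np.int64)
    L = grid.window_len
    regs = grid.regions
    for chrom, sub in muts.groupby("chrom", sort=False):
        rsel = regs["chrom"] == chrom
        if not rsel.any():
            continue
        ridx = np.flatnonzero(rsel)
        starts = regs["span_start"].to_numpy(np.int64)[ridx]
        order = np.argsort(starts)
        ridx, starts = ridx[order], starts[order]
        ends = starts + grid.span_len
        pos = sub["pos"].to_numpy(np.int64)
        strands = (sub["strand"] == "-").to_numpy().astype(int)
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.maximum(j, 0)])
        for p, s_ax, jj in zip(pos[ok], strands[ok], j[ok]):
            w = (p - starts[jj]) // L
            counts[ridx[jj], w, s_ax] += 1
    return counts


def normalized_mutation_counts(
    muts: pd.DataFrame,
    grid: WindowGrid,
    genome: Genome,
    genes: pd.DataFrame | None = None,
    collapse_recurrent: bool = False,
    aggregate: bool = True,
):
    """Context-normalised UV-signature mutation counts around zones.

    MC per window and strand = (TC>TT + CC>CT mutations on that strand) /
    (TC + CC dinucleotide contexts on that strand). With ``genes``
    supplied, mutations inside gene intervals are removed first
    (intergenic mode). ``collapse_recurrent`` counts a site once even if
    mutated in several samples. With ``aggregate`` (default) counts are
    summed over regions and one MC profile per window index is returned;
    otherwise the per-region cell arrays are returned.
    """
    sig = muts[muts["signature"].isin(["TC>TT", "CC>CT"])]
    if genes is not None:
        sig = _remove_in_genes(sig, genes)
    if collapse_recurrent:
        sig = sig.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    mut_counts = _mutation_window_counts(sig, grid)
    ctx_counts = _strand_context_counts(grid, genome)
    if not aggregate:
        with np.errstate(divide="ignore", invalid="ignore"):
            mc = np.where(ctx_counts > 0, mut_counts / np.maximum(ctx_counts, 1), np.nan)
        return mc, mut_counts, ctx_counts
    m = mut_counts.sum(axis=0).astype(float)
    c = ctx_counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mc = np.where(c > 0, m / np.maximum(c, 1), np.nan)
    return pd.DataFrame(
        {
            "window": np.arange(1, grid.window_num + 1),
            "mc_plus": mc[:, 0],
            "mc_minus": mc[:, 1],
            "mut_plus": m[:, 0].astype(int),
            "mut_minus": m[:, 1].astype(int),
            "ctx_plus": c[:, 0].astype(int),
            "ctx_minus": c[:, 1].astype(int),
        }
    )


def quartile_strand_difference(
    muts: pd.DataFrame,
    grid: WindowGrid,
    min_flank: int = 2000,
) -> pd.DataFrame:
    """Absolute between-strand mutation-count difference per zone quartile
    and replication domain, over flanking windows.

    The grid's regions must carry ``quartile`` (and optionally ``domain``)
    labels. Empty quartiles are omitted.
    """
    regs = grid.regions
    if "quartile" not in regs:
        raise ValueError("grid regions carry no quartile labels")
    sig = muts[muts["signature"].isin(["TC>TT", "CC>CT"])]
    counts = _mutation_window_counts(sig, grid)
    offs = grid.window_offsets()
    flank = np.abs(offs) >= min_flank
    left = flank & (offs < 0)
    right = flank & (offs > 0)
    domains = regs["domain"].to_numpy() if "domain" in regs else np.array(["all"] * len(regs))
    quart = regs["quartile"].to_numpy()
    rows = []
    for dom in pd.unique(domains):
        for q in sorted(pd.unique(quart)):
            sel = (domains == dom) & (quart == q)
            if not sel.any():
                continue
            plus = int(counts[sel][:, flank, 0].sum())
            minus = int(counts[sel][:, flank, 1].sum())
            # the between-strand difference is accumulated per zone side:
            # fork polarity mirrors at the center, so a lagging-strand
            # excess appears with opposite strand sign left and right of
            # it and would cancel in a pooled plus-vs-minus total
            absdiff = 0
            for side in (left, right):
                d = counts[sel][:, side, 0].sum(axis=1) - counts[sel][:, side, 1].sum(axis=1)
                absdiff += int(np.abs(d).sum())
            rows.append(
                {
                    "domain": dom,
                    "quartile": int(q),
                    "n_zones": int(sel.sum()),
                    "plus": plus,
                    "minus": minus,
                    "abs_difference": absdiff,
                }
            )
    return pd.DataFrame(rows)
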