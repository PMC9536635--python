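"""Repair-rate computation and strand/domain/phase comparisons.

The *repair rate* (RR) of a genomic window is the excision-repair signal
divided by the damage signal (XR-seq / Damage-seq, RPKM scale); the
*normalized repair rate* (nRR) further divides each assay by its
sequence-context-matched simulation:

    nRR = log2( (XR_real / XR_sim) / (Damage_real / Damage_sim) )

Undefined cells (any zero input) propagate as NaN and are never
zero-filled; every aggregation reports how many cells it used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Genome
from .okseq import template_role
from .timing import assign_to_domains
from .windows import (
    SignalMatrix,
    WindowGrid,
    count_reads_in_regions,
    count_reads_in_windows,
    make_centered_windows,
)


@dataclass
class RepairRateProfile:
    """Per-region x window x strand repair-rate values on a grid.

    ``scale`` is 'linear' for plain RR and 'log2' for nRR; NaN marks
    undefined cells (zero denominators), counted in ``n_undefined``.
    """

    grid: WindowGrid
    values: np.ndarray
    scale: str
    n_undefined: int = 0


def _check_same_grid(*sms: SignalMatrix) -> WindowGrid:
    g0 = sms[0].grid
    for sm in sms[1:]:
        g = sm.grid
        same = (
            g.window_len == g0.window_len
            and g.window_num == g0.window_num
            and len(g.regions) == len(g0.regions)
            and g.regions["span_start"].to_numpy().tolist()
            == g0.regions["span_start"].to_numpy().tolist()
            and g.regions["chrom"].tolist() == g0.regions["chrom"].tolist()
        )
        if not same:
            raise ValueError("signal matrices are on different grids")
    return g0


def repair_rate(xr: SignalMatrix, dmg: SignalMatrix) -> RepairRateProfile:
    """RR = XR RPKM / Damage RPKM per cell; NaN where damage is zero."""
    grid = _check_same_grid(xr, dmg)
    x = xr.rpkm()
    d = dmg.rpkm()
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(d > 0, x / np.maximum(d, 1e-300), np.nan)
    return RepairRateProfile(
        grid=grid, values=rr, scale="linear", n_undefined=int((d <= 0).sum())
    )


def normalized_repair_rate(
    xr_real: SignalMatrix,
    xr_sim: SignalMatrix,
    dmg_real: SignalMatrix,
    dmg_sim: SignalMatrix,
) -> RepairRateProfile:
    """nRR = log2((XRr/XRs)/(Dr/Ds)) per cell; NaN wherever any of the
    four inputs is zero. Exactly invariant to global rescaling of any
    library (depth invariance)."""
    grid = _check_same_grid(xr_real, xr_sim, dmg_real, dmg_sim)
    arrs = [sm.rpkm() for sm in (xr_real, xr_sim, dmg_real, dmg_sim)]
    defined = np.logical_and.reduce([a > 0 for a in arrs])
    xr_r, xr_s, d_r, d_s = [np.where(defined, a, np.nan) for a in arrs]
    with np.errstate(divide="ignore", invalid="ignore"):
        nrr = np.log2((xr_r / xr_s) / (d_r / d_s))
    return RepairRateProfile(
        grid=grid, values=nrr, scale="log2", n_undefined=int((~defined).sum())
    )


def early_late_fold_change(
    rr_early: RepairRateProfile,
    rr_late: RepairRateProfile,
    per: str = "region",
) -> pd.DataFrame:
    """log2 fold change of mean repair rate between S-phase halves.

    ``per='region'`` gives one value per grid region; ``per='domain'``
    aggregates regions by their ``domain`` label first (the grid's regions
    must carry one). Linear-scale profiles are compared as
    log2(mean_early/mean_late); log2-scale (nRR) profiles as the
    difference of means.
    """
    if rr_early.scale != rr_late.scale:
        raise ValueError("profiles must share a scale")
    _check = _check_same_grid  # grids must match
    if rr_early.grid.n_regions != rr_late.grid.n_regions:
        raise ValueError("profiles are on different grids")
    e = np.nanmean(rr_early.values.reshape(rr_early.grid.n_regions, -1), axis=1)
    l = np.nanmean(rr_late.values.reshape(rr_late.grid.n_regions, -1), axis=1)
    regs = rr_early.grid.regions
    if per == "region":
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = e - l if rr_early.scale == "log2" else np.log2(e / l)
        out = regs[["chrom", "name"]].copy()
        if "domain" in regs:
            out["domain"] = regs["domain"].to_numpy()
        out["log2_fc"] = fc
        return out
    if per == "domain":
        if "domain" not in regs:
            raise ValueError("grid regions carry no domain labels")
        rows = []
        for dom, idx in regs.groupby("domain", sort=False).indices.items():
            me, ml = np.nanmean(e[idx]), np.nanmean(l[idx])
            fc = me - ml if rr_early.scale == "log2" else float(np.log2(me / ml))
            rows.append({"domain": dom, "n_regions": len(idx), "log2_fc": fc})
        return pd.DataFrame(rows)
    raise ValueError("per must be 'region' or 'domain'")


def accumulated_repair(dmg_0h: SignalMatrix, dmg_2h: SignalMatrix) -> RepairRateProfile:
    """Fraction of lesions removed by 2 h: (D0 - D2)/D0 on RPKM values.

    NaN where the 0-h signal is zero; negative values (apparent gain) are
    allowed and counted in the result's ``n_negative`` attribute.
    """
    grid = _check_same_grid(dmg_0h, dmg_2h)
    d0 = dmg_0h.rpkm()
    d2 = dmg_2h.rpkm()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d0 > 0, (d0 - d2) / np.maximum(d0, 1e-300), np.nan)
    prof = RepairRateProfile(
        grid=grid, values=frac, scale="linear", n_undefined=int((d0 <= 0).sum())
    )
    prof.n_negative = int(np.nansum(frac < 0))  # type: ignore[attr-defined]
    return prof


def filter_intergenic_reads(reads: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Remove reads overlapping (>= 1 bp) any gene interval, producing the
    intergenic variant of a signal before counting. The number removed is
    reported in ``result.attrs['n_removed']``."""
    keep = np.ones(len(reads), dtype=bool)
    reads = reads.reset_index(drop=True)
    for chrom, sub in genes.groupby("chrom", sort=False):
        m = (reads["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        rs = reads.loc[m, "start"].to_numpy(np.int64)
        re = reads.loc[m, "end"].to_numpy(np.int64)
        gs = sub["start"].to_numpy(np.int64)
        ge = sub["end"].to_numpy(np.int64)
        order = np.argsort(gs)
        gs, ge = gs[order], ge[order]
        cummax = np.maximum.accumulate(ge)
        j = np.searchsorted(gs, re, side="left")
        overlaps = (j > 0) & (cummax[np.maximum(j - 1, 0)] > rs)
        keep[np.flatnonzero(m)[overlaps]] = False
    out = reads[keep].reset_index(drop=True)
    out.attrs["n_removed"] = int(len(reads) - len(out))
    return out


# --------------------------------------------------------------- asymmetry


def strand_asymmetry(
    profile: RepairRateProfile, min_flank: int = 2000
) -> pd.DataFrame:
    """Leading/lagging strand asymmetry of a profile around zone centers.

    The grid must be centered on initiation zones. Windows whose midpoint
    lies < ``min_flank`` bases from the center are excluded; remaining
    windows are split by side and, per window, the plus and minus strand
    values form a pair. Reports per side (and per ``domain`` label when
    the grid's regions carry one): paired n, median plus-minus difference,
    median leading-minus-lagging difference, and a paired Wilcoxon
    signed-rank p-value (suppressed below 5 pairs).
    """
    grid = profile.grid
    offs = grid.window_offsets()
    flank = np.abs(offs) >= min_flank
    side_right = offs > 0
    vals = profile.values  # (regions, windows, 2)
    regs = grid.regions
    domains = regs["domain"].to_numpy() if "domain" in regs else np.array([None] * len(regs))

    rows = []
    groups = [("all", np.ones(len(regs), dtype=bool))]
    for dom in pd.unique(domains):
        if dom is not None and not (isinstance(dom, float) and np.isnan(dom)):
            groups.append((dom, domains == dom))
    for gname, gmask in groups:
        for side in ("left", "right"):
            wmask = flank & (side_right if side == "right" else ~side_right)
            sub = vals[gmask][:, wmask, :]
            plus = sub[:, :, 0].ravel()
            minus = sub[:, :, 1].ravel()
            ok = np.isfinite(plus) & np.isfinite(minus)
            p, m = plus[ok], minus[ok]
            diff = p - m
            lead_lag = diff if side == "left" else -diff
            n = len(diff)
            row = {
                "group": gname,
                "side": side,
                "n_pairs": n,
                "leading_strand": "+" if template_role(side, "+") == "leading" else "-",
                "median_plus_minus": float(np.median(diff)) if n else np.nan,
                "median_leading_minus_lagging": float(np.median(lead_lag)) if n else np.nan,
                "pvalue": np.nan,
            }
            if n >= 5 and np.any(diff != 0):
                row["pvalue"] = float(sps.wilcoxon(p, m).pvalue)
            rows.append(row)
    out = pd.DataFrame(rows)
    # overall leading-minus-lagging combining both sides
    both = []
    for side, s_mask in (("left", ~side_right), ("right", side_right)):
        sub = vals[:, flank & s_mask, :]
        d = sub[:, :, 0].ravel() - sub[:, :, 1].ravel()
        d = d[np.isfinite(d)]
        both.append(d if side == "left" else -d)
    alld = np.concatenate(both) if both else np.array([])
    out.attrs["overall_leading_minus_lagging"] = (
        float(np.median(alld)) if len(alld) else np.nan
    )
    out.attrs["n_pairs_total"] = int(len(alld))
    return out


# ------------------------------------------------------------ TSS and TES


def tss_tes_profile(
    xr_reads: pd.DataFrame,
    dmg_reads: pd.DataFrame,
    genes: pd.DataFrame,
    genome: Genome,
    interval_len: int = 100,
    window_num: int = 40,
) -> dict[str, pd.DataFrame]:
    """Template/non-template strand repair-rate meta-profiles around
    transcription start and end sites.

    For plus-strand genes the template strand (TS) is the minus strand;
    profiles of minus-strand genes are flipped so transcription always
    runs left to right. RR per window is the ratio of mean XR to mean
    damage RPKM over genes. Genes too close to chromosome ends are
    dropped by the windowing rules.
    """
    if "strand" not in genes or genes["strand"].isin(["+", "-"]).all() is False:
        raise ValueError("genes must be stranded")
    out = {}
    for anchor in ("TSS", "TES"):
        pts = genes.copy()
        plus = pts["strand"] == "+"
        pos = np.where(
            plus == (anchor == "TSS"), pts["start"].to_numpy(), pts["end"].to_numpy()
        )
        pts["start"], pts["end"] = pos, pos + 1
        grid = make_centered_windows(pts, interval_len, window_num, genome)
        if grid.n_regions == 0:
            out[anchor] = pd.DataFrame(columns=["window", "TS", "NTS"])
            continue
        xr_sm = count_reads_in_windows(xr_reads, grid)
        dmg_sm = count_reads_in_windows(dmg_reads, grid)
        xr_o = _oriented_strand_means(xr_sm)
        dmg_o = _oriented_strand_means(dmg_sm)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = np.where(dmg_o > 0, xr_o / np.maximum(dmg_o, 1e-300), np.nan)
        out[anchor] = pd.DataFrame(
            {"window": np.arange(1, window_num + 1), "TS": rr[:, 0], "NTS": rr[:, 1]}
        )
    return out


def _oriented_strand_means(sm: SignalMatrix) -> np.ndarray:
    """Mean RPKM per window with minus-strand regions flipped; column 0 is
    the template strand (opposite the gene), column 1 the non-template."""
    vals = sm.rpkm()
    strands = sm.grid.regions["strand"].to_numpy()
    oriented = np.empty_like(vals[:, :, :2])
    plus = strands == "+"
    # plus-strand genes: TS = minus-strand reads, window order unchanged
    oriented[plus, :, 0] = vals[plus][:, :, 1]
    oriented[plus, :, 1] = vals[plus][:, :, 0]
    minus = ~plus
    oriented[minus, :, 0] = vals[minus][:, ::-1, 0]
    oriented[minus, :, 1] = vals[minus][:, ::-1, 1]
    return oriented.mean(axis=0)


# ------------------------------------------------- chromatin-state summary


def segment_nrr(
    segments: pd.DataFrame,
    xr_real: pd.DataFrame,
    xr_sim: pd.DataFrame,
    dmg_real: pd.DataFrame,
    dmg_sim: pd.DataFrame,
) -> pd.DataFrame:
    """Per-segment normalized repair rate from raw read sets (strands
    pooled): log2((XRr/XRs)/(Dr/Ds)) of library-size-normalised counts.
    Segments with any zero input get NaN."""
    out = segments.reset_index(drop=True).copy()
    cols = {}
    for label, reads in (
        ("xr_real", xr_real),
        ("xr_sim", xr_sim),
        ("dmg_real", dmg_real),
        ("dmg_sim", dmg_sim),
    ):
        counted = count_reads_in_regions(reads, out[["chrom", "start", "end"]])
        cols[label] = (
            (counted["count_plus"] + counted["count_minus"]).to_numpy(float),
            max(len(reads), 1),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        xr_r = cols["xr_real"][0] / cols["xr_real"][1]
        xr_s = cols["xr_sim"][0] / cols["xr_sim"][1]
        d_r = cols["dmg_real"][0] / cols["dmg_real"][1]
        d_s = cols["dmg_sim"][0] / cols["dmg_sim"][1]
        defined = (xr_r > 0) & (xr_s > 0) & (d_r > 0) & (d_s > 0)
        out["nrr"] = np.where(defined, np.log2((xr_r / xr_s) / (d_r / d_s)), np.nan)
    return out


def chromatin_state_summary(
    early: pd.DataFrame,
    late: pd.DataFrame,
    domains: pd.DataFrame,
    min_segments: int = 5,
) -> pd.DataFrame:
    """Distributions of per-segment nRR by chromatin state, replication
    domain and S-phase half, with unpaired rank tests between phases.

    ``early``/``late`` are per-segment frames (chrom, start, end, state,
    nrr) for the two phases on identical segments. States with fewer than
    ``min_segments`` segments in a domain are reported without a test.
    """
    e = assign_to_domains(early, domains)
    l = late.reset_index(drop=True)
    rows = []
    for (state, dom), idx in e.groupby(["state", "domain"], dropna=False, sort=False).indices.items():
        ev = e["nrr"].to_numpy()[idx]
        lv = l["nrr"].to_numpy()[idx]
        ev, lv = ev[np.isfinite(ev)], lv[np.isfinite(lv)]
        row = {
            "state": state,
            "domain": dom,
            "n_segments": len(idx),
            "mean_early": float(np.mean(ev)) if len(ev) else np.nan,
            "mean_late": float(np.mean(lv)) if len(lv) else np.nan,
            "pvalue": np.nan,
        }
        if min(len(ev), len(lv)) >= min_segments:
            row["pvalue"] = float(sps.mannwhitneyu(ev, lv).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def phase_preference_tables(
    early: pd.DataFrame, late: pd.DataFrame, domains: pd.DataFrame
) -> dict[str, tuple[int, int, int, int]]:
    """Per-chromatin-state 2x2 tables of domain vs phase preference.

    For each state: a = ERD segments better repaired in early S phase
    (nrr_early > nrr_late), b = ERD segments better in late, c/d the same
    within LRDs. Input frames as for :func:`chromatin_state_summary`.
    """
    e = assign_to_domains(early, domains)
    ev = e["nrr"].to_numpy()
    lv = late.reset_index(drop=True)["nrr"].to_numpy()
    tables = {}
    for state, idx in e.groupby("state", sort=False).indices.items():
        dom = e["domain"].to_numpy()[idx]
        de = ev[idx]
        dl = lv[idx]
        ok = np.isfinite(de) & np.isfinite(dl) & (de != dl)
        better_early = de > dl
        a = int(np.sum(ok & (dom == "ERD") & better_early))
        b = int(np.sum(ok & (dom == "ERD") & ~better_early))
        c = int(np.sum(ok & (dom == "LRD") & better_early))
        d = int(np.sum(ok & (dom == "LRD") & ~better_early))
        tables[state] = (a, b, c, d)
    return tables
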