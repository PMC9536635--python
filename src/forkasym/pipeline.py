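"""End-to-end drivers tying the stages together on synthetic data.

These are the workflows the recovery experiments (and the worked
examples) run: generate a genome and read sets with planted knobs, push
them through damage-site localisation, simulation, windowed counting and
normalisation, and summarise the strand asymmetries the planted
parameters should reappear in.

Both assay simulations are anchored at the lesion dinucleotide (damage
windows at read-orientation positions 5-6, excision fragments 5-6 nt
from the 3' end): with matching hard constraints the two simulations
respond identically to planted composition skew, so their ratio cancels
in the normalized repair rate and the planted repair asymmetry is
recovered cleanly. An unanchored excision simulation tracks composition
skew more weakly than the anchored damage simulation and leaks sequence
asymmetry into nRR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth
from .damage import filter_dipyrimidine, locate_damage_sites
from .genome import Genome
from .mutation import classify_uv_mutations, normalized_mutation_counts
from .repair import normalized_repair_rate, strand_asymmetry
from .simulate import build_profile, dipyrimidine_anchor, simulate_reads
from .synth import SyntheticSpec
from .timing import assign_to_domains
from .windows import SignalMatrix, count_reads_in_windows, make_centered_windows


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def build_iz_grid(
    truth: dict,
    genome: Genome,
    interval_len: int,
    window_num: int,
) -> "WindowGrid":
    """Window grid centered on the planted zone centers, regions labeled
    with their planted domains."""
    izs = truth["izs"].copy()
    pts = izs[["chrom", "domain", "name"]].copy()
    pts["start"] = izs["center"].astype(np.int64)
    pts["end"] = pts["start"] + 1
    return make_centered_windows(pts, interval_len, window_num, genome)


def damage_library(reads: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Damage-seq processing: localise 10-base damage windows and keep
    dipyrimidine sites."""
    return filter_dipyrimidine(locate_damage_sites(reads, genome))


def run_repair_asymmetry(
    spec: SyntheticSpec,
    seed: int,
    n_reads: int = 400_000,
    n_sim: int = 400_000,
    interval_len: int = 1000,
    window_num: int = 40,
    min_flank: int = 2000,
    phase: str | None = None,
) -> dict:
    """Generate data under ``spec``, compute the nRR strand-asymmetry
    summary around planted zones, plus the raw damage asymmetry.

    Returns a dict with the asymmetry table, the overall
    leading-minus-lagging median (log2), the damage lagging-minus-leading
    log2 ratio, and intermediate objects for further analysis.
    """
    s = _child_seeds(seed, 6)
    genome, truth = synth.generate_genome(spec, s[0])
    dmg_reads = synth.generate_damage_reads(spec, genome, truth, n_reads, s[1])
    xr_reads = synth.generate_xr_reads(spec, genome, truth, n_reads, s[2], phase=phase)

    dmg_windows = damage_library(dmg_reads, genome)
    dmg_model = build_profile(dmg_windows, genome, anchor=dipyrimidine_anchor(4))
    dmg_sim = simulate_reads(dmg_model, genome, n_sim, s[3])
    xr_model = build_profile(xr_reads, genome, anchor=dipyrimidine_anchor(-6))
    xr_sim = simulate_reads(xr_model, genome, n_sim, s[4])

    grid = build_iz_grid(truth, genome, interval_len, window_num)
    sms = {
        name: count_reads_in_windows(reads, grid)
        for name, reads in (
            ("xr_real", xr_reads),
            ("xr_sim", xr_sim),
            ("dmg_real", dmg_windows),
            ("dmg_sim", dmg_sim),
        )
    }
    nrr = normalized_repair_rate(sms["xr_real"], sms["xr_sim"], sms["dmg_real"], sms["dmg_sim"])
    asym = strand_asymmetry(nrr, min_flank=min_flank)

    dmg_asym = _count_asymmetry(sms["dmg_real"], min_flank)
    return {
        "genome": genome,
        "truth": truth,
        "grid": grid,
        "signals": sms,
        "nrr": nrr,
        "asymmetry": asym,
        "nrr_leading_minus_lagging": asym.attrs["overall_leading_minus_lagging"],
        "damage_lagging_minus_leading": dmg_asym,
    }


def _count_asymmetry(sm: SignalMatrix, min_flank: int) -> float:
    """Overall log2 lagging/leading count ratio of a signal matrix on an
    IZ-centered grid (flanking windows only)."""
    offs = sm.grid.window_offsets()
    flank = np.abs(offs) >= min_flank
    right = offs > 0
    lag = sm.counts[:, flank & right, 0].sum() + sm.counts[:, flank & ~right, 1].sum()
    lead = sm.counts[:, flank & right, 1].sum() + sm.counts[:, flank & ~right, 0].sum()
    if min(lag, lead) == 0:
        return float("nan")
    return float(np.log2(lag / lead))


def run_phase_fold_change(
    spec: SyntheticSpec,
    seed: int,
    n_reads: int = 300_000,
    interval_len: int = 1000,
    window_num: int = 40,
) -> pd.DataFrame:
    """Early-vs-late repair-rate fold change per planted domain.

    The same damage library and simulations serve both phases, so the
    per-domain nRR difference isolates the planted phase boost.
    """
    from .repair import early_late_fold_change

    s = _child_seeds(seed, 8)
    genome, truth = synth.generate_genome(spec, s[0])
    dmg_reads = synth.generate_damage_reads(spec, genome, truth, n_reads, s[1])
    dmg_windows = damage_library(dmg_reads, genome)
    dmg_model = build_profile(dmg_windows, genome, anchor=dipyrimidine_anchor(4))
    dmg_sim = simulate_reads(dmg_model, genome, n_reads, s[2])

    xr_early = synth.generate_xr_reads(spec, genome, truth, n_reads, s[3], phase="early")
    xr_late = synth.generate_xr_reads(spec, genome, truth, n_reads, s[4], phase="late")
    xr_model = build_profile(xr_early, genome, anchor=dipyrimidine_anchor(-6))
    xr_sim = simulate_reads(xr_model, genome, n_reads, s[5])

    grid = build_iz_grid(truth, genome, interval_len, window_num)
    count = lambda reads: count_reads_in_windows(reads, grid)
    dmg_sm, dmg_sim_sm, xr_sim_sm = count(dmg_windows), count(dmg_sim), count(xr_sim)
    nrr_early = normalized_repair_rate(count(xr_early), xr_sim_sm, dmg_sm, dmg_sim_sm)
    nrr_late = normalized_repair_rate(count(xr_late), xr_sim_sm, dmg_sm, dmg_sim_sm)
    return early_late_fold_change(nrr_early, nrr_late, per="domain")


def run_mutation_asymmetry(
    spec: SyntheticSpec,
    seed: int,
    n_mutations: int = 100_000,
    interval_len: int = 1000,
    window_num: int = 40,
    min_flank: int = 2000,
) -> dict:
    """Normalized-mutation-count (MC) strand asymmetry around planted
    zones, per domain: log2 of lagging over leading MC."""
    s = _child_seeds(seed, 3)
    genome, truth = synth.generate_genome(spec, s[0])
    muts = classify_uv_mutations(
        synth.generate_mutations(spec, genome, truth, n_mutations, s[1]), genome
    )
    grid = build_iz_grid(truth, genome, interval_len, window_num)
    mc, mut_counts, ctx_counts = normalized_mutation_counts(
        muts, grid, genome, aggregate=False
    )
    offs = grid.window_offsets()
    flank = np.abs(offs) >= min_flank
    right = offs > 0
    out = {"genome": genome, "truth": truth, "mutations": muts}
    domains = grid.regions["domain"].to_numpy()
    for dom in ["all"] + sorted(set(domains)):
        sel = np.ones(len(domains), bool) if dom == "all" else domains == dom
        m_lag = mut_counts[sel][:, flank & right, 0].sum() + mut_counts[sel][:, flank & ~right, 1].sum()
        m_lead = mut_counts[sel][:, flank & right, 1].sum() + mut_counts[sel][:, flank & ~right, 0].sum()
        c_lag = ctx_counts[sel][:, flank & right, 0].sum() + ctx_counts[sel][:, flank & ~right, 1].sum()
        c_lead = ctx_counts[sel][:, flank & right, 1].sum() + ctx_counts[sel][:, flank & ~right, 0].sum()
        if min(m_lag, m_lead, c_lag, c_lead) == 0:
            out[f"mc_log2_lagging_over_leading_{dom}"] = float("nan")
        else:
            out[f"mc_log2_lagging_over_leading_{dom}"] = float(
                np.log2((m_lag / c_lag) / (m_lead / c_lead))
            )
    return out
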