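"""Self-contained recovery experiments on planted synthetic data.

Each experiment generates its inputs from the synthetic module under a
given seed, runs the relevant pipeline stage, and returns the measured
quantities next to their planted values. They are the package's own
validation battery: the asymmetry experiments isolate one knob at a time
(all other asymmetry knobs zeroed), the end-to-end experiment runs the
full default study conditions and checks sign structure.

Problem sizes (a 4-Mb two-chromosome genome, 1.5-6x10^5 reads per
library) are chosen so each experiment finishes in seconds to a couple
of minutes on one CPU while leaving the recovered parameters' standard
errors well inside the stated tolerances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import synth
from .damage import read_length_histogram, read_sequences_encoded
from .okseq import call_initiation_zones, compute_rfd
from .pipeline import _child_seeds, run_mutation_asymmetry, run_phase_fold_change, run_repair_asymmetry
from .simulate import build_profile, dipyrimidine_anchor, simulate_reads
from .stats import breslow_day_tarone
from .synth import SyntheticSpec
from .timing import TimingTrack, call_domains


def neutral_spec(**overrides) -> SyntheticSpec:
    """Default spec with every asymmetry knob zeroed (negative control
    base), overridable per experiment."""
    base = dict(
        t_skew={"ERD": 0.0, "LRD": 0.0},
        lead_lag_repair_ratio=1.0,
        phase_boost_log2fc=0.0,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


# ------------------------------------------------------------ read lengths


def excision_length_experiment(seed: int, n: int = 50_000) -> dict:
    """Median and range of generated excision-fragment lengths after the
    standard profiling step."""
    spec = SyntheticSpec()
    genome, truth = synth.generate_genome(spec, seed)
    xr = synth.generate_xr_reads(spec, genome, truth, n, seed + 1)
    hist, median = read_length_histogram(xr)
    return {
        "median_length": median,
        "min_length": int(hist.index.min()),
        "max_length": int(hist.index.max()),
        "mode_length": int(hist.idxmax()),
    }


# --------------------------------------------------------------- simulator


def simulator_contract_experiment(seed: int, n_sim: int = 50_000) -> dict:
    """Frequency-matching contract of the read simulator.

    Uses a compositionally homogeneous genome (the simulator's model
    assumption — a positionally independent background); reports the
    worst per-position total-variation distance between the simulated
    reads' nucleotide frequencies and the source profile, plus the
    dipyrimidine fraction at the anchored lesion position in anchored
    mode.
    """
    spec = neutral_spec(at_content={"ERD": 0.58, "LRD": 0.58})
    s = _child_seeds(seed, 4)
    genome, truth = synth.generate_genome(spec, s[0])
    xr = synth.generate_xr_reads(spec, genome, truth, 100_000, s[1])
    xr26 = xr[(xr["end"] - xr["start"]) == 26]
    model = build_profile(xr26, genome)
    sim = simulate_reads(model, genome, n_sim, s[2])
    mat = read_sequences_encoded(sim, genome, 26)
    emp = np.stack(
        [np.bincount(mat[:, p], minlength=4)[:4] for p in range(26)]
    ).astype(float)
    emp /= emp.sum(axis=1, keepdims=True)
    tv = 0.5 * np.abs(emp - model.pos_freq[26]).sum(axis=1)

    anchored = build_profile(xr26, genome, anchor=dipyrimidine_anchor(-6))
    sim_a = simulate_reads(anchored, genome, 5000, s[3])
    mat_a = read_sequences_encoded(sim_a, genome, 26)
    codes = mat_a[:, 20] * 4 + mat_a[:, 21]
    dipyr_codes = {15, 13, 7, 5}  # TT TC CT CC as 4*b1+b2
    frac = float(np.isin(codes, list(dipyr_codes)).mean())
    return {"max_tv": float(tv.max()), "anchored_dipyrimidine_fraction": frac}


# ------------------------------------------------------------ segmentation


def domain_recovery_experiment(
    seed: int, sigma: float = 0.3, n_bins: int = 500, boundary_every: int = 100
) -> dict:
    """Planted +-1 step domains with Gaussian noise; measures the worst
    boundary error (bins) and the per-bin label accuracy of the caller."""
    rng = np.random.default_rng(seed)
    labels = np.repeat([1, -1], boundary_every)
    truth_sign = np.tile(labels, n_bins // (2 * boundary_every) + 1)[:n_bins]
    ratio = truth_sign + rng.normal(0, sigma, n_bins)
    starts = np.arange(n_bins) * 50_000
    bins = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 50_000,
         "early": 0, "late": 0, "log2_ratio": ratio}
    )
    track = TimingTrack(bins=bins, bin_size=50_000, pseudocount=1.0)
    doms = call_domains(track, smooth_bins=10, min_bins=4, merge_gap_bins=1)

    planted_bounds = [b for b in range(boundary_every, n_bins, boundary_every)]
    called_bounds = sorted(
        set(doms["start"] // 50_000).union(doms["end"] // 50_000) - {0, n_bins}
    )
    errs = [min(abs(b - c) for c in called_bounds) for b in planted_bounds]

    called_sign = np.zeros(n_bins)
    for _, d in doms.iterrows():
        lo, hi = d["start"] // 50_000, d["end"] // 50_000
        called_sign[lo:hi] = 1 if d["label"] == "ERD" else -1
    accuracy = float(np.mean(called_sign == truth_sign))
    return {"max_boundary_error_bins": int(max(errs)), "bin_accuracy": accuracy}


def iz_recovery_experiment(seed: int, n_okseq: int = 600_000) -> dict:
    """Planted initiation zones recovered from simulated Okazaki
    fragments: worst center error (bins) and the Spearman correlation of
    called slope scores with planted efficiencies."""
    spec = SyntheticSpec()
    s = _child_seeds(seed, 2)
    genome, truth = synth.generate_genome(spec, s[0])
    ok = synth.generate_okseq_reads(spec, genome, truth, n_okseq, s[1])
    track = compute_rfd(ok, genome, bin_size=1000)
    zones = call_initiation_zones(track, min_delta=0.5, max_extent=150_000, smooth_bins=5)

    errs = []
    scores = []
    effs = []
    for _, z in truth["izs"].iterrows():
        cand = zones[zones["chrom"] == z["chrom"]]
        if cand.empty:
            errs.append(np.inf)
            continue
        d = (cand["center"] - z["center"]).abs()
        j = d.idxmin()
        errs.append(d.loc[j] / 1000.0)
        scores.append(zones.loc[j, "score"])
        effs.append(z["efficiency"])
    rho = float(sps.spearmanr(scores, effs).statistic)
    return {
        "n_called": len(zones),
        "n_planted": len(truth["izs"]),
        "max_center_error_bins": float(max(errs)),
        "score_efficiency_spearman": rho,
    }


# ---------------------------------------------------- asymmetry parameters


def repair_ratio_recovery_experiment(seed: int, n_reads: int = 600_000) -> dict:
    """Planted leading:lagging repair ratio 1.2, no sequence skew: the
    normalized-repair-rate asymmetry should recover log2(1.2) = 0.263."""
    spec = neutral_spec(lead_lag_repair_ratio=1.2)
    res = run_repair_asymmetry(
        spec, seed, n_reads=n_reads, n_sim=n_reads, interval_len=2000, window_num=40
    )
    return {
        "recovered_log2_asymmetry": float(res["nrr_leading_minus_lagging"]),
        "planted_log2_asymmetry": float(np.log2(1.2)),
    }


def phase_boost_recovery_experiment(seed: int, n_reads: int = 600_000) -> dict:
    """Planted early/late repair boost of 0.3 log2 units: per-domain nRR
    fold change should come back +0.3 in ERDs, -0.3 in LRDs."""
    spec = neutral_spec(phase_boost_log2fc=0.3)
    fc = run_phase_fold_change(
        spec, seed, n_reads=n_reads, interval_len=2000, window_num=20
    ).set_index("domain")
    return {
        "log2fc_erd": float(fc.loc["ERD", "log2_fc"]),
        "log2fc_lrd": float(fc.loc["LRD", "log2_fc"]),
        "planted": 0.3,
    }


def negative_control_experiment(seed: int, n_reads: int = 600_000) -> dict:
    """All asymmetry knobs zero: the median paired strand difference over
    ~2,000 windows should sit at zero."""
    spec = neutral_spec()
    res = run_repair_asymmetry(
        spec, seed, n_reads=n_reads, n_sim=n_reads, interval_len=1000, window_num=128
    )
    return {
        "abs_median_asymmetry": float(abs(res["nrr_leading_minus_lagging"])),
        "n_window_pairs": int(res["asymmetry"].attrs["n_pairs_total"]),
    }


# ------------------------------------------------------------- end to end


def sign_consistency_experiment(
    seed: int, n_seeds: int = 20, n_reads: int = 150_000, n_mutations: int = 80_000
) -> dict:
    """Full default study conditions (lagging-strand T-skew driving a
    lagging damage excess, leading-strand repair excess): per seed, the
    pipeline must report lagging-biased damage, leading-biased normalized
    repair, and lagging-biased normalized mutation rate in LRD zones."""
    spec = SyntheticSpec()
    seeds = _child_seeds(seed, n_seeds)
    ok = 0
    rows = []
    for s in seeds:
        r = run_repair_asymmetry(
            spec, s, n_reads=n_reads, n_sim=n_reads, interval_len=2000, window_num=20
        )
        m = run_mutation_asymmetry(
            spec, s, n_mutations=n_mutations, interval_len=2000, window_num=20
        )
        damage = r["damage_lagging_minus_leading"]
        nrr = r["nrr_leading_minus_lagging"]
        mc = m["mc_log2_lagging_over_leading_LRD"]
        good = damage > 0 and nrr > 0 and mc > 0
        ok += int(good)
        rows.append({"seed": s, "damage": damage, "nrr": nrr, "mc_lrd": mc, "ok": good})
    return {
        "fraction_consistent": ok / n_seeds,
        "n_seeds": n_seeds,
        "details": pd.DataFrame(rows),
    }


# -------------------------------------------------------------- statistics


def bd_calibration_experiment(
    seed: int,
    k: int = 8,
    n_per_stratum: int = 200,
    n_replicates: int = 2000,
    common_or: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the Breslow-Day/Tarone test under a
    homogeneous-odds-ratio null."""
    rng = np.random.default_rng(seed)
    base_p2 = np.linspace(0.2, 0.6, k)
    odds2 = base_p2 / (1 - base_p2)
    p1 = common_or * odds2 / (1 + common_or * odds2)
    half = n_per_stratum // 2
    rejections = 0
    for _ in range(n_replicates):
        tables = []
        a = rng.binomial(half, p1)
        c = rng.binomial(half, base_p2)
        for i in range(k):
            tables.append((int(a[i]), half - int(a[i]), int(c[i]), half - int(c[i])))
        res = breslow_day_tarone(tables)
        rejections += res.pvalue < alpha
    return {
        "type1_error": rejections / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


# ----------------------------------------------------------- AT composition


def at_content_experiment(seed: int) -> dict:
    """AT content of planted initiation zones split by domain (the
    generator plants the 54%/62% ERD/LRD compositions)."""
    from .context import at_content

    spec = SyntheticSpec()
    genome, truth = synth.generate_genome(spec, seed)
    izs = truth["izs"].copy()
    vals = at_content(izs, genome)
    izs["at"] = vals
    by = izs.groupby("domain")["at"].mean()
    return {"at_erd": float(by["ERD"]), "at_lrd": float(by["LRD"])}
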