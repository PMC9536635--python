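"""Synthetic multi-assay data with planted ground truth.

Generates a small multi-chromosome genome whose statistical structure
matches what the analysis assumes — early/late replication domains,
initiation zones with lagging-strand T-skew in their flanks, dipyrimidine
-driven damage reads, excision reads with strand/domain-specific repair
rates, phase-enriched replication reads, Okazaki fragments whose strand
switches across zones, and a UV-signature mutation catalog — plus a
manifest of every knob and planted feature, so each pipeline stage can be
tested by parameter recovery without any external download.

Defaults place 8 initiation zones per 2-Mb chromosome (spacing 250 kb,
extent 30 kb), one ERD and one LRD half per chromosome, base AT content
54% in ERDs and 62% in LRDs with lagging-strand T-skew 0.04/0.10 within
50 kb of zone centers, CPD propensities TT .40 / TC .25 / CT .25 / CC
.10, excision lengths 22-30 with mode 26, a leading:lagging repair ratio
of 1.2 and an early/late phase boost of 0.3 log2 units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, make_reads
from .okseq import template_role

STATE_LABELS = ("Active_Promoter", "Strong_Enhancer", "Txn_Elongation", "Repressed", "Heterochrom")


@dataclass
class SyntheticSpec:
    """All knobs of the generator; identical spec + seed give identical
    outputs. Knob meanings are documented field by field below."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    # initiation zones: centers every `iz_spacing` starting at spacing/2
    iz_spacing: int = 250_000
    iz_extent: int = 30_000
    iz_efficiencies: tuple[float, ...] = (0.5, 0.95, 0.6, 0.85, 0.7, 0.9, 0.55, 0.8)
    # lagging-strand T enrichment (probability mass moved from A to T)
    # within `skew_halfwidth` of zone centers, per domain label
    skew_halfwidth: int = 50_000
    t_skew: dict[str, float] = field(default_factory=lambda: {"ERD": 0.04, "LRD": 0.10})
    # base composition per domain: AT 54% in ERDs, 62% in LRDs
    at_content: dict[str, float] = field(default_factory=lambda: {"ERD": 0.54, "LRD": 0.62})
    # relative CPD formation propensity per dipyrimidine
    damage_propensity: dict[str, float] = field(
        default_factory=lambda: {"TT": 0.40, "TC": 0.25, "CT": 0.25, "CC": 0.10}
    )
    # excision fragment length distribution (22-30, mode 26, median 26)
    excision_length_probs: dict[int, float] = field(
        default_factory=lambda: {
            22: 0.02, 23: 0.04, 24: 0.07, 25: 0.12, 26: 0.30,
            27: 0.20, 28: 0.13, 29: 0.08, 30: 0.04,
        }
    )
    base_repair: float = 0.5            # fraction of lesions removed by 2 h
    lead_lag_repair_ratio: float = 1.2  # leading:lagging template repair
    phase_boost_log2fc: float = 0.3     # early/late repair log2FC (+ in ERD)
    damage_read_length: int = 50
    okazaki_length: int = 150
    edu_read_length: int = 100
    edu_domain_enrichment: float = 4.0  # in-phase vs out-of-phase domains
    gene_length: int = 40_000
    state_segment: int = 50_000
    n_mutation_samples: int = 183

    def validate(self) -> None:
        for name, size in self.chrom_sizes.items():
            if size < self.iz_spacing:
                raise ValueError(f"{name} shorter than one zone spacing")
        if 2 * self.skew_halfwidth > self.iz_spacing:
            raise ValueError("skew regions of adjacent zones would overlap")
        if abs(sum(self.excision_length_probs.values()) - 1) > 1e-9:
            raise ValueError("excision length probabilities must sum to 1")
        if not np.isclose(sum(self.damage_propensity.values()), 1.0):
            total = sum(self.damage_propensity.values())
            for k in self.damage_propensity:
                self.damage_propensity[k] /= total


# ------------------------------------------------------------- truth layout


def planted_domains(spec: SyntheticSpec) -> pd.DataFrame:
    """Half-chromosome ERD/LRD blocks, phase alternating per chromosome."""
    rows = []
    for i, (chrom, size) in enumerate(spec.chrom_sizes.items()):
        first, second = ("ERD", "LRD") if i % 2 == 0 else ("LRD", "ERD")
        rows.append({"chrom": chrom, "start": 0, "end": size // 2, "label": first})
        rows.append({"chrom": chrom, "start": size // 2, "end": size, "label": second})
    return pd.DataFrame(rows)


def planted_izs(spec: SyntheticSpec) -> pd.DataFrame:
    """Zone centers every ``iz_spacing`` with cycling efficiencies and the
    domain label of their position."""
    domains = planted_domains(spec)
    rows = []
    k = 0
    for chrom, size in spec.chrom_sizes.items():
        n = size // spec.iz_spacing
        for i in range(n):
            center = spec.iz_spacing // 2 + i * spec.iz_spacing
            eff = spec.iz_efficiencies[k % len(spec.iz_efficiencies)]
            dom = domains[
                (domains["chrom"] == chrom)
                & (domains["start"] <= center)
                & (center < domains["end"])
            ]["label"].iloc[0]
            rows.append(
                {
                    "chrom": chrom,
                    "start": center - spec.iz_extent // 2,
                    "end": center + spec.iz_extent // 2,
                    "center": center,
                    "efficiency": eff,
                    "domain": dom,
                    "name": f"iz_true_{k}",
                }
            )
            k += 1
    return pd.DataFrame(rows)


def planted_genes(spec: SyntheticSpec) -> pd.DataFrame:
    """One gene in the gap right of each zone's skew region, strands
    alternating; used for TSS/TES and intergenic analyses."""
    izs = planted_izs(spec)
    rows = []
    for i, rec in izs.iterrows():
        start = int(rec["center"]) + spec.skew_halfwidth + 10_000
        end = start + spec.gene_length
        if end > spec.chrom_sizes[rec["chrom"]]:
            continue
        rows.append(
            {
                "chrom": rec["chrom"],
                "start": start,
                "end": end,
                "name": f"gene_{i}",
                "score": 0,
                "strand": "+" if i % 2 == 0 else "-",
            }
        )
    return pd.DataFrame(rows)


def planted_states(spec: SyntheticSpec) -> pd.DataFrame:
    """ChromHMM-like state tiling in fixed-size segments, labels cycling."""
    rows = []
    k = 0
    for chrom, size in spec.chrom_sizes.items():
        for s in range(0, size, spec.state_segment):
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": min(s + spec.state_segment, size),
                    "state": STATE_LABELS[k % len(STATE_LABELS)],
                }
            )
            k += 1
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- genome


def _composition_segments(spec: SyntheticSpec, chrom: str):
    """(start, end, probs[4]) segments of constant base composition."""
    domains = planted_domains(spec)
    izs = planted_izs(spec)
    size = spec.chrom_sizes[chrom]
    breaks = {0, size}
    dsub = domains[domains["chrom"] == chrom]
    for _, d in dsub.iterrows():
        breaks.update((int(d["start"]), int(d["end"])))
    zsub = izs[izs["chrom"] == chrom]
    for _, z in zsub.iterrows():
        c = int(z["center"])
        breaks.update((c - spec.skew_halfwidth, c, c + spec.skew_halfwidth))
    pts = sorted(b for b in breaks if 0 <= b <= size)
    segments = []
    for s, e in zip(pts, pts[1:]):
        mid = (s + e) // 2
        dom = dsub[(dsub["start"] <= mid) & (mid < dsub["end"])]["label"].iloc[0]
        at = spec.at_content[dom]
        p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T
        inz = zsub[(zsub["center"] - spec.skew_halfwidth <= mid) & (mid < zsub["center"] + spec.skew_halfwidth)]
        if len(inz):
            # skew scales with the zone's firing efficiency (efficient
            # origins segregate strands more often), normalised so the
            # domain knob equals the mean across zones
            eff = float(inz["efficiency"].iloc[0])
            eff_scale = eff / float(np.mean(spec.iz_efficiencies))
            s_knob = spec.t_skew.get(dom, 0.0) * eff_scale
            side = "left" if mid < int(inz["center"].iloc[0]) else "right"
            if side == "right":
                # lagging template is the forward strand: enrich T
                p = p + np.array([-s_knob, 0, 0, s_knob])
            else:
                p = p + np.array([s_knob, 0, 0, -s_knob])
        segments.append((s, e, p))
    return segments


def generate_genome(spec: SyntheticSpec, seed: int) -> tuple[Genome, dict]:
    """Genome with planted composition plus the full truth manifest."""
    spec.validate()
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for chrom in spec.chrom_sizes:
        parts = []
        for s, e, p in _composition_segments(spec, chrom):
            p = np.clip(p, 1e-9, None)
            p = p / p.sum()
            draws = rng.choice(4, size=e - s, p=p)
            parts.append(draws.astype(np.uint8))
        seq = bases[np.concatenate(parts)].tobytes().decode("ascii")
        seqs[chrom] = seq
    genome = Genome(seqs)
    truth = {
        "seed": seed,
        "spec": asdict(spec),
        "domains": planted_domains(spec),
        "izs": planted_izs(spec),
        "genes": planted_genes(spec),
        "states": planted_states(spec),
    }
    return genome, truth


def write_manifest(truth: dict, path: str | os.PathLike) -> None:
    payload = {
        "seed": truth["seed"],
        "spec": truth["spec"],
        "domains": truth["domains"].to_dict("records"),
        "izs": truth["izs"].to_dict("records"),
        "genes": truth["genes"].to_dict("records"),
        "states": truth["states"].to_dict("records"),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ------------------------------------------------------------ repair field


def _repair_weight(
    spec: SyntheticSpec,
    truth: dict,
    chrom: str,
    pos: np.ndarray,
    strand_minus: np.ndarray,
    phase: str | None = None,
) -> np.ndarray:
    """Multiplicative repair-rate weight per lesion site.

    Within a zone's skew flank the leading-strand template gets
    sqrt(lead_lag_repair_ratio) and the lagging 1/sqrt (geometric mean 1);
    with a phase, repair is boosted by +phase_boost_log2fc/2 log2 units in
    the in-phase domain and reduced by the same in the other.
    """
    w = np.ones(len(pos), dtype=float)
    r = spec.lead_lag_repair_ratio
    izs = truth["izs"]
    for _, z in izs[izs["chrom"] == chrom].iterrows():
        c = int(z["center"])
        near = (pos >= c - spec.skew_halfwidth) & (pos < c + spec.skew_halfwidth)
        if not near.any():
            continue
        right = near & (pos >= c)
        left = near & ~right
        for side, mask in (("left", left), ("right", right)):
            if not mask.any():
                continue
            plus_role = template_role(side, "+")
            plus_factor = np.sqrt(r) if plus_role == "leading" else 1 / np.sqrt(r)
            minus_factor = 1 / plus_factor
            w[mask & ~strand_minus] *= plus_factor
            w[mask & strand_minus] *= minus_factor
    if phase is not None and spec.phase_boost_log2fc != 0.0:
        doms = truth["domains"]
        half = 2 ** (spec.phase_boost_log2fc / 2)
        for _, d in doms[doms["chrom"] == chrom].iterrows():
            m = (pos >= int(d["start"])) & (pos < int(d["end"]))
            in_phase = (phase == "early") == (d["label"] == "ERD")
            w[m] *= half if in_phase else 1 / half
    return w


# --------------------------------------------------------------- lesions


_DIPYR_PLUS = {(3, 3): "TT", (3, 1): "TC", (1, 3): "CT", (1, 1): "CC"}
# forward code pair -> dipyrimidine on the minus strand (reverse complement)
_DIPYR_MINUS = {(0, 0): "TT", (2, 0): "TC", (0, 2): "CT", (2, 2): "CC"}


def _lesion_candidates(spec: SyntheticSpec, genome: Genome):
    """All dipyrimidine sites per chromosome and strand with formation
    propensities. Returns list of (chrom, positions, strand_minus, weight)."""
    out = []
    prop = spec.damage_propensity
    for chrom in genome.chrom_names:
        arr = genome.encoded(chrom).astype(np.int64)
        c1, c2 = arr[:-1], arr[1:]
        for table, minus in ((_DIPYR_PLUS, False), (_DIPYR_MINUS, True)):
            w = np.zeros(len(c1), dtype=float)
            for (a, b), dinuc in table.items():
                w[(c1 == a) & (c2 == b)] = prop[dinuc]
            pos = np.flatnonzero(w > 0)
            out.append((chrom, pos, minus, w[pos]))
    return out


def _sample_lesions(
    spec: SyntheticSpec,
    genome: Genome,
    truth: dict,
    n: int,
    rng: np.random.Generator,
    extra_weight=None,
) -> pd.DataFrame:
    """Draw n lesion dinucleotide sites ∝ propensity x optional extra
    weight. Returns chrom, pos (dinucleotide start), minus flag."""
    cands = _lesion_candidates(spec, genome)
    chrom_names = list(genome.chrom_names)
    poss, minus, weights, block_ids = [], [], [], []
    for bid, (chrom, pos, is_minus, w) in enumerate(cands):
        if extra_weight is not None:
            w = w * extra_weight(chrom, pos, np.full(len(pos), is_minus))
        poss.append(pos)
        minus.append(np.full(len(pos), is_minus))
        weights.append(w)
        block_ids.append(np.full(len(pos), bid, dtype=np.int16))
    pos = np.concatenate(poss)
    bid = np.concatenate(block_ids)
    mns = np.concatenate(minus)
    w = np.concatenate(weights)
    p = w / w.sum()
    idx = rng.choice(len(pos), size=n, p=p)
    block_chrom = np.array([c for c, *_ in cands], dtype=object)
    return pd.DataFrame(
        {"chrom": block_chrom[bid[idx]], "pos": pos[idx], "minus": mns[idx]}
    )


def generate_damage_reads(
    spec: SyntheticSpec,
    genome: Genome,
    truth: dict,
    n: int,
    seed: int,
    timepoint: str = "0h",
) -> pd.DataFrame:
    """Damage-seq reads: the lesion dinucleotide sits two bases upstream
    of each read's 5' end. At '2h', each of the n drawn lesions survives
    with probability 1 - repaired fraction at its site/strand, so the
    returned library is correspondingly smaller (depth bookkeeping is the
    caller's: ``attrs['n_drawn']`` records n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lesions = _sample_lesions(spec, genome, truth, n, rng)
    if timepoint == "2h":
        keep = np.ones(len(lesions), dtype=bool)
        for chrom, idx in lesions.groupby("chrom", sort=False).indices.items():
            w = _repair_weight(
                spec, truth, chrom,
                lesions["pos"].to_numpy()[idx],
                lesions["minus"].to_numpy()[idx],
            )
            frac = np.clip(spec.base_repair * w, 0.0, 0.95)
            keep[idx] = rng.random(len(idx)) >= frac
        lesions = lesions[keep].reset_index(drop=True)
    elif timepoint != "0h":
        raise ValueError("timepoint must be '0h' or '2h'")
    L = spec.damage_read_length
    p = lesions["pos"].to_numpy(np.int64)
    minus = lesions["minus"].to_numpy(bool)
    start = np.where(minus, p - L, p + 2)
    end = start + L
    clens = lesions["chrom"].map(genome.chrom_lengths).to_numpy(np.int64)
    ok = (start >= 0) & (end <= clens)
    reads = make_reads(
        lesions["chrom"].to_numpy()[ok],
        start[ok],
        end[ok],
        np.where(minus[ok], "-", "+"),
        names=[f"dmg_{i}" for i in range(int(ok.sum()))],
    )
    reads.attrs["n_drawn"] = n
    return reads


def generate_xr_reads(
    spec: SyntheticSpec,
    genome: Genome,
    truth: dict,
    n: int,
    seed: int,
    phase: str | None = None,
) -> pd.DataFrame:
    """XR-seq excision fragments: lesion 5-6 nt from the 3' end, lengths
    from the planted 22-30 distribution, sampling rate ∝ damage propensity
    x repair-rate field (leading/lagging and optional phase knobs)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def xr_weight(chrom, pos, minus):
        return _repair_weight(spec, truth, chrom, pos, minus.astype(bool), phase)

    lesions = _sample_lesions(spec, genome, truth, n, rng, extra_weight=xr_weight)
    lengths = np.array(sorted(spec.excision_length_probs), dtype=np.int64)
    probs = np.array([spec.excision_length_probs[int(l)] for l in lengths])
    L = rng.choice(lengths, size=len(lesions), p=probs)
    p = lesions["pos"].to_numpy(np.int64)
    minus = lesions["minus"].to_numpy(bool)
    # lesion occupies read-orientation 0-based positions L-6, L-5
    start = np.where(minus, p - 4, p - (L - 6))
    end = start + L
    clens = lesions["chrom"].map(genome.chrom_lengths).to_numpy(np.int64)
    ok = (start >= 0) & (end <= clens)
    reads = make_reads(
        lesions["chrom"].to_numpy()[ok],
        start[ok],
        end[ok],
        np.where(minus[ok], "-", "+"),
        names=[f"xr_{i}" for i in range(int(ok.sum()))],
    )
    reads.attrs["n_drawn"] = n
    return reads


def generate_edu_reads(
    spec: SyntheticSpec,
    genome: Genome,
    truth: dict,
    phase: str,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Nascent-DNA reads enriched ``edu_domain_enrichment``-fold in the
    domains replicating in the given phase (early -> ERD, late -> LRD)."""
    if phase not in ("early", "late"):
        raise ValueError("phase must be 'early' or 'late'")
    rng = np.random.default_rng(seed)
    doms = truth["domains"]
    target = "ERD" if phase == "early" else "LRD"
    w = doms["end"] - doms["start"]
    w = w * np.where(doms["label"] == target, spec.edu_domain_enrichment, 1.0)
    p = (w / w.sum()).to_numpy()
    idx = rng.choice(len(doms), size=n, p=p)
    L = spec.edu_read_length
    starts = np.empty(n, dtype=np.int64)
    for i in np.unique(idx):
        m = idx == i
        lo = int(doms["start"].iloc[i])
        hi = int(doms["end"].iloc[i]) - L
        starts[m] = rng.integers(lo, max(hi, lo + 1), size=int(m.sum()))
    return make_reads(
        doms["chrom"].to_numpy()[idx],
        starts,
        starts + L,
        rng.choice(["+", "-"], size=n),
        names=[f"edu_{i}" for i in range(n)],
    )


def _target_rfd(spec: SyntheticSpec, truth: dict, chrom: str, size: int) -> np.ndarray:
    """Per-base sawtooth RFD: rises -eff -> +eff across each zone extent,
    descends linearly between zones (termination), tapers to 0 at ends."""
    izs = truth["izs"]
    zsub = izs[izs["chrom"] == chrom].sort_values("center")
    x = np.zeros(size, dtype=float)
    if zsub.empty:
        return x
    pts_x: list[int] = [0]
    pts_y: list[float] = [0.0]
    for _, z in zsub.iterrows():
        eff = float(z["efficiency"])
        pts_x.extend([int(z["start"]), int(z["end"])])
        pts_y.extend([-eff, +eff])
    pts_x.append(size - 1)
    pts_y.append(0.0)
    return np.interp(np.arange(size), pts_x, pts_y)


def generate_okseq_reads(
    spec: SyntheticSpec,
    genome: Genome,
    truth: dict,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Okazaki fragments at uniform positions whose strand follows the
    planted sawtooth RFD: P(minus/Crick) = (1 + RFD)/2."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = genome.chrom_names
    clens = np.array([genome.length(c) for c in chroms], dtype=np.int64)
    ci = rng.choice(len(chroms), size=n, p=clens / clens.sum())
    L = spec.okazaki_length
    out_parts = []
    for i, chrom in enumerate(chroms):
        m = ci == i
        cnt = int(m.sum())
        if cnt == 0:
            continue
        starts = rng.integers(0, clens[i] - L, size=cnt)
        rfd = _target_rfd(spec, truth, chrom, int(clens[i]))[starts + L // 2]
        is_minus = rng.random(cnt) < (1 + rfd) / 2
        out_parts.append(
            make_reads(
                np.full(cnt, chrom, dtype=object),
                starts,
                starts + L,
                np.where(is_minus, "-", "+"),
            )
        )
    out = pd.concat(out_parts, ignore_index=True)
    out["name"] = [f"ok_{i}" for i in range(len(out))]
    return out


def generate_mutations(
    spec: SyntheticSpec,
    genome: Genome,
    truth: dict,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """UV-signature mutation catalog: C>T (strand-mirrored G>A) events in
    TC/CC contexts, placed ∝ damage propensity x (1 - repaired fraction),
    so poorly repaired lagging-strand lesions mutate most."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prop = spec.damage_propensity
    blocks = []  # (chrom, minus_flag, pos, weight)
    for chrom in genome.chrom_names:
        arr = genome.encoded(chrom).astype(np.int64)
        c1, c2 = arr[:-1], arr[1:]
        for minus_flag, table in ((False, {"TC": (3, 1), "CC": (1, 1)}),
                                  (True, {"TC": (2, 0), "CC": (2, 2)})):
            for dinuc, (a, b) in table.items():
                pos = np.flatnonzero((c1 == a) & (c2 == b))
                if len(pos) == 0:
                    continue
                rw = _repair_weight(
                    spec, truth, chrom, pos, np.full(len(pos), minus_flag)
                )
                frac = np.clip(spec.base_repair * rw, 0.0, 0.95)
                blocks.append((chrom, minus_flag, pos, prop[dinuc] * (1 - frac)))
    pos = np.concatenate([b[2] for b in blocks])
    bid = np.concatenate(
        [np.full(len(b[2]), i, dtype=np.int16) for i, b in enumerate(blocks)]
    )
    w = np.concatenate([b[3] for b in blocks])
    idx = rng.choice(len(pos), size=n, p=w / w.sum())
    block_chrom = np.array([b[0] for b in blocks], dtype=object)
    block_minus = np.array([b[1] for b in blocks])
    chrom = block_chrom[bid]
    mns = block_minus[bid]
    # mutated base: the C of the (T|C)C context; on the minus strand the
    # context is the forward GA/GG pair and the mutated base is the G
    site = pos[idx]
    is_minus = mns[idx]
    mpos = np.where(is_minus, site, site + 1)
    ref = np.where(is_minus, "G", "C")
    alt = np.where(is_minus, "A", "T")
    samples = [f"S{int(s)+1}" for s in rng.integers(0, spec.n_mutation_samples, size=n)]
    return pd.DataFrame(
        {"chrom": chrom[idx], "pos": mpos, "ref": ref, "alt": alt, "sample": samples}
    )


def generate_all(
    spec: SyntheticSpec,
    seed: int,
    outdir: str | os.PathLike,
    n_damage: int = 200_000,
    n_xr: int = 200_000,
    n_edu: int = 100_000,
    n_okseq: int = 400_000,
    n_mutations: int = 50_000,
) -> dict:
    """Generate every assay to files under ``outdir`` plus the manifest."""
    from .genome import write_bed6
    from .mutation import write_mutation_tsv

    os.makedirs(outdir, exist_ok=True)
    genome, truth = generate_genome(spec, seed)
    genome.to_fasta(os.path.join(outdir, "genome.fa"))
    genome.write_chrom_sizes(os.path.join(outdir, "genome.chrom.sizes"))
    outputs = {"genome": genome, "truth": truth}
    sub = np.random.SeedSequence(seed).generate_state(8) % (2**31)
    writers = {
        "damage_0h.bed": generate_damage_reads(spec, genome, truth, n_damage, int(sub[0]), "0h"),
        "damage_2h.bed": generate_damage_reads(spec, genome, truth, n_damage, int(sub[1]), "2h"),
        "xr.bed": generate_xr_reads(spec, genome, truth, n_xr, int(sub[2])),
        "edu_early.bed": generate_edu_reads(spec, genome, truth, "early", n_edu, int(sub[3])),
        "edu_late.bed": generate_edu_reads(spec, genome, truth, "late", n_edu, int(sub[4])),
        "okseq.bed": generate_okseq_reads(spec, genome, truth, n_okseq, int(sub[5])),
    }
    for fname, df in writers.items():
        write_bed6(df, os.path.join(outdir, fname), header_comments=[f"seed={seed}"])
        outputs[fname.split(".")[0]] = df
    muts = generate_mutations(spec, genome, truth, n_mutations, int(sub[6]))
    write_mutation_tsv(muts, os.path.join(outdir, "mutations.tsv"))
    outputs["mutations"] = muts
    for key in ("domains", "izs", "genes"):
        truth[key].to_csv(os.path.join(outdir, f"truth_{key}.tsv"), sep="\t", index=False)
    write_manifest(truth, os.path.join(outdir, "manifest.yaml"))
    return outputs
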