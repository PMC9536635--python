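"""Repair-rate algebra, asymmetry summaries, TSS/TES and state grouping."""

import numpy as np
import pandas as pd
import pytest

from forkasym.genome import Genome, make_reads
from forkasym.repair import (
    RepairRateProfile,
    accumulated_repair,
    chromatin_state_summary,
    early_late_fold_change,
    normalized_repair_rate,
    phase_preference_tables,
    repair_rate,
    segment_nrr,
    strand_asymmetry,
    tss_tes_profile,
)
from forkasym.windows import SignalMatrix, WindowGrid, make_centered_windows


def grid_of(n_regions=2, window_num=4, window_len=100):
    regions = pd.DataFrame(
        {
            "chrom": ["c"] * n_regions,
            "span_start": [i * 10_000 for i in range(n_regions)],
            "span_end": [i * 10_000 + window_len * window_num for i in range(n_regions)],
            "center": [i * 10_000 + window_len * window_num / 2 for i in range(n_regions)],
            "name": [f"r{i}" for i in range(n_regions)],
            "strand": ".",
        }
    )
    return WindowGrid(regions=regions, window_len=window_len, window_num=window_num)


def sm_with(counts, grid, library_size=1000):
    return SignalMatrix(grid=grid, counts=np.asarray(counts, dtype=np.int64),
                        library_size=library_size)


class TestRepairRateAlgebra:
    def test_ratio_and_undefined(self):
        g = grid_of(1, 2)
        xr = sm_with([[[2, 2], [4, 0]]], g)
        dmg = sm_with([[[1, 1], [0, 2]]], g)
        rr = repair_rate(xr, dmg)
        assert rr.values[0, 0, 0] == pytest.approx(2.0)
        assert np.isnan(rr.values[0, 1, 0])
        assert rr.n_undefined == 1

    def test_linearity_in_xr(self):
        g = grid_of(1, 2)
        dmg = sm_with([[[5, 5], [5, 5]]], g)
        xr1 = sm_with([[[2, 4], [6, 8]]], g)
        xr2 = sm_with([[[4, 8], [12, 16]]], g)
        np.testing.assert_allclose(
            repair_rate(xr2, dmg).values, 2 * repair_rate(xr1, dmg).values
        )

    def test_grid_mismatch_errors(self):
        xr = sm_with([[[1, 1]] * 4] * 2, grid_of(2))
        dmg = sm_with([[[1, 1]] * 4] * 3, grid_of(3))
        with pytest.raises(ValueError):
            repair_rate(xr, dmg)

    def test_nrr_zero_when_real_equals_sim(self):
        g = grid_of(2)
        a = sm_with(np.full((2, 4, 2), 7), g)
        nrr = normalized_repair_rate(a, a, a, a)
        np.testing.assert_allclose(nrr.values, 0.0)

    def test_nrr_hand_computed_cell(self):
        g = grid_of(1, 1)
        mk = lambda v: sm_with([[[v, 1]]], g)
        nrr = normalized_repair_rate(mk(6), mk(3), mk(10), mk(5))
        # (6/3)/(10/5) = 1 -> 0
        assert nrr.values[0, 0, 0] == pytest.approx(0.0)
        nrr2 = normalized_repair_rate(mk(6), mk(3), mk(5), mk(5))
        assert nrr2.values[0, 0, 0] == pytest.approx(1.0)

    def test_nrr_depth_invariance(self):
        """Rescaling any library's depth leaves nRR unchanged exactly."""
        rng = np.random.default_rng(0)
        g = grid_of(3)
        c = [rng.integers(1, 50, (3, 4, 2)) for _ in range(4)]
        base = normalized_repair_rate(
            sm_with(c[0], g, 1000), sm_with(c[1], g, 1000),
            sm_with(c[2], g, 1000), sm_with(c[3], g, 1000),
        )
        # sequencing each library k-fold deeper: counts and library size
        # scale together
        scaled = normalized_repair_rate(
            sm_with(c[0] * 5, g, 5000), sm_with(c[1] * 3, g, 3000),
            sm_with(c[2] * 7, g, 7000), sm_with(c[3] * 2, g, 2000),
        )
        np.testing.assert_allclose(base.values, scaled.values)

    def test_nrr_undefined_tallied(self):
        g = grid_of(1, 1)
        nrr = normalized_repair_rate(
            sm_with([[[0, 1]]], g), sm_with([[[1, 1]]], g),
            sm_with([[[1, 1]]], g), sm_with([[[1, 1]]], g),
        )
        assert np.isnan(nrr.values[0, 0, 0]) and nrr.n_undefined == 1

    def test_fold_change_identity_and_doubling(self):
        g = grid_of(2)
        rr = RepairRateProfile(grid=g, values=np.full((2, 4, 2), 3.0), scale="linear")
        rr2 = RepairRateProfile(grid=g, values=np.full((2, 4, 2), 6.0), scale="linear")
        fc0 = early_late_fold_change(rr, rr)
        np.testing.assert_allclose(fc0["log2_fc"], 0.0)
        fc1 = early_late_fold_change(rr2, rr)
        np.testing.assert_allclose(fc1["log2_fc"], 1.0)

    def test_fold_change_per_domain(self):
        g = grid_of(4)
        g.regions["domain"] = ["ERD", "ERD", "LRD", "LRD"]
        vals = np.zeros((4, 4, 2))
        vals[:2] = 0.3  # log2-scale profile: ERD early boosted
        e = RepairRateProfile(grid=g, values=vals, scale="log2")
        l = RepairRateProfile(grid=g, values=np.zeros((4, 4, 2)), scale="log2")
        fc = early_late_fold_change(e, l, per="domain").set_index("domain")
        assert fc.loc["ERD", "log2_fc"] == pytest.approx(0.3)
        assert fc.loc["LRD", "log2_fc"] == pytest.approx(0.0)

    def test_accumulated_repair(self):
        g = grid_of(1, 1)
        prof = accumulated_repair(sm_with([[[100, 100]]], g), sm_with([[[25, 100]]], g))
        assert prof.values[0, 0, 0] == pytest.approx(0.75)
        assert prof.values[0, 0, 1] == pytest.approx(0.0)
        neg = accumulated_repair(sm_with([[[10, 1]]], g), sm_with([[[20, 0]]], g))
        assert neg.values[0, 0, 0] == pytest.approx(-1.0)
        assert neg.n_negative == 1


class TestStrandAsymmetry:
    def make_profile(self, values, window_len=1000, domains=None):
        n_regions, window_num, _ = values.shape
        g = grid_of(n_regions, window_num, window_len)
        if domains is not None:
            g.regions["domain"] = domains
        return RepairRateProfile(grid=g, values=values, scale="log2")

    def test_symmetric_profile_zero_median(self):
        vals = np.tile(np.array([1.0, 1.0])[None, None, :], (2, 8, 1))
        out = strand_asymmetry(self.make_profile(vals), min_flank=2000)
        assert (out["median_plus_minus"].abs() < 1e-12).all()

    def test_planted_ratio_orientation(self):
        """Leading-template excess of 0.263 log2 shows up with the right
        sign on both sides."""
        window_num, wl = 20, 1000
        vals = np.zeros((3, window_num, 2))
        offs = (np.arange(window_num) + 0.5) * wl - window_num * wl / 2
        for w, off in enumerate(offs):
            if off < 0:  # left: plus strand is leading template
                vals[:, w, 0] = 0.263
            else:  # right: minus strand is leading
                vals[:, w, 1] = 0.263
        out = strand_asymmetry(self.make_profile(vals), min_flank=2000)
        assert out.attrs["overall_leading_minus_lagging"] == pytest.approx(0.263)
        left = out[(out["group"] == "all") & (out["side"] == "left")].iloc[0]
        right = out[(out["group"] == "all") & (out["side"] == "right")].iloc[0]
        assert left["median_leading_minus_lagging"] == pytest.approx(0.263)
        assert right["median_leading_minus_lagging"] == pytest.approx(0.263)
        assert left["leading_strand"] == "+" and right["leading_strand"] == "-"

    def test_swapping_strands_negates_summary(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, (4, 12, 2))
        p1 = strand_asymmetry(self.make_profile(vals), min_flank=2000)
        p2 = strand_asymmetry(self.make_profile(vals[:, :, ::-1]), min_flank=2000)
        np.testing.assert_allclose(
            p1["median_plus_minus"], -p2["median_plus_minus"], atol=1e-12
        )

    def test_min_flank_excludes_central_windows(self):
        vals = np.zeros((1, 10, 2))
        prof = self.make_profile(vals)
        out = strand_asymmetry(prof, min_flank=3000)
        # span is 10 kb; windows with |offset| >= 3 kb: 2+... per side
        assert out[out["group"] == "all"]["n_pairs"].sum() == 4

    def test_few_pairs_suppresses_pvalue(self):
        vals = np.random.default_rng(1).normal(size=(1, 6, 2))
        out = strand_asymmetry(self.make_profile(vals), min_flank=2000)
        assert out["n_pairs"].max() < 5
        assert out["pvalue"].isna().all()

    def test_domain_groups_reported(self):
        vals = np.zeros((4, 12, 2))
        prof = self.make_profile(vals, domains=["ERD", "LRD", "ERD", "LRD"])
        out = strand_asymmetry(prof, min_flank=2000)
        assert set(out["group"]) == {"all", "ERD", "LRD"}


class TestTssTes:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(5)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        genome = Genome({"c": bases[rng.integers(0, 4, 60_000)].tobytes().decode()})
        genes = pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "start": [10_000, 30_000],
                "end": [20_000, 40_000],
                "strand": ["+", "-"],
            }
        )
        return genome, genes

    def test_template_strand_only_reads(self, setup):
        genome, genes = setup
        # template strand of a plus gene is minus; of a minus gene is plus
        xr = make_reads(
            ["c"] * 400,
            list(np.linspace(9000, 11_000, 200).astype(int))
            + list(np.linspace(39_000, 41_000, 200).astype(int)),
            list(np.linspace(9000, 11_000, 200).astype(int) + 26)
            + list(np.linspace(39_000, 41_000, 200).astype(int) + 26),
            ["-"] * 200 + ["+"] * 200,
        )
        dmg = make_reads(
            ["c"] * 800,
            list(np.linspace(8000, 12_000, 400).astype(int))
            + list(np.linspace(38_000, 42_000, 400).astype(int)),
            list(np.linspace(8000, 12_000, 400).astype(int) + 10)
            + list(np.linspace(38_000, 42_000, 400).astype(int) + 10),
            ["-"] * 200 + ["+"] * 200 + ["-"] * 200 + ["+"] * 200,
        )
        prof = tss_tes_profile(xr, dmg, genes, genome, interval_len=500, window_num=8)
        tss = prof["TSS"]
        assert np.nansum(tss["TS"]) > 0
        assert np.nansum(tss["NTS"]) == 0

    def test_balanced_reads_symmetric(self, setup):
        genome, genes = setup
        rng = np.random.default_rng(2)
        pos = np.repeat(rng.integers(5000, 45_000, 1000), 2)
        strands = np.tile(["+", "-"], 1000)  # every position on both strands
        xr = make_reads(["c"] * 2000, pos, pos + 26, strands)
        dmg = make_reads(["c"] * 2000, pos, pos + 10, strands)
        prof = tss_tes_profile(xr, dmg, genes, genome, interval_len=1000, window_num=6)
        tss = prof["TSS"].dropna()
        np.testing.assert_allclose(tss["TS"], tss["NTS"], rtol=1e-9)


class TestChromatinStates:
    def segs(self, nrr_e, nrr_l):
        n = len(nrr_e)
        base = pd.DataFrame(
            {
                "chrom": "c",
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "state": ["S1"] * (n // 2) + ["S2"] * (n - n // 2),
            }
        )
        e = base.copy()
        e["nrr"] = nrr_e
        l = base.copy()
        l["nrr"] = nrr_l
        return e, l

    domains = pd.DataFrame(
        {"chrom": ["c"], "start": [0], "end": [100_000], "label": ["ERD"]}
    )

    def test_identical_phases_zero_difference(self):
        e, l = self.segs(np.ones(12), np.ones(12))
        out = chromatin_state_summary(e, l, self.domains)
        assert (out["mean_early"] == out["mean_late"]).all()

    def test_effect_detected_only_in_planted_state(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 0.05, 40)
        e_vals = base.copy()
        e_vals[:20] += 1.0  # S1 boosted in early phase
        e, l = self.segs(e_vals, base)
        out = chromatin_state_summary(e, l, self.domains).set_index("state")
        assert out.loc["S1", "pvalue"] < 0.01
        assert out.loc["S2", "pvalue"] > 0.05

    def test_segment_counts_conserved(self):
        e, l = self.segs(np.ones(10), np.zeros(10))
        out = chromatin_state_summary(e, l, self.domains)
        assert out["n_segments"].sum() == 10

    def test_phase_preference_tables(self):
        doms = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [0, 5000], "end": [5000, 100_000],
             "label": ["ERD", "LRD"]}
        )
        e, l = self.segs(np.array([1.0] * 6 + [0.0] * 6), np.zeros(12))
        tables = phase_preference_tables(e, l, doms)
        a, b, c, d = tables["S1"]
        # S1 = segments 0..5 (ERD except segment 5 in LRD), all early-better
        assert (a, b) == (5, 0) and (c, d) == (1, 0)

    def test_segment_nrr_from_reads(self, toy_genome):
        segs = pd.DataFrame({"chrom": ["chrA"], "start": [1000], "end": [2000]})

        def mk(n_in, n_out):
            starts = [1100] * n_in + [5000] * n_out
            return make_reads(
                ["chrA"] * (n_in + n_out), starts, [s + 100 for s in starts],
                ["+"] * (n_in + n_out)
            )

        # in-segment fractions: XRr 1/2, XRs 1/4, Dr 1/2, Ds 1/2 -> log2 2
        out = segment_nrr(segs, mk(8, 8), mk(4, 12), mk(10, 10), mk(10, 10))
        assert out["nrr"].iloc[0] == pytest.approx(1.0)


class TestIntergenicFilter:
    def test_reads_overlapping_genes_removed(self):
        from forkasym.repair import filter_intergenic_reads

        genes = pd.DataFrame({"chrom": ["c", "c"], "start": [100, 500], "end": [200, 600]})
        reads = make_reads(
            ["c"] * 5, [50, 150, 199, 300, 595], [90, 160, 250, 400, 650], ["+"] * 5
        )
        out = filter_intergenic_reads(reads, genes)
        assert list(out["start"]) == [50, 300]
        assert out.attrs["n_removed"] == 3

    def test_no_genes_is_identity(self):
        from forkasym.repair import filter_intergenic_reads

        reads = make_reads(["c"], [0], [10], ["+"])
        out = filter_intergenic_reads(reads, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(out) == 1 and out.attrs["n_removed"] == 0
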