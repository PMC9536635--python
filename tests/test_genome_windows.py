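"""Genome container, centered windowing, counting, RPKM, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from forkasym.genome import Genome, make_reads, read_bed6, reverse_complement, write_bed6
from forkasym.windows import (
    aggregate_profile,
    count_reads_in_windows,
    make_centered_windows,
    moving_average,
)

import oracles


# ----------------------------------------------------------------- genome


class TestGenome:
    def test_fetch_and_reverse_complement(self, toy_genome):
        fwd = toy_genome.fetch("chrA", 100, 110)
        rev = toy_genome.fetch("chrA", 100, 110, strand="-")
        assert rev == oracles.revcomp(fwd)
        assert set(fwd) <= set("ACGTN")

    def test_out_of_bounds_requests_fail(self, toy_genome):
        with pytest.raises(IndexError):
            toy_genome.fetch("chrA", -1, 10)
        with pytest.raises(IndexError):
            toy_genome.fetch("chrA", 9_990, 10_001)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            Genome({"chr1": "ACGTX"})

    def test_fasta_roundtrip(self, toy_genome, tmp_path):
        path = tmp_path / "g.fa"
        toy_genome.to_fasta(path)
        again = Genome.from_fasta(path)
        assert again.chrom_lengths == toy_genome.chrom_lengths
        assert again.fetch("chrB", 0, 50) == toy_genome.fetch("chrB", 0, 50)

    def test_bed6_roundtrip(self, tmp_path):
        reads = make_reads(["chrA", "chrB"], [0, 10], [5, 20], ["+", "-"])
        path = tmp_path / "r.bed"
        write_bed6(reads, path, header_comments=["hello"])
        again = read_bed6(path)
        pd.testing.assert_frame_equal(reads, again)


# ------------------------------------------------------------- windowing


class TestCenteredWindows:
    def test_spec_example(self, toy_genome):
        """Region [1000,3000), a=100, b=4 expands to [1800,2200)."""
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [1000], "end": [3000]})
        grid = make_centered_windows(regions, 100, 4, toy_genome)
        assert grid.n_regions == 1
        assert grid.regions["span_start"].iloc[0] == 1800
        assert [grid.window_bounds(0, w) for w in range(1, 5)] == [
            (1800, 1900), (1900, 2000), (2000, 2100), (2100, 2200)
        ]

    def test_single_window_identity(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [500], "end": [700]})
        grid = make_centered_windows(regions, 200, 1, toy_genome)
        assert grid.window_bounds(0, 1) == (500, 700)

    def test_overlapping_expansions_both_dropped(self, toy_genome):
        regions = pd.DataFrame(
            {"chrom": ["chrA", "chrA"], "start": [1000, 1399], "end": [1000, 1399]}
        )
        # spans [800,1200) and [1199,1599) overlap by 1 bp
        with pytest.warns(UserWarning):
            grid = make_centered_windows(regions, 100, 4, toy_genome)
        assert grid.n_regions == 0

    def test_out_of_bounds_region_dropped(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA", "chrA"], "start": [10, 5000], "end": [20, 5001]})
        grid = make_centered_windows(regions, 100, 4, toy_genome)
        assert grid.n_regions == 1 and grid.regions["name"].iloc[0] == "region_1"

    def test_invalid_parameters(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [0], "end": [10]})
        with pytest.raises(ValueError):
            make_centered_windows(regions, 0, 4, toy_genome)
        with pytest.raises(ValueError):
            make_centered_windows(regions, 100, 0, toy_genome)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 9_000), st.integers(1, 900), st.sampled_from(["chrA", "chrB"])),
            min_size=1,
            max_size=8,
        ),
        a=st.integers(1, 200),
        b=st.integers(1, 8),
    )
    def test_matches_awk_arithmetic_oracle(self, toy_genome, data, a, b):
        """Surviving spans are bit-identical to direct evaluation of the
        truncated-midpoint formula plus mutual-overlap filtering."""
        regions = pd.DataFrame(
            {
                "chrom": [c for _, _, c in data],
                "start": [s for s, _, _ in data],
                "end": [s + l for s, l, _ in data],
            }
        )
        expected = sorted(
            oracles.filter_spans(
                oracles.awk_window_spans(regions, a, b), toy_genome.chrom_lengths
            )
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = make_centered_windows(regions, a, b, toy_genome)
        got = sorted(
            zip(grid.regions["chrom"], grid.regions["span_start"], grid.regions["span_end"])
        )
        assert got == [(c, int(s), int(e)) for c, s, e in expected]


class TestCounting:
    @pytest.fixture()
    def grid(self, toy_genome):
        regions = pd.DataFrame(
            {"chrom": ["chrA", "chrB"], "start": [2000, 1000], "end": [2000, 1000]}
        )
        return make_centered_windows(regions, 100, 4, toy_genome)

    def test_read_inside_one_window(self, grid):
        reads = make_reads(["chrA"], [2010], [2050], ["+"])  # window 3 of region 0
        sm = count_reads_in_windows(reads, grid)
        assert sm.counts[0, 2, 0] == 1 and sm.counts.sum() == 1

    def test_boundary_read_increments_both_windows(self, grid):
        reads = make_reads(["chrA"], [1995], [2005], ["-"])
        sm = count_reads_in_windows(reads, grid)
        assert sm.counts[0, 1, 1] == 1 and sm.counts[0, 2, 1] == 1

    def test_empty_reads_zero_matrix(self, grid):
        sm = count_reads_in_windows(make_reads([], [], [], []), grid)
        assert sm.counts.sum() == 0

    def test_unknown_chromosome_skipped_and_tallied(self, grid):
        reads = make_reads(["chrZ", "chrA"], [0, 2010], [10, 2020], ["+", "+"])
        sm = count_reads_in_windows(reads, grid)
        assert sm.skipped_reads == 1 and sm.counts.sum() == 1

    @settings(
        max_examples=25,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        reads_spec=st.lists(
            st.tuples(
                st.integers(1500, 2500), st.integers(1, 400), st.sampled_from(["+", "-"])
            ),
            min_size=0,
            max_size=20,
        )
    )
    def test_matches_per_base_brute_force(self, grid, reads_spec):
        reads = make_reads(
            ["chrA"] * len(reads_spec),
            [s for s, _, _ in reads_spec],
            [s + l for s, l, _ in reads_spec],
            [t for _, _, t in reads_spec],
        )
        sm = count_reads_in_windows(reads, grid)
        assert np.array_equal(sm.counts, oracles.brute_window_counts(reads, grid))

    def test_conservation_for_contained_reads(self, grid):
        """Reads each inside a single window sum to the read count."""
        rng = np.random.default_rng(5)
        starts = rng.integers(1800, 2190, 50)
        starts = (starts // 100) * 100 + 5  # inside one window each
        reads = make_reads(["chrA"] * 50, starts, starts + 20, ["+"] * 50)
        sm = count_reads_in_windows(reads, grid)
        assert sm.counts.sum() == 50


class TestAggregateAndSmooth:
    def test_rpkm_arithmetic(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [2000], "end": [2000]})
        grid = make_centered_windows(regions, 1000, 1, toy_genome)
        reads = make_reads(["chrA"] * 10, [1600] * 10, [1650] * 10, ["+"] * 10)
        sm = count_reads_in_windows(reads, grid, library_size=1_000_000)
        prof = aggregate_profile(sm, normalize="rpkm")
        assert prof["plus"].iloc[0] == pytest.approx(10.0)

    def test_mean_over_regions(self, toy_genome):
        regions = pd.DataFrame(
            {"chrom": ["chrA", "chrA"], "start": [2000, 6000], "end": [2000, 6000]}
        )
        grid = make_centered_windows(regions, 100, 2, toy_genome)
        reads = make_reads(
            ["chrA"] * 6, [1910, 1920, 5910, 5920, 5930, 5940],
            [1915, 1925, 5915, 5925, 5935, 5945], ["+"] * 6
        )
        sm = count_reads_in_windows(reads, grid)
        prof = aggregate_profile(sm, normalize="none")
        assert prof["plus"].iloc[0] == pytest.approx(3.0)  # mean of 2 and 4

    def test_rpkm_scale_invariance(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [2000], "end": [2000]})
        grid = make_centered_windows(regions, 100, 4, toy_genome)
        reads = make_reads(["chrA"] * 4, [1810, 1910, 2010, 2110], [1820, 1920, 2020, 2120], ["+"] * 4)
        sm1 = count_reads_in_windows(reads, grid, library_size=1000)
        doubled = pd.concat([reads, reads], ignore_index=True)
        sm2 = count_reads_in_windows(doubled, grid, library_size=2000)
        p1 = aggregate_profile(sm1)
        p2 = aggregate_profile(sm2)
        np.testing.assert_allclose(p1["plus"], p2["plus"])

    def test_rpkm_zero_library_errors(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [2000], "end": [2000]})
        grid = make_centered_windows(regions, 100, 4, toy_genome)
        sm = count_reads_in_windows(make_reads([], [], [], []), grid)
        with pytest.raises(ValueError):
            aggregate_profile(sm, normalize="rpkm")

    @pytest.mark.parametrize(
        "track,k,expected",
        [
            ([3.0] * 7, 5, [3.0] * 7),
            ([1.0, 2.0, 5.0], 1, [1.0, 2.0, 5.0]),
            ([0, 0, 10, 0, 0], 5, None),  # center checked below
        ],
    )
    def test_moving_average_cases(self, track, k, expected):
        out = moving_average(np.array(track, dtype=float), k)
        if expected is not None:
            np.testing.assert_allclose(out, expected)
        else:
            assert out[2] == pytest.approx(2.0)

    def test_moving_average_empty_and_edges(self):
        assert moving_average(np.array([]), 10).size == 0
        out = moving_average(np.arange(5, dtype=float), 3)
        # edge windows use the shorter available window
        assert out[0] == pytest.approx(0.5) and out[-1] == pytest.approx(3.5)


def test_chrom_sizes_and_bedgraph_roundtrip(toy_genome, tmp_path):
    from forkasym.genome import read_chrom_sizes, write_bedgraph

    sizes_path = tmp_path / "g.chrom.sizes"
    toy_genome.write_chrom_sizes(sizes_path)
    assert read_chrom_sizes(sizes_path) == toy_genome.chrom_lengths

    bg = tmp_path / "t.bedgraph"
    write_bedgraph(bg, ["chrA", "chrA"], [0, 100], [100, 200], [1.5, -0.5])
    lines = bg.read_text().splitlines()
    assert lines[0].split("\t") == ["chrA", "0", "100", "1.5"]
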