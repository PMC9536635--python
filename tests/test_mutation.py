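"""UV-signature mutation classification and strand-resolved statistics."""

import numpy as np
import pandas as pd
import pytest

from forkasym.genome import Genome, reverse_complement
from forkasym.mutation import (
    classify_uv_mutations,
    normalized_mutation_counts,
    quartile_strand_difference,
    read_mutation_tsv,
    write_mutation_tsv,
)
from forkasym.windows import make_centered_windows


def mut(chrom, pos, ref, alt, sample="S1"):
    return pd.DataFrame(
        {"chrom": [chrom], "pos": [pos], "ref": [ref], "alt": [alt], "sample": [sample]}
    )


class TestClassification:
    genome = Genome({"c": "AATCAGAACCGG" + "A" * 20})
    #                      0123456789...

    def test_forward_tc_context(self):
        out = classify_uv_mutations(mut("c", 3, "C", "T"), self.genome)  # T at 2
        assert out["signature"].iloc[0] == "TC>TT" and out["strand"].iloc[0] == "+"

    def test_forward_cc_context(self):
        out = classify_uv_mutations(mut("c", 9, "C", "T"), self.genome)  # C at 8
        assert out["signature"].iloc[0] == "CC>CT" and out["strand"].iloc[0] == "+"

    def test_reverse_tc_context(self):
        out = classify_uv_mutations(mut("c", 5, "G", "A"), self.genome)  # A at 6
        assert out["signature"].iloc[0] == "TC>TT" and out["strand"].iloc[0] == "-"

    def test_reverse_cc_context(self):
        out = classify_uv_mutations(mut("c", 10, "G", "A"), self.genome)  # G at 11
        assert out["signature"].iloc[0] == "CC>CT" and out["strand"].iloc[0] == "-"

    @pytest.mark.parametrize("ref,alt", [("A", "G"), ("T", "C"), ("C", "A")])
    def test_other_changes_unassigned(self, ref, alt):
        out = classify_uv_mutations(mut("c", 5, ref, alt), self.genome)
        assert out["signature"].iloc[0] == "other" and out["strand"].iloc[0] == "."

    def test_chromosome_start_context_unassigned(self):
        g = Genome({"c": "CCAAAA"})
        out = classify_uv_mutations(mut("c", 0, "C", "T"), g)
        assert out["signature"].iloc[0] == "other"

    def test_conservation_of_records(self, toy_genome):
        rng = np.random.default_rng(0)
        n = 300
        pos = rng.integers(1, 9_000, n)
        refs = rng.choice(list("ACGT"), n)
        alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
        df = pd.DataFrame({"chrom": "chrA", "pos": pos, "ref": refs, "alt": alts,
                           "sample": "S1"})
        out = classify_uv_mutations(df, toy_genome)
        assert len(out) == n
        n_fwd = ((out["signature"] != "other") & (out["strand"] == "+")).sum()
        n_rev = ((out["signature"] != "other") & (out["strand"] == "-")).sum()
        n_other = (out["signature"] == "other").sum()
        assert n_fwd + n_rev + n_other == n

    def test_involution_under_genome_reverse_complement(self, toy_genome):
        """The same physical events on the reverse-complemented genome get
        swapped strands and identical classes."""
        L = toy_genome.length("chrA")
        rc = Genome({"chrA": reverse_complement(toy_genome.fetch("chrA", 0, L))})
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(1)
        pos = rng.integers(1, L - 1, 200)
        refs = [toy_genome.fetch("chrA", p, p + 1) for p in pos]
        alts = [comp[r] if r in "AG" else ("T" if r == "C" else "C") for r in refs]
        # force C>T / G>A half the time
        alts = ["T" if r == "C" else "A" if r == "G" else a for r, a in zip(refs, alts)]
        cat = pd.DataFrame({"chrom": "chrA", "pos": pos, "ref": refs, "alt": alts,
                            "sample": "S1"})
        fwd = classify_uv_mutations(cat, toy_genome)
        mirrored = cat.copy()
        mirrored["pos"] = L - 1 - cat["pos"]
        mirrored["ref"] = [comp[r] for r in cat["ref"]]
        mirrored["alt"] = [comp[a] for a in cat["alt"]]
        rev = classify_uv_mutations(mirrored, rc)
        assert list(rev["signature"]) == list(fwd["signature"])
        flip = {"+": "-", "-": "+", ".": "."}
        assert list(rev["strand"]) == [flip[s] for s in fwd["strand"]]

    def test_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {"chrom": ["c", "c"], "pos": [5, 9], "ref": ["C", "G"], "alt": ["T", "A"],
             "sample": ["S1", "S2"]}
        )
        path = tmp_path / "m.tsv"
        write_mutation_tsv(df, path)
        again = read_mutation_tsv(path)
        pd.testing.assert_frame_equal(df, again)
        raw = path.read_text().splitlines()
        assert raw[0].split("\t")[1] == "6"  # stored 1-based


class TestNormalizedCounts:
    def test_mc_arithmetic(self):
        """4 TC>TT + 2 CC>CT over 100 TC + 100 CC contexts gives 0.03."""
        seq = "TC" * 100 + "ACC" * 100 + "G" * 124
        genome = Genome({"c": seq})
        regions = pd.DataFrame({"chrom": ["c"], "start": [312], "end": [312]})
        grid = make_centered_windows(regions, 624, 1, genome)
        assert grid.window_bounds(0, 1) == (0, 624)
        muts = pd.DataFrame(
            {
                "chrom": "c",
                "pos": [1, 3, 5, 7, 202, 205],
                "ref": "C",
                "alt": "T",
                "sample": "S1",
            }
        )
        classified = classify_uv_mutations(muts, genome)
        assert list(classified["signature"]) == ["TC>TT"] * 4 + ["CC>CT"] * 2
        out = normalized_mutation_counts(classified, grid, genome)
        # plus-strand contexts: 100 TC (the TC run) + 100 CC (one per ACC)
        expected = 6 / (100 + 100)
        assert out["mc_plus"].iloc[0] == pytest.approx(expected)

    def test_zero_mutations_zero_mc(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [5000], "end": [5000]})
        grid = make_centered_windows(regions, 500, 4, toy_genome)
        empty = classify_uv_mutations(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "sample"]).astype(
                {"pos": int}
            ),
            toy_genome,
        )
        out = normalized_mutation_counts(empty, grid, toy_genome)
        assert (out["mc_plus"] == 0).all()

    def test_intergenic_filter_removes_genic_mutations(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [5000], "end": [5000]})
        grid = make_centered_windows(regions, 500, 4, toy_genome)
        seq = toy_genome.fetch("chrA", 0, 10_000)
        pos = [i for i in range(4100, 5900) if seq[i] == "C" and seq[i - 1] == "T"][:10]
        cat = pd.DataFrame({"chrom": "chrA", "pos": pos, "ref": "C", "alt": "T",
                            "sample": "S1"})
        classified = classify_uv_mutations(cat, toy_genome)
        genes = pd.DataFrame({"chrom": ["chrA"], "start": [0], "end": [10_000]})
        out = normalized_mutation_counts(classified, grid, toy_genome, genes=genes)
        assert out["mut_plus"].sum() == 0
        out2 = normalized_mutation_counts(classified, grid, toy_genome)
        assert out2["mut_plus"].sum() == len(pos)

    def test_collapse_recurrent_sites(self, toy_genome):
        seq = toy_genome.fetch("chrA", 0, 10_000)
        p = next(i for i in range(4600, 5400) if seq[i] == "C" and seq[i - 1] == "T")
        cat = pd.DataFrame({"chrom": "chrA", "pos": [p, p, p], "ref": "C", "alt": "T",
                            "sample": ["S1", "S2", "S3"]})
        classified = classify_uv_mutations(cat, toy_genome)
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [5000], "end": [5000]})
        grid = make_centered_windows(regions, 500, 4, toy_genome)
        per_sample = normalized_mutation_counts(classified, grid, toy_genome)
        collapsed = normalized_mutation_counts(
            classified, grid, toy_genome, collapse_recurrent=True
        )
        assert per_sample["mut_plus"].sum() == 3
        assert collapsed["mut_plus"].sum() == 1


class TestQuartileDifference:
    def build(self, toy_genome, strands):
        regions = pd.DataFrame(
            {"chrom": ["chrA", "chrA"], "start": [3000, 7000], "end": [3000, 7000]}
        )
        grid = make_centered_windows(regions, 500, 8, toy_genome)
        grid.regions["quartile"] = [1, 4]
        grid.regions["domain"] = ["ERD", "LRD"]
        seq = toy_genome.fetch("chrA", 0, 10_000)
        rows = []
        for center, q in ((3000, 1), (7000, 4)):
            count = 5 if q == 1 else 15
            pos = [
                i
                for i in range(center - 1900, center + 1900)
                if seq[i] == "C" and seq[i - 1] == "T" and abs(i - center) > 250
            ][:count]
            for p in pos:
                rows.append({"chrom": "chrA", "pos": p, "ref": "C", "alt": "T",
                             "sample": "S1"})
        cat = classify_uv_mutations(pd.DataFrame(rows), toy_genome)
        return grid, cat

    def test_counts_and_symmetry(self, toy_genome):
        grid, cat = self.build(toy_genome, None)
        out = quartile_strand_difference(cat, grid, min_flank=250)
        q4 = out[out["quartile"] == 4].iloc[0]
        q1 = out[out["quartile"] == 1].iloc[0]
        assert q4["plus"] + q4["minus"] == 15
        assert q1["plus"] + q1["minus"] == 5
        # swapping strands leaves the absolute difference unchanged
        swapped = cat.copy()
        swapped["strand"] = swapped["strand"].map({"+": "-", "-": "+", ".": "."})
        out2 = quartile_strand_difference(swapped, grid, min_flank=250)
        np.testing.assert_array_equal(
            out["abs_difference"].to_numpy(), out2["abs_difference"].to_numpy()
        )

    def test_requires_quartiles(self, toy_genome):
        regions = pd.DataFrame({"chrom": ["chrA"], "start": [3000], "end": [3000]})
        grid = make_centered_windows(regions, 500, 8, toy_genome)
        with pytest.raises(ValueError):
            quartile_strand_difference(pd.DataFrame(), grid)


class TestQuartileEfficiencyRecovery:
    def test_lagging_excess_grows_with_zone_efficiency_in_lrds(self):
        """The planted lagging-strand mutation excess scales with zone
        firing efficiency, so the absolute strand difference increases
        monotonically across efficiency quartiles in LRDs."""
        from scipy.stats import spearmanr

        from forkasym.okseq import quartile_by_score
        from forkasym.pipeline import build_iz_grid
        from forkasym.synth import SyntheticSpec, generate_genome, generate_mutations

        spec = SyntheticSpec()
        genome, truth = generate_genome(spec, 71)
        muts = classify_uv_mutations(
            generate_mutations(spec, genome, truth, 120_000, 72), genome
        )
        izs = truth["izs"].rename(columns={"efficiency": "score"})
        lrd = quartile_by_score(izs[izs["domain"] == "LRD"].reset_index(drop=True))
        grid = build_iz_grid({"izs": lrd}, genome, 2000, 40)
        grid.regions["quartile"] = lrd["quartile"].to_numpy()
        table = quartile_strand_difference(muts, grid, min_flank=2000)
        table = table.sort_values("quartile")
        rho = spearmanr(table["quartile"], table["abs_difference"]).statistic
        assert rho > 0.9
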