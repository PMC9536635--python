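"""Net-T k-mer skew around zones and odds-ratio homogeneity across states.

Part 1: counts mono- to penta-nucleotides on both strands of the
initiation-zone flanks and relates each k-mer's lagging/leading
occurrence ratio to its net T (#T - #A): under the planted lagging-strand
T-skew, T-rich k-mers prefer the lagging strand.

Part 2: builds the chromatin-state x domain 2x2 tables of 'better
repaired early vs late' and runs the Breslow-Day/Tarone homogeneity test
on a simulated homogeneous set.
"""

import numpy as np

from forkasym.context import kmer_percentages, skew_vs_ratio
from forkasym.pipeline import build_iz_grid
from forkasym.stats import breslow_day_tarone, odds_ratio
from forkasym.synth import SyntheticSpec, generate_genome

spec = SyntheticSpec()
genome, truth = generate_genome(spec, seed=60)
grid = build_iz_grid(truth, genome, interval_len=2000, window_num=40)
table = kmer_percentages(grid, genome, k_range=range(1, 6), min_flank=2000)
points, medians = skew_vs_ratio(table)

lrd = medians[medians["domain"] == "LRD"]
print("median lagging/leading occurrence ratio by net T (LRD zones):")
print(lrd.groupby("net_T")["median_ratio"].median().round(3).to_string())
print("A ratio rising with net T reproduces the T-skew structure: the more")
print("net Ts a k-mer has, the more it concentrates on the lagging strand.")

rng = np.random.default_rng(61)
tables = []
for _ in range(8):  # one 2x2 per chromatin state, homogeneous association
    a = rng.binomial(100, 0.6)
    c = rng.binomial(100, 0.4)
    tables.append((a, 100 - a, c, 100 - c))
print("\nper-state odds ratios (ERD-and-early-better association):")
for i, t in enumerate(tables):
    print(f"  state {i}: OR = {odds_ratio(t).odds_ratio:.2f}")
res = breslow_day_tarone(tables)
print(f"Breslow-Day/Tarone: statistic {res.statistic:.2f}, df {res.df}, "
      f"p = {res.pvalue:.3f} (large p: no evidence the association differs "
      "between states)")
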