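"""Simulation-normalized repair rates and their strand asymmetry.

Runs the core pipeline on synthetic data with a planted leading:lagging
repair ratio of 1.2 (and no sequence skew, to isolate the knob):
real and simulated damage/excision libraries are counted on windows
around initiation-zone centers, combined into the normalized repair rate
nRR = log2((XR_real/XR_sim)/(Dmg_real/Dmg_sim)), and summarised as
paired plus/minus strand differences per side of the zone center.
"""

import numpy as np

from forkasym.pipeline import run_repair_asymmetry
from forkasym.synth import SyntheticSpec

spec = SyntheticSpec(
    t_skew={"ERD": 0.0, "LRD": 0.0},
    lead_lag_repair_ratio=1.2,
    phase_boost_log2fc=0.0,
)
result = run_repair_asymmetry(
    spec, seed=40, n_reads=200_000, n_sim=200_000, interval_len=2000, window_num=20
)

print("strand asymmetry of nRR around initiation-zone centers")
print("(paired Wilcoxon on per-window plus-vs-minus values):")
cols = ["group", "side", "n_pairs", "leading_strand",
        "median_leading_minus_lagging", "pvalue"]
print(result["asymmetry"][cols].round(4).to_string(index=False))
recovered = result["nrr_leading_minus_lagging"]
print(f"\noverall leading-minus-lagging nRR: {recovered:+.3f} log2 units")
print(f"planted value: log2(1.2) = {np.log2(1.2):+.3f}")
print("A positive value means the leading-strand template is repaired faster,")
print("as planted; the damage signal itself stays strand-balanced "
      f"({result['damage_lagging_minus_leading']:+.3f} log2).")
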