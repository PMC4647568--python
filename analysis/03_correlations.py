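#!/usr/bin/env python
"""Species-level rank correlations among the four meristic traits.

Computes the tie-corrected Spearman coefficient for T_n–T_var, T_n–T_range,
S_tr–T_var and S_tr–T_range over the eight central-population species, with
the t-approximation p and a seeded 10,000-draw permutation p. Writes
results/correlations.csv.
"""

from pathlib import Path

import pandas as pd

from triturus_axial import tables
from triturus_axial.pipeline import run_correlations, run_summaries
from triturus_axial.records import round_half_up

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

summaries = run_summaries(tables.load_table1_records(), zone_filter="central")
results = run_correlations(summaries, permutations=10_000, seed=1)
df = pd.DataFrame(
    dict(pair=name, r_s=round_half_up(res.r_s, 2), n=res.n,
         p_t=round(res.p_t, 4), p_perm=round(res.p_perm, 4))
    for name, res in results.items()
)
df.to_csv(OUT / "correlations.csv", index=False)
print(df.to_string(index=False))
print("\nModal count and non-modal fraction rise together (r_s = "
      f"{round_half_up(results['T_n~T_var'].r_s, 2)}); the transitional-"
      "sacrum frequency tracks neither variation measure.")
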