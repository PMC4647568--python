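#!/usr/bin/env python
"""Synthetic-data sanity checks for the whole pipeline.

Simulates record sets whose generating specs mirror the eight
central-population samples (sample sizes, modal counts, empirical count
spreads, transitional frequencies), re-runs the summary + correlation
stages on each replicate, and reports how well the generating values are
recovered.  Writes results/synthetic_recovery.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from triturus_axial.pipeline import run_correlations, run_summaries
from triturus_axial.simulate import simulate_records, table1_sim_specs

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=100)
args = parser.parse_args()

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

specs = table1_sim_specs()
tvar = {s.species: [] for s in specs}
str_ = {s.species: [] for s in specs}
r_obs = []
for rep in range(args.replicates):
    recs = simulate_records(specs, seed=args.seed * 100_000 + rep)
    summaries = run_summaries(recs, zone_filter="central")
    for sp, s in summaries.items():
        tvar[sp].append(s.t_var)
        str_[sp].append(s.s_tr)
    r_obs.append(run_correlations(summaries)["T_n~T_var"].r_s)

rows = []
for spec in specs:
    q = sum(p for off, p in spec.count_spread.items() if off != 0)
    rows.append(
        dict(
            species=spec.species,
            generating_T_var=round(100 * q * (1 - spec.p_transitional), 2),
            recovered_T_var=round(float(np.mean(tvar[spec.species])), 2),
            generating_S_tr=round(100 * spec.p_transitional, 2),
            recovered_S_tr=round(float(np.mean(str_[spec.species])), 2),
        )
    )
df = pd.DataFrame(rows)
df.to_csv(OUT / "synthetic_recovery.csv", index=False)
print(df.to_string(index=False))
print(f"\nmean r_s(T_n, T_var) over {args.replicates} synthetic datasets: "
      f"{np.mean(r_obs):.3f} (table-derived value 0.752)")
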