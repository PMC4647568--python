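#!/usr/bin/env python
"""Species-level summaries and homeotic-transformation tallies.

Recomputes, from the expanded records, the per-species statistics (modal
thoracic count T_n, percent non-modal T_var, span T_range, percent
transitional S_tr), the transformation tallies with left/right asymmetries,
the overall transitional-sacrum prevalence (hybrids excluded), and the
hybrid block. Writes results/species_summaries.csv and
results/transformations.csv.
"""

from pathlib import Path

import pandas as pd

from triturus_axial import tables
from triturus_axial.pipeline import (
    hybrid_intermediate_fraction,
    run_summaries,
    run_tallies,
)
from triturus_axial.records import round_half_up, summarize_species

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

records = tables.load_table1_records()
summaries = run_summaries(records, zone_filter="central")
rows = [
    dict(species=sp, n=s.n, T_n=s.t_n, T_range=s.t_range,
         S_tr=s.s_tr_rounded(), T_var=s.t_var_rounded())
    for sp, s in summaries.items()
]
hyb = summarize_species(tables.load_table3_records(), "cristatus_x_marmoratus")
rows.append(dict(species="cristatus_x_marmoratus (F1)", n=hyb.n, T_n=hyb.t_n,
                 T_range=hyb.t_range, S_tr=hyb.s_tr_rounded(),
                 T_var=hyb.t_var_rounded()))
df = pd.DataFrame(rows)
df.to_csv(OUT / "species_summaries.csv", index=False)
print(df.to_string(index=False))

full = tables.load_table2_records()
tallies, (k, n, pct) = run_tallies(full)
tdf = pd.DataFrame(
    dict(species=t.species, n=t.n, any=t.any_transformation,
         cervical_complete=t.cervical_complete,
         cervical_incomplete=t.cervical_incomplete,
         sacral_left=t.sacral_left, sacral_right=t.sacral_right,
         thoracic_incomplete=t.thoracic_to_sacral_incomplete)
    for t in tallies.values()
)
tdf.loc["total"] = ["total", *tdf.drop(columns="species").sum()]
tdf.to_csv(OUT / "transformations.csv", index=False)
print()
print(tdf.to_string(index=False))
print(f"\nTransitional sacrum, hybrids excluded: {k}/{n} "
      f"({round_half_up(pct, 1)}%)")

ki, ni, pcti = hybrid_intermediate_fraction(
    tables.load_table3_records(), "cristatus_x_marmoratus", (12, 15)
)
print(f"F1 hybrids with intermediate thoracic number: {ki}/{ni} "
      f"({round_half_up(pcti, 1)}%)")
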