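#!/usr/bin/env python
"""Expand the packaged species tables into specimen-level record files.

Writes the central-population, full-sample and hybrid record sets to
results/records/ in the record CSV dialect, so every later stage (and any
external tool) can consume them through the same path as user data.
"""

from pathlib import Path

from triturus_axial import tables
from triturus_axial.records import write_records

OUT = Path(__file__).resolve().parent.parent / "results" / "records"
OUT.mkdir(parents=True, exist_ok=True)

for name, loader in [
    ("central_populations.csv", tables.load_table1_records),
    ("full_sample.csv", tables.load_table2_records),
    ("hybrids_and_parents.csv", tables.load_table3_records),
]:
    records = loader()
    write_records(records, OUT / name)
    print(f"{name}: {len(records)} records")
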