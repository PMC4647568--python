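"""Packaged fixtures: the printed species tables and the calibrated tree.

Four small CSV files transcribe the published summary tables at the
distribution level, so that every printed statistic can be recomputed
through the ordinary record-level code path:

* ``table1_central_distributions.csv`` — per-species thoracic-score
  distributions, central populations only (score, count).
* ``table2_transformations.csv`` — per-species homeotic-transformation
  category counts over the full sample (central + fringe).
* ``table3_hybrid_distributions.csv`` — F1 hybrids (*T. cristatus* ×
  *T. marmoratus*) and both parental species.
* ``table4_zone_counts.csv`` — modal / non-modal counts in central vs
  fringe populations for the five species with parapatric distributions.

The packaged Newick tree carries the published topology for the eight
species; its branch lengths are an *approximate* ultrametric calibration
(root depth 24 Ma) because node ages are not printed — analyses that depend
on exact ages should supply their own tree.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Dict

import numpy as np

from .records import VertebralRecord, expand_distribution, summarize_species

SPECIES_ORDER = (
    "marmoratus",
    "pygmaeus",
    "ivanbureschi",
    "karelinii",
    "carnifex",
    "macedonicus",
    "cristatus",
    "dobrogicus",
)

HYBRID_TOKEN = "cristatus_x_marmoratus"


def _data_text(name: str) -> str:
    return (resources.files("triturus_axial") / "data" / name).read_text(
        encoding="utf-8"
    )


def _load_distribution_records(name: str) -> list[VertebralRecord]:
    rows = list(csv.DictReader(_data_text(name).splitlines()))
    by_species: dict[tuple[str, str], dict[float, int]] = {}
    for row in rows:
        key = (row["species"], row["zone"])
        by_species.setdefault(key, {})[float(row["score"])] = int(row["count"])
    records: list[VertebralRecord] = []
    for (species, zone), dist in by_species.items():
        records.extend(expand_distribution(species, dist, zone=zone))
    return records


def load_table1_records() -> list[VertebralRecord]:
    """Central-population records for the eight species (n = 643)."""
    return _load_distribution_records("table1_central_distributions.csv")


def load_table3_records() -> list[VertebralRecord]:
    """Hybrid and parental-species records (hybrids n = 68)."""
    return _load_distribution_records("table3_hybrid_distributions.csv")


def load_table2_records() -> list[VertebralRecord]:
    """Full-sample records (n = 1,368, hybrids excluded) with transformation
    annotations matching the printed per-species category counts.

    The per-specimen thoracic counts are placed at the species' modal number
    (the table reports transformation categories, not count distributions),
    so these records support transformation tallies and transitional-sacrum
    prevalence, not count-variation statistics.
    """
    rows = list(csv.DictReader(_data_text("table2_transformations.csv").splitlines()))
    records: list[VertebralRecord] = []
    for row in rows:
        n = int(row["n"])
        modal = int(row["modal_count"])
        left = int(row["sacral_left"])
        right = int(row["sacral_right"])
        dist = {float(modal): n - left - right, modal + 0.5: left + right}
        records.extend(
            expand_distribution(
                row["species"],
                dist,
                zone="central",
                annotations={
                    "sacral_left": left,
                    "sacral_right": right,
                    "cervical_complete": int(row["cervical_complete"]),
                    "cervical_incomplete": int(row["cervical_incomplete"]),
                    "thoracic_incomplete": int(row["thoracic_incomplete"]),
                },
            )
        )
    return records


def load_table4_tables() -> Dict[str, np.ndarray]:
    """Per-species 2×2 contingency tables, rows (central, fringe) ×
    columns (modal, non-modal)."""
    rows = list(csv.DictReader(_data_text("table4_zone_counts.csv").splitlines()))
    return {
        row["species"]: np.array(
            [
                [int(row["central_modal"]), int(row["central_nonmodal"])],
                [int(row["fringe_modal"]), int(row["fringe_nonmodal"])],
            ]
        )
        for row in rows
    }


def load_tree():
    """The eight-species tree (approximate ultrametric branch lengths)."""
    from .trees import read_newick

    return read_newick(_data_text("triturus_tree_approximate.nwk"))


def table1_trait_vectors() -> Dict[str, Dict[str, float]]:
    """The four species-level traits (T_n, T_var, T_range, S_tr) keyed by
    species, computed from the central-population distributions."""
    records = load_table1_records()
    traits: Dict[str, Dict[str, float]] = {
        "T_n": {},
        "T_var": {},
        "T_range": {},
        "S_tr": {},
    }
    for sp in SPECIES_ORDER:
        s = summarize_species(records, sp, zone_filter="central")
        traits["T_n"][sp] = float(s.t_n)
        traits["T_var"][sp] = s.t_var
        traits["T_range"][sp] = float(s.t_range)
        traits["S_tr"][sp] = s.s_tr
    return traits
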