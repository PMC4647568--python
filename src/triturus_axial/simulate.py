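"""Synthetic data generators for the vertebral-variation analyses.

Two generators cover the two kinds of data the analyses consume:

* :func:`simulate_records` draws specimen-level vertebral records per
  species — complete thoracic counts scattered around a modal number, rare
  transitional sacral vertebrae (independent of the count, matching the
  observed lack of an S_tr–T_var association; an optional coupling knob
  simulates the alternative), and rare cervical transformations.

* :func:`simulate_bm` evolves a continuous trait by Brownian motion along a
  time-calibrated tree: each branch adds an independent N(0, σ²·length)
  increment.  This is the null model under which independent contrasts are
  standardized, so it doubles as the calibration generator for the
  comparative methods.

All randomness flows from a single root seed through per-species spawned
streams, so runs are reproducible and species blocks are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np

from .records import (
    THORACIC_MAX,
    THORACIC_MIN,
    VertebralRecord,
)
from .tables import SPECIES_ORDER, load_table1_records
from .records import summarize_species, thoracic_score
from .trees import PhyloTree, TreeNode


class SimulationError(ValueError):
    pass


@dataclass
class SpeciesSimSpec:
    """Generating distribution for one species' vertebral records.

    ``count_spread`` maps integer offsets from the modal count to
    probabilities; unassigned mass goes to offset 0 (the modal count).
    ``p_transitional`` is the probability of a transitional sacral vertebra,
    drawn independently of the count offset; ``transitional_coupling``
    multiplies it by (1 + coupling·|offset|) to simulate frequencies of
    incomplete transformations rising with count deviation.
    """

    species: str
    n: int
    modal_count: int
    count_spread: Dict[int, float] = field(default_factory=dict)
    p_transitional: float = 0.0
    p_cervical: float = 0.0
    zone: str = "central"
    transitional_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SimulationError(f"{self.species}: n must be positive")
        mass = sum(self.count_spread.values())
        if any(p < 0 for p in self.count_spread.values()) or mass > 1 + 1e-9:
            raise SimulationError(
                f"{self.species}: count_spread must be a sub-probability mass"
            )
        for p, name in [
            (self.p_transitional, "p_transitional"),
            (self.p_cervical, "p_cervical"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{self.species}: {name} outside [0,1]")


def simulate_records(
    specs: Sequence[SpeciesSimSpec], seed: int
) -> list[VertebralRecord]:
    """Draw specimen records for each species spec; seeded and reproducible."""
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    records: list[VertebralRecord] = []
    for spec, ss in zip(specs, streams):
        rng = np.random.default_rng(ss)
        offsets = sorted(spec.count_spread)
        probs = np.array([spec.count_spread[o] for o in offsets])
        rest = 1.0 - probs.sum()
        if rest > 1e-12:
            offsets = offsets + [0]
            probs = np.append(probs, rest)
        probs = probs / probs.sum()
        draw_offsets = rng.choice(offsets, size=spec.n, p=probs)
        u_tr = rng.random(spec.n)
        tr_type = rng.integers(0, 2, size=spec.n)
        tr_side = rng.integers(0, 2, size=spec.n)
        u_cerv = rng.random(spec.n)
        cerv_type = rng.integers(0, 2, size=spec.n)
        for i in range(spec.n):
            count = int(spec.modal_count + draw_offsets[i])
            count = min(max(count, THORACIC_MIN), THORACIC_MAX)
            p_tr = spec.p_transitional * (
                1.0 + spec.transitional_coupling * abs(int(draw_offsets[i]))
            )
            p_tr = min(p_tr, 1.0)
            if u_tr[i] < p_tr:
                sacral = (
                    "transitional_two_vertebra" if tr_type[i] else "transitional_single"
                )
                asym = "left" if tr_side[i] else "right"
            else:
                sacral, asym = "regular", "none"
            if u_cerv[i] < spec.p_cervical:
                cervical = (
                    "complete_to_thoracic" if cerv_type[i] else "incomplete_to_thoracic"
                )
            else:
                cervical = "regular"
            records.append(
                VertebralRecord(
                    specimen_id=f"sim-{spec.species}-{i + 1:04d}",
                    species=spec.species,
                    population_id=f"sim-{spec.species}",
                    zone=spec.zone,
                    cervical_state=cervical,
                    thoracic_complete=count,
                    sacral_state=sacral,
                    asymmetry=asym,
                )
            )
    return records


def table1_sim_specs() -> list[SpeciesSimSpec]:
    """Generating specs mirroring the eight central-population samples.

    Sample size and modal count are the printed ones; the count spread is
    the empirical offset distribution of the non-transitional specimens and
    ``p_transitional`` the printed per-species transitional percentage.
    """
    records = load_table1_records()
    specs = []
    for sp in SPECIES_ORDER:
        s = summarize_species(records, sp, zone_filter="central")
        sel = [r for r in records if r.species == sp]
        integral = [r for r in sel if thoracic_score(r) == int(thoracic_score(r))]
        spread: Dict[int, float] = {}
        for r in integral:
            off = r.thoracic_complete - s.t_n
            spread[off] = spread.get(off, 0.0) + 1.0 / len(integral)
        specs.append(
            SpeciesSimSpec(
                species=sp,
                n=s.n,
                modal_count=s.t_n,
                count_spread=spread,
                p_transitional=s.s_tr / 100.0,
                p_cervical=0.0,
                zone="central",
            )
        )
    return specs


def simulate_bm(
    tree: PhyloTree, sigma2: float, root_state: float, seed: int
) -> Dict[str, float]:
    """Brownian motion on the tree: tip values after N(0, σ²·length) branch
    increments from ``root_state`` at the root."""
    if sigma2 <= 0:
        raise SimulationError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    values: Dict[str, float] = {}

    def walk(node: TreeNode, state: float) -> None:
        if node.parent is not None:
            state += rng.normal(0.0, np.sqrt(sigma2 * (node.length or 0.0)))
        if node.is_tip:
            values[node.label] = state
        else:
            for c in node.children:
                walk(c, state)

    walk(tree.root, root_state)
    return values
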