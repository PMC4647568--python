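"""Specimen-level vertebral records and species-level meristic summaries.

A *Triturus* newt's vertebral formula is recorded as the counts of cervical
(always one, the atlas), thoracic (rib-bearing) and sacral vertebrae.  A
transitional sacral vertebra — thoracic rib on one side, sacral rib on the
other — marks an incomplete homeotic transformation and is scored as half a
thoracic vertebra, added to the count of complete thoracic vertebrae.

This module holds the record data model, CSV I/O, the half-score scoring
rule, and the per-species summary statistics:

``T_n``
    modal (most frequent) integer thoracic count,
``T_var``
    percent of specimens whose *complete* thoracic count differs from the
    modal number — specimens carrying a transitional sacral vertebra (half
    scores) are excluded from the numerator,
``T_range``
    span between the largest and smallest integer thoracic counts observed,
``S_tr``
    percent of specimens with a transitional sacral vertebra.
"""

from __future__ import annotations

import csv
import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

logger = logging.getLogger(__name__)

ZONES = ("central", "fringe")
CERVICAL_STATES = ("regular", "incomplete_to_thoracic", "complete_to_thoracic")
SACRAL_STATES = (
    "regular",
    "transitional_two_vertebra",
    "transitional_single",
    "thoracic_incomplete",
)
ASYMMETRY_STATES = ("none", "left", "right")

#: sacral states that constitute a transitional sacral vertebra (0.5 score)
TRANSITIONAL_SACRAL = frozenset({"transitional_two_vertebra", "transitional_single"})

THORACIC_MIN = 10
THORACIC_MAX = 20

CSV_FIELDS = (
    "specimen_id",
    "species",
    "population_id",
    "zone",
    "cervical_state",
    "thoracic_complete",
    "sacral_state",
    "asymmetry",
)


class RecordError(ValueError):
    """Base class for record-layer errors."""


class RecordFormatError(RecordError):
    """Malformed input file (bad header, unknown token, unparsable field)."""


class RecordValidationError(RecordError):
    """A parsed record violates a biological invariant."""


class EmptySelectionError(RecordError):
    """A species/zone selection matched no records."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def is_hybrid(species: str) -> bool:
    """Hybrid species tokens join the parental names with ``_x_``."""
    return "_x_" in species


@dataclass(frozen=True)
class VertebralRecord:
    """One specimen's regionalized vertebral counts plus transformation annotations.

    ``thoracic_complete`` counts fully rib-bearing (complete) thoracic
    vertebrae only; a transitional sacral vertebra is carried in
    ``sacral_state`` together with the side of the asymmetry.
    """

    specimen_id: str
    species: str
    population_id: str
    zone: str
    cervical_state: str = "regular"
    thoracic_complete: int = 13
    sacral_state: str = "regular"
    asymmetry: str = "none"

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise RecordValidationError(
                f"{self.specimen_id}: unknown zone {self.zone!r}"
            )
        if self.cervical_state not in CERVICAL_STATES:
            raise RecordValidationError(
                f"{self.specimen_id}: unknown cervical_state {self.cervical_state!r}"
            )
        if self.sacral_state not in SACRAL_STATES:
            raise RecordValidationError(
                f"{self.specimen_id}: unknown sacral_state {self.sacral_state!r}"
            )
        if self.asymmetry not in ASYMMETRY_STATES:
            raise RecordValidationError(
                f"{self.specimen_id}: unknown asymmetry {self.asymmetry!r}"
            )
        if not isinstance(self.thoracic_complete, int) or not (
            THORACIC_MIN <= self.thoracic_complete <= THORACIC_MAX
        ):
            raise RecordValidationError(
                f"{self.specimen_id}: thoracic_complete={self.thoracic_complete!r} "
                f"outside [{THORACIC_MIN}, {THORACIC_MAX}]"
            )
        transitional = self.sacral_state in TRANSITIONAL_SACRAL
        if transitional != (self.asymmetry != "none"):
            raise RecordValidationError(
                f"{self.specimen_id}: asymmetry must be left/right exactly when the "
                f"sacral vertebra is transitional (sacral_state={self.sacral_state!r}, "
                f"asymmetry={self.asymmetry!r})"
            )

    @property
    def is_transitional_sacral(self) -> bool:
        return self.sacral_state in TRANSITIONAL_SACRAL

    @property
    def has_transformation(self) -> bool:
        """Any non-regular state anywhere along the column."""
        return self.cervical_state != "regular" or self.sacral_state != "regular"


def thoracic_score(record: VertebralRecord) -> float:
    """Thoracic score: complete count, plus 0.5 for a transitional sacral vertebra.

    A one-sided thoracic change without any change of the sacral vertebra
    (``sacral_state == "thoracic_incomplete"``) does *not* add the half score.
    """
    if record.is_transitional_sacral:
        return record.thoracic_complete + 0.5
    return float(record.thoracic_complete)


# ---------------------------------------------------------------------------
# CSV I/O

def read_records(source: Union[str, Path, io.TextIOBase]) -> list[VertebralRecord]:
    """Read specimen records from the record CSV dialect.

    The dialect is UTF-8 with a fixed header row naming the eight fields in
    order; enum tokens are lower-case.  Raises :class:`RecordFormatError` for
    malformed rows (naming the 1-based data row) and
    :class:`RecordValidationError` for rows violating invariants (naming the
    specimen).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_records(fh)
    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise RecordFormatError("empty record file") from None
    if tuple(header) != CSV_FIELDS:
        raise RecordFormatError(
            f"bad header {header!r}; expected {','.join(CSV_FIELDS)}"
        )
    records: list[VertebralRecord] = []
    for i, row in enumerate(reader, start=1):
        if not row:
            continue
        if len(row) != len(CSV_FIELDS):
            raise RecordFormatError(f"row {i}: expected {len(CSV_FIELDS)} fields")
        fields = dict(zip(CSV_FIELDS, row))
        try:
            fields["thoracic_complete"] = int(fields["thoracic_complete"])
        except ValueError:
            raise RecordFormatError(
                f"row {i}: thoracic_complete={fields['thoracic_complete']!r} "
                "is not an integer"
            ) from None
        if fields["zone"] not in ZONES:
            raise RecordFormatError(f"row {i}: unknown zone {fields['zone']!r}")
        records.append(VertebralRecord(**fields))
    return records


def write_records(
    records: Iterable[VertebralRecord], dest: Union[str, Path, io.TextIOBase]
) -> None:
    """Write records in the canonical CSV dialect (``\\n`` line endings).

    ``read_records`` followed by ``write_records`` reproduces a canonical
    file byte for byte.
    """
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_records(records, fh)
        return
    writer = csv.writer(dest, lineterminator="\n")
    writer.writerow(CSV_FIELDS)
    for r in records:
        writer.writerow(
            [
                r.specimen_id,
                r.species,
                r.population_id,
                r.zone,
                r.cervical_state,
                r.thoracic_complete,
                r.sacral_state,
                r.asymmetry,
            ]
        )


# ---------------------------------------------------------------------------
# Species summaries

@dataclass
class SpeciesSummary:
    """Per-species distribution of thoracic scores and derived statistics.

    Percentages are stored unrounded; use :meth:`t_var_rounded` /
    :meth:`s_tr_rounded` (round-half-up to one decimal) for reporting.
    """

    species: str
    n: int
    score_distribution: dict[float, int] = field(default_factory=dict)
    t_n: int = 0
    t_var: float = 0.0
    t_range: int = 0
    s_tr: float = 0.0

    def t_var_rounded(self) -> float:
        return round_half_up(self.t_var, 1)

    def s_tr_rounded(self) -> float:
        return round_half_up(self.s_tr, 1)


def _select(
    records: Sequence[VertebralRecord], species: str, zone_filter: Optional[str]
) -> list[VertebralRecord]:
    sel = [r for r in records if r.species == species]
    if zone_filter is not None:
        if zone_filter not in ZONES:
            raise RecordFormatError(f"unknown zone filter {zone_filter!r}")
        sel = [r for r in sel if r.zone == zone_filter]
    return sel


def summarize_species(
    records: Sequence[VertebralRecord],
    species: str,
    zone_filter: Optional[str] = None,
) -> SpeciesSummary:
    """Summarize one species' thoracic-score distribution.

    The modal number ``T_n`` is taken over integer scores only (ties broken
    toward the smaller count, with a warning).  Half-score specimens — those
    with a transitional sacral vertebra — never enter the ``T_var``
    numerator: a specimen contributes to at most one of the ``T_var`` and
    ``S_tr`` numerators.  ``T_range`` is the span of the observed *complete*
    thoracic counts over all specimens (a 12.5-scored specimen contributes
    its 12 complete vertebrae), which reproduces every printed range.
    """
    sel = _select(records, species, zone_filter)
    if not sel:
        raise EmptySelectionError(
            f"no records for species {species!r}"
            + (f" in zone {zone_filter!r}" if zone_filter else "")
        )
    n = len(sel)
    scores = [thoracic_score(r) for r in sel]
    dist = Counter(scores)
    integer_counts = Counter(
        int(s) for s in scores if s == int(s)
    )
    if not integer_counts:
        raise RecordValidationError(
            f"{species}: no specimens with an integral thoracic score; "
            "modal number undefined"
        )
    max_count = max(integer_counts.values())
    modal_candidates = sorted(k for k, v in integer_counts.items() if v == max_count)
    t_n = modal_candidates[0]
    if len(modal_candidates) > 1:
        logger.warning(
            "%s: modal thoracic count tied among %s; using smallest (%d)",
            species,
            modal_candidates,
            t_n,
        )
    non_modal = sum(
        1
        for r in sel
        if not r.is_transitional_sacral and r.thoracic_complete != t_n
    )
    transitional = sum(1 for r in sel if r.is_transitional_sacral)
    return SpeciesSummary(
        species=species,
        n=n,
        score_distribution={float(s): int(c) for s, c in sorted(dist.items())},
        t_n=t_n,
        t_var=100.0 * non_modal / n,
        t_range=max(r.thoracic_complete for r in sel)
        - min(r.thoracic_complete for r in sel),
        s_tr=100.0 * transitional / n,
    )


@dataclass
class TransformationTally:
    """Counts of homeotic transformation categories in one species sample."""

    species: str
    n: int
    any_transformation: int
    cervical_complete: int
    cervical_incomplete: int
    sacral_left: int
    sacral_right: int
    thoracic_to_sacral_incomplete: int


def tally_transformations(
    records: Sequence[VertebralRecord], species: str
) -> TransformationTally:
    """Tally transformation categories, each specimen counted once per category.

    ``any_transformation`` counts specimens carrying any non-regular state.
    Left and right asymmetries of the transitional sacral vertebra are kept
    separate; the rarer one-sided thoracic-to-sacral change without a change
    of the sacral vertebra is its own category.
    """
    sel = [r for r in records if r.species == species]
    if not sel:
        raise EmptySelectionError(f"no records for species {species!r}")
    return TransformationTally(
        species=species,
        n=len(sel),
        any_transformation=sum(1 for r in sel if r.has_transformation),
        cervical_complete=sum(
            1 for r in sel if r.cervical_state == "complete_to_thoracic"
        ),
        cervical_incomplete=sum(
            1 for r in sel if r.cervical_state == "incomplete_to_thoracic"
        ),
        sacral_left=sum(
            1 for r in sel if r.is_transitional_sacral and r.asymmetry == "left"
        ),
        sacral_right=sum(
            1 for r in sel if r.is_transitional_sacral and r.asymmetry == "right"
        ),
        thoracic_to_sacral_incomplete=sum(
            1 for r in sel if r.sacral_state == "thoracic_incomplete"
        ),
    )


def transitional_prevalence(
    records: Sequence[VertebralRecord], exclude_hybrids: bool = True
) -> tuple[int, int, float]:
    """(count, n, percent) of specimens with a transitional sacral vertebra."""
    pool = [r for r in records if not (exclude_hybrids and is_hybrid(r.species))]
    if not pool:
        raise EmptySelectionError("no records after hybrid exclusion")
    k = sum(1 for r in pool if r.is_transitional_sacral)
    return k, len(pool), 100.0 * k / len(pool)


# ---------------------------------------------------------------------------
# Distribution expansion (printed-table rows -> record level)

def expand_distribution(
    species: str,
    distribution: Mapping[float, int],
    zone: str = "central",
    population_id: str = "pooled",
    annotations: Optional[Mapping[str, int]] = None,
) -> list[VertebralRecord]:
    """Expand a thoracic-score distribution into synthetic specimen records.

    ``distribution`` maps half-integral scores to specimen counts.  Records
    at half scores carry a transitional sacral vertebra; ``annotations`` may
    fix the category counts (``sacral_left``, ``sacral_right``,
    ``cervical_complete``, ``cervical_incomplete``, ``thoracic_incomplete``).
    Left/right counts must sum to the number of half-score specimens; when
    omitted, sides alternate deterministically starting left.  Cervical and
    incomplete thoracic annotations are assigned to integral-score specimens.
    Specimen ids are deterministic, so the expansion is reproducible and
    ``summarize_species`` applied to the output restores ``distribution``
    exactly.
    """
    ann = dict(annotations or {})
    known = {
        "sacral_left",
        "sacral_right",
        "cervical_complete",
        "cervical_incomplete",
        "thoracic_incomplete",
    }
    unknown = set(ann) - known
    if unknown:
        raise RecordFormatError(f"unknown annotation categories {sorted(unknown)}")
    if any(c < 0 for c in ann.values()) or any(
        c < 0 for c in distribution.values()
    ):
        raise RecordFormatError("negative counts")

    half_total = sum(c for s, c in distribution.items() if s != int(s))
    int_total = sum(c for s, c in distribution.items() if s == int(s))
    if "sacral_left" in ann or "sacral_right" in ann:
        left = ann.get("sacral_left", 0)
        right = ann.get("sacral_right", 0)
        if left + right != half_total:
            raise RecordFormatError(
                f"{species}: sacral_left+sacral_right={left + right} inconsistent "
                f"with {half_total} half-score specimens"
            )
    else:
        left = (half_total + 1) // 2
        right = half_total - left
    n_cerv = ann.get("cervical_complete", 0) + ann.get("cervical_incomplete", 0)
    n_thor = ann.get("thoracic_incomplete", 0)
    if n_cerv + n_thor > int_total:
        raise RecordFormatError(
            f"{species}: annotation totals exceed available specimens"
        )

    records: list[VertebralRecord] = []
    sides = ["left"] * left + ["right"] * right
    cervical_states = (
        ["complete_to_thoracic"] * ann.get("cervical_complete", 0)
        + ["incomplete_to_thoracic"] * ann.get("cervical_incomplete", 0)
    )
    thoracic_left = n_thor
    i = 0
    side_i = 0
    for score in sorted(distribution):
        count = distribution[score]
        is_half = score != int(score)
        for _ in range(count):
            i += 1
            if is_half:
                sacral = "transitional_single"
                asym = sides[side_i]
                side_i += 1
            elif thoracic_left > 0:
                sacral = "thoracic_incomplete"
                asym = "none"
                thoracic_left -= 1
            else:
                sacral = "regular"
                asym = "none"
            # keep categories disjoint so each specimen carries one annotation
            cervical = (
                cervical_states.pop()
                if (cervical_states and sacral == "regular")
                else "regular"
            )
            records.append(
                VertebralRecord(
                    specimen_id=f"{species}-{zone}-{i:04d}",
                    species=species,
                    population_id=population_id,
                    zone=zone,
                    cervical_state=cervical,
                    thoracic_complete=int(score),
                    sacral_state=sacral,
                    asymmetry=asym,
                )
            )
    if cervical_states:
        raise RecordFormatError(
            f"{species}: could not place all cervical annotations"
        )
    return records
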