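"""Orchestration: reproduce the full analysis from records plus a tree.

Stages mirror the results sections: per-species summaries (central
populations), transformation tallies and transitional-sacrum prevalence,
the four species-level rank correlations, central-vs-fringe and
hybrid-vs-parental G-tests, and the phylogenetic comparative battery
(tip-permutation signal tests and contrast regressions).  Hybrid records
(species tokens containing ``_x_``) are excluded from species-level stages
unless a stage asks for them.  Every stage is seeded and logged; re-running
with the same inputs and seed reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .records import (
    EmptySelectionError,
    SpeciesSummary,
    TransformationTally,
    VertebralRecord,
    is_hybrid,
    round_half_up,
    summarize_species,
    tally_transformations,
    thoracic_score,
    transitional_prevalence,
)
from .stats import GTestResult, SpearmanResult, g_test, spearman
from .phylo import (
    ContrastRegressionResult,
    PermutationResult,
    PhyloError,
    contrast_regression,
    pic,
    signal_permutation_test,
)
from .trees import PhyloTree

logger = logging.getLogger(__name__)

TRAITS = ("T_n", "T_var", "T_range", "S_tr")

#: the four correlations examined at the species level: (x, y)
CORRELATION_PAIRS = (
    ("T_n", "T_var"),
    ("T_n", "T_range"),
    ("S_tr", "T_var"),
    ("S_tr", "T_range"),
)

#: the four contrast regressions: (y on x)
REGRESSION_PAIRS = (
    ("T_var", "T_n"),
    ("T_range", "T_n"),
    ("T_var", "S_tr"),
    ("T_range", "S_tr"),
)


def _digest(records: Sequence[VertebralRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(repr(r).encode())
    return h.hexdigest()[:16]


@dataclass
class AnalysisReport:
    summaries: Dict[str, SpeciesSummary] = field(default_factory=dict)
    tallies: Dict[str, TransformationTally] = field(default_factory=dict)
    prevalence: Optional[tuple] = None  # (count, n, percent), hybrids excluded
    correlations: Dict[str, SpearmanResult] = field(default_factory=dict)
    group_tests: Dict[str, GTestResult] = field(default_factory=dict)
    group_tables: Dict[str, np.ndarray] = field(default_factory=dict)
    signal: Dict[str, PermutationResult] = field(default_factory=dict)
    regressions: Dict[str, ContrastRegressionResult] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)


def species_in_order(records: Sequence[VertebralRecord]) -> list[str]:
    seen: list[str] = []
    for r in records:
        if r.species not in seen and not is_hybrid(r.species):
            seen.append(r.species)
    return seen


def run_summaries(
    records: Sequence[VertebralRecord],
    zone_filter: Optional[str] = "central",
    include_hybrids: bool = False,
) -> Dict[str, SpeciesSummary]:
    """Per-species summaries; species with an empty zone selection are
    omitted with a warning; hybrids are excluded unless requested."""
    out: Dict[str, SpeciesSummary] = {}
    names = species_in_order(records)
    if include_hybrids:
        names += [
            s
            for s in dict.fromkeys(r.species for r in records)
            if is_hybrid(s)
        ]
    for sp in names:
        try:
            out[sp] = summarize_species(records, sp, zone_filter=zone_filter)
        except EmptySelectionError:
            logger.warning(
                "species %s has no records in zone %r; omitted", sp, zone_filter
            )
    return out


def run_tallies(
    records: Sequence[VertebralRecord],
) -> tuple[Dict[str, TransformationTally], tuple]:
    """Transformation tallies per species plus overall transitional-sacrum
    prevalence (hybrids excluded from both)."""
    tallies = {
        sp: tally_transformations(records, sp) for sp in species_in_order(records)
    }
    return tallies, transitional_prevalence(records, exclude_hybrids=True)


def run_correlations(
    summaries: Mapping[str, SpeciesSummary],
    permutations: Optional[int] = None,
    seed: Optional[int] = None,
) -> Dict[str, SpearmanResult]:
    """The four species-level Spearman correlations among T_n, T_var,
    T_range and S_tr (keys like ``"T_n~T_var"``)."""
    species = list(summaries)
    vectors = {
        "T_n": [float(summaries[s].t_n) for s in species],
        "T_var": [summaries[s].t_var for s in species],
        "T_range": [float(summaries[s].t_range) for s in species],
        "S_tr": [summaries[s].s_tr for s in species],
    }
    out: Dict[str, SpearmanResult] = {}
    for x, y in CORRELATION_PAIRS:
        out[f"{x}~{y}"] = spearman(
            vectors[x], vectors[y], permutations=permutations, seed=seed
        )
    return out


def hybrid_intermediate_fraction(
    records: Sequence[VertebralRecord],
    hybrid_species: str,
    parent_modals: tuple[int, int],
) -> tuple[int, int, float]:
    """(count, n, percent) of hybrids with a thoracic score strictly between
    the parental modal numbers."""
    lo, hi = sorted(parent_modals)
    sel = [r for r in records if r.species == hybrid_species]
    if not sel:
        raise EmptySelectionError(f"no records for {hybrid_species!r}")
    k = sum(1 for r in sel if lo < thoracic_score(r) < hi)
    return k, len(sel), 100.0 * k / len(sel)


def zone_tables_from_records(
    records: Sequence[VertebralRecord],
) -> Dict[str, np.ndarray]:
    """Per-species 2×2 tables (central, fringe) × (modal, non-modal).

    The modal number is taken over the pooled integer scores of both zones.
    Species present in only one zone are skipped with a warning; specimens
    with a transitional sacral vertebra count as non-modal only through
    their complete count, consistent with the summary statistics.
    """
    tables: Dict[str, np.ndarray] = {}
    for sp in species_in_order(records):
        sel = [r for r in records if r.species == sp]
        zones = {r.zone for r in sel}
        if zones != {"central", "fringe"}:
            logger.warning("species %s present in one zone only; skipped", sp)
            continue
        pooled = summarize_species(records, sp, zone_filter=None)
        modal = pooled.t_n
        table = np.zeros((2, 2), dtype=int)
        for r in sel:
            i = 0 if r.zone == "central" else 1
            j = 0 if r.thoracic_complete == modal and not r.is_transitional_sacral else 1
            table[i, j] += 1
        tables[sp] = table
    return tables


def run_group_tests(
    records: Optional[Sequence[VertebralRecord]] = None,
    zone_tables: Optional[Mapping[str, np.ndarray]] = None,
    hybrid_species: str = "cristatus_x_marmoratus",
    williams: bool = False,
) -> tuple[Dict[str, GTestResult], Dict[str, np.ndarray]]:
    """Central-vs-fringe G-tests per species (plus pooled) and, when hybrid
    records are present, the hybrid-vs-parental transitional-sacrum test.

    ``zone_tables`` may supply the 2×2 tables directly (e.g. from a printed
    table); otherwise they are built from the records.
    """
    tables: Dict[str, np.ndarray] = {}
    if zone_tables is not None:
        tables.update({k: np.asarray(v) for k, v in zone_tables.items()})
    elif records is not None:
        tables.update(zone_tables_from_records(records))
    results: Dict[str, GTestResult] = {}
    for sp, table in tables.items():
        results[f"zone:{sp}"] = g_test(table, williams=williams)
    if tables:
        pooled = np.sum(list(tables.values()), axis=0)
        tables["pooled"] = pooled
        results["zone:pooled"] = g_test(pooled, williams=williams)

    if records is not None and any(r.species == hybrid_species for r in records):
        parents = hybrid_species.split("_x_")
        hyb = [r for r in records if r.species == hybrid_species]
        par = [r for r in records if r.species in parents]
        table = np.array(
            [
                [
                    sum(1 for r in hyb if r.is_transitional_sacral),
                    sum(1 for r in hyb if not r.is_transitional_sacral),
                ],
                [
                    sum(1 for r in par if r.is_transitional_sacral),
                    sum(1 for r in par if not r.is_transitional_sacral),
                ],
            ]
        )
        tables["hybrid_vs_parents"] = table
        results["hybrid_vs_parents"] = g_test(table, williams=williams)
    return results, tables


def run_phylo(
    summaries: Mapping[str, SpeciesSummary],
    tree: PhyloTree,
    iterations: int = 10_000,
    seed: int = 0,
    weighted: bool = False,
) -> tuple[Dict[str, PermutationResult], Dict[str, ContrastRegressionResult]]:
    """Signal tests for each trait and the four contrast regressions."""
    vectors: Dict[str, Dict[str, float]] = {t: {} for t in TRAITS}
    for sp, s in summaries.items():
        vectors["T_n"][sp] = float(s.t_n)
        vectors["T_var"][sp] = s.t_var
        vectors["T_range"][sp] = float(s.t_range)
        vectors["S_tr"][sp] = s.s_tr
    signal = {}
    for i, trait in enumerate(TRAITS):
        signal[trait] = signal_permutation_test(
            tree, vectors[trait], iterations=iterations, seed=seed + i,
            weighted=weighted,
        )
        logger.info(
            "signal %s: observed=%.4g p=%.4g seed=%d",
            trait, signal[trait].statistic_observed, signal[trait].p, seed + i,
        )
    contrasts = {t: pic(tree, vectors[t]) for t in TRAITS}
    regressions = {}
    for y, x in REGRESSION_PAIRS:
        try:
            regressions[f"{y}~{x}"] = contrast_regression(
                contrasts[x], contrasts[y]
            )
        except PhyloError as exc:  # e.g. constant predictor trait
            logger.warning("regression %s~%s skipped: %s", y, x, exc)
    return signal, regressions


def run_report(
    records: Sequence[VertebralRecord],
    tree: Optional[PhyloTree] = None,
    zone_filter: Optional[str] = "central",
    iterations: int = 10_000,
    seed: int = 0,
    williams: bool = False,
) -> AnalysisReport:
    """Run every stage and assemble a traceable report."""
    report = AnalysisReport()
    report.metadata = {
        "version": __version__,
        "seed": seed,
        "iterations": iterations,
        "zone_filter": zone_filter,
        "n_records": len(records),
        "records_digest": _digest(records),
    }
    report.summaries = run_summaries(records, zone_filter=zone_filter)
    report.tallies, report.prevalence = run_tallies(records)
    if len(report.summaries) >= 3:
        report.correlations = run_correlations(report.summaries)
    report.group_tests, report.group_tables = run_group_tests(records, williams=williams)
    if tree is not None:
        usable = {
            sp: s for sp, s in report.summaries.items()
            if sp in set(tree.tip_labels())
        }
        if set(usable) == set(tree.tip_labels()):
            report.signal, report.regressions = run_phylo(
                usable, tree, iterations=iterations, seed=seed
            )
        else:
            logger.warning("summaries do not cover all tree tips; phylo skipped")
    return report


def render_report(report: AnalysisReport) -> str:
    """Plain-text rendering with percentages rounded half-up to 1 decimal."""
    lines = ["# Vertebral-formula analysis report", ""]
    meta = report.metadata
    lines.append(
        f"records={meta.get('n_records')} digest={meta.get('records_digest')} "
        f"seed={meta.get('seed')} version={meta.get('version')}"
    )
    lines.append("")
    lines.append("## Species summaries (zone filter: %s)" % meta.get("zone_filter"))
    lines.append("species\tn\tT_n\tT_range\tS_tr%\tT_var%")
    for sp, s in report.summaries.items():
        lines.append(
            f"{sp}\t{s.n}\t{s.t_n}\t{s.t_range}"
            f"\t{s.s_tr_rounded()}\t{s.t_var_rounded()}"
        )
    if report.prevalence:
        k, n, pct = report.prevalence
        lines.append("")
        lines.append(
            f"Transitional sacrum (hybrids excluded): {k}/{n} "
            f"({round_half_up(pct, 1)}%)"
        )
    if report.correlations:
        lines.append("")
        lines.append("## Spearman correlations (species level)")
        for name, res in report.correlations.items():
            lines.append(
                f"{name}: r_s={round_half_up(res.r_s, 2)} n={res.n} "
                f"p_t={res.p_t:.3f}"
            )
    if report.group_tests:
        lines.append("")
        lines.append("## G-tests of independence")
        for name, res in report.group_tests.items():
            lines.append(
                f"{name}: G={res.G:.2f} df={res.df} p={res.p:.4f}"
                + (" (Williams)" if res.williams_corrected else "")
            )
    if report.signal:
        lines.append("")
        lines.append("## Phylogenetic signal (tip permutation)")
        for trait, res in report.signal.items():
            lines.append(
                f"{trait}: observed={res.statistic_observed:.4f} "
                f"p={res.p:.4f} iterations={res.iterations} seed={res.seed}"
            )
    if report.regressions:
        lines.append("")
        lines.append("## Contrast regressions (through origin)")
        for name, res in report.regressions.items():
            lines.append(
                f"{name}: slope={res.slope:.4f} t={res.t:.3f} "
                f"df={res.df} p={res.p:.4f}"
            )
    return "\n".join(lines) + "\n"
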