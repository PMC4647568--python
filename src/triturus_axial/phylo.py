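"""Phylogenetic comparative methods for species-level traits.

Three procedures, all assuming a rooted binary tree with branch lengths:

* **Independent contrasts** (Felsenstein's pruning): standardized
  differences between sister lineages that are mutually independent with
  unit variance when the trait evolves by Brownian motion; cross-species
  relationships are then tested by regression *through the origin* on the
  standardized contrasts.

* **Squared-change parsimony**: ancestral states minimizing the sum of
  squared changes along branches.  With unit branch weights (the default)
  every branch contributes (Δstate)² regardless of its length; a
  branch-length-weighted variant divides each squared change by the branch
  length.  The minimum is the phylogenetic-signal statistic.

* **Tip-permutation signal test**: the trait values are shuffled across the
  tips; phylogenetic signal is declared when the observed minimal squared
  change is small relative to the permutation null (lower-tail test,
  add-one p-value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import stats as _sps

from .trees import PhyloTree, TreeNode, TreeError

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    pass


def _check_traits(tree: PhyloTree, traits: Mapping[str, float]) -> None:
    tips = set(tree.tip_labels())
    keys = set(traits)
    if tips != keys:
        missing = sorted(tips - keys)
        extra = sorted(keys - tips)
        raise PhyloError(
            f"trait keys must match tree tips exactly "
            f"(missing {missing}, extra {extra})"
        )


# ---------------------------------------------------------------------------
# Independent contrasts

@dataclass
class ContrastSet:
    """Standardized independent contrasts, one per internal node (postorder)."""

    node_ids: list
    raw: np.ndarray
    variance: np.ndarray
    standardized: np.ndarray

    def __len__(self) -> int:
        return len(self.raw)


def pic(tree: PhyloTree, traits: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's independent contrasts by post-order pruning.

    At each internal node with child values x1, x2 on working branch lengths
    v1, v2: the raw contrast is x1 − x2 with expected variance v1 + v2, the
    node value is the variance-weighted average, and the parent branch is
    lengthened by v1·v2/(v1 + v2).  Returns tips − 1 contrasts.

    Zero-length branches (from polytomy resolution) are replaced by 1e-8 of
    tree depth, with a warning.
    """
    _check_traits(tree, traits)
    if not tree.is_binary():
        raise PhyloError("tree must be binary for independent contrasts")
    eps = 1e-8 * tree.depth()
    zero_seen = False

    node_ids: list = []  # canonical subtree signatures, so sets from
    raw: list[float] = []  # different trees can never be mixed silently
    var: list[float] = []

    def length_of(node: TreeNode) -> float:
        nonlocal zero_seen
        v = node.length if node.length is not None else 0.0
        if v == 0.0 and node.parent is not None:
            zero_seen = True
            v = eps
        return v

    def prune(node: TreeNode) -> Tuple[float, float, tuple]:
        """Return (value, working branch length, tip signature)."""
        if node.is_tip:
            return traits[node.label], length_of(node), (node.label,)
        (x1, v1, s1), (x2, v2, s2) = (prune(c) for c in node.children)
        node_ids.append(tuple(sorted(s1 + s2)))
        raw.append(x1 - x2)
        var.append(v1 + v2)
        value = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        return value, length_of(node) + v1 * v2 / (v1 + v2), s1 + s2

    prune(tree.root)
    if zero_seen:
        logger.warning(
            "zero-length branches replaced by %.3g for contrast variances", eps
        )
    raw_a = np.array(raw)
    var_a = np.array(var)
    return ContrastSet(
        node_ids=node_ids,
        raw=raw_a,
        variance=var_a,
        standardized=raw_a / np.sqrt(var_a),
    )


@dataclass
class ContrastRegressionResult:
    slope: float
    t: float
    p: float
    df: int


def contrast_regression(
    cx: ContrastSet, cy: ContrastSet
) -> ContrastRegressionResult:
    """Through-origin regression of y-contrasts on x-contrasts.

    Contrast signs are arbitrary, so x-contrasts are positivized with the
    paired y-contrasts flipped in tandem (the through-origin fit is
    invariant to these joint flips).  slope = Σcx·cy / Σcx²; the t statistic
    uses the residual variance on k − 1 degrees of freedom.
    """
    if cx.node_ids != cy.node_ids:
        raise PhyloError("contrast sets come from different trees/node orders")
    x = cx.standardized.copy()
    y = cy.standardized.copy()
    k = x.size
    if k < 2:
        raise PhyloError("need at least 2 contrasts")
    flip = x < 0
    x[flip] *= -1
    y[flip] *= -1
    sxx = float(x @ x)
    if sxx == 0:
        raise PhyloError("x contrasts are all zero: slope undefined")
    sxy = float(x @ y)
    syy = float(y @ y)
    beta = sxy / sxx
    s2 = max(syy - beta * sxy, 0.0) / (k - 1)
    if s2 == 0.0:
        t = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    else:
        t = beta / np.sqrt(s2 / sxx)
        p = float(2.0 * _sps.t.sf(abs(t), k - 1))
    return ContrastRegressionResult(slope=beta, t=float(t), p=p, df=k - 1)


# ---------------------------------------------------------------------------
# Squared-change parsimony

class SquaredChangeSolver:
    """Minimal sum of squared changes over branches, tips held fixed.

    The objective Σ_e w_e (x_parent − x_child)² is a strictly convex
    quadratic in the internal states, minimized by solving the graph
    Laplacian system; the minimum itself is the Schur-complement quadratic
    form in the tip values, which this class precomputes so that many
    permutations of the same tip values can be evaluated cheaply.

    ``weighted=False`` (default) uses unit weights; ``weighted=True``
    weights each branch by 1/length.
    """

    def __init__(self, tree: PhyloTree, weighted: bool = False) -> None:
        nodes = list(tree.postorder())
        self.tip_labels = [n.label for n in nodes if n.is_tip]
        tips = [n for n in nodes if n.is_tip]
        internals = [n for n in nodes if not n.is_tip]
        if not internals:
            raise PhyloError("tree has no internal nodes")
        t_index = {id(n): i for i, n in enumerate(tips)}
        i_index = {id(n): i for i, n in enumerate(internals)}
        nt, ni = len(tips), len(internals)
        ltt = np.zeros((nt, nt))
        lii = np.zeros((ni, ni))
        lit = np.zeros((ni, nt))
        eps = 1e-8 * max(tree.depth(), 1.0)
        for node in nodes:
            if node.parent is None:
                continue
            if weighted:
                length = node.length if node.length else eps
                w = 1.0 / length
            else:
                w = 1.0
            p = node.parent
            pi = i_index[id(p)]  # parents are always internal
            lii[pi, pi] += w
            if node.is_tip:
                ci = t_index[id(node)]
                ltt[ci, ci] += w
                lit[pi, ci] -= w
            else:
                ci = i_index[id(node)]
                lii[ci, ci] += w
                lii[pi, ci] -= w
                lii[ci, pi] -= w
        self._neg_lii_inv_lit = -np.linalg.solve(lii, lit)
        self._schur = ltt - lit.T @ (-self._neg_lii_inv_lit)
        self._internal_nodes = internals

    def tip_vector(self, traits: Mapping[str, float]) -> np.ndarray:
        return np.array([traits[lbl] for lbl in self.tip_labels])

    def statistic(self, tip_values: np.ndarray) -> float:
        return float(tip_values @ self._schur @ tip_values)

    def statistics(self, tip_matrix: np.ndarray) -> np.ndarray:
        """Row-wise statistic for a (m × tips) matrix of tip values."""
        return np.einsum("ij,jk,ik->i", tip_matrix, self._schur, tip_matrix)

    def ancestral_states(self, tip_values: np.ndarray) -> np.ndarray:
        return self._neg_lii_inv_lit @ tip_values


def squared_change_statistic(
    tree: PhyloTree, traits: Mapping[str, float], weighted: bool = False
) -> Tuple[float, Dict[str, float]]:
    """Minimal sum of squared changes and the minimizing ancestral states.

    Returns ``(statistic, states)`` where ``states`` maps internal node ids
    (postorder position, or label when present) to the optimal state.
    """
    _check_traits(tree, traits)
    solver = SquaredChangeSolver(tree, weighted=weighted)
    x = solver.tip_vector(traits)
    stat = solver.statistic(x)
    states = solver.ancestral_states(x)
    names = [
        n.label or f"node{i + 1}" for i, n in enumerate(solver._internal_nodes)
    ]
    return max(stat, 0.0), dict(zip(names, states.tolist()))


# ---------------------------------------------------------------------------
# Tip-permutation phylogenetic-signal test

@dataclass
class PermutationResult:
    statistic_observed: float
    null_statistics: np.ndarray = field(repr=False)
    p: float = 1.0
    iterations: int = 0
    seed: int = 0


def signal_permutation_test(
    tree: PhyloTree,
    traits: Mapping[str, float],
    iterations: int = 10_000,
    seed: int = 0,
    weighted: bool = False,
) -> PermutationResult:
    """Phylogenetic-signal test by random tip permutation.

    The statistic is the minimal total squared change; signal means the
    observed statistic is *small* compared to values under random shuffles
    of the trait over the tips, so p = (#{null ≤ observed} + 1)/(m + 1).
    Fixed seeds give bit-reproducible results.
    """
    _check_traits(tree, traits)
    if iterations < 1:
        raise PhyloError("iterations must be >= 1")
    solver = SquaredChangeSolver(tree, weighted=weighted)
    x = solver.tip_vector(traits)
    observed = solver.statistic(x)
    if np.ptp(x) == 0:
        warnings.warn(
            "constant trait: all permutations identical, p = 1", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    perms = np.empty((iterations, x.size))
    for i in range(iterations):
        perms[i] = rng.permutation(x)
    null = solver.statistics(perms)
    b = int(np.sum(null <= observed + 1e-12))
    return PermutationResult(
        statistic_observed=observed,
        null_statistics=null,
        p=(b + 1) / (iterations + 1),
        iterations=iterations,
        seed=seed,
    )
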