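"""Rank correlation and log-likelihood-ratio (G) independence tests.

Spearman's coefficient is computed as the Pearson correlation of midranks,
which handles the heavy ties of meristic data correctly; its p-value comes
from the usual t approximation on n − 2 degrees of freedom, with an optional
seeded permutation p-value.  The G-test is the likelihood-ratio alternative
to Pearson's chi-square, G = 2 Σ O ln(O/E), optionally with the Williams
small-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps


class StatsError(ValueError):
    pass


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks with tied values sharing the mean of the positions they span."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise StatsError("empty input")
    if not np.all(np.isfinite(arr)):
        raise StatsError("non-finite values cannot be ranked")
    return _sps.rankdata(arr, method="average")


@dataclass
class SpearmanResult:
    r_s: float
    n: int
    p_t: float
    p_perm: Optional[float] = None
    seed: Optional[int] = None


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    return float(cx @ cy / np.sqrt((cx @ cx) * (cy @ cy)))


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    permutations: Optional[int] = None,
    seed: Optional[int] = None,
) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation.

    ``p_t`` is two-sided from t = r√((n−2)/(1−r²)) on n − 2 df.  If
    ``permutations`` is given, ``p_perm`` = (b + 1)/(m + 1) where b counts
    permutations of y with |r| at least the observed |r| (add-one rule, so
    the estimate is never zero).
    """
    rx = midranks(x)
    ry = midranks(y)
    if rx.size != ry.size:
        raise StatsError("x and y must have equal length")
    n = rx.size
    if n < 3:
        raise StatsError("need at least 3 observations")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise StatsError("zero rank variance: correlation undefined")
    r = _rank_corr(rx, ry)
    if abs(r) >= 1.0:
        p_t = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p_t = float(2.0 * _sps.t.sf(abs(t), n - 2))
    p_perm = None
    if permutations is not None:
        if permutations < 1:
            raise StatsError("permutations must be >= 1")
        rng = np.random.default_rng(seed)
        b = 0
        target = abs(r) - 1e-12  # guard against float noise on exact ties
        for _ in range(permutations):
            rp = rng.permutation(ry)
            if abs(_rank_corr(rx, rp)) >= target:
                b += 1
        p_perm = (b + 1) / (permutations + 1)
    return SpearmanResult(r_s=r, n=int(n), p_t=p_t, p_perm=p_perm, seed=seed)


@dataclass
class GTestResult:
    G: float
    df: int
    p: float
    williams_corrected: bool


def g_test(table, williams: bool = False) -> GTestResult:
    """G-test of independence on an r×c table of counts.

    Cells with O = 0 contribute nothing.  With ``williams=True`` the
    statistic is divided by Williams' q = 1 + (N·Σ1/Rᵢ − 1)(N·Σ1/Cⱼ − 1) /
    (6·N·df) before the chi-square tail is taken.
    """
    obs = np.asarray(table)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise StatsError("table must be at least 2x2")
    if not np.issubdtype(obs.dtype, np.integer):
        if not np.allclose(obs, np.round(obs)):
            raise StatsError("counts must be integers")
        obs = np.round(obs).astype(np.int64)
    if np.any(obs < 0):
        raise StatsError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise StatsError("zero row or column margin")
    n = obs.sum()
    expected = np.outer(rows, cols) / n
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if williams:
        q = 1.0 + (
            (n * np.sum(1.0 / rows) - 1.0) * (n * np.sum(1.0 / cols) - 1.0)
        ) / (6.0 * n * df)
        g /= q
    g = max(g, 0.0)
    return GTestResult(
        G=g, df=int(df), p=float(_sps.chi2.sf(g, df)), williams_corrected=williams
    )
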