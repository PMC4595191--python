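"""Pairwise checkerboard (C-score) co-occurrence tests on incidence data.

The statistic for a pair of groups with occupied-unit counts ``r_i``,
``r_j`` and ``S`` shared units is the normalised checkerboard score
``(r_i - S) (r_j - S) / (r_i r_j)``: 0 for identical occupancy, 1 for
fully disjoint occupancy.  Significance comes from permutation null
models of the incidence matrix.

Null models
-----------
``fixed_fixed``
    Sequential-swap Markov chain preserving both per-group occupancy and
    per-unit richness (the conservative default for incidence data).
``fixed_rows``
    Per-group occupancy preserved, occupied units drawn uniformly.
``equiprobable_rows``
    Independent Bernoulli fill per group at the observed fill rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from tickstats.survey import PresenceMatrix

NULL_METHODS = ("fixed_fixed", "fixed_rows", "equiprobable_rows")


class DegenerateNullWarning(UserWarning):
    """The null model cannot move: every permutation equals the data."""


@dataclass
class CScoreTest:
    level: str
    group_pair: tuple[str, str]
    c_score: float
    n_permutations: int
    null_scores: np.ndarray
    p_value: float
    direction: str  # segregated | aggregated | none
    method: str
    seed: int | None


def c_score(matrix: PresenceMatrix, g_i, g_j) -> float:
    """Normalised checkerboard score for one group pair.

    Undefined (raises) when either group occupies no unit.
    """
    a = matrix.cells[matrix.group_index(g_i)]
    b = matrix.cells[matrix.group_index(g_j)]
    return _c_score_rows(a, b)


def _c_score_rows(a: np.ndarray, b: np.ndarray) -> float:
    r_i = int(a.sum())
    r_j = int(b.sum())
    if r_i == 0 or r_j == 0:
        raise ValueError("C-score undefined: a group occupies no unit")
    s = int((a & b).sum())
    return (r_i - s) * (r_j - s) / (r_i * r_j)


def _swap_chain(cells: np.ndarray, n_attempts: int,
                rng: np.random.Generator) -> int:
    """Run checkerboard swaps in place; returns the number accepted."""
    n_rows, n_cols = cells.shape
    if n_rows < 2 or n_cols < 2:
        return 0
    rows = rng.integers(0, n_rows, size=(n_attempts, 2))
    cols = rng.integers(0, n_cols, size=(n_attempts, 2))
    accepted = 0
    for (r1, r2), (c1, c2) in zip(rows, cols):
        if r1 == r2 or c1 == c2:
            continue
        a, b = cells[r1, c1], cells[r1, c2]
        c, d = cells[r2, c1], cells[r2, c2]
        # swap only 2x2 checkerboards: keeps both margins fixed
        if a == d and b == c and a != b:
            cells[r1, c1], cells[r1, c2] = b, a
            cells[r2, c1], cells[r2, c2] = d, c
            accepted += 1
    return accepted


def permutation_null(matrix: PresenceMatrix, method: str = "fixed_fixed",
                     n: int = 5000, seed: int | None = None,
                     burnin: int = 5000, thin: int = 100) -> np.ndarray:
    """Draw ``n`` null incidence matrices, shape ``(n, n_groups, n_units)``.

    ``burnin``/``thin`` are swap *attempts* for the ``fixed_fixed`` chain
    and ignored by the independent-draw methods.  The sequence is
    reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method not in NULL_METHODS:
        raise ValueError(f"unknown null method {method!r}")
    rng = np.random.default_rng(seed)
    cells = matrix.cells.astype(np.int8)
    n_groups, n_units = cells.shape

    if method == "fixed_rows":
        draws = np.zeros((n, n_groups, n_units), dtype=np.int8)
        for g in range(n_groups):
            r = int(cells[g].sum())
            # uniform r-subsets via partial argsort of random keys
            keys = rng.random((n, n_units))
            idx = np.argpartition(keys, r - 1, axis=1)[:, :r] if r else \
                np.empty((n, 0), dtype=int)
            np.put_along_axis(draws[:, g, :], idx, 1, axis=1)
        return draws

    if method == "equiprobable_rows":
        fill = cells.mean(axis=1)
        return (rng.random((n, n_groups, n_units))
                < fill[None, :, None]).astype(np.int8)

    # fixed_fixed sequential swap
    work = cells.copy()
    accepted = _swap_chain(work, burnin, rng)
    draws = np.empty((n, n_groups, n_units), dtype=np.int8)
    for k in range(n):
        accepted += _swap_chain(work, thin, rng)
        draws[k] = work
    if accepted == 0:
        warnings.warn(
            "no swappable 2x2 submatrix: fixed_fixed null is degenerate",
            DegenerateNullWarning, stacklevel=2)
    return draws


def _null_c_scores(draws: np.ndarray, i: int, j: int) -> np.ndarray:
    a = draws[:, i, :]
    b = draws[:, j, :]
    r_i = a.sum(axis=1).astype(float)
    r_j = b.sum(axis=1).astype(float)
    s = (a & b).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (r_i - s) * (r_j - s) / (r_i * r_j)
    return np.where((r_i > 0) & (r_j > 0), out, np.nan)


def two_sided_permutation_p(observed: float,
                            null_scores: np.ndarray) -> float:
    """Two-sided Monte-Carlo p with add-one correction, capped at 1.

    Ties count toward both tails (conservative); the returned p is always
    strictly positive.
    """
    null_scores = null_scores[~np.isnan(null_scores)]
    n = len(null_scores)
    hi = (int((null_scores >= observed - 1e-12).sum()) + 1) / (n + 1)
    lo = (int((null_scores <= observed + 1e-12).sum()) + 1) / (n + 1)
    return min(1.0, 2.0 * min(hi, lo))


def c_score_test(matrix: PresenceMatrix, g_i, g_j,
                 method: str = "fixed_fixed", n: int = 5000,
                 seed: int | None = None, burnin: int = 5000,
                 thin: int = 100) -> CScoreTest:
    """Permutation test of the pairwise C-score against a null model.

    Direction is ``segregated`` when the observed score exceeds the null
    mean, ``aggregated`` when below, ``none`` for a degenerate null.
    """
    observed = c_score(matrix, g_i, g_j)
    draws = permutation_null(matrix, method=method, n=n, seed=seed,
                             burnin=burnin, thin=thin)
    i = matrix.group_index(g_i)
    j = matrix.group_index(g_j)
    null_scores = _null_c_scores(draws, i, j)
    finite = null_scores[~np.isnan(null_scores)]
    if len(finite) == 0 or np.allclose(finite, observed):
        warnings.warn("degenerate null distribution; p reported as 1",
                      DegenerateNullWarning, stacklevel=2)
        p, direction = 1.0, "none"
    else:
        p = two_sided_permutation_p(observed, null_scores)
        mean_null = float(finite.mean())
        if observed > mean_null:
            direction = "segregated"
        elif observed < mean_null:
            direction = "aggregated"
        else:
            direction = "none"
    pair = (matrix.group_labels[i], matrix.group_labels[j])
    return CScoreTest(level=matrix.level, group_pair=pair, c_score=observed,
                      n_permutations=n, null_scores=null_scores, p_value=p,
                      direction=direction, method=method, seed=seed)
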