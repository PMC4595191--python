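"""Sexual-isolation indices on 2x2 mating tables with bootstrap inference.

Implements the pair sexual isolation index (PSI, observed over expected
pairs under random mating among mated individuals), the pair total index
(PTI, expectations from all sampled individuals), the joint isolation
index (I_PSI, in [-1, 1]) and the hetero-specific asymmetry ratio
(IA_PSI), together with bootstrap standard errors and two-tail deviation
probabilities.

Reporting convention: summary estimates follow the historical mate-choice
software in quoting the *bootstrap mean* of each index alongside its
bootstrap standard error; the plug-in (point) estimates are always carried
too.  For ratio-type indices the two differ slightly (Jensen bias), which
matters when comparing against published 2-decimal values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from tickstats.survey import MatingTable

_NULL_VALUE = {"psi": 1.0, "pti": 1.0, "ipsi": 0.0, "iapsi": 1.0}


@dataclass
class IsolationResult:
    """Plug-in and bootstrap summaries of the isolation indices.

    ``psi``/``pti`` are 2x2 (male species x female species); ``pti`` is
    ``None`` when population counts are absent.  ``boot_mean``, ``se`` and
    ``p_two_tail`` are keyed by index name (``"psi"``, ``"pti"``,
    ``"ipsi"``, ``"iapsi"``) with array values matching each index's shape.
    """

    psi: np.ndarray
    pti: np.ndarray | None
    ipsi: float
    iapsi: float
    boot_mean: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    p_two_tail: dict = field(default_factory=dict)
    n_bootstrap: int = 0
    n_redrawn: int = 0
    n_nonfinite_iapsi: int = 0
    seed: int | None = None


def expected_pairs_mated(table: MatingTable) -> np.ndarray:
    """Expected pair counts under random mating among mated individuals.

    ``E[i, j] = (row_i marginal) * (column_j marginal) / T``.
    """
    o = table.pairs.astype(float)
    t = o.sum()
    if t < 1:
        raise ValueError("mating table has no pairs")
    return np.outer(o.sum(axis=1), o.sum(axis=0)) / t


def psi(table: MatingTable) -> np.ndarray:
    """Pair sexual isolation index ``O / E``; NaN flags zero-expected cells."""
    e = expected_pairs_mated(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = table.pairs / e
    return np.where(e > 0, out, np.nan)


def expected_pairs_total(table: MatingTable) -> np.ndarray:
    """Expected pairs under random mating of *all* sampled individuals."""
    if table.population is None:
        raise ValueError("population counts required for PTI")
    males = table.population[:, 0].astype(float)
    females = table.population[:, 1].astype(float)
    if males.sum() == 0 or females.sum() == 0:
        raise ValueError("population counts required for PTI")
    t = table.pairs.sum()
    return t * np.outer(males / males.sum(), females / females.sum())


def pti(table: MatingTable) -> np.ndarray | None:
    """Pair total index, or ``None`` when population counts are missing
    or degenerate (no sampled males or no sampled females)."""
    if table.population is None or table.population[:, 0].sum() == 0 \
            or table.population[:, 1].sum() == 0:
        return None
    e = expected_pairs_total(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = table.pairs / e
    return np.where(e > 0, out, np.nan)


def _ipsi_from_psi(p: np.ndarray) -> float:
    # undefined (NaN) cells carry no pairs and drop out of both sums
    con = np.nansum([p[0, 0], p[1, 1]])
    het = np.nansum([p[0, 1], p[1, 0]])
    if con + het == 0:
        raise ValueError("all PSI values zero; I_PSI undefined")
    return float((con - het) / (con + het))


def ipsi(table: MatingTable) -> float:
    """Joint isolation index in [-1, 1]; 1 = complete isolation."""
    return _ipsi_from_psi(psi(table))


def iapsi(table: MatingTable) -> float:
    """Asymmetry of hetero-specific mating: max/min ratio of the two
    hetero-specific PSI values (>= 1; +inf when one of them is zero)."""
    p = psi(table)
    lo = min(p[0, 1], p[1, 0])
    hi = max(p[0, 1], p[1, 0])
    if lo == 0:
        return math.inf
    return float(hi / lo)


def _two_tail_p(replicates: np.ndarray, null: float) -> float:
    """Percentile-crossing two-tail p with add-one correction.

    Ties with the null count toward both tails (conservative).
    """
    b = replicates[np.isfinite(replicates)]
    n = len(b)
    if n == 0:
        return 1.0
    lo = (int((b <= null).sum()) + 1) / (n + 1)
    hi = (int((b >= null).sum()) + 1) / (n + 1)
    return min(1.0, 2.0 * min(lo, hi))


def bootstrap_isolation(table: MatingTable, n: int = 10000,
                        seed: int | None = None,
                        resample_population: bool = True) -> IsolationResult:
    """Bootstrap the isolation indices from the observed pair distribution.

    Each replicate redraws the ``T`` observed pairs multinomially over the
    four cells; replicates with an empty row or column marginal (undefined
    PSI) are redrawn so that exactly ``n`` valid replicates contribute, and
    the number of redraws is reported.  When population counts are present
    and ``resample_population`` is set, the male and female population
    compositions are redrawn per replicate for PTI.

    Replicates whose hetero-specific asymmetry is infinite (a zero
    hetero-specific cell) are excluded from the IA_PSI mean/se and counted
    in ``n_nonfinite_iapsi``.
    """
    if table.total_pairs < 2:
        raise ValueError("need at least 2 pairs to bootstrap")
    rng = np.random.default_rng(seed)
    o = table.pairs.astype(float)
    t = int(o.sum())
    probs = (o / t).ravel()
    row_obs = o.sum(axis=1) > 0
    col_obs = o.sum(axis=0) > 0

    draws = np.empty((n, 2, 2))
    pending = np.arange(n)
    n_redrawn = 0
    while len(pending):
        new = rng.multinomial(t, probs, size=len(pending)
                              ).reshape(-1, 2, 2).astype(float)
        draws[pending] = new
        # redraw replicates that lost a marginal the data actually has
        bad = (((new.sum(axis=2) == 0) & row_obs).any(axis=1)
               | (((new.sum(axis=1) == 0) & col_obs).any(axis=1)))
        n_redrawn += int(bad.sum())
        pending = pending[bad]

    row = draws.sum(axis=2)
    col = draws.sum(axis=1)
    e = row[:, :, None] * col[:, None, :] / t
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_b = np.where(e > 0, draws / e, np.nan)

    con = np.nansum(np.stack([psi_b[:, 0, 0], psi_b[:, 1, 1]]), axis=0)
    het = np.nansum(np.stack([psi_b[:, 0, 1], psi_b[:, 1, 0]]), axis=0)
    ipsi_b = (con - het) / (con + het)

    het_pair = np.stack([psi_b[:, 0, 1], psi_b[:, 1, 0]], axis=1)
    lo = het_pair.min(axis=1)
    hi = het_pair.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        iapsi_b = np.where(lo > 0, hi / lo, np.inf)
    finite = np.isfinite(iapsi_b)

    result = IsolationResult(
        psi=psi(table), pti=pti(table), ipsi=ipsi(table), iapsi=iapsi(table),
        n_bootstrap=n, n_redrawn=n_redrawn,
        n_nonfinite_iapsi=int((~finite).sum()), seed=seed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        result.boot_mean["psi"] = np.nanmean(psi_b, axis=0)
        result.se["psi"] = np.nanstd(psi_b, axis=0, ddof=1)
    result.p_two_tail["psi"] = np.array(
        [[_two_tail_p(psi_b[:, i, j], _NULL_VALUE["psi"])
          for j in range(2)] for i in range(2)])
    result.boot_mean["ipsi"] = float(ipsi_b.mean())
    result.se["ipsi"] = float(ipsi_b.std(ddof=1))
    result.p_two_tail["ipsi"] = _two_tail_p(ipsi_b, _NULL_VALUE["ipsi"])
    if finite.any():
        result.boot_mean["iapsi"] = float(iapsi_b[finite].mean())
        result.se["iapsi"] = float(iapsi_b[finite].std(ddof=1)) \
            if finite.sum() > 1 else 0.0
    else:
        result.boot_mean["iapsi"] = math.inf
        result.se["iapsi"] = math.nan
    result.p_two_tail["iapsi"] = _two_tail_p(iapsi_b, _NULL_VALUE["iapsi"])

    if result.pti is not None:
        males = table.population[:, 0].astype(float)
        females = table.population[:, 1].astype(float)
        if resample_population and males.sum() > 0 and females.sum() > 0:
            mdraw = rng.multinomial(int(males.sum()), males / males.sum(),
                                    size=n).astype(float)
            fdraw = rng.multinomial(int(females.sum()),
                                    females / females.sum(),
                                    size=n).astype(float)
        else:
            mdraw = np.broadcast_to(males, (n, 2)).copy()
            fdraw = np.broadcast_to(females, (n, 2)).copy()
        with np.errstate(divide="ignore", invalid="ignore"):
            e_tot = t * (mdraw / mdraw.sum(axis=1, keepdims=True)
                         )[:, :, None] * (
                fdraw / fdraw.sum(axis=1, keepdims=True))[:, None, :]
            pti_b = np.where(e_tot > 0, draws / e_tot, np.nan)
        result.boot_mean["pti"] = np.nanmean(pti_b, axis=0)
        result.se["pti"] = np.nanstd(pti_b, axis=0, ddof=1)
        result.p_two_tail["pti"] = np.array(
            [[_two_tail_p(pti_b[:, i, j], _NULL_VALUE["pti"])
              for j in range(2)] for i in range(2)])
    return result


def round_half_up(value: float, decimals: int = 2) -> float:
    """Display rounding with exact halves rounded away from zero."""
    factor = 10 ** decimals
    return math.floor(abs(value) * factor + 0.5) / factor * math.copysign(
        1.0, value)
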