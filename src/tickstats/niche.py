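"""Attachment-niche overlap between and within species (Schoener's D).

Two flavours of the index are computed from attachment distributions:

* between-species overlap on co-infested animals (one value per sex), and
* within-species overlap comparing animals carrying one versus both
  species (one value per species and sex).

Both are reported per cattle-infestation stratum (total adult ticks on the
animal: <30, 30-69, >=70) and for all laid-down animals pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from tickstats.survey import (
    SPECIES,
    AttachmentDistribution,
    TickObservation,
    attachment_distribution,
)

#: (lower, upper, label) host-infestation strata by total adult tick count.
INFESTATION_STRATA: tuple[tuple[float, float, str], ...] = (
    (0, 30, "lt_30"),
    (30, 70, "30_to_70"),
    (70, np.inf, "ge_70"),
)
STRATUM_LABELS: tuple[str, ...] = ("all",) + tuple(
    s[2] for s in INFESTATION_STRATA)


@dataclass
class OverlapResult:
    """A Schoener's D value for one comparison, or a flagged absence."""

    index_kind: str  # "D_H" (between species) or "D_C" (co-infestation)
    sex: str
    stratum: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    value: float | None
    available: bool

    def __post_init__(self) -> None:
        if self.available and not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ValueError("Schoener's D must lie in [0, 1]")


def schoener_d(p: AttachmentDistribution | Sequence[float],
               q: AttachmentDistribution | Sequence[float]) -> float:
    """Schoener's overlap ``1 - 0.5 * sum_i |p_i - q_i|``.

    Both arguments must be distributions over the same ordered region set.
    """
    if isinstance(p, AttachmentDistribution) and isinstance(
            q, AttachmentDistribution):
        if p.regions != q.regions:
            raise ValueError("mismatched region sets")
        pv, qv = p.proportions, q.proportions
    else:
        pv = p.proportions if isinstance(p, AttachmentDistribution) \
            else np.asarray(p, dtype=float)
        qv = q.proportions if isinstance(q, AttachmentDistribution) \
            else np.asarray(q, dtype=float)
        if pv.shape != qv.shape:
            raise ValueError("mismatched region sets")
    return float(1.0 - 0.5 * np.abs(pv - qv).sum())


def _laid_down(obs: Iterable[TickObservation]) -> list[TickObservation]:
    return [o for o in obs if o.inspection_mode == "laid_down"]


def _animal_burden(obs: Sequence[TickObservation]) -> dict[tuple, int]:
    burden: dict[tuple, int] = {}
    for o in obs:
        key = (o.site_id, o.animal_id)
        burden[key] = burden.get(key, 0) + 1
    return burden


def _animal_species(obs: Sequence[TickObservation]) -> dict[tuple, set]:
    present: dict[tuple, set] = {}
    for o in obs:
        present.setdefault((o.site_id, o.animal_id), set()).add(o.species)
    return present


def _stratum_animals(burden: dict[tuple, int], stratum: str) -> set:
    if stratum == "all":
        return set(burden)
    for lo, hi, label in INFESTATION_STRATA:
        if label == stratum:
            return {a for a, n in burden.items() if lo <= n < hi}
    raise ValueError(f"unknown stratum {stratum!r}")


def _try_distribution(obs, selector):
    try:
        return attachment_distribution(obs, selector)
    except ValueError:
        return None


def _result(kind, sex, stratum, ga, gb, da, db) -> OverlapResult:
    ok = da is not None and db is not None
    return OverlapResult(
        index_kind=kind, sex=sex, stratum=stratum, group_a=ga, group_b=gb,
        n_a=da.n_ticks if da else 0, n_b=db.n_ticks if db else 0,
        value=schoener_d(da, db) if ok else None, available=ok)


def overlap_heterospecific(obs: Sequence[TickObservation], sex: str,
                           strata: Sequence[str] = STRATUM_LABELS,
                           ) -> list[OverlapResult]:
    """Between-species attachment overlap on co-infested laid-down animals.

    For each requested stratum the two species' attachment distributions
    (ticks of ``sex`` on animals carrying both species) are compared with
    :func:`schoener_d`.  Strata where either species contributes no tick
    are returned flagged unavailable rather than as silent zeros.
    """
    laid = _laid_down(obs)
    burden = _animal_burden(laid)
    present = _animal_species(laid)
    coinfested = {a for a, sp in present.items() if len(sp) == 2}
    results = []
    for stratum in strata:
        animals = _stratum_animals(burden, stratum) & coinfested
        dists = [
            _try_distribution(laid, lambda o, s=species: (
                o.species == s and o.sex == sex
                and (o.site_id, o.animal_id) in animals))
            for species in SPECIES]
        results.append(_result("D_H", sex, stratum, f"{SPECIES[0]}{sex}",
                               f"{SPECIES[1]}{sex}", *dists))
    return results


def overlap_coinfestation(obs: Sequence[TickObservation], species: str,
                          sex: str,
                          strata: Sequence[str] = STRATUM_LABELS,
                          ) -> list[OverlapResult]:
    """Within-species overlap across co-infestation status.

    Compares the attachment distribution of ``species`` ticks of ``sex`` on
    animals carrying only that species against the distribution on animals
    carrying both species.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    laid = _laid_down(obs)
    burden = _animal_burden(laid)
    present = _animal_species(laid)
    single = {a for a, sp in present.items() if sp == {species}}
    coinfested = {a for a, sp in present.items() if len(sp) == 2}
    results = []
    for stratum in strata:
        in_stratum = _stratum_animals(burden, stratum)
        dists = [
            _try_distribution(laid, lambda o, animals=animals: (
                o.species == species and o.sex == sex
                and (o.site_id, o.animal_id) in animals))
            for animals in (single & in_stratum, coinfested & in_stratum)]
        results.append(_result(
            "D_C", sex, stratum, f"{species}{sex} single-species",
            f"{species}{sex} co-infested", *dists))
    return results
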