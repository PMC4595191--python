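"""Survey data model, CSV I/O, eligibility filtering and summary builders.

The survey format is one adult tick per row.  Two delimited text files make
up a survey: a tick file and an animals file, both UTF-8, comma-separated,
with a versioned ``# tickstats-...`` comment on the first line.

Tick file columns
    ``site_id, animal_id, inspection_mode, species, sex, body_region,
    cluster_id, partner_species``

Animals file columns
    ``site_id, animal_id, inspection_mode, days_since_amitraz,
    days_since_pyrethroid``

Empty fields encode missing values (no body region for corridor
inspections, no treatment date for untreated animals, and so on).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

SPECIES: tuple[str, ...] = ("Av", "Ah")
SEXES: tuple[str, ...] = ("M", "F")
INSPECTION_MODES: tuple[str, ...] = ("laid_down", "corridor")
BODY_REGIONS: tuple[str, ...] = (
    "perineum_thigh",
    "inguinal",
    "axillary",
    "belly",
    "head",
    "legs",
    "tail",
    "dewlap",
)
PARTNER_CODES: tuple[str, ...] = ("Av", "Ah", "single")
LEVELS: tuple[str, ...] = ("animal", "attachment_site", "cluster")
INFESTATION_CATEGORIES: tuple[str, ...] = (
    "absent",
    "lt_0.1",
    "0.1_to_1",
    "1_to_10",
    "ge_10",
)

SURVEY_SCHEMA_VERSION = "1"
_SURVEY_HEADER = ("site_id", "animal_id", "inspection_mode", "species", "sex",
                  "body_region", "cluster_id", "partner_species")
_ANIMALS_HEADER = ("site_id", "animal_id", "inspection_mode",
                   "days_since_amitraz", "days_since_pyrethroid")


class SurveyFormatError(ValueError):
    """Raised when a survey file violates the documented schema.

    Carries the 1-based line number and offending field when known.
    """

    def __init__(self, message: str, line: int | None = None,
                 fieldname: str | None = None):
        loc = ""
        if line is not None:
            loc += f" (line {line}"
            if fieldname is not None:
                loc += f", field '{fieldname}'"
            loc += ")"
        super().__init__(message + loc)
        self.line = line
        self.fieldname = fieldname


def group_label(species: str, sex: str) -> str:
    """Canonical label for a (species, sex) group, e.g. ``"AvM"``."""
    return f"{species}{sex}"


def parse_group(group: str | tuple[str, str]) -> tuple[str, str]:
    """Normalise a group given as ``"AvM"`` or ``("Av", "M")``."""
    if isinstance(group, tuple):
        species, sex = group
    else:
        species, sex = group[:-1], group[-1]
    if species not in SPECIES or sex not in SEXES:
        raise ValueError(f"unknown group {group!r}; expected species in "
                         f"{SPECIES} and sex in {SEXES}")
    return species, sex


@dataclass(frozen=True)
class TickObservation:
    """One adult tick found on one animal.

    Parameters
    ----------
    site_id, animal_id
        Identifiers; ``animal_id`` is unique within a site.
    inspection_mode
        ``"laid_down"`` (full-body examination, placement recorded) or
        ``"corridor"`` (count-only examination, no placement).
    species, sex
        ``"Av"``/``"Ah"`` and ``"M"``/``"F"``.
    body_region
        One of the eight body regions; ``None`` for corridor inspections.
    cluster_id
        Identifier of the <5 cm aggregation group within
        ``(animal_id, body_region)``; ``None`` when the tick is not part of
        a recorded cluster or the inspection was corridor mode.
    partner_species
        For females only: species of the attached mating partner, or
        ``"single"``; ``None`` when unobserved (males, corridor mode).
    """

    site_id: str
    animal_id: str
    inspection_mode: str
    species: str
    sex: str
    body_region: str | None = None
    cluster_id: str | None = None
    partner_species: str | None = None

    def __post_init__(self) -> None:
        if self.inspection_mode not in INSPECTION_MODES:
            raise ValueError(f"unknown inspection_mode {self.inspection_mode!r}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.body_region is not None and self.body_region not in BODY_REGIONS:
            raise ValueError(f"unknown body_region {self.body_region!r}")
        if self.partner_species is not None:
            if self.sex != "F":
                raise ValueError("partner_species must be null for males")
            if self.partner_species not in PARTNER_CODES:
                raise ValueError(
                    f"unknown partner_species {self.partner_species!r}")
        if self.inspection_mode == "corridor":
            if self.body_region is not None or self.cluster_id is not None:
                raise ValueError(
                    "body_region/cluster_id must be null for corridor "
                    "inspections")
        elif self.body_region is None:
            raise ValueError("body_region required for laid_down inspections")
        if self.cluster_id is not None and self.body_region is None:
            raise ValueError("cluster_id requires body_region")


@dataclass(frozen=True)
class AnimalRecord:
    """One examined animal with its acaricide-treatment history.

    ``days_since_*`` of ``None`` means the animal was never treated with
    that product class (retained by the eligibility filter).
    """

    animal_id: str
    site_id: str
    inspection_mode: str
    days_since_amitraz: int | None = None
    days_since_pyrethroid: int | None = None

    def __post_init__(self) -> None:
        if self.inspection_mode not in INSPECTION_MODES:
            raise ValueError(f"unknown inspection_mode {self.inspection_mode!r}")
        for name in ("days_since_amitraz", "days_since_pyrethroid"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SiteSummary:
    """Per-site abundance summary for both species."""

    site_id: str
    n_animals_examined: int
    n_av: int
    n_ah: int
    mean_abundance_av: float
    mean_abundance_ah: float
    category_av: str
    category_ah: str


@dataclass
class AttachmentDistribution:
    """Proportions of selected ticks over the eight body regions.

    ``proportions`` is aligned with ``regions`` and sums to 1.
    """

    proportions: np.ndarray
    regions: tuple[str, ...] = BODY_REGIONS
    n_ticks: int = 0

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.regions),):
            raise ValueError("proportions must align with regions")
        if not np.isclose(self.proportions.sum(), 1.0, atol=1e-9):
            raise ValueError("proportions must sum to 1")


@dataclass
class PresenceMatrix:
    """Binary groups-by-units incidence matrix at a chosen spatial level.

    ``cells[g, u]`` is 1 iff at least one tick of group ``g`` was found in
    unit ``u``.  Units are animals, ``(animal, body_region)`` attachment
    sites, or ``(animal, body_region, cluster)`` aggregation groups,
    always qualified by site.
    """

    level: str
    unit_ids: list[tuple]
    group_labels: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.group_labels), len(self.unit_ids)):
            raise ValueError("cells must be (n_groups, n_units)")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def group_index(self, group: str | tuple[str, str]) -> int:
        label = group_label(*parse_group(group))
        try:
            return self.group_labels.index(label)
        except ValueError:
            raise KeyError(f"group {label!r} not in matrix") from None

    def occupancy(self, group: str | tuple[str, str]) -> int:
        """Number of units occupied by ``group``."""
        return int(self.cells[self.group_index(group)].sum())

    def write_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["unit"] + list(self.group_labels))
            for u, col in zip(self.unit_ids, self.cells.T):
                w.writerow(["/".join(map(str, u))] + [int(c) for c in col])


@dataclass
class MatingTable:
    """2x2 male-species x female-species mating-pair counts.

    ``pairs[i, j]`` counts attached pairs of a male of ``SPECIES[i]`` with a
    female of ``SPECIES[j]``.  ``single_females[j]`` counts females of
    ``SPECIES[j]`` attached without a partner.  ``population[i, k]``, when
    present, counts all sampled individuals of ``SPECIES[i]`` and
    ``SEXES[k]`` (mated and single).
    """

    pairs: np.ndarray
    single_females: np.ndarray = field(
        default_factory=lambda: np.zeros(2, dtype=int))
    population: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.single_females = np.asarray(self.single_females, dtype=int)
        if self.pairs.shape != (2, 2):
            raise ValueError("pairs must be 2x2")
        if self.single_females.shape != (2,):
            raise ValueError("single_females must have one count per species")
        if (self.pairs < 0).any() or (self.single_females < 0).any():
            raise ValueError("counts must be non-negative")
        if self.population is not None:
            self.population = np.asarray(self.population, dtype=int)
            if self.population.shape != (2, 2) or (self.population < 0).any():
                raise ValueError("population must be non-negative 2x2 "
                                 "(species x sex)")

    @property
    def total_pairs(self) -> int:
        return int(self.pairs.sum())

    def n_females(self, species: str) -> int:
        """Females of ``species`` with an observed outcome (mated or single)."""
        j = SPECIES.index(species)
        return int(self.pairs[:, j].sum() + self.single_females[j])

    def female_outcome_rate(self, species: str, outcome: str) -> float:
        """Proportion of ``species`` females with the given outcome.

        ``outcome`` is ``"conspecific"``, ``"heterospecific"`` or
        ``"single"``; the denominator is all females of that species with an
        observed outcome.
        """
        j = SPECIES.index(species)
        denom = self.n_females(species)
        if denom == 0:
            raise ValueError(f"no {species} females with observed outcome")
        if outcome == "conspecific":
            num = self.pairs[j, j]
        elif outcome == "heterospecific":
            num = self.pairs[1 - j, j]
        elif outcome == "single":
            num = self.single_females[j]
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        return float(num) / denom


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_optional_int(value: str, line: int, fieldname: str) -> int | None:
    if value == "":
        return None
    try:
        n = int(value)
    except ValueError:
        raise SurveyFormatError(f"expected integer, got {value!r}",
                                line, fieldname) from None
    if n < 0:
        raise SurveyFormatError(f"expected non-negative integer, got {n}",
                                line, fieldname)
    return n


def _check_header(row: Sequence[str], expected: Sequence[str], line: int,
                  path) -> None:
    if tuple(row) != tuple(expected):
        raise SurveyFormatError(
            f"bad header in {path}: expected {','.join(expected)}", line)


def _open_rows(path, kind: str, schema_version: str):
    """Yield (line_number, row) pairs, consuming the version comment."""
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.reader(fh)
    line = 0
    first = True
    for row in reader:
        line += 1
        if not row:
            continue
        if first and row[0].startswith("#"):
            comment = ",".join(row).lstrip("#").strip()
            expected = f"tickstats-{kind} v{schema_version}"
            if comment != expected:
                fh.close()
                raise SurveyFormatError(
                    f"schema mismatch: file declares {comment!r}, expected "
                    f"{expected!r}", line)
            first = False
            continue
        first = False
        yield line, row
    fh.close()


def read_survey(ticks_path, animals_path=None,
                schema_version: str = SURVEY_SCHEMA_VERSION,
                ) -> tuple[list[TickObservation], list[AnimalRecord]]:
    """Read a survey from its tick file and optional animals file.

    Every row is either parsed into a validated record or rejected with a
    :class:`SurveyFormatError` naming the line and field.

    Returns
    -------
    (observations, animals)
        ``animals`` is empty when ``animals_path`` is not given.
    """
    observations: list[TickObservation] = []
    rows = _open_rows(ticks_path, "survey", schema_version)
    header_seen = False
    for line, row in rows:
        if not header_seen:
            _check_header(row, _SURVEY_HEADER, line, ticks_path)
            header_seen = True
            continue
        if len(row) != len(_SURVEY_HEADER):
            raise SurveyFormatError(
                f"expected {len(_SURVEY_HEADER)} fields, got {len(row)}", line)
        rec = dict(zip(_SURVEY_HEADER, (v.strip() for v in row)))
        for fieldname, allowed in (
                ("inspection_mode", INSPECTION_MODES),
                ("species", SPECIES), ("sex", SEXES)):
            if rec[fieldname] not in allowed:
                raise SurveyFormatError(
                    f"value {rec[fieldname]!r} not in {allowed}",
                    line, fieldname)
        if rec["body_region"] and rec["body_region"] not in BODY_REGIONS:
            raise SurveyFormatError(
                f"value {rec['body_region']!r} not in {BODY_REGIONS}",
                line, "body_region")
        if rec["partner_species"] and rec["partner_species"] not in PARTNER_CODES:
            raise SurveyFormatError(
                f"value {rec['partner_species']!r} not in {PARTNER_CODES}",
                line, "partner_species")
        try:
            observations.append(TickObservation(
                site_id=rec["site_id"],
                animal_id=rec["animal_id"],
                inspection_mode=rec["inspection_mode"],
                species=rec["species"],
                sex=rec["sex"],
                body_region=rec["body_region"] or None,
                cluster_id=rec["cluster_id"] or None,
                partner_species=rec["partner_species"] or None,
            ))
        except ValueError as exc:
            raise SurveyFormatError(str(exc), line) from None

    animals: list[AnimalRecord] = []
    if animals_path is not None:
        seen: set[tuple[str, str]] = set()
        header_seen = False
        for line, row in _open_rows(animals_path, "animals", schema_version):
            if not header_seen:
                _check_header(row, _ANIMALS_HEADER, line, animals_path)
                header_seen = True
                continue
            if len(row) != len(_ANIMALS_HEADER):
                raise SurveyFormatError(
                    f"expected {len(_ANIMALS_HEADER)} fields, got {len(row)}",
                    line)
            rec = dict(zip(_ANIMALS_HEADER, (v.strip() for v in row)))
            key = (rec["site_id"], rec["animal_id"])
            if key in seen:
                raise SurveyFormatError(
                    f"duplicate animal {rec['animal_id']!r} at site "
                    f"{rec['site_id']!r}", line, "animal_id")
            seen.add(key)
            try:
                animals.append(AnimalRecord(
                    animal_id=rec["animal_id"],
                    site_id=rec["site_id"],
                    inspection_mode=rec["inspection_mode"],
                    days_since_amitraz=_parse_optional_int(
                        rec["days_since_amitraz"], line, "days_since_amitraz"),
                    days_since_pyrethroid=_parse_optional_int(
                        rec["days_since_pyrethroid"], line,
                        "days_since_pyrethroid"),
                ))
            except ValueError as exc:
                if isinstance(exc, SurveyFormatError):
                    raise
                raise SurveyFormatError(str(exc), line) from None
    return observations, animals


def write_survey(ticks_path, observations: Iterable[TickObservation],
                 animals_path=None,
                 animals: Iterable[AnimalRecord] = (),
                 schema_version: str = SURVEY_SCHEMA_VERSION) -> None:
    """Write a survey in the documented CSV schema (round-trips with
    :func:`read_survey`)."""
    with open(ticks_path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# tickstats-survey v{schema_version}\n")
        w = csv.writer(fh)
        w.writerow(_SURVEY_HEADER)
        for o in observations:
            w.writerow([o.site_id, o.animal_id, o.inspection_mode, o.species,
                        o.sex, o.body_region or "", o.cluster_id or "",
                        o.partner_species or ""])
    if animals_path is not None:
        with open(animals_path, "w", newline="", encoding="utf-8") as fh:
            fh.write(f"# tickstats-animals v{schema_version}\n")
            w = csv.writer(fh)
            w.writerow(_ANIMALS_HEADER)
            for a in animals:
                w.writerow([
                    a.site_id, a.animal_id, a.inspection_mode,
                    "" if a.days_since_amitraz is None
                    else a.days_since_amitraz,
                    "" if a.days_since_pyrethroid is None
                    else a.days_since_pyrethroid])


_MATING_HEADER = ("record_type", "male_species", "female_species", "sex",
                  "count")


def read_mating_table(path) -> MatingTable:
    """Read a mating table from its long-format CSV.

    Rows are ``pair,<male_species>,<female_species>,,<count>``,
    ``single,,<female_species>,,<count>`` and optionally
    ``population,<species>,,<sex>,<count>``.
    """
    pairs = np.zeros((2, 2), dtype=int)
    singles = np.zeros(2, dtype=int)
    population = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(
            row for row in fh if not row.startswith("#"))
        if tuple(reader.fieldnames or ()) != _MATING_HEADER:
            raise SurveyFormatError(
                f"bad header in {path}: expected {','.join(_MATING_HEADER)}")
        for i, rec in enumerate(reader, start=2):
            count = _parse_optional_int(rec["count"], i, "count")
            if count is None:
                raise SurveyFormatError("count required", i, "count")
            kind = rec["record_type"]
            if kind == "pair":
                pairs[SPECIES.index(rec["male_species"]),
                      SPECIES.index(rec["female_species"])] = count
            elif kind == "single":
                singles[SPECIES.index(rec["female_species"])] = count
            elif kind == "population":
                if population is None:
                    population = np.zeros((2, 2), dtype=int)
                population[SPECIES.index(rec["male_species"]),
                           SEXES.index(rec["sex"])] = count
            else:
                raise SurveyFormatError(f"unknown record_type {kind!r}", i,
                                        "record_type")
    return MatingTable(pairs, singles, population)


def write_mating_table(path, table: MatingTable) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_MATING_HEADER)
        for i, m in enumerate(SPECIES):
            for j, f in enumerate(SPECIES):
                w.writerow(["pair", m, f, "", int(table.pairs[i, j])])
        for j, f in enumerate(SPECIES):
            w.writerow(["single", "", f, "", int(table.single_females[j])])
        if table.population is not None:
            for i, s in enumerate(SPECIES):
                for k, x in enumerate(SEXES):
                    w.writerow(["population", s, "", x,
                                int(table.population[i, k])])


# ---------------------------------------------------------------------------
# Filtering and summaries


def eligibility_filter(animals: Iterable[AnimalRecord],
                       amitraz_min_days: int = 8,
                       pyrethroid_min_days: int = 15) -> list[AnimalRecord]:
    """Drop animals treated with acaricides too recently.

    An animal is retained when each treatment was at least the product's
    residual-effect duration ago — 8 days for amitraz, 15 for pyrethroids —
    or never happened (``None`` date).  Thresholds are inclusive.
    """
    if amitraz_min_days <= 0 or pyrethroid_min_days <= 0:
        raise ValueError("thresholds must be positive")
    return [a for a in animals
            if (a.days_since_amitraz is None
                or a.days_since_amitraz >= amitraz_min_days)
            and (a.days_since_pyrethroid is None
                 or a.days_since_pyrethroid >= pyrethroid_min_days)]


def infestation_category(count: int, mean_abundance: float) -> str:
    """Half-open abundance bin: absent, <0.1, [0.1, 1), [1, 10), >=10."""
    if count == 0:
        return "absent"
    if mean_abundance < 0.1:
        return "lt_0.1"
    if mean_abundance < 1:
        return "0.1_to_1"
    if mean_abundance < 10:
        return "1_to_10"
    return "ge_10"


def summarize_site(observations: Iterable[TickObservation],
                   animals: Iterable[AnimalRecord],
                   site_id: str) -> SiteSummary:
    """Mean abundance (adults per examined animal) and category per species.

    Only ticks on the provided (typically eligibility-filtered) animals are
    counted.
    """
    site_animals = [a for a in animals if a.site_id == site_id]
    n_examined = len(site_animals)
    if n_examined == 0:
        raise ValueError(f"no examined animals at site {site_id!r}")
    keep = {a.animal_id for a in site_animals}
    counts = {s: 0 for s in SPECIES}
    for o in observations:
        if o.site_id == site_id and o.animal_id in keep:
            counts[o.species] += 1
    mean_av = counts["Av"] / n_examined
    mean_ah = counts["Ah"] / n_examined
    return SiteSummary(
        site_id=site_id,
        n_animals_examined=n_examined,
        n_av=counts["Av"],
        n_ah=counts["Ah"],
        mean_abundance_av=mean_av,
        mean_abundance_ah=mean_ah,
        category_av=infestation_category(counts["Av"], mean_av),
        category_ah=infestation_category(counts["Ah"], mean_ah),
    )


# ---------------------------------------------------------------------------
# Downstream input builders


def _unit_key(o: TickObservation, level: str) -> tuple:
    if level == "animal":
        return (o.site_id, o.animal_id)
    if level == "attachment_site":
        return (o.site_id, o.animal_id, o.body_region)
    if level == "cluster":
        return (o.site_id, o.animal_id, o.body_region, o.cluster_id)
    raise ValueError(f"unknown level {level!r}")


def build_presence_matrix(observations: Sequence[TickObservation],
                          level: str,
                          groups: Sequence[str | tuple[str, str]] | None = None,
                          drop_empty: bool = True) -> PresenceMatrix:
    """Binary incidence of (species, sex) groups over spatial units.

    Units are animals, attachment sites or clusters depending on ``level``.
    The unit universe is every unit holding at least one tick of any group
    in ``observations``; with ``drop_empty`` (default) units holding none of
    the requested ``groups`` are then removed, since empty units are not
    recorded by the field protocol.

    Corridor observations carry no placement, so sub-animal levels reject
    them.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    if groups is None:
        groups = [group_label(s, x) for s in SPECIES for x in SEXES]
    labels = [group_label(*parse_group(g)) for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate groups")

    if level != "animal":
        bad = [o for o in observations if o.inspection_mode == "corridor"]
        if bad:
            raise ValueError(
                f"{len(bad)} corridor observations have no placement; "
                f"level={level!r} requires laid_down observations only")
        observations = [o for o in observations if o.body_region is not None
                        and (level != "cluster" or o.cluster_id is not None)]

    unit_ids = sorted({_unit_key(o, level) for o in observations})
    index = {u: i for i, u in enumerate(unit_ids)}
    cells = np.zeros((len(labels), len(unit_ids)), dtype=np.int8)
    for o in observations:
        label = group_label(o.species, o.sex)
        if label in labels:
            cells[labels.index(label), index[_unit_key(o, level)]] = 1
    if drop_empty and unit_ids:
        keep = cells.any(axis=0)
        cells = cells[:, keep]
        unit_ids = [u for u, k in zip(unit_ids, keep) if k]
    return PresenceMatrix(level=level, unit_ids=list(unit_ids),
                          group_labels=labels, cells=cells)


def attachment_distribution(observations: Iterable[TickObservation],
                            selector: Callable[[TickObservation], bool]
                            | None = None) -> AttachmentDistribution:
    """Proportions of the selected ticks across the eight body regions.

    Only laid-down observations carry a body region; corridor observations
    are ignored.  Raises on an empty selection.
    """
    counts = np.zeros(len(BODY_REGIONS), dtype=float)
    n = 0
    for o in observations:
        if o.body_region is None:
            continue
        if selector is not None and not selector(o):
            continue
        counts[BODY_REGIONS.index(o.body_region)] += 1
        n += 1
    if n == 0:
        raise ValueError("no ticks selected")
    return AttachmentDistribution(proportions=counts / n, n_ticks=n)


def build_mating_table(observations: Iterable[TickObservation],
                       site_id: str | None = None) -> MatingTable:
    """Tally attached mating pairs and single females, optionally per site.

    Females with a null ``partner_species`` (corridor inspections) do not
    contribute pair or single counts but do count toward the population
    totals, which cover all sampled individuals at the site.
    """
    pairs = np.zeros((2, 2), dtype=int)
    singles = np.zeros(2, dtype=int)
    population = np.zeros((2, 2), dtype=int)
    for o in observations:
        if site_id is not None and o.site_id != site_id:
            continue
        population[SPECIES.index(o.species), SEXES.index(o.sex)] += 1
        if o.sex == "F" and o.partner_species is not None:
            j = SPECIES.index(o.species)
            if o.partner_species == "single":
                singles[j] += 1
            else:
                pairs[SPECIES.index(o.partner_species), j] += 1
    return MatingTable(pairs, singles, population)


def pct_attached_in_presence(observations: Sequence[TickObservation],
                             focal_group: str | tuple[str, str],
                             reference_group: str | tuple[str, str],
                             level: str) -> float:
    """Percentage of focal-group ticks sharing their unit with the reference
    group.

    A focal tick counts as "in presence" when its animal / attachment site /
    cluster holds at least one reference-group tick.  Corridor observations
    are excluded at sub-animal levels (no placement).
    """
    f_species, f_sex = parse_group(focal_group)
    r_species, r_sex = parse_group(reference_group)
    if level != "animal":
        observations = [o for o in observations
                        if o.inspection_mode == "laid_down"
                        and o.body_region is not None
                        and (level != "cluster" or o.cluster_id is not None)]
    ref_units = {_unit_key(o, level) for o in observations
                 if o.species == r_species and o.sex == r_sex}
    focal = [o for o in observations
             if o.species == f_species and o.sex == f_sex]
    if not focal:
        raise ValueError("no focal ticks at this level")
    hits = sum(1 for o in focal if _unit_key(o, level) in ref_units)
    return 100.0 * hits / len(focal)


def pct_units_coinfested(observations: Sequence[TickObservation],
                         group_a: str | tuple[str, str],
                         group_b: str | tuple[str, str],
                         level: str = "animal") -> float:
    """Percentage of occupied units holding both groups.

    The denominator is units holding at least one tick of either group
    (unoccupied units are unobservable in the field protocol).
    """
    m = build_presence_matrix(observations, level, groups=[group_a, group_b],
                              drop_empty=True)
    if m.n_units == 0:
        raise ValueError("no occupied units")
    both = int((m.cells.sum(axis=0) == 2).sum())
    return 100.0 * both / m.n_units
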