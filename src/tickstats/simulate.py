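"""Seeded synthetic surveys with the hierarchical structure the analysis
assumes.

Two generators are provided.  :func:`generate_survey` is mechanistic: it
draws negative-binomially dispersed per-host burdens, places males into
body regions and pheromone-driven clusters by preferential attachment,
attracts females to clusters, and assigns mating partners by preference
odds — exercising the full pipeline with known generating parameters.
:func:`generate_mating_counts` draws regression units straight from a
beta-binomial model with known coefficients and intraclass correlation,
giving exact distributional ground truth for the regression module.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import special, stats

from tickstats.betabinom import ALL_TERMS, BetaBinomDataset
from tickstats.survey import (
    BODY_REGIONS,
    SPECIES,
    AnimalRecord,
    TickObservation,
)

_DEFAULT_PREF_AV = (0.40, 0.30, 0.15, 0.05, 0.03, 0.03, 0.02, 0.02)
_DEFAULT_PREF_AH = (0.35, 0.25, 0.25, 0.05, 0.03, 0.03, 0.02, 0.02)


@dataclass
class SimulationConfig:
    """Generating parameters for the mechanistic survey generator.

    Cluster weights ``w_con``/``w_het`` scale a male's tendency to join a
    cluster per con-/hetero-specific male already in it (``w_new`` is the
    weight of opening a new cluster); ``a_*`` are the female analogues.
    ``m_con``/``m_het`` are per-male mating-preference odds.  ``rho_sim``
    is the target intraclass correlation of the direct-draw generator.
    """

    n_sites: int = 1
    animals_per_site: int = 50
    laid_down_per_site: int = 10
    mean_abundance: dict = field(
        default_factory=lambda: {"Av": 4.0, "Ah": 4.0})
    nb_dispersion: float = 1.0  # negative-binomial size parameter
    male_fraction: float = 0.6
    preference: dict = field(default_factory=lambda: {
        "Av": _DEFAULT_PREF_AV, "Ah": _DEFAULT_PREF_AH})
    w_con: float = 2.0
    w_het: float = 0.5
    w_new: float = 1.0
    a_con: float = 2.0
    a_het: float = 0.5
    a_new: float = 0.5
    m_con: float = 3.0
    m_het: float = 1.0
    p_single: float = 0.15
    rho_sim: float = 0.0
    beta: dict = field(default_factory=lambda: {
        "intercept": 0.5, "species": 0.0, "male": 4.0, "female": -1.0,
        "interaction": -4.0})
    mean_trials: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for species in SPECIES:
            pref = np.asarray(self.preference[species], dtype=float)
            if pref.shape != (len(BODY_REGIONS),) or pref.min() < 0 or \
                    not np.isclose(pref.sum(), 1.0):
                raise ValueError(f"preference[{species}] must be a "
                                 "distribution over the 8 body regions")
        for name in ("w_con", "w_het", "w_new", "a_con", "a_het", "a_new",
                     "m_con", "m_het"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_single <= 1:
            raise ValueError("p_single must lie in [0, 1]")
        if not 0 <= self.rho_sim < 1:
            raise ValueError("rho_sim must lie in [0, 1)")


@dataclass
class _Cluster:
    region: str
    cluster_id: str
    males: np.ndarray  # count per species


def _negbin(rng, mean: float, size_param: float, n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _place_male(rng, cfg, clusters, species, counters):
    j = SPECIES.index(species)
    weights = [cfg.w_con * c.males[j] + cfg.w_het * c.males[1 - j]
               for c in clusters]
    weights.append(cfg.w_new)
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        choice = len(clusters)
    else:
        choice = rng.choice(len(w), p=w / w.sum())
    if choice == len(clusters):
        region = rng.choice(BODY_REGIONS,
                            p=np.asarray(cfg.preference[species]))
        cluster = _Cluster(region=region,
                           cluster_id=f"c{next(counters[region])}",
                           males=np.zeros(2))
        clusters.append(cluster)
    else:
        cluster = clusters[choice]
    cluster.males[j] += 1
    return cluster


def _place_female(rng, cfg, clusters, species, counters):
    j = SPECIES.index(species)
    weights = [cfg.a_con * c.males[j] + cfg.a_het * c.males[1 - j]
               for c in clusters]
    weights.append(cfg.a_new)
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        choice = len(clusters)
    else:
        choice = rng.choice(len(w), p=w / w.sum())
    if choice == len(clusters):
        region = rng.choice(BODY_REGIONS,
                            p=np.asarray(cfg.preference[species]))
        cluster = _Cluster(region=region,
                           cluster_id=f"c{next(counters[region])}",
                           males=np.zeros(2))
        clusters.append(cluster)
    else:
        cluster = clusters[choice]
    # partner assignment among males in the female's cluster
    n_con = cluster.males[j]
    n_het = cluster.males[1 - j]
    if n_con + n_het == 0 or rng.random() < cfg.p_single:
        partner = "single"
    else:
        odds_con = cfg.m_con * n_con
        odds_het = cfg.m_het * n_het
        if odds_con + odds_het == 0:
            partner = "single"
        else:
            partner = species if rng.random() < odds_con / (
                odds_con + odds_het) else SPECIES[1 - j]
    return cluster, partner


def generate_survey(config: SimulationConfig, seed: int | None = None
                    ) -> tuple[list[TickObservation], list[AnimalRecord],
                               dict]:
    """Draw a full synthetic survey; returns (observations, animals, truth).

    The truth record holds every generating parameter (the config as a
    dict) plus the seed actually used.  Identical (config, seed) pairs
    produce identical surveys.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    observations: list[TickObservation] = []
    animals: list[AnimalRecord] = []

    for s in range(config.n_sites):
        site_id = f"s{s + 1}"
        n_animals = config.animals_per_site
        burdens = {sp: _negbin(rng, config.mean_abundance[sp],
                               config.nb_dispersion, n_animals)
                   for sp in SPECIES}
        for a in range(n_animals):
            animal_id = f"a{a + 1}"
            mode = "laid_down" if a < config.laid_down_per_site \
                else "corridor"
            animals.append(AnimalRecord(
                animal_id=animal_id, site_id=site_id, inspection_mode=mode,
                days_since_amitraz=None if rng.random() < 0.5
                else int(rng.integers(8, 60)),
                days_since_pyrethroid=None))
            sexes = {}
            for sp in SPECIES:
                total = int(burdens[sp][a])
                n_m = int(rng.binomial(total, config.male_fraction))
                sexes[sp] = (n_m, total - n_m)
            if mode == "corridor":
                for sp in SPECIES:
                    n_m, n_f = sexes[sp]
                    observations.extend(
                        TickObservation(site_id, animal_id, mode, sp, "M")
                        for _ in range(n_m))
                    observations.extend(
                        TickObservation(site_id, animal_id, mode, sp, "F")
                        for _ in range(n_f))
                continue

            clusters: list[_Cluster] = []
            counters = {region: itertools.count(1)
                        for region in BODY_REGIONS}
            male_queue = [sp for sp in SPECIES
                          for _ in range(sexes[sp][0])]
            rng.shuffle(male_queue)
            for sp in male_queue:
                cluster = _place_male(rng, config, clusters, sp, counters)
                observations.append(TickObservation(
                    site_id, animal_id, mode, sp, "M",
                    body_region=cluster.region,
                    cluster_id=cluster.cluster_id))
            female_queue = [sp for sp in SPECIES
                            for _ in range(sexes[sp][1])]
            rng.shuffle(female_queue)
            for sp in female_queue:
                cluster, partner = _place_female(rng, config, clusters, sp,
                                                 counters)
                observations.append(TickObservation(
                    site_id, animal_id, mode, sp, "F",
                    body_region=cluster.region,
                    cluster_id=cluster.cluster_id,
                    partner_species=partner))
    truth = {"config": asdict(config), "seed": int(seed)}
    return observations, animals, truth


def generate_mating_counts(config: SimulationConfig, n_animals: int = 200,
                           seed: int | None = None
                           ) -> tuple[BetaBinomDataset, dict]:
    """Direct beta-binomial draws for regression parameter recovery.

    One unit per animal: covariates drawn uniformly, trials
    ``1 + Poisson(mean_trials - 1)``, successes from the beta-binomial
    with mean from the linear predictor (``config.beta``) and intraclass
    correlation ``config.rho_sim``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    species = rng.choice(SPECIES, size=n_animals)
    p_male = rng.uniform(0.0, 1.0, size=n_animals)
    p_female = rng.uniform(0.0, 1.0, size=n_animals)
    x_male = p_male - 0.5
    x_female = p_female - 0.5
    trials = 1 + rng.poisson(max(config.mean_trials - 1.0, 0.0),
                             size=n_animals)
    beta = np.array([config.beta[t] for t in ALL_TERMS])
    x = np.column_stack([
        np.ones(n_animals), (species == SPECIES[1]).astype(float),
        x_male, x_female, x_male * x_female])
    mu = special.expit(x @ beta)
    rho = config.rho_sim
    if rho < 1e-8:
        successes = rng.binomial(trials, mu)
    else:
        a = mu * (1 - rho) / rho
        b = (1 - mu) * (1 - rho) / rho
        successes = stats.betabinom.rvs(trials, a, b, random_state=rng)
    dataset = BetaBinomDataset(
        trials=trials, successes=successes, female_species=species,
        x_male=x_male, x_female=x_female,
        animal_id=[("sim", f"a{i + 1}") for i in range(n_animals)])
    truth = {"beta": dict(config.beta), "rho": rho, "seed": int(seed),
             "n_animals": n_animals}
    return dataset, truth
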