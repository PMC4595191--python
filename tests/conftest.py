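import numpy as np
import pytest

from tickstats.survey import MatingTable, TickObservation


def make_obs(species, sex, *, site="s55", animal="a1", mode="laid_down",
             region="inguinal", cluster=None, partner=None):
    return TickObservation(
        site_id=site, animal_id=animal, inspection_mode=mode,
        species=species, sex=sex,
        body_region=None if mode == "corridor" else region,
        cluster_id=cluster, partner_species=partner)


@pytest.fixture
def site55_table() -> MatingTable:
    """Printed mating counts at the equi-abundant co-infested site:
    40 AvM-AvF, 4 AvM-AhF, 9 AhM-AvF, 20 AhM-AhF pairs, 9 single Av
    females, 8 single Ah females."""
    return MatingTable(pairs=np.array([[40, 4], [9, 20]]),
                       single_females=np.array([9, 8]))


@pytest.fixture
def site55_obs() -> list[TickObservation]:
    """Observation-level fixture encoding the printed female outcomes."""
    obs = []
    outcomes = [("Av", "Av", 40), ("Av", "Ah", 9), ("Av", "single", 9),
                ("Ah", "Ah", 20), ("Ah", "Av", 4), ("Ah", "single", 8)]
    i = 0
    for female_species, partner, count in outcomes:
        for _ in range(count):
            i += 1
            obs.append(make_obs(female_species, "F", animal=f"a{i % 10 + 1}",
                                partner=partner))
    # males so that population counts exist; exact totals were not printed
    for species, count in (("Av", 60), ("Ah", 55)):
        for j in range(count):
            obs.append(make_obs(species, "M", animal=f"a{j % 10 + 1}"))
    return obs


@pytest.fixture
def coinfestation_obs() -> list[TickObservation]:
    """61 animals with the printed male-infestation composition: 36 carry
    males of both species, 21 only Av males, 4 only Ah males."""
    obs = []
    for i in range(61):
        animal = f"a{i + 1}"
        if i < 36:
            kinds = ("Av", "Ah")
        elif i < 57:
            kinds = ("Av",)
        else:
            kinds = ("Ah",)
        for species in kinds:
            obs.append(make_obs(species, "M", site="s1", animal=animal,
                                mode="corridor"))
    return obs
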