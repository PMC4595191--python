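import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tickstats import survey as sv
from tickstats.simulate import SimulationConfig, generate_survey

from conftest import make_obs


# ---------------------------------------------------------------------------
# CSV I/O


def _write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


TICK_HEADER = ("site_id,animal_id,inspection_mode,species,sex,body_region,"
               "cluster_id,partner_species")


class TestReadSurvey:
    def test_three_row_fixture(self, tmp_path):
        path = tmp_path / "ticks.csv"
        _write_lines(path, [
            "# tickstats-survey v1",
            TICK_HEADER,
            "s1,a1,laid_down,Av,M,inguinal,c1,",
            "s1,a1,laid_down,Ah,F,axillary,,Av",
            "s1,a2,corridor,Av,F,,,",
        ])
        obs, animals = sv.read_survey(path)
        assert len(obs) == 3
        assert animals == []
        assert obs[0].species == "Av" and obs[0].cluster_id == "c1"
        assert obs[1].partner_species == "Av"
        assert obs[2].body_region is None

    def test_male_with_partner_rejected(self, tmp_path):
        path = tmp_path / "ticks.csv"
        _write_lines(path, [
            TICK_HEADER,
            "s1,a1,laid_down,Av,M,inguinal,,Av",
        ])
        with pytest.raises(sv.SurveyFormatError, match="line 2"):
            sv.read_survey(path)

    def test_unknown_species_names_line_and_field(self, tmp_path):
        path = tmp_path / "ticks.csv"
        _write_lines(path, [
            TICK_HEADER,
            "s1,a1,laid_down,Av,M,inguinal,,",
            "s1,a1,laid_down,Ax,M,inguinal,,",
        ])
        with pytest.raises(sv.SurveyFormatError,
                           match=r"line 3, field 'species'"):
            sv.read_survey(path)

    def test_unknown_body_region_rejected(self, tmp_path):
        path = tmp_path / "ticks.csv"
        _write_lines(path, [
            TICK_HEADER,
            "s1,a1,laid_down,Av,M,shoulder,,",
        ])
        with pytest.raises(sv.SurveyFormatError, match="body_region"):
            sv.read_survey(path)

    def test_schema_version_mismatch(self, tmp_path):
        path = tmp_path / "ticks.csv"
        _write_lines(path, ["# tickstats-survey v99", TICK_HEADER])
        with pytest.raises(sv.SurveyFormatError, match="schema mismatch"):
            sv.read_survey(path)

    def test_duplicate_animal_rejected(self, tmp_path):
        tpath = tmp_path / "ticks.csv"
        apath = tmp_path / "animals.csv"
        _write_lines(tpath, [TICK_HEADER])
        _write_lines(apath, [
            "site_id,animal_id,inspection_mode,days_since_amitraz,"
            "days_since_pyrethroid",
            "s1,a1,laid_down,,",
            "s1,a1,corridor,,",
        ])
        with pytest.raises(sv.SurveyFormatError, match="duplicate"):
            sv.read_survey(tpath, apath)


def test_roundtrip_identity_on_generated_survey(tmp_path):
    obs, animals, _ = generate_survey(SimulationConfig(seed=11))
    tpath = tmp_path / "ticks.csv"
    apath = tmp_path / "animals.csv"
    sv.write_survey(tpath, obs, apath, animals)
    obs2, animals2 = sv.read_survey(tpath, apath)
    assert obs2 == obs
    assert animals2 == animals


# ---------------------------------------------------------------------------
# Eligibility filter


def _animal(amitraz=None, pyrethroid=None, ident="a1"):
    return sv.AnimalRecord(animal_id=ident, site_id="s1",
                           inspection_mode="laid_down",
                           days_since_amitraz=amitraz,
                           days_since_pyrethroid=pyrethroid)


class TestEligibilityFilter:
    def test_amitraz_boundary_day_retained(self):
        assert sv.eligibility_filter([_animal(amitraz=8)]) != []

    def test_amitraz_too_recent_excluded(self):
        assert sv.eligibility_filter([_animal(amitraz=7)]) == []

    def test_pyrethroid_boundary(self):
        assert sv.eligibility_filter([_animal(pyrethroid=15)]) != []
        assert sv.eligibility_filter([_animal(pyrethroid=14)]) == []

    def test_untreated_retained(self):
        assert sv.eligibility_filter([_animal()]) != []

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            sv.eligibility_filter([], amitraz_min_days=0)


# ---------------------------------------------------------------------------
# Site summaries


class TestSummarizeSite:
    def test_bin_boundary_closed_left(self):
        animals = [_animal(ident=f"a{i}") for i in range(50)]
        obs = [make_obs("Av", "M", site="s1", animal=f"a{i}")
               for i in range(5)]
        s = sv.summarize_site(obs, animals, "s1")
        assert s.mean_abundance_av == pytest.approx(0.1)
        assert s.category_av == "0.1_to_1"

    def test_absent(self):
        s = sv.summarize_site([], [_animal()], "s1")
        assert s.category_av == s.category_ah == "absent"
        assert s.n_av == 0

    def test_610_over_61(self):
        animals = [_animal(ident=f"a{i}") for i in range(61)]
        obs = [make_obs("Ah", "F", site="s1", animal=f"a{i % 61}")
               for i in range(610)]
        s = sv.summarize_site(obs, animals, "s1")
        assert s.mean_abundance_ah == pytest.approx(10.0)
        assert s.category_ah == "ge_10"

    def test_zero_animals_error(self):
        with pytest.raises(ValueError):
            sv.summarize_site([], [], "s1")


@given(st.integers(0, 2000), st.integers(1, 100))
def test_category_bins_partition(count, n_animals):
    cat = sv.infestation_category(count, count / n_animals)
    assert cat in sv.INFESTATION_CATEGORIES
    mean = count / n_animals
    if count == 0:
        assert cat == "absent"
    elif mean < 0.1:
        assert cat == "lt_0.1"
    elif mean < 1:
        assert cat == "0.1_to_1"
    elif mean < 10:
        assert cat == "1_to_10"
    else:
        assert cat == "ge_10"


# ---------------------------------------------------------------------------
# Presence matrices


class TestPresenceMatrix:
    def test_presence_not_count(self):
        obs = [make_obs("Av", "M", cluster="c1"),
               make_obs("Av", "M", cluster="c1")]
        m = sv.build_presence_matrix(obs, "cluster", groups=["AvM"])
        assert m.cells.shape == (1, 1)
        assert m.cells[0, 0] == 1

    def test_hand_built_three_animals(self):
        obs = [make_obs("Av", "M", animal="a1"),
               make_obs("Ah", "M", animal="a1"),
               make_obs("Av", "M", animal="a2"),
               make_obs("Ah", "M", animal="a3")]
        m = sv.build_presence_matrix(obs, "animal", groups=["AvM", "AhM"])
        expected = np.array([[1, 1, 0],
                             [1, 0, 1]])
        np.testing.assert_array_equal(m.cells, expected)
        assert m.occupancy("AvM") == 2

    def test_empty_observations(self):
        m = sv.build_presence_matrix([], "animal")
        assert m.n_units == 0
        assert m.cells.shape == (4, 0)

    def test_corridor_at_subanimal_level_rejected(self):
        obs = [make_obs("Av", "M", mode="corridor")]
        with pytest.raises(ValueError, match="corridor"):
            sv.build_presence_matrix(obs, "cluster")

    def test_idempotent_under_duplication(self):
        obs = [make_obs("Av", "M", animal="a1"),
               make_obs("Ah", "F", animal="a2", partner="single")]
        m1 = sv.build_presence_matrix(obs, "animal")
        m2 = sv.build_presence_matrix(obs * 3, "animal")
        np.testing.assert_array_equal(m1.cells, m2.cells)
        assert m1.unit_ids == m2.unit_ids

    def test_drop_empty_config(self):
        obs = [make_obs("Av", "M", animal="a1"),
               make_obs("Ah", "M", animal="a2")]
        m = sv.build_presence_matrix(obs, "animal", groups=["AvM"],
                                     drop_empty=False)
        assert m.n_units == 2
        m = sv.build_presence_matrix(obs, "animal", groups=["AvM"])
        assert m.n_units == 1


# ---------------------------------------------------------------------------
# Attachment distributions


class TestAttachmentDistribution:
    def test_all_inguinal(self):
        obs = [make_obs("Av", "M", region="inguinal") for _ in range(3)]
        d = sv.attachment_distribution(obs)
        expected = np.zeros(8)
        expected[sv.BODY_REGIONS.index("inguinal")] = 1.0
        np.testing.assert_allclose(d.proportions, expected)

    def test_split_2_1_1(self):
        obs = [make_obs("Av", "M", region="perineum_thigh"),
               make_obs("Av", "M", region="perineum_thigh"),
               make_obs("Av", "M", region="inguinal"),
               make_obs("Av", "M", region="axillary")]
        d = sv.attachment_distribution(obs)
        np.testing.assert_allclose(
            d.proportions[:3], [0.5, 0.25, 0.25])
        assert d.n_ticks == 4

    def test_empty_selection_error(self):
        with pytest.raises(ValueError, match="no ticks"):
            sv.attachment_distribution([], selector=lambda o: True)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_sums_to_one_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        obs = [make_obs("Av", "M", region=rng.choice(sv.BODY_REGIONS))
               for _ in range(int(rng.integers(1, 40)))]
        d = sv.attachment_distribution(obs)
        assert abs(d.proportions.sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# Mating tables


class TestMatingTable:
    def test_site55_fixture(self, site55_obs):
        t = sv.build_mating_table(site55_obs, "s55")
        np.testing.assert_array_equal(t.pairs, [[40, 4], [9, 20]])
        np.testing.assert_array_equal(t.single_females, [9, 8])
        assert t.total_pairs == 73
        # population counts cover all sampled individuals
        assert t.population[0, 0] == 60   # Av males
        assert t.population[0, 1] == 58   # Av females
        assert t.population[1, 1] == 32   # Ah females

    def test_all_single(self):
        obs = [make_obs("Av", "F", partner="single") for _ in range(5)]
        t = sv.build_mating_table(obs)
        assert t.total_pairs == 0
        assert t.single_females[0] == 5

    def test_cross_mating_rate_av(self, site55_obs):
        t = sv.build_mating_table(site55_obs, "s55")
        assert t.female_outcome_rate("Av", "heterospecific") * 100 == \
            pytest.approx(100 * 9 / 58)

    def test_roundtrip_csv(self, tmp_path, site55_obs):
        t = sv.build_mating_table(site55_obs, "s55")
        path = tmp_path / "mating.csv"
        sv.write_mating_table(path, t)
        t2 = sv.read_mating_table(path)
        np.testing.assert_array_equal(t.pairs, t2.pairs)
        np.testing.assert_array_equal(t.single_females, t2.single_females)
        np.testing.assert_array_equal(t.population, t2.population)


# ---------------------------------------------------------------------------
# Co-attachment percentages


class TestPctAttachedInPresence:
    def test_always_colocated(self):
        obs = [make_obs("Av", "M", animal="a1", cluster="c1"),
               make_obs("Ah", "M", animal="a1", cluster="c1")]
        for level in sv.LEVELS:
            assert sv.pct_attached_in_presence(obs, "AvM", "AhM",
                                               level) == 100.0

    def test_disjoint_units(self):
        obs = [make_obs("Av", "M", animal="a1"),
               make_obs("Ah", "M", animal="a2")]
        assert sv.pct_attached_in_presence(obs, "AvM", "AhM", "animal") == 0.0

    def test_hand_built_five_animals(self):
        # Av males on a1..a4; Ah males on a1, a2, a5 -> 2 of 4 in presence
        obs = [make_obs("Av", "M", animal=f"a{i}") for i in range(1, 5)]
        obs += [make_obs("Ah", "M", animal=a) for a in ("a1", "a2", "a5")]
        assert sv.pct_attached_in_presence(obs, "AvM", "AhM", "animal") == \
            pytest.approx(50.0)
        assert sv.pct_attached_in_presence(obs, "AhM", "AvM", "animal") == \
            pytest.approx(100 * 2 / 3)

    def test_zero_focal_error(self):
        obs = [make_obs("Ah", "M")]
        with pytest.raises(ValueError):
            sv.pct_attached_in_presence(obs, "AvM", "AhM", "animal")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_in_level_coarseness(self, seed):
        rng = np.random.default_rng(seed)
        obs = []
        for _ in range(int(rng.integers(5, 60))):
            obs.append(make_obs(
                rng.choice(["Av", "Ah"]), "M",
                animal=f"a{rng.integers(1, 6)}",
                region=rng.choice(sv.BODY_REGIONS[:3]),
                cluster=f"c{rng.integers(1, 3)}"))
        has = {(o.species, o.sex) for o in obs}
        if ("Av", "M") not in has or ("Ah", "M") not in has:
            return
        values = [sv.pct_attached_in_presence(obs, "AvM", "AhM", level)
                  for level in ("animal", "attachment_site", "cluster")]
        assert values[0] >= values[1] >= values[2]


def test_pct_units_coinfested(coinfestation_obs):
    pct = sv.pct_units_coinfested(coinfestation_obs, "AvM", "AhM")
    assert pct == pytest.approx(100 * 36 / 61)
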