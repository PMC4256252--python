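"""Cohort construction: sex, mortality sampling, onset quotas, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adscreensim import RunConfig
from adscreensim.fixtures import (
    Fixtures,
    IncidenceModel,
    LifeTable,
    SexProportions,
)
from adscreensim.population import (
    assign_ad_onsets,
    assign_sex,
    build_cohort,
    conversion_quotas,
    incidence_rate,
    sample_death_age_no_ad,
    sample_death_ages,
    validate_population,
)


def _flat_life_table(q=0.1, start=100, n=3):
    qs = np.full(n, q)
    qs[-1] = 1.0
    return LifeTable(start_age=start, q_male=qs, q_female=qs)


class TestAssignSex:
    def test_degenerate_proportions(self, rng):
        sp1 = SexProportions(prop_female={55: 1.0})
        assert assign_sex(100, 55, sp1, rng).all()
        sp0 = SexProportions(prop_female={55: 0.0})
        assert not assign_sex(100, 55, sp0, rng).any()

    def test_large_sample_fraction(self, rng):
        sp = SexProportions(prop_female={55: 0.55})
        frac = assign_sex(1_000_000, 55, sp, rng).mean()
        assert abs(frac - 0.55) < 0.002  # binomial 99% interval at n=1e6

    def test_missing_base_age_raises(self, rng):
        with pytest.raises(Exception, match="base age"):
            assign_sex(10, 60, SexProportions(prop_female={55: 0.5}), rng)


class TestDeathSampling:
    def test_certain_death_at_base_age(self, rng):
        lt = _flat_life_table(q=1.0)
        assert sample_death_age_no_ad("male", 100, lt, rng) == 100

    def test_cap_when_no_draw_fires(self, rng):
        qs = np.zeros(21)
        qs[-1] = 1.0
        lt = LifeTable(start_age=100, q_male=qs, q_female=qs)
        # q=0 until the terminal age 120, whose q=1 forces death at the cap
        ages = sample_death_ages(np.zeros(50, dtype=bool), 100, lt, rng)
        assert (ages == 120).all()

    def test_geometric_mean_death_age(self, rng):
        # constant q=0.1 from age 55: death age ~ 55 + Geometric time,
        # E = (1-q)/q ~= 9 (cap effects negligible over 65 years)
        qs = np.full(66, 0.1)
        qs[-1] = 1.0
        lt = LifeTable(start_age=55, q_male=qs, q_female=qs)
        ages = sample_death_ages(np.zeros(100_000, dtype=bool), 55, lt, rng)
        assert ages.mean() == pytest.approx(55 + 9.0, abs=0.15)

    def test_scalar_and_vector_agree_in_distribution(self, rng):
        lt = _flat_life_table(q=0.5)
        scalar = [
            sample_death_age_no_ad("female", 100, lt, np.random.default_rng(s))
            for s in range(4000)
        ]
        vector = sample_death_ages(
            np.ones(4000, dtype=bool), 100, lt, np.random.default_rng(99)
        )
        assert np.mean(scalar) == pytest.approx(np.mean(vector), abs=0.05)


class TestIncidenceQuotas:
    def test_quota_bookkeeping_is_exact(self):
        model = IncidenceModel(lambda60=0.005, doubling_time=5.0)
        ages, quotas = conversion_quotas(100_000, 60, model)
        # independently recompute with plain python floats
        remaining, carry, expected = 100_000, 0.0, []
        for age in ages:
            x = incidence_rate(int(age), model) * remaining + carry
            k = int(np.floor(x + 0.5))
            k = max(0, min(k, remaining))
            carry, remaining = x - k, remaining - k
            expected.append(k)
        assert quotas.tolist() == expected
        assert quotas.sum() <= 100_000

    @given(lam=st.floats(1e-4, 0.02), n=st.integers(100, 5000))
    @settings(max_examples=25, deadline=None)
    def test_quota_totals_never_exceed_cohort(self, lam, n):
        ages, quotas = conversion_quotas(n, 55, IncidenceModel(lambda60=lam))
        assert quotas.min() >= 0
        assert quotas.sum() <= n

    def test_zero_incidence_gives_no_onsets(self):
        risk = np.random.default_rng(0).uniform(size=500)
        death = np.full(500, 90)
        model = IncidenceModel(lambda60=1e-12)
        onset = assign_ad_onsets(risk, death, 55, model)
        assert np.isnan(onset).all()

    def test_certain_incidence_converts_everyone_in_year_one(self):
        risk = np.random.default_rng(0).uniform(size=500)
        death = np.full(500, 90)
        model = IncidenceModel(lambda60=1.0)  # rate clips to 1 at all ages >= 60
        onset = assign_ad_onsets(risk, death, 60, model)
        assert (onset == 60).all()

    def test_highest_risk_convert_first(self):
        rng = np.random.default_rng(1)
        risk = rng.uniform(size=2000)
        death = np.full(2000, 100)
        onset = assign_ad_onsets(risk, death, 60, IncidenceModel(lambda60=0.01))
        destined = np.isfinite(onset)
        if destined.any() and (~destined).any():
            assert risk[destined].min() > risk[~destined].max()
        # earlier onset years hold strictly higher risk scores than later ones
        import pandas as pd

        by_year = (
            pd.DataFrame({"onset": onset[destined], "risk": risk[destined]})
            .groupby("onset")["risk"]
            .agg(["min", "max"])
            .sort_index()
        )
        assert np.all(by_year["min"].to_numpy()[:-1] >= by_year["max"].to_numpy()[1:])

    def test_alive_only_risk_set_never_censors(self):
        rng = np.random.default_rng(2)
        risk = rng.uniform(size=5000)
        death = rng.integers(60, 90, size=5000)
        onset = assign_ad_onsets(
            risk, death, 55, IncidenceModel(lambda60=0.005), quota_risk_set="alive"
        )
        destined = np.isfinite(onset)
        assert destined.any()
        assert np.all(onset[destined] < death[destined])

    def test_monotone_in_lambda60(self):
        rng = np.random.default_rng(3)
        risk = rng.uniform(size=20_000)
        death = np.full(20_000, 95)
        totals = []
        for lam in (0.0005, 0.001, 0.002):
            onset = assign_ad_onsets(risk, death, 55, IncidenceModel(lambda60=lam))
            eff = np.isfinite(onset) & (onset < death)
            totals.append(int(eff.sum()))
        assert totals[0] < totals[1] < totals[2]


class TestBuildCohort:
    def test_deterministic_given_seed(self, toy_fixtures):
        cfg = RunConfig(population_size=2000, seed=42)
        a = build_cohort(cfg, toy_fixtures)
        b = build_cohort(cfg, toy_fixtures)
        np.testing.assert_array_equal(a.death_age_no_ad, b.death_age_no_ad)
        np.testing.assert_array_equal(a.onset_age, b.onset_age)
        np.testing.assert_array_equal(a.u_class, b.u_class)

    def test_invariants(self, toy_fixtures):
        cfg = RunConfig(population_size=5000, seed=1)
        c = build_cohort(cfg, toy_fixtures)
        assert (c.death_age_no_ad >= c.base_age).all()
        assert (c.death_age_no_ad <= 120).all()
        destined = np.isfinite(c.onset_age)
        assert (c.onset_age[destined] >= c.base_age).all()
        assert ((c.risk >= 0) & (c.risk <= 1)).all()

    def test_oracle_equivalence_small_cohort(self, toy_fixtures):
        """A naive per-individual reimplementation with the same seed stream
        reproduces every death age and onset age of a 100-person cohort."""
        cfg = RunConfig(population_size=100, seed=17)
        cohort = build_cohort(cfg, toy_fixtures)

        streams = np.random.SeedSequence(17).spawn(6)
        life, sexes, model = (
            toy_fixtures.life_table,
            toy_fixtures.sex_proportions,
            toy_fixtures.incidence,
        )
        n, base = 100, cfg.base_age
        female = np.random.default_rng(streams[0]).uniform(size=n) < sexes.at(base)
        assert (female == cohort.female).all()

        death_rng = np.random.default_rng(streams[1])
        death = [120] * n
        undecided = list(range(n))
        for age in range(base, 120):
            draws = death_rng.uniform(size=len(undecided))
            still = []
            for u, i in zip(draws, undecided):
                q = life.q_at(age, "female" if female[i] else "male")
                if u < q:
                    death[i] = age
                else:
                    still.append(i)
            undecided = still
        assert death == cohort.death_age_no_ad.tolist()

        risk = np.random.default_rng(streams[2]).uniform(size=n)
        assert (risk == cohort.risk).all()
        order = sorted(range(n), key=lambda i: (-risk[i], i))
        onset = [float("nan")] * n
        remaining, carry, cum = n, 0.0, 0
        for age in range(base, 120):
            x = model.rate(age) * remaining + carry
            k = max(0, min(int(np.floor(x + 0.5)), remaining))
            carry = x - k
            remaining -= k
            for i in order[cum : cum + k]:
                onset[i] = float(age)
            cum += k
        np.testing.assert_array_equal(np.asarray(onset), cohort.onset_age)

    def test_no_individual_converts_before_base_age(self, toy_fixtures):
        c = build_cohort(RunConfig(population_size=3000, seed=5), toy_fixtures)
        destined = np.isfinite(c.onset_age)
        assert (c.onset_age[destined] >= c.base_age).all()

    def test_cohort_csv_round_trip(self, toy_fixtures, tmp_path):
        import pandas as pd

        c = build_cohort(RunConfig(population_size=200, seed=5), toy_fixtures)
        p = tmp_path / "cohort.csv"
        c.to_csv(p)
        df = pd.read_csv(p)
        assert len(df) == 200
        np.testing.assert_array_equal(df["death_age_no_ad"], c.death_age_no_ad)


class TestValidatePopulation:
    def test_survival_matches_product_survival(self, toy_fixtures):
        cfg = RunConfig(population_size=200_000, seed=23)
        cohort = build_cohort(cfg, toy_fixtures)
        report = validate_population(cohort, toy_fixtures)
        # binomial error bound at n=2e5 is ~0.1pp; assert the 0.5pp contract
        assert report.max_survival_abs_dev < 0.005

    def test_conversions_match_quotas_exactly(self, toy_fixtures):
        cfg = RunConfig(population_size=200_000, seed=23)
        cohort = build_cohort(cfg, toy_fixtures)
        report = validate_population(cohort, toy_fixtures)
        assert (report.incidence["conversions"] == report.incidence["quota"]).all()
        assert report.max_incidence_rel_dev < 0.10
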