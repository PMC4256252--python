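"""Untreated-world cohort construction.

Each simulated individual receives a sex, a non-AD death age sampled year by
year from the life table, a uniform conversion-risk score, and possibly a
destined AD onset age.  Onsets are assigned by an annual quota mechanism
calibrated to the incidence model: each year the incidence-implied number of
new converters (rate x not-yet-converted count, rounded with carry) is taken
from the not-yet-converted individuals with the highest risk scores.  By
default the quota denominator is the *original* cohort and conversions may be
assigned to the already-dead; such censored conversions are recorded but
contribute nothing downstream.

The RNG draw discipline is fixed so an independent per-individual
reimplementation can reproduce a cohort exactly: from ``SeedSequence(seed)``
six children are spawned in order (sex, death, risk, AD paths,
classification/harm/discontinuation/cancellation uniforms, trials); death
sampling draws one uniform per not-yet-dead individual per year, in id order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fixtures import AGE_CAP, Fixtures, IncidenceModel, LifeTable, SexProportions

__all__ = [
    "Individual",
    "Cohort",
    "assign_sex",
    "sample_death_age_no_ad",
    "sample_death_ages",
    "incidence_rate",
    "conversion_quotas",
    "assign_ad_onsets",
    "build_cohort",
    "validate_population",
    "PopulationReport",
]

# spawn order of child seeds in build_cohort
_STREAMS = ("sex", "death", "risk", "paths", "uniforms", "trials")


@dataclass(frozen=True)
class Individual:
    """Scalar view of one cohort member's untreated-world life history."""

    id: int
    sex: str
    base_age: int
    risk_score: float
    death_age_no_ad: int
    ad_onset_age: int | None
    diagnostic_label: str | None = None


@dataclass
class Cohort:
    """A simulated population of AD-free adults at a common base age.

    Array fields are aligned by individual id (= array index).  ``onset_age``
    is NaN for individuals never destined to convert.  The four ``u_*``
    uniforms are latent per-individual draws consumed by screening and
    treatment, stored here so that every strategy and parameter setting sees
    identical randomness (common random numbers).
    """

    base_age: int
    female: np.ndarray
    risk: np.ndarray
    death_age_no_ad: np.ndarray
    onset_age: np.ndarray
    u_class: np.ndarray
    u_harm: np.ndarray
    u_disc: np.ndarray
    u_cancel: np.ndarray
    path_seed: np.random.SeedSequence
    trial_seed: np.random.SeedSequence
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.female.size

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n)

    @property
    def effective_converter(self) -> np.ndarray:
        """Destined converters whose onset precedes the non-AD death."""
        return np.isfinite(self.onset_age) & (self.onset_age < self.death_age_no_ad)

    @property
    def censored_converter(self) -> np.ndarray:
        return np.isfinite(self.onset_age) & (self.onset_age >= self.death_age_no_ad)

    def individual(self, i: int) -> Individual:
        onset = self.onset_age[i]
        return Individual(
            id=int(i),
            sex="female" if self.female[i] else "male",
            base_age=self.base_age,
            risk_score=float(self.risk[i]),
            death_age_no_ad=int(self.death_age_no_ad[i]),
            ad_onset_age=None if np.isnan(onset) else int(onset),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sex": np.where(self.female, "female", "male"),
                "base_age": self.base_age,
                "risk_score": self.risk,
                "death_age_no_ad": self.death_age_no_ad,
                "ad_onset_age": self.onset_age,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def assign_sex(
    n: int,
    base_age: int,
    sex_proportions: SexProportions,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean is-female vector of length ``n``, Bernoulli(prop_female)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = sex_proportions.at(base_age)
    return rng.uniform(size=n) < p


def sample_death_age_no_ad(
    sex: str,
    base_age: int,
    life_table: LifeTable,
    rng: np.random.Generator,
    cap: int = AGE_CAP,
) -> int:
    """Scalar reference sampler: first year y >= base_age with draw < q(y,sex).

    Returns ``cap`` if no draw fires before it (the terminal-age q of 1 makes
    that possible only when the table ends below the cap).
    """
    for age in range(base_age, cap):
        if rng.uniform() < life_table.q_at(age, sex):
            return age
    return cap


def sample_death_ages(
    female: np.ndarray,
    base_age: int,
    life_table: LifeTable,
    rng: np.random.Generator,
    cap: int = AGE_CAP,
) -> np.ndarray:
    """Vectorized death ages; one uniform per not-yet-dead individual per year.

    Draws are made in id order within each year, which is the contract the
    oracle-equivalence tests rely on.
    """
    n = female.size
    death = np.full(n, cap, dtype=np.int64)
    undecided = np.arange(n)
    for age in range(base_age, cap):
        if undecided.size == 0:
            break
        u = rng.uniform(size=undecided.size)
        q = np.where(
            female[undecided],
            life_table.q_at(age, "female"),
            life_table.q_at(age, "male"),
        )
        died = u < q
        death[undecided[died]] = age
        undecided = undecided[~died]
    return death


def incidence_rate(age, incidence_model: IncidenceModel):
    """Annual AD incidence at ``age`` (Brookmeyer-type exponential)."""
    return incidence_model.rate(age)


def conversion_quotas(
    n: int,
    base_age: int,
    incidence_model: IncidenceModel,
    cap: int = AGE_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer conversion quotas per year under the original-cohort risk set.

    Each year's quota is ``rate(age) * remaining`` rounded to the nearest
    integer, with the fractional remainder carried into the next year so
    long-run totals are unbiased.  ``remaining`` counts not-yet-converted
    members of the original cohort, alive or dead.
    """
    ages = np.arange(base_age, cap)
    quotas = np.zeros(ages.size, dtype=np.int64)
    remaining = n
    carry = 0.0
    for i, age in enumerate(ages):
        x = incidence_model.rate(int(age)) * remaining + carry
        k = int(np.floor(x + 0.5))
        k = max(0, min(k, remaining))
        carry = x - k
        quotas[i] = k
        remaining -= k
    return ages, quotas


def assign_ad_onsets(
    risk: np.ndarray,
    death_age_no_ad: np.ndarray,
    base_age: int,
    incidence_model: IncidenceModel,
    quota_risk_set: str = "original",
    cap: int = AGE_CAP,
) -> np.ndarray:
    """Destined onset ages (NaN = never), by risk-rank quota.

    ``quota_risk_set="original"``: quotas computed on the original cohort and
    filled from the globally highest-risk not-yet-converted individuals,
    alive or dead.  ``"alive"``: each year's quota uses the living
    not-yet-converted count and only living individuals may convert.
    Risk ties break by id (ascending), so assignment is deterministic given
    the risk scores.
    """
    n = risk.size
    onset = np.full(n, np.nan)
    order = np.lexsort((np.arange(n), -risk))  # risk desc, id asc
    if quota_risk_set == "original":
        ages, quotas = conversion_quotas(n, base_age, incidence_model, cap)
        cum = 0
        for age, k in zip(ages, quotas):
            if k:
                onset[order[cum : cum + k]] = age
                cum += k
            if cum >= n:
                break
    elif quota_risk_set == "alive":
        converted_sorted = np.zeros(n, dtype=bool)  # in risk order
        death_sorted = death_age_no_ad[order]
        carry = 0.0
        for age in range(base_age, cap):
            eligible = ~converted_sorted & (death_sorted > age)
            m = int(eligible.sum())
            if m == 0:
                continue
            x = incidence_model.rate(age) * m + carry
            k = max(0, min(int(np.floor(x + 0.5)), m))
            carry = x - k
            if k:
                pick = np.nonzero(eligible)[0][:k]
                converted_sorted[pick] = True
                onset[order[pick]] = age
    else:
        raise ValueError("quota_risk_set must be 'original' or 'alive'")
    return onset


def build_cohort(config, fixtures: Fixtures) -> Cohort:
    """Build the full untreated-world cohort; deterministic given config.seed."""
    n = config.population_size
    base = config.base_age
    if base < fixtures.life_table.start_age:
        raise ValueError("life table does not cover the base age")
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    streams = dict(zip(_STREAMS, children))

    female = assign_sex(
        n, base, fixtures.sex_proportions, np.random.default_rng(streams["sex"])
    )
    death = sample_death_ages(
        female, base, fixtures.life_table, np.random.default_rng(streams["death"])
    )
    risk = np.random.default_rng(streams["risk"]).uniform(size=n)
    onset = assign_ad_onsets(
        risk, death, base, fixtures.incidence, config.quota_risk_set
    )
    u_rng = np.random.default_rng(streams["uniforms"])
    u_class = u_rng.uniform(size=n)
    u_harm = u_rng.uniform(size=n)
    u_disc = u_rng.uniform(size=n)
    u_cancel = u_rng.uniform(size=n)
    return Cohort(
        base_age=base,
        female=female,
        risk=risk,
        death_age_no_ad=death,
        onset_age=onset,
        u_class=u_class,
        u_harm=u_harm,
        u_disc=u_disc,
        u_cancel=u_cancel,
        path_seed=streams["paths"],
        trial_seed=streams["trials"],
        provenance={
            "seed": config.seed,
            "population_size": n,
            "base_age": base,
            "quota_risk_set": config.quota_risk_set,
            "fixtures": fixtures.source,
            "lambda60": fixtures.incidence.lambda60,
            "doubling_time": fixtures.incidence.doubling_time,
        },
    )


@dataclass
class PopulationReport:
    """Actual-vs-predicted calibration tables for a built cohort."""

    survival: pd.DataFrame
    incidence: pd.DataFrame
    max_survival_abs_dev: float
    max_incidence_rel_dev: float


def validate_population(cohort: Cohort, fixtures: Fixtures) -> PopulationReport:
    """Compare simulated survival and conversion against analytic expectations.

    Survival: fraction with ``death_age_no_ad > age`` versus the life-table
    product survival mixed by the cohort's realized sex split.  Conversion:
    destined conversions per year versus independently recomputed quotas, and
    the implied annual conversion rate versus the incidence model.
    """
    base = cohort.base_age
    life = fixtures.life_table
    ages = np.arange(base, life.terminal_age + 1)
    f = float(cohort.female.mean())
    predicted = f * life.survival(base, "female") + (1 - f) * life.survival(base, "male")
    actual = (cohort.death_age_no_ad[None, :] > ages[:, None]).mean(axis=1)
    survival = pd.DataFrame(
        {"age": ages, "actual": actual, "predicted": predicted}
    )
    max_surv_dev = float(np.abs(actual - predicted).max())

    q_ages, quotas = conversion_quotas(cohort.n, base, fixtures.incidence)
    onset = cohort.onset_age
    destined = np.isfinite(onset)
    counts = np.zeros(q_ages.size, dtype=np.int64)
    idx = (onset[destined] - base).astype(int)
    np.add.at(counts, idx, 1)
    not_yet = cohort.n - np.concatenate(([0], np.cumsum(counts)[:-1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        actual_rate = np.where(not_yet > 0, counts / not_yet, np.nan)
    model_rate = fixtures.incidence.rate(q_ages)
    incidence = pd.DataFrame(
        {
            "age": q_ages,
            "conversions": counts,
            "quota": quotas,
            "actual_rate": actual_rate,
            "model_rate": model_rate,
        }
    )
    mask = (model_rate > 1e-3) & np.isfinite(actual_rate)
    max_inc_dev = float(
        np.max(np.abs(actual_rate[mask] - model_rate[mask]) / model_rate[mask])
        if mask.any()
        else 0.0
    )
    return PopulationReport(
        survival=survival,
        incidence=incidence,
        max_survival_abs_dev=max_surv_dev,
        max_incidence_rel_dev=max_inc_dev,
    )
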