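"""Calibration fixtures: life tables, sex proportions and the AD incidence model.

The simulation is calibrated against three small tables:

* a sex-specific annual life table (age, sex -> annual probability of death),
* a base-age -> proportion-female table used to assign sex at cohort entry,
* an exponential age-incidence model for Alzheimer disease (incidence doubles
  every ``doubling_time`` years above age 60 and halves every 5 years below it).

The packaged defaults are *synthetic* stand-ins: smooth Gompertz approximations
to the CDC US period life table and US-census sex proportions, shipped as plain
CSV under ``adscreensim/data``.  :func:`make_toy_fixtures` builds even smaller
internally-consistent fixtures so every module can be exercised without any
transcribed data at all.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "AGE_CAP",
    "LifeTable",
    "SexProportions",
    "IncidenceModel",
    "Fixtures",
    "FixtureError",
    "load_life_table",
    "load_sex_proportions",
    "default_life_table",
    "default_sex_proportions",
    "default_incidence_model",
    "default_fixtures",
    "make_toy_fixtures",
    "write_summary",
    "read_summary",
]

SEXES = ("male", "female")

#: All individuals die by this age; the life table's terminal row enforces it.
AGE_CAP = 120


class FixtureError(ValueError):
    """Raised when a calibration fixture fails validation."""


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific annual death probabilities over a contiguous age span.

    Both sexes must cover the same contiguous span, and the terminal age must
    have ``q == 1`` so death is forced at or before the model's age cap.
    """

    start_age: int
    q_male: np.ndarray
    q_female: np.ndarray

    def __post_init__(self) -> None:
        qm = np.asarray(self.q_male, dtype=float)
        qf = np.asarray(self.q_female, dtype=float)
        object.__setattr__(self, "q_male", qm)
        object.__setattr__(self, "q_female", qf)
        if qm.ndim != 1 or qf.ndim != 1 or qm.size == 0:
            raise FixtureError("life table must hold one 1-d q vector per sex")
        if qm.size != qf.size:
            raise FixtureError("life table must cover the same ages for both sexes")
        for sex, q in (("male", qm), ("female", qf)):
            if np.any((q < 0) | (q > 1)) or np.any(~np.isfinite(q)):
                raise FixtureError(f"{sex} q values must lie in [0, 1]")
            if q[-1] != 1.0:
                raise FixtureError(
                    f"{sex} q at the terminal age {self.terminal_age} must be 1 "
                    "(the model forces death by its age cap)"
                )
        if self.terminal_age > AGE_CAP:
            raise FixtureError(f"life table extends beyond the age cap {AGE_CAP}")

    @property
    def terminal_age(self) -> int:
        return self.start_age + self.q_male.size - 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.terminal_age + 1)

    def q(self, sex: str) -> np.ndarray:
        if sex not in SEXES:
            raise FixtureError(f"unknown sex {sex!r}")
        return self.q_male if sex == "male" else self.q_female

    def q_at(self, age: int, sex: str) -> float:
        """Annual death probability at ``age``; 1.0 beyond the terminal age."""
        if age < self.start_age:
            raise FixtureError(f"age {age} below life-table start {self.start_age}")
        if age > self.terminal_age:
            return 1.0
        return float(self.q(sex)[age - self.start_age])

    def survival(self, base_age: int, sex: str) -> np.ndarray:
        """P(death age > a) for a = base_age .. terminal_age (product survival)."""
        if base_age < self.start_age:
            raise FixtureError("base age not covered by life table")
        q = self.q(sex)[base_age - self.start_age :]
        return np.cumprod(1.0 - q)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            rows.append(
                pd.DataFrame({"age": self.ages, "sex": sex, "q": self.q(sex)})
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        missing = {"age", "sex", "q"} - set(df.columns)
        if missing:
            raise FixtureError(f"life table missing column(s): {sorted(missing)}")
        per_sex = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].sort_values("age")
            if sub.empty:
                raise FixtureError(f"life table has no rows for sex {sex!r}")
            ages = sub["age"].to_numpy(dtype=int)
            if np.any(np.diff(ages) != 1):
                raise FixtureError(f"{sex} ages are not contiguous")
            per_sex[sex] = (int(ages[0]), sub["q"].to_numpy(dtype=float))
        (sm, qm), (sf, qf) = per_sex["male"], per_sex["female"]
        if sm != sf:
            raise FixtureError("male and female age spans must start at the same age")
        return cls(start_age=sm, q_male=qm, q_female=qf)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SexProportions:
    """Mapping base age -> proportion female at cohort entry."""

    prop_female: dict[int, float]

    def __post_init__(self) -> None:
        for age, p in self.prop_female.items():
            if not 0.0 <= p <= 1.0:
                raise FixtureError(f"proportion female at base age {age} not in [0,1]")

    def at(self, base_age: int) -> float:
        try:
            return self.prop_female[int(base_age)]
        except KeyError:
            raise FixtureError(
                f"base age {base_age} missing from sex-proportion table "
                f"(available: {sorted(self.prop_female)})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        ages = sorted(self.prop_female)
        return pd.DataFrame(
            {"base_age": ages, "prop_female": [self.prop_female[a] for a in ages]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SexProportions":
        missing = {"base_age", "prop_female"} - set(df.columns)
        if missing:
            raise FixtureError(f"sex proportions missing column(s): {sorted(missing)}")
        return cls(
            prop_female=dict(
                zip(df["base_age"].astype(int), df["prop_female"].astype(float))
            )
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class IncidenceModel:
    """Exponential age model of annual AD incidence.

    ``rate(age) = lambda60 * 2**((age - 60) / doubling_time)`` for ages >= 60,
    clipped to [0, 1].  Below 60 the incidence halves every
    ``sub60_halving_interval`` years (fixed at 5 by convention):
    ``rate(age) = lambda60 * 2**(-(60 - age) / 5)``.
    """

    lambda60: float = 0.001
    doubling_time: float = 5.0
    sub60_halving_interval: float = 5.0

    def __post_init__(self) -> None:
        if self.lambda60 <= 0:
            raise FixtureError("lambda60 must be positive")
        if self.doubling_time <= 0:
            raise FixtureError("doubling_time must be positive")
        if self.sub60_halving_interval <= 0:
            raise FixtureError("sub60_halving_interval must be positive")

    def rate(self, age):
        """Annual AD incidence probability at ``age`` (scalar or array)."""
        age = np.asarray(age, dtype=float)
        above = self.lambda60 * 2.0 ** ((age - 60.0) / self.doubling_time)
        below = self.lambda60 * 2.0 ** (-(60.0 - age) / self.sub60_halving_interval)
        out = np.clip(np.where(age >= 60.0, above, below), 0.0, 1.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Fixtures:
    """Bundle of the three calibration inputs used to build a cohort."""

    life_table: LifeTable
    sex_proportions: SexProportions
    incidence: IncidenceModel
    source: str = "packaged"


# ---------------------------------------------------------------------------
# loading / packaged defaults


def _read_fixture_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FixtureError(f"fixture file not found: {path}")
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FixtureError(f"could not parse fixture file {path}: {exc}") from exc


def load_life_table(path: str | Path) -> LifeTable:
    """Load and validate a life table CSV with columns ``age,sex,q``."""
    return LifeTable.from_frame(_read_fixture_csv(path))


def load_sex_proportions(path: str | Path) -> SexProportions:
    """Load and validate a ``base_age,prop_female`` CSV."""
    return SexProportions.from_frame(_read_fixture_csv(path))


def _data_path(name: str) -> Path:
    return Path(resources.files("adscreensim").joinpath("data", name))  # type: ignore[arg-type]


def default_life_table() -> LifeTable:
    """Packaged synthetic (Gompertz, CDC-style) US life table."""
    return load_life_table(_data_path("life_table_synthetic_us.csv"))


def default_sex_proportions() -> SexProportions:
    """Packaged synthetic (US-census-style) base-age sex proportions."""
    return load_sex_proportions(_data_path("sex_proportions_synthetic_us.csv"))


def default_incidence_model() -> IncidenceModel:
    return IncidenceModel()


def default_fixtures() -> Fixtures:
    return Fixtures(
        life_table=default_life_table(),
        sex_proportions=default_sex_proportions(),
        incidence=default_incidence_model(),
        source="packaged",
    )


# ---------------------------------------------------------------------------
# toy fixtures


def make_toy_fixtures(seed: int = 0) -> tuple[LifeTable, SexProportions, IncidenceModel]:
    """Small internally consistent synthetic fixtures for download-free tests.

    The toy life table follows a Gompertz-like hazard (monotone non-decreasing
    in age, q=1 at the terminal age); the toy incidence model doubles every
    ``doubling_time`` years above 60 and halves every 5 years below.
    Deterministic for a given ``seed``.
    """
    rng = np.random.default_rng(seed)
    start, terminal = 55, 110
    n = terminal - start + 1
    q0 = 0.004 * float(rng.uniform(0.8, 1.5))
    growth = float(rng.uniform(0.075, 0.10))
    ages = np.arange(n)
    base_q = np.minimum(0.9, q0 * np.exp(growth * ages))
    sex_gap = float(rng.uniform(0.6, 0.9))  # female mortality advantage
    q_male = base_q.copy()
    q_female = np.minimum(0.9, base_q * sex_gap)
    q_male[-1] = q_female[-1] = 1.0
    life = LifeTable(start_age=start, q_male=q_male, q_female=q_female)

    props = {
        a: float(np.clip(0.5 + rng.uniform(0.0, 0.08), 0.0, 1.0))
        for a in (55, 60, 65, 70, 75)
    }
    sexes = SexProportions(prop_female=props)

    incidence = IncidenceModel(
        lambda60=float(rng.uniform(0.0008, 0.003)),
        doubling_time=float(rng.uniform(4.0, 6.0)),
    )
    return life, sexes, incidence


# ---------------------------------------------------------------------------
# result output

#: Column order of the per-strategy summary table (one row per age/strategy).
SUMMARY_COLUMNS = [
    "base_age",
    "strategy",
    "net_qaly_per_1000_screened",
    "net_qaly_per_1000_treated",
    "n_treated_per_1000",
    "n_false_positive_per_1000",
    "fp_net_qaly_per_1000_screened",
    "sd_net_per_1000_screened",
    "n_trials",
    "trial_size",
]


def write_summary(results, path: str | Path) -> None:
    """Write trial summaries to CSV, one row per (age, strategy).

    ``results`` may be an iterable of ``TrialSummary`` dataclasses or plain
    dicts with the same field names.  An empty iterable yields a header-only
    CSV.
    """
    rows = []
    for r in results:
        if dataclasses.is_dataclass(r):
            r = dataclasses.asdict(r)
        rows.append({c: r.get(c) for c in SUMMARY_COLUMNS})
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read back a summary CSV written by :func:`write_summary`."""
    return pd.read_csv(path)
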