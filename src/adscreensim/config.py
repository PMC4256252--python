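"""Run configuration: one YAML document fully determines a simulation run.

The default configuration enumerates every base-case parameter (utilities,
transition probabilities, intervention and diagnostic parameters, incidence
coefficients), so a run is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fixtures import (
    Fixtures,
    IncidenceModel,
    default_life_table,
    default_sex_proportions,
    load_life_table,
    load_sex_proportions,
)
from .progression import ProgressionParams
from .screening import ScreeningParams
from .treatment import TreatmentParams

__all__ = ["RunConfig", "load_config", "PAPER_BASE_AGES"]

#: Base ages with published sex proportions; other ages are allowed if the
#: sex-proportion fixture covers them.
PAPER_BASE_AGES = (55, 60, 65, 70, 75)

STRATEGIES = ("screen_and_treat", "treat_all", "none")


@dataclass
class RunConfig:
    base_age: int = 55
    population_size: int = 1_000_000
    n_trials: int = 1000
    trial_size: int = 1000
    seed: int = 0
    strategy: str = "screen_and_treat"
    #: "original": annual conversion quotas use the original cohort as
    #: denominator and may assign onsets to the already-dead (censored);
    #: "alive": quotas and draws restricted to the living.
    quota_risk_set: str = "original"
    incidence: IncidenceModel = field(default_factory=IncidenceModel)
    progression: ProgressionParams = field(default_factory=ProgressionParams)
    treatment: TreatmentParams = field(default_factory=TreatmentParams)
    screening: ScreeningParams = field(default_factory=ScreeningParams)
    #: optional fixture file overrides; None = packaged synthetic fixtures
    life_table_path: str | None = None
    sex_proportions_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("population_size", "n_trials", "trial_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.quota_risk_set not in ("original", "alive"):
            raise ValueError("quota_risk_set must be 'original' or 'alive'")

    def fixtures(self) -> Fixtures:
        life = (
            load_life_table(self.life_table_path)
            if self.life_table_path
            else default_life_table()
        )
        sexes = (
            load_sex_proportions(self.sex_proportions_path)
            if self.sex_proportions_path
            else default_sex_proportions()
        )
        return Fixtures(
            life_table=life,
            sex_proportions=sexes,
            incidence=self.incidence,
            source=self.life_table_path or "packaged",
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "base_age": self.base_age,
            "population_size": self.population_size,
            "n_trials": self.n_trials,
            "trial_size": self.trial_size,
            "seed": self.seed,
            "strategy": self.strategy,
            "quota_risk_set": self.quota_risk_set,
            "life_table_path": self.life_table_path,
            "sex_proportions_path": self.sex_proportions_path,
            "incidence": dataclasses.asdict(self.incidence),
            "screening": dataclasses.asdict(self.screening),
            "treatment": dataclasses.asdict(self.treatment),
            "progression": {
                "initial_severity": list(self.progression.initial_severity),
                "severity_transitions": [
                    list(r) for r in self.progression.severity_transitions
                ],
                "nh_entry": list(self.progression.nh_entry),
                "ad_utilities": [list(r) for r in self.progression.ad_utilities],
                "no_ad_utilities": list(self.progression.no_ad_utilities),
                "age_band_edges": list(self.progression.age_band_edges),
                "discount_rate": self.progression.discount_rate,
            },
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for simple in (
            "base_age",
            "population_size",
            "n_trials",
            "trial_size",
            "seed",
            "strategy",
            "quota_risk_set",
            "life_table_path",
            "sex_proportions_path",
        ):
            if simple in d:
                kwargs[simple] = d[simple]
        if "incidence" in d:
            kwargs["incidence"] = IncidenceModel(**d["incidence"])
        if "screening" in d:
            kwargs["screening"] = ScreeningParams(**d["screening"])
        if "treatment" in d:
            kwargs["treatment"] = TreatmentParams(**d["treatment"])
        if "progression" in d:
            p = dict(d["progression"])
            for key in ("initial_severity", "nh_entry", "no_ad_utilities", "age_band_edges"):
                if key in p:
                    p[key] = tuple(p[key])
            for key in ("severity_transitions", "ad_utilities"):
                if key in p:
                    p[key] = tuple(tuple(r) for r in p[key])
            kwargs["progression"] = ProgressionParams(**p)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; ``None`` returns base-case defaults."""
    if path is None:
        return RunConfig()
    return RunConfig.from_yaml(path)
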