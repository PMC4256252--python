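"""Diagnostic classification against a 20-year conversion horizon.

The screen is a pure (sensitivity, specificity) gate applied once at the base
age: individuals destined to convert within the horizon screen positive with
probability ``sensitivity``; everyone else screens positive with probability
``1 - specificity``.  Both true and false positives are treated.

By default "converter" means *destined* to convert within the horizon,
whether or not death intervenes first — the pre-test 20-year risk is a
population incidence quantity with no mortality adjustment, and destined
converters who die early still count toward the screen's target condition
(they receive no treatment benefit downstream).  Set
``count_censored_conversions=False`` to require the onset to precede death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LABELS",
    "TP",
    "FP",
    "TN",
    "FN",
    "ScreeningParams",
    "is_horizon_converter",
    "horizon_converters",
    "classify",
    "classify_cohort",
]

LABELS = ("TP", "FP", "TN", "FN")
TP, FP, TN, FN = range(4)


@dataclass(frozen=True)
class ScreeningParams:
    sensitivity: float = 0.65
    specificity: float = 0.95
    horizon_years: int = 20
    #: count destined converters whose death precedes onset as converters
    count_censored_conversions: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0,1]")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError("specificity must lie in [0,1]")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be positive")


def is_horizon_converter(individual, params: ScreeningParams) -> bool:
    """Whether one individual counts as a within-horizon converter.

    The horizon comparison is inclusive: an onset exactly ``horizon_years``
    after the base age counts.  ``individual`` needs ``base_age``,
    ``ad_onset_age`` (None when never destined) and ``death_age_no_ad``.
    """
    onset = individual.ad_onset_age
    if onset is None or (isinstance(onset, float) and np.isnan(onset)):
        return False
    if onset - individual.base_age > params.horizon_years:
        return False
    if not params.count_censored_conversions and onset >= individual.death_age_no_ad:
        return False
    return True


def horizon_converters(
    onset_age: np.ndarray,
    death_age_no_ad: np.ndarray,
    base_age: int,
    params: ScreeningParams,
) -> np.ndarray:
    """Vectorized within-horizon converter mask (NaN onset = never destined)."""
    destined = np.isfinite(onset_age)
    within = destined & (onset_age - base_age <= params.horizon_years)
    if not params.count_censored_conversions:
        within &= onset_age < death_age_no_ad
    return within


def classify(individual, params: ScreeningParams, rng: np.random.Generator) -> str:
    """Assign one diagnostic label ("TP"/"FP"/"TN"/"FN") with a fresh draw."""
    u = rng.uniform()
    if is_horizon_converter(individual, params):
        return "TP" if u < params.sensitivity else "FN"
    return "FP" if u >= params.specificity else "TN"


def classify_cohort(
    converter: np.ndarray,
    u_class: np.ndarray,
    params: ScreeningParams,
) -> np.ndarray:
    """Vectorized diagnostic labels from per-individual classification uniforms.

    Converters screen positive when ``u < sensitivity`` (TP, else FN);
    non-converters screen positive when ``u >= specificity`` (FP, else TN).
    Using a stored uniform per individual makes labels common-random-number
    coupled across parameter settings: raising sensitivity only ever flips
    FN -> TP, raising specificity only FP -> TN.
    """
    labels = np.empty(converter.shape, dtype=np.int8)
    pos_conv = u_class < params.sensitivity
    pos_non = u_class >= params.specificity
    labels[converter & pos_conv] = TP
    labels[converter & ~pos_conv] = FN
    labels[~converter & pos_non] = FP
    labels[~converter & ~pos_non] = TN
    return labels
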