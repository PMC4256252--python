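"""Lead-time-dependent treatment effects, harm and discontinuation.

Treatment starts at the base (screening) age.  Its efficacy is a relative
risk reduction that grows linearly with the lead time between treatment
initiation and the destined AD onset — ``RRR = min(slope * years, ceiling)``
— and is realized as an all-or-nothing cancellation of the destined onset,
drawn once at the onset year and conditional on still being on treatment.
A cancelled onset returns the individual to their untreated non-AD life
course (the pre-drawn life-table death age), avoiding immortal-cohort bias.

While on treatment each year carries an independent probability of a harm
event (a one-time QALY decrement, discounted at the harm year, after which
treatment stops permanently) and of non-harm discontinuation (treatment stops,
no decrement).  Within a year harm is checked before discontinuation.
Individuals whose destined onset is censored by earlier death can be harmed
but can never benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TreatmentParams",
    "relative_risk_reduction",
    "first_event_year",
    "TreatmentOutcome",
    "simulate_treatment_course",
    "net_individual_utility",
]


@dataclass(frozen=True)
class TreatmentParams:
    rrr_slope: float = 0.03
    rrr_ceiling: float = 0.5
    harm_prob: float = 0.001
    harm_magnitude: float = 0.06
    discontinuation_rate: float = 0.05
    #: hook for alternative efficacy mechanisms; only all-or-nothing
    #: onset cancellation is implemented
    prevention_mode: str = "all_or_nothing"

    def __post_init__(self) -> None:
        for name in ("rrr_slope", "rrr_ceiling", "harm_prob", "discontinuation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.harm_magnitude < 0:
            raise ValueError("harm magnitude must be non-negative")
        if self.prevention_mode != "all_or_nothing":
            raise ValueError(
                f"unsupported prevention mode {self.prevention_mode!r}"
            )


def relative_risk_reduction(years_to_onset, params: TreatmentParams):
    """``min(slope * years, ceiling)`` for non-negative lead times."""
    years = np.asarray(years_to_onset, dtype=float)
    if np.any(np.where(np.isfinite(years), years, 0.0) < 0):
        raise ValueError("years to onset must be non-negative")
    out = np.minimum(params.rrr_slope * years, params.rrr_ceiling)
    return float(out) if out.ndim == 0 else out


def first_event_year(u, p: float):
    """First 0-based year an annual-probability event fires, from uniforms.

    Inverse-transform of the geometric distribution: monotone decreasing in
    ``p`` for a fixed uniform, which is what makes paired-seed sensitivity
    curves monotone.  ``p = 0`` maps every uniform to +inf (never fires).
    """
    u = np.asarray(u, dtype=float)
    if p <= 0.0:
        out = np.full(u.shape, np.inf)
    elif p >= 1.0:
        out = np.zeros(u.shape)
    else:
        out = np.floor(np.log1p(-u) / np.log1p(-p))
    return float(out) if out.ndim == 0 else out


@dataclass
class TreatmentOutcome:
    """Treated-world slots for every individual (arrays aligned with cohort).

    ``net`` is the discounted treated-minus-untreated QALY difference under
    common random numbers: a cancelled onset contributes the difference
    between the non-AD tail and the AD-path tail, a harm event subtracts the
    (discounted) one-time decrement, and everyone else contributes zero.
    """

    treated: np.ndarray
    on_treatment_at_onset: np.ndarray
    cancelled: np.ndarray
    harmed: np.ndarray
    harm_year: np.ndarray  # 0-based years since base age; +inf if no harm
    discontinuation_year: np.ndarray  # +inf if never (before treatment end)
    net: np.ndarray


def simulate_treatment_course(
    *,
    treated: np.ndarray,
    y_onset: np.ndarray,
    y_death_no_ad: np.ndarray,
    effective_converter: np.ndarray,
    nonad_tail: np.ndarray,
    ad_tail: np.ndarray,
    u_harm: np.ndarray,
    u_disc: np.ndarray,
    u_cancel: np.ndarray,
    params: TreatmentParams,
    discount_rate: float,
) -> TreatmentOutcome:
    """Vectorized treated-world simulation for a whole cohort.

    All ``y_*`` arguments are 0-based years since the base age.
    ``y_onset`` is +inf for individuals with no expressed (effective) onset;
    ``nonad_tail``/``ad_tail`` are the discounted QALY tails from onset to the
    life-table death age and along the AD path respectively (only read where
    ``effective_converter``).

    Event logic per treated individual: the candidate harm year ``Th`` and
    discontinuation year ``Td`` come from the stored uniforms; treatment stops
    at ``min(Th, Td)`` (harm wins ties).  The individual is on treatment at
    the destined onset iff ``min(Th, Td) >= y_onset``, in which case the onset
    is cancelled with probability ``RRR(y_onset)``.  Harm fires only if it
    precedes discontinuation and falls inside the treated span, which ends at
    onset for non-cancelled converters and at death otherwise.
    """
    n = treated.shape[0]
    th = first_event_year(u_harm, params.harm_prob)
    td = first_event_year(u_disc, params.discontinuation_rate)
    stop = np.minimum(th, td)

    rrr = np.zeros(n)
    eff = effective_converter
    rrr[eff] = relative_risk_reduction(y_onset[eff], params)

    on_at_onset = treated & eff & (stop >= y_onset)
    cancelled = on_at_onset & (u_cancel < rrr)

    # treated span end: onset for converters whose onset still happens,
    # life-table death otherwise (incl. cancelled onsets and never-converters)
    span_end = np.where(eff & ~cancelled, np.minimum(y_onset, y_death_no_ad), y_death_no_ad)
    harmed = treated & (th <= td) & (th < span_end)

    net = np.zeros(n)
    net[cancelled] = nonad_tail[cancelled] - ad_tail[cancelled]
    if params.harm_magnitude > 0 and harmed.any():
        net[harmed] -= params.harm_magnitude * (1.0 - discount_rate) ** th[harmed]

    harm_year = np.where(harmed, th, np.inf)
    disc_year = np.where(treated & (td < th) & (td < span_end), td, np.inf)
    return TreatmentOutcome(
        treated=treated,
        on_treatment_at_onset=on_at_onset,
        cancelled=cancelled,
        harmed=harmed,
        harm_year=harm_year,
        discontinuation_year=disc_year,
        net=net,
    )


def net_individual_utility(outcome: TreatmentOutcome, i: int) -> float:
    """Treated-minus-untreated discounted QALY difference for individual ``i``."""
    return float(outcome.net[i])
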