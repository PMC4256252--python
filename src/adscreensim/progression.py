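"""Markov model of the Alzheimer disease course and QALY accounting.

Disease severity (mild / moderate / severe) and living location (community /
nursing home) are hierarchically structured: severity never improves and a
nursing-home move is never reversed.  Mortality with AD is governed solely by
the severity-specific transition rows; the pre-drawn life-table death age is
discarded at onset.  Utilities are accrued annually — non-AD years by age band,
AD years by severity x location — and discounted as ``(1 - rate)**years`` from
the base (screening) age.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fixtures import AGE_CAP

__all__ = [
    "SEVERITIES",
    "LOCATIONS",
    "DEAD",
    "ProgressionParams",
    "ADPath",
    "discount_factor",
    "utility_without_ad",
    "draw_initial_severity",
    "step_severity",
    "step_location",
    "simulate_ad_course",
    "simulate_ad_paths",
    "life_course_qalys",
]

logger = logging.getLogger(__name__)

SEVERITIES = ("mild", "moderate", "severe")
LOCATIONS = ("community", "nursing_home")

#: Index of the absorbing death state in a transition row (mild, mod, sev, dead).
DEAD = 3

# Annual transition probabilities, one row per current severity, columns
# (mild, moderate, severe, dead).  Severity never improves, so entries below
# the diagonal are structurally zero.
_DEFAULT_TRANSITIONS = (
    (0.614, 0.322, 0.042, 0.021),
    (0.0, 0.565, 0.339, 0.053),
    (0.0, 0.0, 0.847, 0.153),
)


@dataclass
class ProgressionParams:
    """Parameters of the AD course model and QALY accounting.

    ``severity_transitions`` rows are renormalized proportionally to sum to 1
    at construction (the published moderate row sums to 0.957); a log message
    records any renormalization.  ``no_ad_utilities`` applies to the age bands
    [55,65), [65,75), [75,85), [85, cap]; ages below 55 reuse the first band.
    """

    initial_severity: tuple[float, float, float] = (0.6, 0.4, 0.0)
    severity_transitions: tuple = _DEFAULT_TRANSITIONS
    nh_entry: tuple[float, float, float] = (0.038, 0.110, 0.259)
    ad_utilities: tuple = ((0.37, 0.52), (0.18, 0.21), (0.02, 0.0))
    no_ad_utilities: tuple[float, float, float, float] = (0.872, 0.836, 0.809, 0.775)
    age_band_edges: tuple[int, int, int] = (65, 75, 85)
    discount_rate: float = 0.03

    # filled in __post_init__
    transitions: np.ndarray = field(init=False, repr=False)
    _initial: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        init = np.asarray(self.initial_severity, dtype=float)
        if init.shape != (3,) or np.any(init < 0) or init.sum() <= 0:
            raise ValueError("initial severity distribution malformed")
        self._initial = init / init.sum()

        raw = np.asarray(self.severity_transitions, dtype=float)
        if raw.shape != (3, 4) or np.any(raw < 0):
            raise ValueError("severity transitions must be a non-negative 3x4 table")
        if np.any(np.tril(raw[:, :3], k=-1) != 0):
            raise ValueError("severity may not improve (lower-triangle must be 0)")
        sums = raw.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("each severity transition row needs positive mass")
        if np.any(np.abs(sums - 1.0) > 1e-9):
            logger.info(
                "renormalizing severity transition rows with sums %s", sums.round(4)
            )
        self.transitions = raw / sums[:, None]

        nh = np.asarray(self.nh_entry, dtype=float)
        if nh.shape != (3,) or np.any((nh < 0) | (nh > 1)):
            raise ValueError("nursing-home entry probabilities must lie in [0,1]")
        adu = np.asarray(self.ad_utilities, dtype=float)
        if adu.shape != (3, 2) or np.any((adu < 0) | (adu > 1)):
            raise ValueError("AD utilities must be a 3x2 table in [0,1]")
        nau = np.asarray(self.no_ad_utilities, dtype=float)
        if nau.shape != (4,) or np.any((nau < 0) | (nau > 1)):
            raise ValueError("non-AD utilities must be 4 values in [0,1]")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")

    @property
    def initial_severity_dist(self) -> np.ndarray:
        return self._initial

    @property
    def nh_entry_arr(self) -> np.ndarray:
        return np.asarray(self.nh_entry, dtype=float)

    @property
    def ad_utility_table(self) -> np.ndarray:
        return np.asarray(self.ad_utilities, dtype=float)


@dataclass(frozen=True)
class ADPath:
    """One individual's AD course from onset to death.

    ``severities``/``locations`` hold one entry per lived AD year (year 0 is
    the onset year); death occurs at ``onset_age + len(severities)``, capped
    at the model's maximum age.
    """

    onset_age: int
    severities: np.ndarray
    locations: np.ndarray

    @property
    def death_age(self) -> int:
        return self.onset_age + len(self.severities)

    def to_rows(self) -> list[tuple[int, str, str]]:
        """(age, severity, location) rows, e.g. for CSV export."""
        return [
            (self.onset_age + i, SEVERITIES[s], LOCATIONS[l])
            for i, (s, l) in enumerate(zip(self.severities, self.locations))
        ]


def discount_factor(years_since_base, rate: float):
    """Discount weight ``(1 - rate)**years`` — the model's convention.

    Note this is *not* the usual ``1/(1+r)**t``; at rate 0.03 a year 35 years
    after the base age carries weight 0.97**35 ~= 0.34.
    """
    if rate >= 1.0:
        raise ValueError("discount rate must be below 1")
    years = np.asarray(years_since_base, dtype=float)
    if np.any(years < 0):
        raise ValueError("years since base must be non-negative")
    out = (1.0 - rate) ** years
    return float(out) if out.ndim == 0 else out


def utility_without_ad(age, params: ProgressionParams):
    """Age-band utility for a year lived without AD."""
    age = np.asarray(age)
    idx = np.searchsorted(np.asarray(params.age_band_edges), age, side="right")
    out = np.asarray(params.no_ad_utilities, dtype=float)[idx]
    return float(out) if out.ndim == 0 else out


def draw_initial_severity(params: ProgressionParams, rng: np.random.Generator) -> int:
    """Severity index at onset, drawn from the initial severity distribution."""
    u = rng.uniform()
    return int(np.searchsorted(np.cumsum(params.initial_severity_dist), u, side="right"))


def step_severity(severity: int, params: ProgressionParams, rng: np.random.Generator) -> int:
    """One annual severity transition; returns new severity or ``DEAD``."""
    row = params.transitions[severity]
    u = rng.uniform()
    return int(np.searchsorted(np.cumsum(row), u, side="right"))


def step_location(severity: int, location: int, params: ProgressionParams, rng: np.random.Generator) -> int:
    """One annual location transition; the nursing home is absorbing."""
    if location == 1:
        return 1
    return 1 if rng.uniform() < params.nh_entry_arr[severity] else 0


def simulate_ad_course(
    onset_age: int,
    params: ProgressionParams,
    rng: np.random.Generator,
    cap: int = AGE_CAP,
) -> ADPath:
    """Simulate one AD course from onset to death (scalar reference version).

    Year 0 accrues at the drawn initial severity in the community; each later
    year applies the severity transition first (death ends the path), then the
    location transition.  Reaching the age cap forces death.
    """
    if onset_age < 0:
        raise ValueError("onset age must be non-negative")
    sev = draw_initial_severity(params, rng)
    loc = 0
    sevs, locs = [sev], [loc]
    age = int(onset_age)
    while True:
        age += 1
        if age >= cap:
            break
        nxt = step_severity(sev, params, rng)
        if nxt == DEAD:
            break
        sev = nxt
        loc = step_location(sev, loc, params, rng)
        sevs.append(sev)
        locs.append(loc)
    return ADPath(
        onset_age=int(onset_age),
        severities=np.asarray(sevs, dtype=np.int8),
        locations=np.asarray(locs, dtype=np.int8),
    )


def simulate_ad_paths(
    onset_ages: np.ndarray,
    base_age: int,
    params: ProgressionParams,
    rng: np.random.Generator,
    cap: int = AGE_CAP,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized AD courses for many individuals at once.

    Returns ``(discounted_qalys, death_age)`` arrays aligned with
    ``onset_ages``.  QALYs are discounted from ``base_age`` at the params'
    discount rate.  Each simulated year draws one severity uniform and (for
    survivors still in the community) one location uniform, so the stream is
    reproducible for a fixed ``rng`` state.
    """
    onset = np.asarray(onset_ages, dtype=np.int64)
    m = onset.size
    qalys = np.zeros(m)
    death = np.full(m, cap, dtype=np.int64)
    if m == 0:
        return qalys, death

    keep = 1.0 - params.discount_rate
    cum_init = np.cumsum(params.initial_severity_dist)
    cum_rows = np.cumsum(params.transitions, axis=1)
    nh = params.nh_entry_arr
    util = params.ad_utility_table

    sev = np.searchsorted(cum_init, rng.uniform(size=m), side="right").astype(np.int8)
    loc = np.zeros(m, dtype=np.int8)
    age = onset.copy()
    alive = age < cap
    death[~alive] = cap
    qalys[alive] = util[sev[alive], 0] * keep ** (age[alive] - base_age)

    while alive.any():
        idx = np.nonzero(alive)[0]
        age[idx] += 1
        capped = age[idx] >= cap
        if capped.any():
            ci = idx[capped]
            death[ci] = cap
            alive[ci] = False
            idx = idx[~capped]
            if idx.size == 0:
                continue
        u = rng.uniform(size=idx.size)
        rows = cum_rows[sev[idx]]
        new = (u[:, None] >= rows[:, :3]).sum(axis=1).astype(np.int8)
        died = new == DEAD
        di = idx[died]
        death[di] = age[di]
        alive[di] = False
        si = idx[~died]
        if si.size:
            sev[si] = new[~died]
            u2 = rng.uniform(size=si.size)
            move = (loc[si] == 0) & (u2 < nh[sev[si]])
            loc[si[move]] = 1
            qalys[si] += util[sev[si], loc[si]] * keep ** (age[si] - base_age)
    return qalys, death


def life_course_qalys(individual, ad_path: ADPath | None, params: ProgressionParams) -> float:
    """Total discounted QALYs over one complete life history.

    ``individual`` needs ``base_age`` and ``death_age_no_ad`` attributes.  With
    no AD path, every year from the base age to the (exclusive) death year
    accrues the age-band utility.  With a path, non-AD utility accrues up to
    the onset year and the path's severity x location utilities take over;
    the death year itself contributes nothing.
    """
    base = int(individual.base_age)
    keep = 1.0 - params.discount_rate
    end_no_ad = int(individual.death_age_no_ad) if ad_path is None else ad_path.onset_age
    total = 0.0
    for age in range(base, end_no_ad):
        total += utility_without_ad(age, params) * keep ** (age - base)
    if ad_path is not None:
        util = params.ad_utility_table
        for i, (s, l) in enumerate(zip(ad_path.severities, ad_path.locations)):
            age = ad_path.onset_age + i
            total += util[s, l] * keep ** (age - base)
    return total
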