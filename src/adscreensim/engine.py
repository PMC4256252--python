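"""Monte Carlo trial engine.

Each strategy comparison is run under common random numbers: the untreated
world (death ages, onsets, AD paths, discounted QALY tails) is computed once
per cohort and progression-parameter set, and the treated world differs only
through onset cancellations and harm decrements driven by per-individual
uniforms stored on the cohort.  Net utility is therefore exactly zero for a
null treatment, and per-trial aggregates reduce to sums over precomputed
per-individual nets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .fixtures import AGE_CAP, Fixtures
from .population import Cohort, build_cohort
from .progression import ProgressionParams, simulate_ad_paths, utility_without_ad
from .screening import FP, ScreeningParams, classify_cohort, horizon_converters
from .treatment import TreatmentOutcome, TreatmentParams, simulate_treatment_course

__all__ = [
    "TrialSummary",
    "Worlds",
    "compute_worlds",
    "evaluate_strategy",
    "run_trial",
    "run_simulation",
    "prevalence_curve",
    "sample_without_replacement",
    "Simulator",
]


@dataclass
class TrialSummary:
    """Per-strategy aggregate over all Monte Carlo trials (one Table row)."""

    base_age: int
    strategy: str
    net_qaly_per_1000_screened: float
    net_qaly_per_1000_treated: float
    n_treated_per_1000: float
    n_false_positive_per_1000: float
    fp_net_qaly_per_1000_screened: float
    sd_net_per_1000_screened: float
    n_trials: int
    trial_size: int


@dataclass
class Worlds:
    """Untreated-world discounted QALY decomposition for a cohort.

    ``y_onset`` is +inf where no onset is expressed (never destined, or
    censored by earlier death).  ``nonad_tail`` / ``ad_tail`` are the
    discounted QALY streams from onset to the life-table death age and along
    the simulated AD path; they are NaN for non-expressed onsets.
    """

    untreated_qalys: np.ndarray
    nonad_tail: np.ndarray
    ad_tail: np.ndarray
    ad_death_age: np.ndarray
    effective_converter: np.ndarray
    y_onset: np.ndarray
    y_death_no_ad: np.ndarray
    discount_rate: float


def _discounted_noad_cumsum(base_age: int, params: ProgressionParams) -> np.ndarray:
    """W[a] = sum of discounted non-AD utility over ages [base, a)."""
    W = np.zeros(AGE_CAP + 2)
    ages = np.arange(base_age, AGE_CAP)
    w = utility_without_ad(ages, params) * (1.0 - params.discount_rate) ** (
        ages - base_age
    )
    W[base_age + 1 : AGE_CAP + 1] = np.cumsum(w)
    return W


def compute_worlds(cohort: Cohort, params: ProgressionParams) -> Worlds:
    """Simulate the untreated world for every cohort member.

    AD paths for effective converters are drawn from the cohort's dedicated
    path seed, so recomputing the worlds under different progression
    parameters reuses the same underlying uniform stream (common random
    numbers across parameter settings).
    """
    base = cohort.base_age
    n = cohort.n
    W = _discounted_noad_cumsum(base, params)
    death = cohort.death_age_no_ad
    nonad_full = W[death] - W[base]

    eff = cohort.effective_converter
    onset = np.where(eff, cohort.onset_age, np.nan)
    ad_tail = np.full(n, np.nan)
    nonad_tail = np.full(n, np.nan)
    ad_death = np.full(n, -1, dtype=np.int64)
    if eff.any():
        onsets_int = cohort.onset_age[eff].astype(np.int64)
        rng = np.random.default_rng(cohort.path_seed)
        qalys, deaths = simulate_ad_paths(onsets_int, base, params, rng)
        ad_tail[eff] = qalys
        ad_death[eff] = deaths
        nonad_tail[eff] = W[death[eff]] - W[onsets_int]

    untreated = nonad_full.copy()
    if eff.any():
        untreated[eff] = (W[onset[eff].astype(np.int64)] - W[base]) + ad_tail[eff]

    y_onset = np.where(eff, cohort.onset_age - base, np.inf)
    return Worlds(
        untreated_qalys=untreated,
        nonad_tail=nonad_tail,
        ad_tail=ad_tail,
        ad_death_age=ad_death,
        effective_converter=eff,
        y_onset=y_onset,
        y_death_no_ad=(death - base).astype(float),
        discount_rate=params.discount_rate,
    )


@dataclass
class StrategyEvaluation:
    """Per-individual outcomes of one strategy on one cohort."""

    strategy: str
    labels: np.ndarray | None  # None for strategy "none"
    treated: np.ndarray
    fp_mask: np.ndarray
    outcome: TreatmentOutcome | None
    net: np.ndarray


def evaluate_strategy(
    cohort: Cohort,
    worlds: Worlds,
    strategy: str,
    s_params: ScreeningParams,
    t_params: TreatmentParams,
) -> StrategyEvaluation:
    """Classify, treat, and compute per-individual net QALYs for a strategy.

    Under ``treat_all`` the screen is bypassed; a "false positive" is then any
    treated individual who is not a within-horizon converter.
    """
    n = cohort.n
    conv = horizon_converters(
        cohort.onset_age, cohort.death_age_no_ad, cohort.base_age, s_params
    )
    if strategy == "none":
        zeros = np.zeros(n, dtype=bool)
        return StrategyEvaluation(
            strategy, None, zeros, zeros, None, np.zeros(n)
        )
    if strategy == "screen_and_treat":
        labels = classify_cohort(conv, cohort.u_class, s_params)
        treated = (labels == 0) | (labels == FP)
        fp_mask = labels == FP
    elif strategy == "treat_all":
        labels = classify_cohort(conv, cohort.u_class, s_params)
        treated = np.ones(n, dtype=bool)
        fp_mask = ~conv
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    outcome = simulate_treatment_course(
        treated=treated,
        y_onset=worlds.y_onset,
        y_death_no_ad=worlds.y_death_no_ad,
        effective_converter=worlds.effective_converter,
        nonad_tail=worlds.nonad_tail,
        ad_tail=worlds.ad_tail,
        u_harm=cohort.u_harm,
        u_disc=cohort.u_disc,
        u_cancel=cohort.u_cancel,
        params=t_params,
        discount_rate=worlds.discount_rate,
    )
    return StrategyEvaluation(strategy, labels, treated, fp_mask, outcome, outcome.net)


def sample_without_replacement(
    rng: np.random.Generator, n: int, k: int
) -> np.ndarray:
    """Uniform k-subset of range(n) via Floyd's algorithm (O(k) for k << n)."""
    if k > n:
        raise ValueError("cannot sample more individuals than the cohort holds")
    if k * 3 >= n:
        return rng.permutation(n)[:k]
    chosen: set[int] = set()
    out = np.empty(k, dtype=np.int64)
    for i, j in enumerate(range(n - k, n)):
        t = int(rng.integers(0, j + 1))
        if t in chosen:
            t = j
        chosen.add(t)
        out[i] = t
    return out


def run_trial(
    evaluation: StrategyEvaluation,
    trial_size: int,
    rng: np.random.Generator,
) -> dict:
    """One trial: sample ``trial_size`` individuals and aggregate outcomes."""
    n = evaluation.net.size
    idx = sample_without_replacement(rng, n, trial_size)
    net = float(evaluation.net[idx].sum())
    treated = int(evaluation.treated[idx].sum())
    fp = int(evaluation.fp_mask[idx].sum())
    fp_net = float(evaluation.net[idx][evaluation.fp_mask[idx]].sum())
    return {
        "net": net,
        "n_treated": treated,
        "n_false_positive": fp,
        "fp_net": fp_net,
    }


def _summarize_trials(
    trials: pd.DataFrame, base_age: int, strategy: str, trial_size: int
) -> TrialSummary:
    scale = 1000.0 / trial_size
    per_screened = float(trials["net"].mean()) * scale
    n_treated = float(trials["n_treated"].mean()) * scale
    per_treated = per_screened * 1000.0 / n_treated if n_treated > 0 else float("nan")
    return TrialSummary(
        base_age=base_age,
        strategy=strategy,
        net_qaly_per_1000_screened=per_screened,
        net_qaly_per_1000_treated=per_treated,
        n_treated_per_1000=n_treated,
        n_false_positive_per_1000=float(trials["n_false_positive"].mean()) * scale,
        fp_net_qaly_per_1000_screened=float(trials["fp_net"].mean()) * scale,
        sd_net_per_1000_screened=float(trials["net"].std(ddof=1)) * scale
        if len(trials) > 1
        else 0.0,
        n_trials=len(trials),
        trial_size=trial_size,
    )


class Simulator:
    """Caches the cohort and untreated world across strategy evaluations.

    The expensive pieces — cohort construction and the untreated-world QALY
    decomposition — depend only on (population parameters, seed) and on the
    progression parameters respectively, so sensitivity analyses that sweep
    intervention parameters reuse them and stay cheap.
    """

    def __init__(self, config: RunConfig, fixtures: Fixtures | None = None):
        self.config = config
        self.fixtures = fixtures if fixtures is not None else config.fixtures()
        self._cohort: Cohort | None = None
        self._worlds_key = None
        self._worlds: Worlds | None = None

    @property
    def cohort(self) -> Cohort:
        if self._cohort is None:
            self._cohort = build_cohort(self.config, self.fixtures)
        return self._cohort

    def worlds(self, prog: ProgressionParams | None = None) -> Worlds:
        prog = prog if prog is not None else self.config.progression
        key = (
            tuple(prog.initial_severity_dist),
            tuple(prog.transitions.ravel()),
            tuple(prog.nh_entry_arr),
            tuple(prog.ad_utility_table.ravel()),
            tuple(prog.no_ad_utilities),
            tuple(prog.age_band_edges),
            prog.discount_rate,
        )
        if self._worlds_key != key:
            self._worlds = compute_worlds(self.cohort, prog)
            self._worlds_key = key
        return self._worlds

    def evaluate(
        self,
        strategy: str | None = None,
        s_params: ScreeningParams | None = None,
        t_params: TreatmentParams | None = None,
        prog_params: ProgressionParams | None = None,
        n_trials: int | None = None,
        trial_size: int | None = None,
        return_trials: bool = False,
    ):
        cfg = self.config
        strategy = strategy or cfg.strategy
        s_params = s_params or cfg.screening
        t_params = t_params or cfg.treatment
        n_trials = n_trials or cfg.n_trials
        trial_size = trial_size or cfg.trial_size
        worlds = self.worlds(prog_params)
        evaluation = evaluate_strategy(self.cohort, worlds, strategy, s_params, t_params)
        rng = np.random.default_rng(self.cohort.trial_seed)
        records = [run_trial(evaluation, trial_size, rng) for _ in range(n_trials)]
        trials = pd.DataFrame.from_records(records)
        summary = _summarize_trials(trials, cfg.base_age, strategy, trial_size)
        if return_trials:
            return summary, trials, evaluation
        return summary


def run_simulation(config: RunConfig, fixtures: Fixtures | None = None) -> TrialSummary:
    """Build the cohort and run the configured Monte Carlo study end to end."""
    return Simulator(config, fixtures).evaluate()


def prevalence_curve(
    cohort: Cohort,
    prog_params: ProgressionParams,
    flat_rrr: float,
    max_age: int = 105,
) -> pd.DataFrame:
    """AD prevalence among survivors by age, untreated vs treat-all.

    The treated arm applies a constant relative risk reduction ``flat_rrr`` to
    every expressed onset with no harm, no discontinuation and no screening —
    the simple validation scenario in which each destined conversion is
    cancelled with probability ``flat_rrr`` (via the stored cancellation
    uniform, so ``flat_rrr=0`` reproduces the untreated curve exactly).
    """
    if not 0.0 <= flat_rrr <= 1.0:
        raise ValueError("flat_rrr must lie in [0,1]")
    worlds = compute_worlds(cohort, prog_params)
    eff = worlds.effective_converter
    cancelled = eff & (cohort.u_cancel < flat_rrr)

    ages = np.arange(cohort.base_age, max_age + 1)
    onset = cohort.onset_age
    rows = {}
    for arm in ("untreated", "treated"):
        converts = eff if arm == "untreated" else (eff & ~cancelled)
        death = np.where(converts, worlds.ad_death_age, cohort.death_age_no_ad)
        prev = np.empty(ages.size)
        for i, a in enumerate(ages):
            alive = death > a
            n_alive = int(alive.sum())
            with_ad = int((converts & (onset <= a) & alive).sum())
            prev[i] = with_ad / n_alive if n_alive else np.nan
        rows[arm] = prev
    return pd.DataFrame(
        {
            "age": ages,
            "prevalence_untreated": rows["untreated"],
            "prevalence_treated": rows["treated"],
        }
    )
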