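"""One-way, two-way and probabilistic sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from adscreensim import RunConfig
from adscreensim.engine import run_simulation
from adscreensim.sensitivity import (
    PSAResult,
    PSASpec,
    draw_parameters,
    one_way,
    run_psa,
    summarize_psa,
    two_way_harm,
)


@pytest.fixture(scope="module")
def sweep_config():
    return RunConfig(population_size=30_000, n_trials=50, trial_size=500, seed=21)


class TestOneWay:
    def test_single_point_matches_run_simulation(self, sweep_config, toy_fixtures):
        df = one_way(sweep_config, "rrr_ceiling", [0.5], toy_fixtures)
        full = run_simulation(sweep_config, toy_fixtures)
        assert df.loc[0, "net_qaly_per_1000_screened"] == pytest.approx(
            full.net_qaly_per_1000_screened
        )

    def test_zero_ceiling_nonpositive_base_positive(self, sweep_config, toy_fixtures):
        df = one_way(sweep_config, "rrr_ceiling", [0.0, 0.5], toy_fixtures)
        vals = df["net_qaly_per_1000_screened"].to_numpy()
        assert vals[0] <= 0.0
        assert vals[1] > 0.0

    def test_monotone_in_harm_magnitude(self, sweep_config, toy_fixtures):
        df = one_way(sweep_config, "harm_magnitude", [0.0, 1.0, 3.0, 6.0], toy_fixtures)
        vals = df["net_qaly_per_1000_screened"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-9)

    def test_unknown_parameter_rejected(self, sweep_config, toy_fixtures):
        with pytest.raises(KeyError, match="unknown parameter"):
            one_way(sweep_config, "not_a_parameter", [0.1], toy_fixtures)


class TestTwoWay:
    def test_zero_zero_cell_equals_no_harm_base(self, sweep_config, toy_fixtures):
        df = two_way_harm(sweep_config, [0.0], [0.0], toy_fixtures)
        base = one_way(sweep_config, "harm_prob", [0.0], toy_fixtures)
        assert df.loc[0, "net_qaly_per_1000_screened"] == pytest.approx(
            base.loc[0, "net_qaly_per_1000_screened"]
        )

    def test_matrix_non_increasing_along_both_axes(self, sweep_config, toy_fixtures):
        df = two_way_harm(
            sweep_config, [0.0, 0.02, 0.08], [0.0, 1.0, 4.0], toy_fixtures
        )
        mat = df.pivot(
            index="harm_magnitude", columns="harm_prob",
            values="net_qaly_per_1000_screened",
        ).to_numpy()
        assert np.all(np.diff(mat, axis=0) <= 1e-9)
        assert np.all(np.diff(mat, axis=1) <= 1e-9)


class TestPSADraws:
    def test_draws_respect_bounds(self, rng):
        spec = PSASpec(n_iterations=1)
        base = RunConfig().progression
        for _ in range(50):
            prog, s, t, iv = draw_parameters(spec, base, rng)
            assert 0.5 <= s.sensitivity <= 1.0
            assert 0.5 <= s.specificity <= 1.0
            assert 0.0 <= t.harm_prob <= 0.1
            assert 0.0 <= t.harm_magnitude <= 6.0
            np.testing.assert_allclose(prog.transitions.sum(axis=1), 1.0)
            assert np.all(prog.ad_utility_table >= 0)
            assert np.all(prog.ad_utility_table <= 1)
            assert 0.0 <= prog.discount_rate <= 0.25

    def test_transition_perturbation_within_ten_percent(self, rng):
        spec = PSASpec(n_iterations=1)
        base = RunConfig().progression
        raw = np.asarray(base.severity_transitions)
        for _ in range(20):
            prog, *_ = draw_parameters(spec, base, rng)
            # compare pre-normalization structure: zero entries stay zero
            assert np.all(prog.transitions[np.asarray(raw) == 0] == 0)


class TestRunPSA:
    def test_reproducible_given_seed(self, toy_fixtures):
        spec = PSASpec(n_iterations=20, population_size=5000, n_trials=10)
        a = run_psa(spec, toy_fixtures, seed=5)
        b = run_psa(spec, toy_fixtures, seed=5)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_overwhelming_harm_never_beneficial(self, toy_fixtures):
        spec = PSASpec(
            n_iterations=30,
            population_size=5000,
            n_trials=10,
            intervention_ranges={
                "rrr_slope": (0.03, 0.03),
                "rrr_ceiling": (0.5, 0.5),
                "harm_prob": (0.1, 0.1),
                "harm_magnitude": (6.0, 6.0),
                "discontinuation_rate": (0.05, 0.05),
                "sensitivity": (0.65, 0.65),
                "specificity": (0.95, 0.95),
                "discount_rate": (0.03, 0.03),
            },
        )
        res = run_psa(spec, toy_fixtures, seed=6)
        assert res.beneficial_count == 0

    def test_degenerate_base_case_spec_mostly_beneficial(self, toy_fixtures):
        # all mass at the (net-positive) base case: the beneficial flag should
        # fire in essentially every iteration
        spec = PSASpec(
            n_iterations=20,
            population_size=20_000,
            n_trials=20,
            intervention_ranges={
                "rrr_slope": (0.03, 0.03),
                "rrr_ceiling": (0.5, 0.5),
                "harm_prob": (0.001, 0.001),
                "harm_magnitude": (0.06, 0.06),
                "discontinuation_rate": (0.05, 0.05),
                "sensitivity": (0.65, 0.65),
                "specificity": (0.95, 0.95),
                "discount_rate": (0.03, 0.03),
            },
            probability_rel_delta=0.0,
            ad_utility_delta=0.0,
            no_ad_utility_ranges=tuple((u, u) for u in (0.872, 0.836, 0.809, 0.775)),
        )
        res = run_psa(spec, toy_fixtures, seed=7)
        assert res.beneficial_count >= 18

    def test_beneficial_monotone_under_harm_range_shift(self, toy_fixtures):
        def spec_with_harm(hi_p, hi_m):
            return PSASpec(
                n_iterations=60,
                population_size=5000,
                n_trials=10,
                intervention_ranges={
                    "rrr_slope": (0.0, 0.06),
                    "rrr_ceiling": (0.0, 1.0),
                    "harm_prob": (0.0, hi_p),
                    "harm_magnitude": (0.0, hi_m),
                    "discontinuation_rate": (0.0, 0.2),
                    "sensitivity": (0.5, 1.0),
                    "specificity": (0.5, 1.0),
                    "discount_rate": (0.0, 0.25),
                },
            )

        low = run_psa(spec_with_harm(0.005, 0.3), toy_fixtures, seed=8)
        high = run_psa(spec_with_harm(0.1, 6.0), toy_fixtures, seed=8)
        assert low.beneficial_count > high.beneficial_count


class TestSummarizePSA:
    def _synthetic_result(self):
        rows = []
        for i in range(10):
            rows.append(
                {
                    "iteration": i,
                    "rrr_slope": 0.01 * i,
                    "rrr_ceiling": 0.1 * i,
                    "realized_mean_rrr": 0.05 * i,
                    "realized_mean_rrr_expressed": 0.05 * i,
                    "harm_prob": 0.01,
                    "harm_magnitude": 0.1 * i,
                    "total_harm": 0.001 * i,
                    "discontinuation_rate": 0.05,
                    "sensitivity": 0.7,
                    "specificity": 0.9,
                    "discount_rate": 0.03,
                    "n_treated": 100,
                    "net_qaly_per_1000_screened": i - 4.5,
                    "beneficial": i > 4,
                }
            )
        return PSAResult(frame=pd.DataFrame(rows), spec=PSASpec(n_iterations=10), seed=0)

    def test_quantiles_match_hand_computation(self):
        s = summarize_psa(self._synthetic_result())
        # beneficial iterations are 5..9 with total harm 0.005..0.009
        ben = pd.Series([0.005, 0.006, 0.007, 0.008, 0.009])
        assert s.harm_quantiles_beneficial[0.75] == pytest.approx(ben.quantile(0.75))
        assert s.n_beneficial == 5
        assert s.group_means.loc["total_harm", True] == pytest.approx(0.007)
        assert s.group_means.loc["total_harm", False] == pytest.approx(0.002)

    def test_single_iteration_quantiles_equal_value(self):
        res = self._synthetic_result()
        res.frame = res.frame.iloc[[9]].reset_index(drop=True)
        s = summarize_psa(res)
        for q in (0.5, 0.75, 0.95):
            assert s.harm_quantiles_beneficial[q] == pytest.approx(0.009)

    def test_empty_beneficial_set_marked(self):
        res = self._synthetic_result()
        res.frame["beneficial"] = False
        s = summarize_psa(res)
        assert s.n_beneficial == 0
        assert np.isnan(s.harm_quantiles_beneficial[0.75])

    def test_quintile_table_has_five_ranked_groups(self):
        s = summarize_psa(self._synthetic_result())
        assert len(s.quintile_table) == 5
        assert s.quintile_table["mean_rrr"].is_monotonic_increasing
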