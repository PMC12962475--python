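"""Session simulation, screening, preference ratios and model fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songpath import (
    ModelSpec,
    SamplerConfig,
    TimingConfig,
    baseline_bias_screen,
    compare_models,
    fit_choice_glmm,
    logs_from_csv,
    logs_to_csv,
    logs_to_frame,
    preference_ratio,
    simulate_experiment,
    simulate_session,
)

FAST_SAMPLER = SamplerConfig(n_steps=4000, n_burn=1500, thin=3, seed=7)


class TestPreferenceRatio:
    def test_time_proportion_worked_example(self):
        # proportions of time on the long vs short arm
        assert preference_ratio(0.598, 0.25) == pytest.approx(0.598 / 0.848)

    def test_count_examples(self):
        assert preference_ratio(60, 40) == pytest.approx(0.600)
        assert preference_ratio(0, 5) == 0.0

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="both counts"):
            preference_ratio(0, 0)

    @given(
        a=st.floats(0.01, 1e6), b=st.floats(0.01, 1e6)
    )
    @settings(max_examples=50, deadline=None)
    def test_complementarity(self, a, b):
        assert preference_ratio(a, b) + preference_ratio(b, a) == pytest.approx(1.0)


class TestBaselineBiasScreen:
    @pytest.mark.parametrize(
        "stages,expected",
        [
            (((10, 10),), "pass"),
            (((15, 5),), "pass"),  # 0.75 < 0.80
            (((16, 4),), "rerun_baseline"),  # exactly 0.80 triggers
            (((16, 4), (17, 3)), "retest_later"),  # persisted same side
            (((16, 4), (10, 10)), "pass"),  # bias gone at rerun
            (((16, 4), (3, 17)), "pass"),  # bias flipped side
            (((16, 4), (17, 3), (18, 2)), "exclude"),  # persisted through retest
            (((16, 4), (17, 3), (9, 11)), "pass"),  # retest clean
        ],
    )
    def test_decision_states(self, stages, expected):
        assert baseline_bias_screen(*stages) == expected

    def test_invariant_to_side_relabeling(self):
        for stages in [((16, 4),), ((16, 4), (17, 3)), ((16, 4), (17, 3), (18, 2))]:
            mirrored = tuple((r, l) for l, r in stages)
            assert baseline_bias_screen(*stages) == baseline_bias_screen(*mirrored)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero triggers"):
            baseline_bias_screen((0, 0))


class TestSimulateSession:
    def test_forced_preference_all_long(self):
        log = simulate_session(mu=np.inf, sigma_bird=0.0, n_trials=50, seed=1)
        playback = log.phase_records("playback")
        assert all(r.stimulus_category == "long" for r in playback)

    def test_null_preference_near_half(self):
        timing = TimingConfig(playback_duration_s=10000 * 8.5)
        log = simulate_session(
            mu=0.0, sigma_bird=0.0, n_trials=10000, seed=2, timing=timing
        )
        frac = np.mean(
            [r.stimulus_category == "long" for r in log.phase_records("playback")]
        )
        assert abs(frac - 0.5) < 3 * 0.005  # binomial SE at n=10000

    def test_deterministic_given_seed(self):
        a = simulate_session(mu=0.5, sigma_bird=0.5, n_trials=30, seed=9)
        b = simulate_session(mu=0.5, sigma_bird=0.5, n_trials=30, seed=9)
        assert a == b

    def test_trial_spacing_honored(self):
        log = simulate_session(mu=0.0, sigma_bird=0.0, n_trials=40, seed=3)
        t = [r.t_start for r in log.phase_records("playback")]
        spacing = TimingConfig().trial_spacing_s
        assert np.allclose(np.diff(t), spacing)

    def test_impossible_timing_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            simulate_session(mu=0.0, sigma_bird=0.0, n_trials=500, seed=0)

    def test_phases_ordered(self):
        log = simulate_session(mu=0.0, sigma_bird=0.0, n_trials=10, seed=4)
        phases = [r.phase for r in log.records]
        order = {p: i for i, p in enumerate(("baseline", "playback", "post"))}
        assert phases == sorted(phases, key=order.__getitem__)

    def test_experiment_trial_counts_in_config_bounds(self):
        logs = simulate_experiment(n_birds=4, n_trials=110, seed=0)
        for log in logs:
            assert 100 <= len(log.phase_records("playback")) <= 120


class TestLogCsvRoundTrip:
    def test_lossless(self, tmp_path):
        logs = simulate_experiment(n_birds=3, n_trials=20, seed=5, both_sessions=True)
        path = tmp_path / "logs.csv"
        logs_to_csv(logs, path)
        back = logs_from_csv(path)
        assert logs_to_frame(back).equals(logs_to_frame(logs))


class TestFitChoiceGlmm:
    def test_single_bird_rejected(self):
        logs = simulate_experiment(n_birds=1, n_trials=20, seed=0)
        with pytest.raises(ValueError, match=">= 2 birds"):
            fit_choice_glmm(logs, sampler=FAST_SAMPLER)

    def test_complete_separation_handled_by_priors(self):
        # every bird always chooses long: the weakly-informative prior keeps
        # the posterior finite and concentrated at high preference
        logs = [
            simulate_session(
                mu=np.inf, sigma_bird=0.0, n_trials=40, seed=i,
                bird_id=f"b{i}", side_assignment="left" if i % 2 else "right",
            )
            for i in range(4)
        ]
        est = fit_choice_glmm(logs, sampler=FAST_SAMPLER)
        mu_draws = est.idata.posterior["mu"].values.ravel()
        p_draws = 1 / (1 + np.exp(-mu_draws))
        assert np.mean(p_draws > 0.9) > 0.5
        assert est.pr_mean > 0.9

    def test_null_data_ci_contains_zero(self):
        logs = simulate_experiment(
            n_birds=8, n_trials=100, mu=0.0, sigma_bird=0.0, seed=11
        )
        est = fit_choice_glmm(logs, sampler=FAST_SAMPLER)
        assert est.ci95_low < 0.0 < est.ci95_high
        assert abs(est.pr_mean - 0.5) < 0.05

    def test_estimate_invariants(self):
        logs = simulate_experiment(n_birds=6, n_trials=60, seed=21)
        est = fit_choice_glmm(logs, sampler=FAST_SAMPLER)
        assert est.ci95_low <= est.posterior_mean_logit <= est.ci95_high
        assert est.pr_mean == pytest.approx(
            1 / (1 + np.exp(-est.posterior_mean_logit))
        )


class TestCompareModels:
    def test_identical_specs_tie(self):
        logs = simulate_experiment(n_birds=6, n_trials=60, seed=31)
        table = compare_models(
            logs,
            [ModelSpec("base"), ModelSpec("base")],
            sampler=FAST_SAMPLER,
        )
        assert table["tie_with_best"].all()

    def test_phase_effect_detected(self):
        # playback preference 1.0 logit above the silent-phase side bias
        logs = simulate_experiment(
            n_birds=10, n_trials=100, mu=1.0, sigma_bird=0.3, seed=41,
            phase_effect=1.0, n_baseline=40, n_post=40,
        )
        table = compare_models(
            logs,
            [ModelSpec("base"), ModelSpec("phase", ("phase",))],
            phases=("baseline", "playback", "post"),
            sampler=FAST_SAMPLER,
        )
        assert table.index[table["rank"] == 0][0].startswith("phase")

    def test_no_spurious_preference_for_larger_model_on_null_data(self):
        wins = 0
        reps = 3
        for rep in range(reps):
            logs = simulate_experiment(
                n_birds=6, n_trials=60, mu=0.5, sigma_bird=0.3,
                seed=100 + rep, phase_effect=0.0, n_baseline=30, n_post=30,
            )
            table = compare_models(
                logs,
                [ModelSpec("base"), ModelSpec("phase", ("phase",))],
                phases=("baseline", "playback", "post"),
                sampler=FAST_SAMPLER,
            )
            base_row = table.loc[[i for i in table.index if i.startswith("base")][0]]
            # base loses only if beaten by more than 1 SE of the difference
            if base_row["rank"] == 0 or base_row["elpd_diff"] <= base_row["dse"]:
                wins += 1
        assert wins >= (reps + 1) // 2
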