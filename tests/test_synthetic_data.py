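"""Generators: crossover design, stimulation trains, task observers."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from somacross import synthetic_data as sd


class TestCrossoverDesign:
    def test_even_n_splits_exactly_in_half(self):
        design = sd.generate_crossover_design(34, seed=9)
        counts = pd.Series(design.order_assignment).value_counts()
        assert counts["RSS-first"] == counts["sham-first"] == 17

    def test_odd_n_groups_differ_by_one(self):
        design = sd.generate_crossover_design(33, seed=4)
        counts = pd.Series(design.order_assignment).value_counts()
        assert sorted(counts) == [16, 17]

    def test_seeded_determinism(self):
        a = sd.generate_crossover_design(33, seed=7)
        b = sd.generate_crossover_design(33, seed=7)
        assert a.order_assignment == b.order_assignment

    def test_rejects_degenerate_n(self):
        with pytest.raises(ValueError):
            sd.generate_crossover_design(1, seed=0)


class TestStimTrain:
    def test_rss_rate_near_one_hz_across_seeds(self):
        rates = [
            sd.generate_stim_train("RSS", sd.RSS_DURATION_S, seed).mean_rate
            for seed in range(10)
        ]
        assert abs(np.mean(rates) - 1.0) < 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rss_isi_bounds(self, seed):
        train = sd.generate_stim_train("RSS", 3600.0, seed)
        isis = np.diff(train.pulse_times)
        assert isis.min() >= sd.ISI_LOW_S and isis.max() <= sd.ISI_HIGH_S

    def test_truncated_isi_mean_calibrated(self, rng):
        isis = sd._sample_truncated_exp_isis(rng, 100_000)
        assert abs(isis.mean() - 1.0) < 0.01

    def test_sham_active_time_is_15_minutes(self):
        train = sd.generate_stim_train("sham", sd.RSS_DURATION_S, 3)
        assert train.active_time == pytest.approx(900.0)

    def test_sham_pulses_confined_to_blocks(self):
        train = sd.generate_stim_train("sham", sd.RSS_DURATION_S, 5)
        assert train.blocks is not None and len(train.blocks) == 6
        in_block = np.zeros(len(train.pulse_times), dtype=bool)
        for a, b in train.blocks:
            in_block |= (train.pulse_times >= a) & (train.pulse_times < b)
        assert in_block.all()

    def test_pulse_times_strictly_increasing_within_duration(self):
        train = sd.generate_stim_train("RSS", 1800.0, 11)
        assert (np.diff(train.pulse_times) > 0).all()
        assert train.pulse_times[0] >= 0 and train.pulse_times[-1] < 1800.0

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_stim_train("tens", 3600.0, 0)


class TestBinaryTask:
    def test_trial_counts_match_task_designs(self, cell):
        obs = sd.ObserverParams()
        assert len(sd.simulate_binary_task(obs, "2PDT", cell, 8, 0)) == 64
        assert len(sd.simulate_binary_task(obs, "TMT", cell, 12, 0)) == 108

    def test_chance_rate_at_pse(self, cell):
        # no lapse, stimulus pinned at the PSE: responses are fair coin flips
        obs = sd.ObserverParams(pse_tmt=0.0, lapse=0.0)
        tables = [
            sd.simulate_binary_task(obs, "TMT", cell, 12, seed)
            for seed in range(50)
        ]
        big = pd.concat(tables)
        at_pse = big[big["distortion"] == 0.0]
        rate = (at_pse["response"] == "larger").mean()
        assert abs(rate - 0.5) < 0.05

    def test_psychometric_probability_model(self, cell):
        # far below / above the 2PDT threshold the response saturates
        obs = sd.ObserverParams(pse_2pdt=1.3, slope_2pdt=50.0, lapse=0.0)
        table = sd.simulate_binary_task(obs, "2PDT", cell, 8, 1)
        low = table[table["separation"] == 0.0]
        high = table[table["separation"] == 2.5]
        assert (low["response"] == "one").all()
        assert (high["response"] == "two").all()

    def test_rss_effect_applied_post_rss_only(self):
        obs = sd.ObserverParams(pse_tmt=0.0, rss_effects={"pse_tmt": -7.4})
        assert obs.for_cell("RSS", "post").pse_tmt == pytest.approx(-7.4)
        for intervention, session in [("RSS", "pre"), ("sham", "post"), ("sham", "pre")]:
            assert obs.for_cell(intervention, session).pse_tmt == 0.0

    def test_rejects_bad_reps(self, cell):
        with pytest.raises(ValueError):
            sd.simulate_binary_task(sd.ObserverParams(), "2PDT", cell, 0, 0)

    def test_bitwise_determinism(self, cell):
        obs = sd.ObserverParams()
        a = sd.simulate_binary_task(obs, "TMT", cell, 12, 99)
        b = sd.simulate_binary_task(obs, "TMT", cell, 12, 99)
        assert_frame_equal(a, b)


class TestDistanceTask:
    def test_forty_rows_by_default(self, exact_observer, cell):
        assert len(sd.simulate_distance_task(exact_observer, cell, 0)) == 40

    def test_identity_observer_reproduces_true_distances(self, exact_observer, cell):
        table = sd.simulate_distance_task(exact_observer, cell, 1)
        assert np.allclose(table["judged_length"], table["true_distance"])

    def test_linear_gain(self, cell):
        obs = sd.ObserverParams(
            distance_gain=0.8, distance_bias=0.0, distance_noise_sd=0.0,
            distance_position_effect=0.0,
        )
        table = sd.simulate_distance_task(obs, cell, 2)
        far = table[table["true_distance"] == 30.0]
        assert np.allclose(far["judged_length"], 24.0)


class TestLocalizationTask:
    def test_ninety_rows_covering_nine_targets(self, exact_observer, cell):
        table = sd.simulate_localization_task(exact_observer, cell, 80.0, 0)
        assert len(table) == 90
        assert table.groupby(["phalanx", "position"]).size().eq(10).all()

    def test_noiseless_unbiased_observer_is_exact(self, exact_observer, cell):
        table = sd.simulate_localization_task(exact_observer, cell, 80.0, 1)
        assert np.allclose(table["judged_x"], table["real_x"])
        assert np.allclose(table["judged_y"], table["real_y"])

    def test_bias_displaces_by_fraction_of_finger_length(self, exact_observer, cell):
        obs = sd.ObserverParams(
            localization_bias={
                "proximal": np.zeros(2),
                "middle": np.zeros(2),
                "distal": np.array([0.0, -0.05]),
            },
            localization_cov={ph: np.zeros((2, 2)) for ph in sd.PHALANGES},
        )
        table = sd.simulate_localization_task(obs, cell, 80.0, 2)
        distal = table[table["phalanx"] == "distal"]
        assert np.allclose(distal["judged_y"] - distal["real_y"], -4.0)
        others = table[table["phalanx"] != "distal"]
        assert np.allclose(others["judged_y"], others["real_y"])

    def test_rejects_nonpositive_finger(self, exact_observer, cell):
        with pytest.raises(ValueError):
            sd.simulate_localization_task(exact_observer, cell, 0.0, 0)

    def test_targets_at_quarter_points_of_equal_thirds(self):
        targets = sd.target_locations(90.0)
        proximal = targets[targets["phalanx"] == "proximal"]["real_y"].to_numpy()
        assert np.allclose(proximal, [7.5, 15.0, 22.5])


class TestMissingnessInjection:
    def test_zero_rate_is_identity(self, small_study):
        table = small_study.tables["TLT"]
        out = sd.inject_missing_and_outliers(table, miss_rate=0.0, seed=0)
        assert_frame_equal(out, table)

    def test_small_rate_removes_matching_fraction(self, small_study):
        table = small_study.tables["TLT"]
        out = sd.inject_missing_and_outliers(table, miss_rate=0.002, seed=1)
        frac = 1 - len(out) / len(table)
        assert 0 <= frac < 0.01

    def test_invalid_rate_rejected(self, small_study):
        with pytest.raises(ValueError):
            sd.inject_missing_and_outliers(small_study.tables["TLT"], miss_rate=0.5)

    def test_outlier_injection_shifts_one_participant(self, small_study):
        table = small_study.tables["TDJT"]
        spec = {"participant": "P01", "column": "judged_length", "shift": 5.0}
        out = sd.inject_missing_and_outliers(table, outlier_spec=spec, seed=2)
        shifted = out[out["participant"] == "P01"]["judged_length"].mean()
        original = table[table["participant"] == "P01"]["judged_length"].mean()
        assert shifted > original + 4 * table["judged_length"].std()


class TestStudySimulation:
    def test_counts_and_determinism(self):
        study = sd.simulate_study(n_participants=4, seed=31)
        again = sd.simulate_study(n_participants=4, seed=31)
        expected = {"2PDT": 64, "TMT": 108, "TDJT": 40, "TLT": 90}
        for task, per_cell in expected.items():
            assert len(study.tables[task]) == 4 * 4 * per_cell
            assert_frame_equal(study.tables[task], again.tables[task])
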