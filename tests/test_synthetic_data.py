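import numpy as np
import pytest
from scipy.special import expit

from lekaccel.accel_io import write_dataset
from lekaccel.config import DEFAULT_CONFIG, deep_merge
from lekaccel.synthetic_data import (BEHAVIOUR_CLASSES, BirdSchedule,
                                     ClassSignature, EnvironmentModel,
                                     TrueResponseModel, burst_samples,
                                     default_environment, default_response,
                                     default_signatures, generate_burst,
                                     generate_dataset, generate_schedules,
                                     generate_temperature, substream)


class TestClassSignature:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ClassSignature((0, 0, 1), (0.1, -0.1, 0.1), (0, 0, 0))

    def test_mean_outside_sensor_range_rejected(self):
        with pytest.raises(ValueError, match="sensor range"):
            ClassSignature((0, 0, 7.0), (0, 0, 0), (0, 0, 0))

    def test_defaults_cover_all_classes(self):
        sigs = default_signatures()
        assert set(sigs) == set(BEHAVIOUR_CLASSES)


class TestGenerateBurst:
    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown behaviour class"):
            generate_burst("preen", default_signatures()["rest"], seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            burst_samples(default_signatures()["rest"], n_samples=0, seed=0)

    def test_zero_sd_gives_exact_static_mean(self):
        sig = ClassSignature((-0.03, 0.81, 0.60), (0, 0, 0), (0, 0, 0))
        s = burst_samples(sig, n_samples=10, seed=3)
        assert np.allclose(s, np.tile([-0.03, 0.81, 0.60], (10, 1)))

    def test_display_signature_grand_means(self):
        # printed video-validated signature: sway -0.03, surge 0.81, heave 0.60
        rng = substream(99, "bursts")
        sig = default_signatures()["display"]
        means = np.stack([burst_samples(sig, 10, rng=rng).mean(axis=0)
                          for _ in range(10_000)])
        assert np.allclose(means.mean(axis=0), [-0.03, 0.81, 0.60], atol=0.01)
        assert np.allclose(means.std(axis=0, ddof=1), [0.03, 0.09, 0.10], atol=0.015)

    def test_flight_norms_rarely_near_3g_never_over_6(self):
        rng = substream(4, "bursts")
        sig = default_signatures()["flight"]
        norms = np.concatenate([
            np.linalg.norm(burst_samples(sig, 10, rng=rng), axis=1)
            for _ in range(2_000)])
        assert (norms >= 2.5).mean() > 0.001       # some approach 3 g
        assert (norms >= 3.0).mean() < 0.05        # but rarely reach it
        assert norms.max() <= 6.0 * np.sqrt(3) + 1e-9
        assert np.abs(norms).max() < 6.5           # per-axis clipped at 6 g

    def test_signature_convergence_se_scaling(self):
        # empirical mean error shrinks ~1/sqrt(n) between two sample sizes
        sig = default_signatures()["display"]
        errs = []
        for n in (200, 12_800):
            reps = []
            for rep in range(5):
                rng = np.random.default_rng(1000 * n + rep)
                m = np.stack([burst_samples(sig, 10, rng=rng).mean(axis=0)
                              for _ in range(n)]).mean(axis=0)
                reps.append(np.abs(m - np.array(sig.static_mean)).mean())
            errs.append(np.mean(reps))
        assert errs[1] < errs[0] / 3  # expect ~1/8, allow slack


class TestSchedules:
    def test_mean_duration_matches_study(self):
        durs = np.concatenate([
            [s.duration for s in generate_schedules(17, seed)]
            for seed in range(100)])
        assert abs(durs.mean() - 12.8) < 0.5
        assert durs.min() >= 2 and durs.max() <= 25

    def test_single_bird(self):
        (s,) = generate_schedules(1, seed=5)
        assert 2 <= s.duration <= 25
        assert s.burst_interval in (10, 20)

    def test_fixed_seed_is_deterministic(self):
        assert generate_schedules(17, seed=11) == generate_schedules(17, seed=11)

    def test_different_seeds_differ(self):
        a = generate_schedules(17, seed=1)
        b = generate_schedules(17, seed=2)
        assert a != b

    def test_n_birds_validated(self):
        with pytest.raises(ValueError, match="n_birds"):
            generate_schedules(0, seed=1)

    def test_schedule_invariants_enforced(self):
        with pytest.raises(ValueError, match="duration"):
            BirdSchedule("b", "s", 100, 30, 10)
        with pytest.raises(ValueError, match="burst_interval"):
            BirdSchedule("b", "s", 100, 10, 15)


class TestTemperature:
    def test_empty_days_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            generate_temperature(default_environment(), [], ["site_0"], seed=1)

    def test_degenerate_model_is_constant(self):
        env = EnvironmentModel(daytime_mean=18.0, seasonal_slope=0.0,
                               diurnal_amplitude=0.0, site_offset_sd=0.0,
                               hourly_noise_sd=0.0, daily_anomaly_sd=0.0)
        temps = generate_temperature(env, range(100, 105), ["site_0"], seed=1)
        assert np.allclose(temps["temp_c"], 18.0)

    def test_daytime_mean_calibrated(self):
        env = default_environment()
        temps = generate_temperature(env, range(95, 152),
                                     [f"site_{i}" for i in range(5)], seed=8)
        day = temps[(temps["hour"] >= 5) & (temps["hour"] < 21)]
        assert abs(day["temp_c"].mean() - 18.0) < 0.5

    def test_daily_daytime_means_span_wide_range(self):
        env = default_environment()
        temps = generate_temperature(env, range(95, 152),
                                     [f"site_{i}" for i in range(5)], seed=8)
        day = temps[(temps["hour"] >= 5) & (temps["hour"] < 21)]
        daily = day.groupby(["site_id", "jdate"])["temp_c"].mean()
        assert daily.min() < 13.0
        assert daily.max() > 23.0


class TestResponseModel:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrueResponseModel(0.0, (0, 1), (0, 0), (0, 1), (0, 0), (0, 1), (0, 0),
                              nondisplay_mixture={"rest": 0.7, "forage": 0.7})

    def test_default_shape_constraints(self):
        r = default_response()
        t = np.linspace(4, 38, 200)
        ft = r.f_temp(t)
        # steep decline 4 -> 20, plateau 20 -> 30, decline after
        assert ft[0] - r.f_temp(20) > 1.0
        assert abs(r.f_temp(20) - r.f_temp(30)) < 0.3
        assert r.f_temp(38) < r.f_temp(30) - 0.5
        # overall non-increasing
        assert np.all(np.diff(ft) <= 1e-12)
        # hour effect elevated early morning then flat
        assert r.f_hour(5) > r.f_hour(10) + 0.5
        assert abs(r.f_hour(12) - r.f_hour(20)) < 1e-9
        # date effect rises from 107, peaks near 124
        d = np.arange(107, 152)
        fd = r.f_date(d)
        assert int(d[np.argmax(fd)]) == 124


class TestGenerateDataset:
    def test_labels_one_to_one(self, small_study):
        ds = small_study
        assert len(ds.bursts) == len(ds.samples)
        assert ds.bursts["burst_id"].is_unique
        assert ds.bursts["true_class"].isin(BEHAVIOUR_CLASSES).all()

    def test_null_response_prevalence_matches_intercept(self):
        from conftest import make_null_dataset

        ds = make_null_dataset(seed=5, intercept=-0.4)
        assert abs((ds.bursts["true_class"] == "display").mean()
                   - expit(-0.4)) < 0.02

    def test_prevalence_monotone_in_intercept(self):
        from conftest import make_null_dataset

        prevs = [(make_null_dataset(seed=9, intercept=b).bursts["true_class"]
                  == "display").mean() for b in (-1.0, 0.0, 1.0)]
        assert prevs[0] < prevs[1] < prevs[2]

    def test_complete_10min_day_has_96_daylight_bursts(self):
        sched = [BirdSchedule("bird_00", "site_0", 110, 3, 10)]
        ds = generate_dataset(sched, default_environment(), default_response(),
                              default_signatures(), seed=3, missing_prob=0.0)
        day = ds.bursts[(ds.bursts["jdate"] == 111)
                        & ds.bursts["hour"].between(5, 20)]
        assert len(day) == 96

    def test_missingness_drops_bursts(self):
        sched = generate_schedules(3, seed=2)
        full = generate_dataset(sched, default_environment(), default_response(),
                                default_signatures(), seed=2, missing_prob=0.0)
        thinned = generate_dataset(sched, default_environment(), default_response(),
                                   default_signatures(), seed=2, missing_prob=0.3)
        assert 0.6 < len(thinned.bursts) / len(full.bursts) < 0.8

    def test_invalid_missing_prob(self):
        with pytest.raises(ValueError, match="missing_prob"):
            generate_dataset(generate_schedules(1, 1), default_environment(),
                             default_response(), default_signatures(), seed=1,
                             missing_prob=1.0)

    def test_truth_record_retains_response(self, small_study):
        ds = small_study
        assert set(ds.truth["u_bird"]) == {s.bird_id for s in ds.schedules}
        for key in ("f_temp", "f_hour", "f_date"):
            assert len(ds.truth[key]["grid"]) == len(ds.truth[key]["value"])
        # per-burst p consistent with tabulated pieces
        row = ds.bursts.iloc[42]
        assert np.isclose(
            row["true_p"],
            expit(ds.truth["intercept"] + row["true_f_temp"]
                  + row["true_f_hour"] + row["true_f_date"] + row["u_bird"]))

    def test_fixed_seed_byte_identical_outputs(self, tmp_path, small_study):
        sched = generate_schedules(2, seed=4)
        args = (default_environment(), default_response(), default_signatures())
        for sub in ("a", "b"):
            ds = generate_dataset(sched, *args, seed=4, missing_prob=0.1)
            write_dataset(ds, tmp_path / sub)
        for name in ("bursts.csv", "labels.csv", "temperature.csv",
                     "truth.json", "schedules.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name


def test_substream_names_are_checked():
    with pytest.raises(KeyError, match="unknown random substream"):
        substream(1, "nope")


def test_default_study_prevalence_near_study_value(default_study):
    # printed study prevalence 41.5% of daylight bursts
    assert abs(default_study.display_prevalence() - 0.415) < 0.03
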