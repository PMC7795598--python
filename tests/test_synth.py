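import numpy as np
import pytest

from ischemap.errors import ParameterError, WeightNormalizationWarning
from ischemap.synth import (
    APParams,
    MINUTES,
    SimulationConfig,
    VFHazardModel,
    _local_maxima,
    ap_waveform,
    lead_electrogram,
    make_trajectory,
    simulate_animal,
    simulate_cohort,
)

FS = 4000.0
DT = 1000.0 / FS


def _grid(duration_ms: float) -> np.ndarray:
    return np.arange(int(duration_ms / DT)) * DT


class TestAPWaveform:
    @pytest.mark.parametrize("at,apd", [(20.0, 200.0), (55.5, 145.0), (30.25, 250.0)])
    def test_steepest_slopes_sit_on_true_fiducials(self, at, apd):
        t = _grid(600.0)
        v = ap_waveform(t, APParams(at_true=at, apd=apd))
        d = np.gradient(v, DT)
        assert abs(t[np.argmax(d)] - at) <= DT
        assert abs(t[np.argmin(d)] - (at + apd)) <= DT

    def test_zero_amplitude_gives_resting_trace(self):
        t = _grid(300.0)
        v = ap_waveform(t, APParams(amplitude=0.0, resting_potential=-85.0))
        np.testing.assert_allclose(v, -85.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            APParams(apd=-5.0)
        with pytest.raises(ParameterError):
            APParams(apd=1.0, upstroke_width=2.0)
        with pytest.raises(ParameterError):
            ap_waveform(np.array([0.0, 1.0, 3.0]), APParams())  # nonuniform grid


class TestLeadElectrogram:
    def test_identical_remote_cancels_to_st_shift(self):
        t = _grid(500.0)
        ap = ap_waveform(t, APParams())
        phi = lead_electrogram(ap, [ap], st_shift=1.5)
        np.testing.assert_allclose(phi, 1.5, atol=1e-12)

    def test_wyatt_extrema_recover_truth_on_brute_force_scan(self):
        # local AP at 20 ms / APD 200 ms against a blurred far-field pool
        t = _grid(600.0)
        local = ap_waveform(t, APParams(at_true=20.0, apd=200.0))
        pool = [
            ap_waveform(
                t,
                APParams(
                    at_true=at, apd=apd, upstroke_width=12.0, repol_width=100.0
                ),
            )
            for at, apd in [(12.0, 210.0), (25.0, 195.0), (35.0, 205.0)]
        ]
        phi = lead_electrogram(local, pool)
        d = np.gradient(phi, DT)
        qrs = slice(0, int(100 / DT))
        assert abs(t[qrs][np.argmin(d[qrs])] - 20.0) <= DT
        twin = slice(int(120 / DT), int(400 / DT))
        assert abs(t[twin][np.argmax(d[twin])] - 220.0) <= DT

    def test_weights_renormalised_with_warning(self):
        t = _grid(300.0)
        a = ap_waveform(t, APParams(at_true=30.0))
        b = ap_waveform(t, APParams(at_true=60.0))
        with pytest.warns(WeightNormalizationWarning):
            phi = lead_electrogram(a, [a, b], weights=np.array([1.0, 1.0]))
        expected = 0.5 * a + 0.5 * b - a
        np.testing.assert_allclose(phi, expected)

    def test_fixed_seed_is_bit_reproducible(self):
        t = _grid(300.0)
        a = ap_waveform(t, APParams())
        one = lead_electrogram(a, [a], noise_sd=0.5, seed=42)
        two = lead_electrogram(a, [a], noise_sd=0.5, seed=42)
        np.testing.assert_array_equal(one, two)


class TestTrajectory:
    def test_baseline_deltas_are_zero(self, control_trajectory):
        for region, deltas in control_trajectory.delta_at.items():
            assert deltas[0] == 0.0
            assert control_trajectory.delta_apd[region][0] == 0.0

    def test_control_at_max_is_biphasic(self, control_trajectory):
        atmax = np.array([control_trajectory.true_at_max(m) for m in MINUTES])
        assert atmax[MINUTES == 5.0] > atmax[MINUTES == 10.0]
        assert atmax[MINUTES == 10.0] < atmax[MINUTES == 25.0]
        peaks = MINUTES[_local_maxima(atmax)]
        assert any(3.0 <= p <= 5.0 for p in peaks)
        assert any(15.0 <= p <= 30.0 for p in peaks)

    def test_true_dor_nondecreasing_to_its_peak(self, control_trajectory):
        dor = np.array([control_trajectory.true_dor(m) for m in MINUTES])
        peak = int(np.argmax(dor))
        assert 20.0 <= MINUTES[peak] <= 30.0
        occl = dor[1 : peak + 1]
        assert np.all(np.diff(occl) >= -1e-9)

    def test_melatonin_border_zone_preserved_at_baseline(self, melatonin_trajectory):
        i10 = melatonin_trajectory.minute_index(10.0)
        assert melatonin_trajectory.delta_at["IVS_base"][i10] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "group,region,target",
        [
            ("control", "IVS_base", 35.4),
            ("melatonin", "IVS_base", 23.0),
            ("control", "LV_middle", 24.6),
            ("melatonin", "LV_middle", 17.5),
        ],
    )
    def test_postdrug_means_hit_calibration_targets(self, group, region, target):
        traj = make_trajectory(group=group)
        assert traj.postdrug_mean_at(region) == pytest.approx(target, abs=1e-9)

    def test_nonmonotone_minute_grid_rejected(self):
        with pytest.raises(ParameterError):
            make_trajectory({"minutes": np.array([0.0, 5.0, 2.5])})

    def test_ischemic_ari_shortening_is_monotone(self, control_trajectory):
        for region in ("LV_apex", "IVS_apex", "IVS_middle"):
            assert np.all(np.diff(control_trajectory.delta_apd[region]) <= 1e-12)


class TestHazardAndCohort:
    def test_probabilities_in_unit_interval(self, control_trajectory):
        model = VFHazardModel(intercept=-4.7)
        for minute in MINUTES[1:]:
            p = model.prob(
                control_trajectory.true_at("IVS_base", minute),
                control_trajectory.true_at_max(minute),
                control_trajectory.true_dor(minute),
            )
            assert 0.0 < p < 1.0

    def test_calibrated_intercept_hits_target_incidence(self, control_trajectory):
        model = VFHazardModel.calibrated(control_trajectory, target_cumulative=0.5)
        assert model.cumulative_incidence(control_trajectory) == pytest.approx(0.5)

    def test_zero_hazard_never_fibrillates(self, control_trajectory, no_vf_hazard):
        animal = simulate_animal(
            "a", "control", control_trajectory, no_vf_hazard, seed=3
        )
        assert animal.vf_minute is None
        assert len(animal.truth) == 11

    def test_certain_hazard_fibrillates_at_first_minute(self, control_trajectory):
        certain = VFHazardModel(intercept=np.inf)
        animal = simulate_animal("a", "control", control_trajectory, certain, seed=3)
        assert animal.vf_minute == 1.0
        assert animal.minutes == [0.0, 1.0]  # nothing recorded after VF

    def test_animal_is_deterministic_under_seed(self, control_trajectory):
        hz = VFHazardModel(intercept=-4.7)
        one = simulate_animal("a", "control", control_trajectory, hz, seed=9)
        two = simulate_animal("a", "control", control_trajectory, hz, seed=9)
        assert one.vf_minute == two.vf_minute
        for t1, t2 in zip(one.truth, two.truth):
            np.testing.assert_array_equal(
                t1.frame["at_ms"].to_numpy(), t2.frame["at_ms"].to_numpy()
            )

    def test_default_cohort_matches_study_arms(self):
        cohort = simulate_cohort(seed=1)
        assert len(cohort.animals) == 25
        groups = [a.group for a in cohort.animals]
        assert groups.count("control") == 13
        assert groups.count("melatonin") == 12
        assert cohort.seed == 1

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            simulate_cohort(n_control=0, n_melatonin=0)

    def test_different_seeds_give_different_vf_patterns(self):
        one = simulate_cohort(seed=1)
        two = simulate_cohort(seed=2)
        assert [a.vf_minute for a in one.animals] != [a.vf_minute for a in two.animals]

    def test_truncation_after_vf(self):
        cohort = simulate_cohort(seed=1)
        for animal in cohort.animals:
            if animal.vf_minute is not None:
                assert animal.minutes[-1] == animal.vf_minute
                assert all(m <= animal.vf_minute for m in animal.minutes)


def test_group_mean_postdrug_at_recovers_target_at_scale():
    """With 200 animals per arm the simulated post-drug IVS-base AT means
    stay within 5% of the calibration targets (stochastic check)."""
    cfg = SimulationConfig(
        n_control=200,
        n_melatonin=200,
        hazard=VFHazardModel(intercept=-np.inf),
        seed=11,
    )
    cohort = simulate_cohort(config=cfg)
    for group, target in (("control", 35.4), ("melatonin", 23.0)):
        values = []
        for animal in cohort.animals:
            if animal.group != group:
                continue
            per_minute = []
            for table in animal.truth:
                if table.minute < 1.0:
                    continue
                f = table.frame
                per_minute.append(
                    f.loc[(f["wall"] == "IVS") & (f["level"] == "base"), "at_ms"].mean()
                )
            values.append(np.mean(per_minute))
        assert np.mean(values) == pytest.approx(target, rel=0.05)
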