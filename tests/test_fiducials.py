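import numpy as np
import pytest

from conftest import FS, QRS_TIME
from ischemap.errors import EmptyTableError, NoBeatError, ParameterError
from ischemap.fiducials import (
    annotate_recording,
    detect_at,
    detect_beats,
    detect_qrs_onset,
    detect_rt,
    smooth_derivative,
)
from ischemap.recording import ElectrogramRecording
from ischemap.synth import APParams, SimulationConfig, ap_waveform, simulate_animal

DT = 1000.0 / FS


def _grid(duration_ms):
    return np.arange(int(duration_ms / DT)) * DT


class TestSmoothDerivative:
    def test_linear_signal_gives_constant_slope(self):
        t = _grid(100.0)
        d = smooth_derivative(2.0 * t, FS)
        np.testing.assert_allclose(d[25:-25], 2.0, atol=1e-9)

    def test_constant_signal_gives_zero(self):
        d = smooth_derivative(np.full(400, 3.3), FS)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_sine_peak_slope_matches_analytic(self):
        t = _grid(1000.0)
        freq_hz = 5.0
        omega = 2 * np.pi * freq_hz / 1000.0  # rad/ms
        d = smooth_derivative(np.sin(omega * t), FS)
        assert d.max() == pytest.approx(omega, rel=0.01)

    def test_window_validation(self):
        with pytest.raises(ParameterError):
            smooth_derivative(np.zeros(10), FS, window_ms=100.0)
        with pytest.raises(ParameterError):
            smooth_derivative(np.zeros(400), FS, window_ms=0.25)


def _reference(beats, duration_ms=2000.0, upstroke=1.5):
    t = _grid(duration_ms)
    ref = np.zeros_like(t)
    for b in beats:
        ref += ap_waveform(
            t,
            APParams(
                resting_potential=0.0,
                amplitude=1.0,
                upstroke_width=upstroke,
                apd=80.0,
                at_true=b,
                repol_width=25.0,
            ),
        )
    return ref


class TestBeatDetection:
    def test_onset_precedes_known_upstroke_within_5ms(self):
        ref = _reference([100.0])
        onset = detect_qrs_onset(ref, FS)
        assert 95.0 <= onset <= 100.0

    def test_flat_trace_raises_no_beat(self):
        with pytest.raises(NoBeatError):
            detect_qrs_onset(np.zeros(4000), FS)

    def test_onset_invariant_to_constant_offset(self):
        ref = _reference([100.0])
        assert detect_qrs_onset(ref + 5.0, FS) == detect_qrs_onset(ref, FS)

    def test_rr_is_median_of_inter_onset_intervals(self):
        ref = _reference([100.0, 700.0, 1304.0, 1900.0], duration_ms=2300.0)
        onsets, rr = detect_beats(ref, FS)
        assert len(onsets) == 4
        assert rr == pytest.approx(600.0, abs=1.0)

    def test_two_beats_600ms_apart(self):
        ref = _reference([100.0, 700.0], duration_ms=1200.0)
        _, rr = detect_beats(ref, FS)
        assert rr == pytest.approx(600.0, abs=1.0)

    def test_single_beat_has_undefined_rr(self):
        ref = _reference([100.0], duration_ms=600.0)
        onsets, rr = detect_beats(ref, FS)
        assert len(onsets) == 1
        assert rr is None


class TestATRTDetection:
    def test_noiseless_recovery_exact_to_one_sample(self, signal_animal):
        """Wyatt property: on noiseless generated leads, detected AT and RT
        hit the generator truth to within the 0.25 ms sampling step."""
        for truth, rec in zip(signal_animal.truth[:3], signal_animal.recordings[:3]):
            for i, signal in enumerate(rec.signals):
                at_true = truth.frame["at_ms"].iloc[i]
                rt_true = truth.frame["rt_ms"].iloc[i]
                at = detect_at(signal, FS, (0.0, 150.0), onset=QRS_TIME)
                rt = detect_rt(signal, FS, (120.0, 540.0), onset=QRS_TIME)
                assert abs(at - at_true) <= 0.25
                assert abs(rt - rt_true) <= 0.25

    def test_tie_breaks_to_earliest_instant(self):
        from ischemap.fiducials import _extremum_in_window

        d = np.zeros(1000)
        d[[200, 600]] = -5.0  # two exactly equal minima
        d[[300, 700]] = 5.0   # two exactly equal maxima
        assert _extremum_in_window(d, FS, 0.0, 240.0, "min").ms == 200 * DT
        assert _extremum_in_window(d, FS, 0.0, 240.0, "max").ms == 300 * DT

    def test_empty_window_rejected(self, recording):
        with pytest.raises(ParameterError):
            detect_at(recording.signals[0], FS, (50.0, 40.0), onset=QRS_TIME)

    def test_inverted_t_wave_still_recovered(self):
        """A lead with longer APD than its surroundings has an inverted
        T wave; the Wyatt dV/dt-maximum rule still lands on the truth."""
        t = _grid(700.0)
        local = ap_waveform(t, APParams(at_true=20.0, apd=240.0))
        pool = [
            ap_waveform(
                t,
                APParams(at_true=a, apd=180.0, upstroke_width=12.0, repol_width=100.0),
            )
            for a in (10.0, 15.0, 30.0)
        ]
        phi = np.mean(pool, axis=0) - local
        rt = detect_rt(phi, FS, (120.0, 600.0), onset=0.0)
        assert rt == pytest.approx(260.0, abs=0.5)

    def test_noisy_recovery_rms_bounds(self, control_trajectory, no_vf_hazard):
        """200 noisy leads (noise 5% of QRS amplitude): AT RMS <= 2 ms,
        RT RMS <= 5 ms."""
        cfg = SimulationConfig(signals=True, noise_sd=0.05 * 15.0)
        animal = simulate_animal(
            "n", "control", control_trajectory, no_vf_hazard, seed=77, config=cfg
        )
        at_err, rt_err = [], []
        for truth, rec in zip(animal.truth, animal.recordings):
            for i, signal in enumerate(rec.signals):
                at = detect_at(signal, FS, (0.0, 150.0), onset=QRS_TIME)
                rt = detect_rt(signal, FS, (120.0, 540.0), onset=QRS_TIME)
                at_err.append(at - truth.frame["at_ms"].iloc[i])
                rt_err.append(rt - truth.frame["rt_ms"].iloc[i])
            if len(at_err) >= 200:
                break
        at_err, rt_err = np.asarray(at_err), np.asarray(rt_err)
        assert np.sqrt(np.mean(at_err**2)) <= 2.0
        assert np.sqrt(np.mean(rt_err**2)) <= 5.0


class TestAnnotateRecording:
    def test_all_leads_ok_and_ari_matches_truth(self, signal_animal):
        truth = signal_animal.truth[0]
        table = annotate_recording(signal_animal.recordings[0])
        assert table.n_ok == 48
        np.testing.assert_allclose(
            table.frame["ari_ms"], truth.frame["ari_ms"], atol=1.0
        )

    def test_ari_identity_on_every_ok_row(self, signal_animal):
        table = annotate_recording(signal_animal.recordings[0])
        ok = table.ok
        np.testing.assert_array_equal(
            ok["ari_ms"].to_numpy(), (ok["rt_ms"] - ok["at_ms"]).to_numpy()
        )

    def test_low_amplitude_lead_excluded_not_dropped(self, recording):
        rec = ElectrogramRecording(
            animal_id=recording.animal_id,
            group=recording.group,
            minute=recording.minute,
            fs=recording.fs,
            signals=recording.signals.copy(),
            leads=recording.leads,
            reference=recording.reference,
        )
        rec.signals[5] = rec.signals[5].mean() + 0.001 * (
            rec.signals[5] - rec.signals[5].mean()
        )
        table = annotate_recording(rec)
        row = table.frame.iloc[5]
        assert row["flag"] == "excluded"
        assert row["reason"] == "low_amplitude"
        assert len(table.frame) == 48

    def test_all_leads_excluded_raises(self, recording):
        rec = ElectrogramRecording(
            animal_id=recording.animal_id,
            group=recording.group,
            minute=recording.minute,
            fs=recording.fs,
            signals=np.zeros_like(recording.signals),
            leads=recording.leads,
            reference=recording.reference,
        )
        with pytest.raises((EmptyTableError, NoBeatError, ParameterError)):
            annotate_recording(rec)

    def test_translation_equivariance(self, recording):
        """Shifting the whole recording by a whole number of samples leaves
        onset-relative fiducials unchanged."""
        shift = 400  # 100 ms
        rec = ElectrogramRecording(
            animal_id=recording.animal_id,
            group=recording.group,
            minute=recording.minute,
            fs=recording.fs,
            signals=np.roll(recording.signals, shift, axis=1),
            leads=recording.leads,
            reference=np.roll(recording.reference, shift),
        )
        base = annotate_recording(recording)
        moved = annotate_recording(rec)
        assert moved.meta["onset_ms"] == pytest.approx(
            base.meta["onset_ms"] + shift * 1000.0 / FS, abs=0.25
        )
        np.testing.assert_allclose(
            moved.frame["at_ms"], base.frame["at_ms"], atol=0.25
        )
        np.testing.assert_allclose(
            moved.frame["rt_ms"], base.frame["rt_ms"], atol=0.25
        )

    def test_constant_offset_and_slow_drift_move_fiducials_below_1ms(self, recording):
        base = annotate_recording(recording)
        drift = np.linspace(0.0, 1.0, recording.n_samples)  # ~0.5 Hz-equivalent ramp
        rec = ElectrogramRecording(
            animal_id=recording.animal_id,
            group=recording.group,
            minute=recording.minute,
            fs=recording.fs,
            signals=recording.signals + 2.0 + drift,
            leads=recording.leads,
            reference=recording.reference,
        )
        shifted = annotate_recording(rec)
        np.testing.assert_allclose(
            shifted.frame["at_ms"], base.frame["at_ms"], atol=1.0
        )
        np.testing.assert_allclose(
            shifted.frame["rt_ms"], base.frame["rt_ms"], atol=1.0
        )

    def test_rr_recovered_from_reference(self, signal_animal):
        table = annotate_recording(signal_animal.recordings[0])
        assert table.rr_ms == pytest.approx(signal_animal.truth[0].rr_ms, abs=1.0)
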