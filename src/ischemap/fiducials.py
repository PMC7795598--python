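"""Beat timing and per-lead activation/repolarization fiducials.

Detection follows the classical dV/dt rules for unipolar electrograms:

* activation time (AT) — instant of the dV/dt **minimum** within the QRS
  window, measured from QRS onset;
* repolarization time (RT) — instant of the dV/dt **maximum** within the
  T-wave window (the Wyatt rule, valid irrespective of T-wave polarity);
* ARI = RT - AT, a surrogate of local action-potential duration.

The derivative is a local-polynomial (Savitzky-Golay, order 2) least-squares
first derivative, which preserves extremum locations and is exact for
linear trends, so constant offsets and slow linear drift do not move the
fiducials.  Ties between equal extrema break to the earliest instant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import EmptyTableError, NoBeatError, ParameterError
from .recording import ElectrogramRecording, FiducialTable
from scipy.signal import savgol_filter


@dataclass(frozen=True)
class FiducialConfig:
    """Detector settings (all times in ms).

    The QRS search window is widened automatically when the derivative
    minimum sits on the window boundary — ischemic activation delays can
    push AT tens of ms beyond its baseline position.  The T-wave window
    scales with the RR interval; the source recordings carry one analyzed
    QRS-T complex per time point, so detection runs on the first beat.
    """

    deriv_window_ms: float = 5.0
    onset_deriv_window_ms: float = 2.0  # short window keeps the onset tight
    qrs_window: tuple[float, float] = (0.0, 100.0)
    qrs_window_extended: tuple[float, float] = (0.0, 150.0)
    t_window_start: float = 120.0
    t_window_rr_fraction: float = 0.9
    t_window_fallback_end: float = 540.0  # used when RR is undefined
    onset_threshold: float = 0.3          # fraction of the peak |dV/dt|
    onset_sustain_ms: float = 1.0
    min_slope: float = 0.05               # mV/ms; below this -> no beat
    refractory_ms: float = 250.0
    min_amplitude_fraction: float = 0.05  # of the median lead peak-to-peak


class _Extremum(NamedTuple):
    ms: float
    on_boundary: bool


def smooth_derivative(
    signal: np.ndarray, fs: float, window_ms: float = 5.0, polyorder: int = 2
) -> np.ndarray:
    """Least-squares local-polynomial first derivative, mV/ms, length preserving."""
    x = np.asarray(signal, dtype=float)
    n_win = int(round(window_ms * fs / 1000.0))
    if n_win % 2 == 0:
        n_win += 1
    if n_win < 3:
        raise ParameterError("derivative window must span at least 3 samples")
    if n_win > x.size:
        raise ParameterError("derivative window longer than the signal")
    return savgol_filter(x, n_win, polyorder, deriv=1, delta=1000.0 / fs)


def _sustained_onset(
    absd: np.ndarray, threshold: float, sustain: int
) -> np.ndarray:
    """Boolean mask of samples that start a sustained suprathreshold run."""
    above = absd >= threshold
    if sustain <= 1:
        return above
    # run of `sustain` consecutive suprathreshold samples starting here
    window = np.lib.stride_tricks.sliding_window_view(above, sustain)
    starts = window.all(axis=1)
    return np.concatenate([starts, np.zeros(sustain - 1, dtype=bool)])


def detect_qrs_onset(
    reference: np.ndarray, fs: float, cfg: FiducialConfig | None = None
) -> float:
    """Earliest instant (ms from trace start) of sustained suprathreshold |dV/dt|."""
    onsets, _ = detect_beats(reference, fs, cfg)
    return onsets[0]


def detect_beats(
    reference: np.ndarray, fs: float, cfg: FiducialConfig | None = None
) -> tuple[list[float], float | None]:
    """Beat onsets (ms) and RR (median inter-onset interval; None if < 2 beats)."""
    cfg = cfg or FiducialConfig()
    d = np.abs(smooth_derivative(reference, fs, cfg.onset_deriv_window_ms))
    peak = float(d.max())
    if peak < cfg.min_slope:
        raise NoBeatError(
            f"no suprathreshold activity (peak |dV/dt| {peak:.3g} mV/ms)"
        )
    sustain = max(int(round(cfg.onset_sustain_ms * fs / 1000.0)), 1)
    starts = _sustained_onset(d, cfg.onset_threshold * peak, sustain)
    refractory = int(round(cfg.refractory_ms * fs / 1000.0))
    onsets: list[int] = []
    for k in np.flatnonzero(starts):
        if onsets and k - onsets[-1] < refractory:
            continue
        onsets.append(int(k))
    if not onsets:
        raise NoBeatError("no sustained suprathreshold run found")
    onsets_ms = [k * 1000.0 / fs for k in onsets]
    rr = float(np.median(np.diff(onsets_ms))) if len(onsets_ms) >= 2 else None
    return onsets_ms, rr


def _extremum_in_window(
    d: np.ndarray,
    fs: float,
    lo_ms: float,
    hi_ms: float,
    mode: str,
) -> _Extremum:
    i0 = int(np.ceil(lo_ms * fs / 1000.0))
    i1 = int(np.floor(hi_ms * fs / 1000.0))
    i0 = max(i0, 0)
    i1 = min(i1, d.size - 1)
    if i1 < i0:
        raise ParameterError(f"empty search window [{lo_ms}, {hi_ms}] ms")
    segment = d[i0 : i1 + 1]
    j = int(np.argmin(segment) if mode == "min" else np.argmax(segment))
    return _Extremum((i0 + j) * 1000.0 / fs, j == 0 or j == segment.size - 1)


def detect_at(
    egm: np.ndarray,
    fs: float,
    qrs_window: tuple[float, float],
    onset: float,
    window_ms: float = 5.0,
) -> float:
    """AT (ms from onset): argmin of the smoothed dV/dt inside the QRS window."""
    d = smooth_derivative(egm, fs, window_ms)
    ext = _extremum_in_window(
        d, fs, onset + qrs_window[0], onset + qrs_window[1], "min"
    )
    return ext.ms - onset


def detect_rt(
    egm: np.ndarray,
    fs: float,
    t_window: tuple[float, float],
    onset: float,
    window_ms: float = 5.0,
) -> float:
    """RT (ms from onset): argmax of the smoothed dV/dt inside the T window."""
    d = smooth_derivative(egm, fs, window_ms)
    ext = _extremum_in_window(
        d, fs, onset + t_window[0], onset + t_window[1], "max"
    )
    return ext.ms - onset


def annotate_recording(
    rec: ElectrogramRecording, cfg: FiducialConfig | None = None
) -> FiducialTable:
    """Detect AT/RT/ARI on every lead of a recording.

    Leads failing quality rules are flagged ``excluded`` with a reason
    (low amplitude; fiducial pinned to a window boundary after widening)
    rather than dropped.  Raises :class:`EmptyTableError` if nothing
    survives.
    """
    cfg = cfg or FiducialConfig()
    onsets, rr = detect_beats(rec.reference, rec.fs, cfg)
    onset = onsets[0]
    rr_ms = float(rr) if rr is not None else float("nan")

    p2p = rec.signals.max(axis=1) - rec.signals.min(axis=1)
    median_p2p = float(np.median(p2p))
    t_end = (
        cfg.t_window_rr_fraction * rr_ms
        if np.isfinite(rr_ms)
        else cfg.t_window_fallback_end
    )
    t_window = (cfg.t_window_start, t_end)

    rows = []
    for lead, signal, amplitude in zip(rec.leads, rec.signals, p2p):
        flag, reason = "ok", ""
        at = rt = ari = np.nan
        if amplitude < cfg.min_amplitude_fraction * median_p2p:
            flag, reason = "excluded", "low_amplitude"
        else:
            d = smooth_derivative(signal, rec.fs, cfg.deriv_window_ms)
            ext = _extremum_in_window(
                d, rec.fs, onset + cfg.qrs_window[0], onset + cfg.qrs_window[1], "min"
            )
            if ext.on_boundary:
                ext = _extremum_in_window(
                    d,
                    rec.fs,
                    onset + cfg.qrs_window_extended[0],
                    onset + cfg.qrs_window_extended[1],
                    "min",
                )
            if ext.on_boundary:
                flag, reason = "excluded", "at_on_boundary"
            else:
                at = ext.ms - onset
                rt_ext = _extremum_in_window(
                    d, rec.fs, onset + t_window[0], onset + t_window[1], "max"
                )
                if rt_ext.on_boundary:
                    flag, reason = "excluded", "rt_on_boundary"
                else:
                    rt = rt_ext.ms - onset
                    ari = rt - at
        rows.append(
            {
                "lead_id": lead.lead_id,
                "wall": lead.wall,
                "level": lead.level,
                "zone": lead.zone,
                "at_ms": at,
                "rt_ms": rt,
                "ari_ms": ari,
                "flag": flag,
                "reason": reason,
            }
        )
    frame = pd.DataFrame(rows)
    if (frame["flag"] == "ok").sum() == 0:
        raise EmptyTableError("all leads excluded by quality rules")
    return FiducialTable(
        frame=frame,
        rr_ms=rr_ms,
        animal_id=rec.animal_id,
        group=rec.group,
        minute=rec.minute,
        meta={"onset_ms": onset},
    ).validate()
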