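"""Synthetic ischemic electrogram cohorts.

The generator produces multichannel unipolar electrograms with analytically
known ground truth so that every downstream stage (fiducial detection,
dispersion metrics, logistic association) can be validated by parameter
recovery.

Signal model
------------
Each lead carries a phenomenological local action potential built from two
logistic edges,

    AP(t) = V_rest + A * [sigma((t - AT)/s_u) - sigma((t - AT - APD)/s_r)],

with the steepest positive slope at the true activation instant ``AT`` and
the steepest negative slope at ``AT + APD``.  The unipolar electrogram of
lead *i* is the remote-minus-local superposition

    phi_i(t) = sum_j w_j * AP_j(t) - AP_i(t) + ST_shift + noise,

the minimal construction under which the dV/dt fiducial rules are exact:
with zero noise the global minimum of dphi/dt inside the QRS window falls
on the local upstroke and the global maximum inside the T window falls on
``AT + APD`` (the Wyatt property), regardless of T-wave polarity.  The
injury current of ischemic tissue enters only as the additive baseline
offset ``ST_shift``, which leaves every derivative extremum in place.

Far-field contributions are spatially averaged over the remote myocardium,
so the remote-pool waveforms carry broader transition edges than the local
AP.  This is also what makes the Wyatt property hold to one sample: the
shift of a local derivative extremum caused by the remote sum is bounded
by ``0.77 * s_local^3 / s_remote^2`` (logistic-edge scales), which stays
well below the 0.25 ms sampling step for the default widths (local
upstroke 2 ms / repolarization 15 ms against remote 12 ms / 100 ms).

Ischemia dynamics
-----------------
Region-level trajectories prescribe, per occlusion minute, the added
activation delay, the action-potential-duration (ARI) change and the ST
baseline shift.  The defaults emulate the acute LAD-occlusion phenotype:
abrupt biphasic ("spike and dome") activation delay in the ischemic
regions with maxima in the 3-5 and 15-30 min windows, progressive ARI
shortening there, growing dispersion of repolarization peaking at
20-30 min, and — in the melatonin arm — border-zone activation preserved
at the preischemic level through the 20th minute.  Border-zone amplitudes
are calibrated so the post-drug group means reproduce the study values
(IVS base 35.4 ms control vs 23.0 ms melatonin; LV middle 24.6 vs
17.5 ms).

Ventricular fibrillation is drawn per recording minute from a logistic
hazard on the animal's true covariates (AT IVS base, maximal AT, DOR);
recordings stop at the VF minute.  VF is an event label only — no
fibrillation waveform is synthesised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ParameterError, WeightNormalizationWarning
from .montage import LeadInfo, default_montage, REGION_NAMES
from .recording import ElectrogramRecording, FiducialTable, OCCLUSION_MINUTES

#: logistic-edge scale such that `width` is the 10-90% rise time
_LOG81 = math.log(81.0)

#: canonical occlusion-minute grid
MINUTES = np.asarray(OCCLUSION_MINUTES)

#: preischemic activation times (ms from QRS onset); the IVS base is the
#: latest-activated region at baseline
BASELINE_AT = {
    "LV_apex": 12.0,
    "LV_middle": 17.0,
    "LV_base": 20.0,
    "IVS_apex": 10.0,
    "IVS_middle": 14.0,
    "IVS_base": 22.0,
}

#: preischemic activation-recovery intervals (ms)
BASELINE_ARI = {
    "LV_apex": 205.0,
    "LV_middle": 208.0,
    "LV_base": 212.0,
    "IVS_apex": 200.0,
    "IVS_middle": 203.0,
    "IVS_base": 210.0,
}

_ZONE_OF_REGION = {
    "LV_apex": "ischemic",
    "IVS_apex": "ischemic",
    "IVS_middle": "ischemic",
    "LV_middle": "border",
    "IVS_base": "border",
    "LV_base": "normal",
}


# ---------------------------------------------------------------------------
# action-potential waveform and lead electrogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APParams:
    """Parameters of the phenomenological local action potential.

    ``apd`` is the true activation-recovery interval the detectors must
    recover; ``at_true`` the true activation instant (ms from trace start);
    widths are 10-90% transition times.
    """

    resting_potential: float = -85.0  # mV
    amplitude: float = 15.0           # mV
    upstroke_width: float = 2.0       # ms
    apd: float = 200.0                # ms
    at_true: float = 20.0             # ms
    repol_width: float = 15.0         # ms

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.apd <= 0:
            raise ParameterError("apd must be > 0")
        if self.apd <= self.upstroke_width:
            raise ParameterError("apd must exceed upstroke_width")
        if self.repol_width <= 0 or self.upstroke_width <= 0:
            raise ParameterError("transition widths must be > 0")


def ap_waveform(t_ms: np.ndarray, p: APParams) -> np.ndarray:
    """Sample the action potential on a uniform time grid (ms) -> mV."""
    t = np.asarray(t_ms, dtype=float)
    if t.size > 1:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0]):
            raise ParameterError("t_grid must be uniformly spaced")
    s_u = p.upstroke_width / _LOG81
    s_r = p.repol_width / _LOG81
    return p.resting_potential + p.amplitude * (
        expit((t - p.at_true) / s_u) - expit((t - p.at_true - p.apd) / s_r)
    )


def lead_electrogram(
    local: np.ndarray,
    remote_pool: list[np.ndarray],
    weights: np.ndarray | None = None,
    noise_sd: float = 0.0,
    st_shift: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Unipolar electrogram: weighted remote average minus the local AP.

    Weights must sum to one; if they do not they are renormalised and a
    :class:`WeightNormalizationWarning` is issued.
    """
    local = np.asarray(local, dtype=float)
    pool = [np.asarray(r, dtype=float) for r in remote_pool]
    if not pool:
        raise ParameterError("remote_pool must contain at least one trace")
    for r in pool:
        if r.shape != local.shape:
            raise ParameterError("remote traces must match the local trace length")
    if weights is None:
        weights = np.full(len(pool), 1.0 / len(pool))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(pool),):
            raise ParameterError("one weight per remote trace required")
        total = weights.sum()
        if total <= 0:
            raise ParameterError("weights must have a positive sum")
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-12):
            warnings.warn(
                f"remote weights sum to {total:.6g}; renormalising",
                WeightNormalizationWarning,
                stacklevel=2,
            )
            weights = weights / total
    phi = np.einsum("j,jt->t", weights, np.stack(pool)) - local + st_shift
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        phi = phi + rng.normal(0.0, noise_sd, size=phi.shape)
    return phi


# ---------------------------------------------------------------------------
# ischemia trajectories
# ---------------------------------------------------------------------------

# Zone-level occlusion profiles on the canonical minute grid.  The ischemic
# activation delay is biphasic (maxima near 5 and 20 min with a dip at 10);
# the ischemic ARI change is monotone non-increasing; border-zone delay
# develops within ~5 min and persists (control) or stays at baseline through
# 20 min (melatonin).  Border amplitudes are rescaled at construction time
# to meet the post-drug calibration targets below.
_ISCHEMIC_DELTA_AT = np.array(
    [0.0, 10.0, 22.0, 28.0, 15.0, 24.0, 30.0, 28.0, 16.0, 22.0, 23.0]
)
_ISCHEMIC_DELTA_APD = np.array(
    [0.0, -2.0, -12.0, -20.0, -32.0, -42.0, -50.0, -55.0, -55.0, -55.0, -55.0]
)
_BORDER_DELTA_AT = {
    "control": np.array(
        [0.0, 7.0, 12.5, 14.3, 14.3, 14.3, 14.3, 14.3, 14.3, 14.3, 14.3]
    ),
    "melatonin": np.array(
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 2.0, 3.0, 3.0, 3.0]
    ),
}
_BORDER_DELTA_APD = np.array(
    [0.0, 0.0, -1.0, -2.0, -3.0, -4.0, -4.0, -5.0, -5.0, -5.0, -5.0]
)
_ST_SHIFT = {
    "ischemic": np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]),
    "border": np.array([0.0, 0.25, 0.5, 0.75, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]),
    "normal": np.zeros(11),
}

#: post-drug (minutes >= 1) mean-AT calibration targets per group, ms
AT_TARGETS = {
    "control": {"IVS_base": 35.4, "LV_middle": 24.6},
    "melatonin": {"IVS_base": 23.0, "LV_middle": 17.5},
}

DEFAULT_PROFILE = {
    "minutes": MINUTES,
    "ischemic_delta_at": _ISCHEMIC_DELTA_AT,
    "ischemic_delta_apd": _ISCHEMIC_DELTA_APD,
    "border_delta_at": _BORDER_DELTA_AT,
    "border_delta_apd": _BORDER_DELTA_APD,
    "st_shift": _ST_SHIFT,
    "at_targets": AT_TARGETS,
    "baseline_at": BASELINE_AT,
    "baseline_ari": BASELINE_ARI,
}


@dataclass
class IschemiaTrajectory:
    """Per-region occlusion time courses of activation delay, ARI change and ST shift."""

    group: str
    minutes: np.ndarray
    baseline_at: dict[str, float]
    baseline_ari: dict[str, float]
    delta_at: dict[str, np.ndarray]
    delta_apd: dict[str, np.ndarray]
    st_shift: dict[str, np.ndarray]

    def validate(self) -> "IschemiaTrajectory":
        if np.any(np.diff(self.minutes) <= 0):
            raise ParameterError("minute grid must be strictly increasing")
        for region in REGION_NAMES:
            for table in (self.delta_at, self.delta_apd, self.st_shift):
                if len(table[region]) != len(self.minutes):
                    raise ParameterError(f"trajectory length mismatch for {region}")
                if table[region][0] != 0.0:
                    raise ParameterError("all deltas must be zero at baseline")
            if _ZONE_OF_REGION[region] == "ischemic" and np.any(
                np.diff(self.delta_apd[region]) > 1e-12
            ):
                raise ParameterError(
                    f"ischemic-zone delta_apd must be non-increasing ({region})"
                )
        return self

    # -- ground-truth summaries (region level, jitter-free) ----------------

    def minute_index(self, minute: float) -> int:
        idx = np.flatnonzero(np.isclose(self.minutes, minute))
        if idx.size == 0:
            raise ParameterError(f"minute {minute} not on the trajectory grid")
        return int(idx[0])

    def true_at(self, region: str, minute: float) -> float:
        i = self.minute_index(minute)
        return self.baseline_at[region] + float(self.delta_at[region][i])

    def true_ari(self, region: str, minute: float) -> float:
        i = self.minute_index(minute)
        return self.baseline_ari[region] + float(self.delta_apd[region][i])

    def true_rt(self, region: str, minute: float) -> float:
        return self.true_at(region, minute) + self.true_ari(region, minute)

    def true_at_max(self, minute: float) -> float:
        return max(self.true_at(r, minute) for r in REGION_NAMES)

    def true_dor(self, minute: float) -> float:
        rts = [self.true_rt(r, minute) for r in REGION_NAMES]
        return max(rts) - min(rts)

    def postdrug_mean_at(self, region: str) -> float:
        """Mean true AT over the post-drug window (all minutes >= 1)."""
        post = self.minutes >= 1.0
        return float(
            self.baseline_at[region] + np.mean(self.delta_at[region][post])
        )


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    v = np.asarray(values, dtype=float)
    return np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])) + 1


def make_trajectory(profile: dict | None = None, group: str = "control") -> IschemiaTrajectory:
    """Build a per-region trajectory from zone-level profiles.

    Border-zone activation delays are rescaled so the post-drug mean AT of
    the IVS base hits the group's calibration target exactly; the LV middle
    reuses the same shape with a gain derived from its own target.
    """
    if group not in ("control", "melatonin"):
        raise ParameterError(f"unknown group {group!r}")
    prof = dict(DEFAULT_PROFILE)
    if profile:
        prof.update(profile)
    minutes = np.asarray(prof["minutes"], dtype=float)
    if np.any(np.diff(minutes) <= 0):
        raise ParameterError("minute grid must be strictly increasing")
    base_at = dict(prof["baseline_at"])
    base_ari = dict(prof["baseline_ari"])
    post = minutes >= 1.0

    border_shape = np.asarray(prof["border_delta_at"][group], dtype=float)
    targets = prof["at_targets"][group]
    # scale the border shape so mean(baseline + delta) over minutes>=1 == target
    shape_mean = border_shape[post].mean()
    ivs_gain = (
        (targets["IVS_base"] - base_at["IVS_base"]) / shape_mean if shape_mean else 0.0
    )
    lv_gain = (
        (targets["LV_middle"] - base_at["LV_middle"]) / shape_mean if shape_mean else 0.0
    )

    delta_at = {}
    delta_apd = {}
    st_shift = {}
    for region in REGION_NAMES:
        zone = _ZONE_OF_REGION[region]
        if zone == "ischemic":
            delta_at[region] = np.asarray(prof["ischemic_delta_at"], dtype=float)
            delta_apd[region] = np.asarray(prof["ischemic_delta_apd"], dtype=float)
        elif zone == "border":
            gain = ivs_gain if region == "IVS_base" else lv_gain
            delta_at[region] = gain * border_shape
            delta_apd[region] = np.asarray(prof["border_delta_apd"], dtype=float)
        else:
            delta_at[region] = np.zeros_like(minutes)
            delta_apd[region] = np.zeros_like(minutes)
        st_shift[region] = np.asarray(prof["st_shift"][zone], dtype=float)

    return IschemiaTrajectory(
        group=group,
        minutes=minutes,
        baseline_at=base_at,
        baseline_ari=base_ari,
        delta_at=delta_at,
        delta_apd=delta_apd,
        st_shift=st_shift,
    ).validate()


# ---------------------------------------------------------------------------
# VF hazard
# ---------------------------------------------------------------------------

@dataclass
class VFHazardModel:
    """Per-minute logistic hazard of ventricular fibrillation.

    Log-odds are linear in the true covariates (per ms): AT in the IVS
    base, maximal AT and DOR.  The default coefficients reinterpret the
    study's univariate odds ratios as generative effects — ln(1.037)/ms on
    AT IVS base and ln(1.015)/ms on DOR — and the intercept is calibrated
    so roughly half of a control cohort fibrillates within 40 min.
    """

    beta_at_ivs_base: float = math.log(1.037)
    beta_at_max: float = 0.0
    beta_dor: float = math.log(1.015)
    intercept: float = -4.7
    phase_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"1A": (1.0, 5.0), "1B": (15.0, 40.0)}
    )

    def linear_predictor(self, at_ivs_base: float, at_max: float, dor: float) -> float:
        return (
            self.intercept
            + self.beta_at_ivs_base * at_ivs_base
            + self.beta_at_max * at_max
            + self.beta_dor * dor
        )

    def prob(self, at_ivs_base: float, at_max: float, dor: float) -> float:
        return float(expit(self.linear_predictor(at_ivs_base, at_max, dor)))

    def cumulative_incidence(self, trajectory: IschemiaTrajectory) -> float:
        """P(VF by end of protocol) on the jitter-free trajectory truth."""
        surv = 1.0
        for minute in trajectory.minutes[trajectory.minutes >= 1.0]:
            p = self.prob(
                trajectory.true_at("IVS_base", minute),
                trajectory.true_at_max(minute),
                trajectory.true_dor(minute),
            )
            surv *= 1.0 - p
        return 1.0 - surv

    @classmethod
    def calibrated(
        cls,
        trajectory: IschemiaTrajectory,
        target_cumulative: float = 0.5,
        **coefficients: float,
    ) -> "VFHazardModel":
        """Solve for the intercept giving ``target_cumulative`` VF incidence
        on the (control) trajectory truth."""
        if not 0 < target_cumulative < 1:
            raise ParameterError("target_cumulative must be in (0, 1)")

        def gap(b: float) -> float:
            model = cls(intercept=b, **coefficients)
            return model.cumulative_incidence(trajectory) - target_cumulative

        intercept = brentq(gap, -60.0, 30.0, xtol=1e-10)
        return cls(intercept=float(intercept), **coefficients)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions of a simulated cohort (defaults are the study's)."""

    n_control: int = 13
    n_melatonin: int = 12
    fs: float = 4000.0
    rr_ms: float = 600.0
    rr_between_animal_sd: float = 30.0
    at_jitter_sd: float = 2.0       # lead-level, ms
    apd_jitter_sd: float = 5.0      # lead-level, ms
    animal_at_sd: float = 1.5       # animal-level common AT offset, ms
    animal_gain_sd: float = 0.15    # lognormal sd of the per-animal delay gain
    n_per_region: int = 8
    noise_sd: float = 0.0           # additive signal noise, mV
    signals: bool = False           # synthesise waveforms (True) or truth only
    qrs_time_ms: float = 150.0      # reference upstroke instant in the trace
    amplitude: float = 15.0
    upstroke_width: float = 2.0
    repol_width: float = 15.0
    remote_upstroke_width: float = 12.0  # far-field edges are spatially blurred
    remote_repol_width: float = 100.0
    hazard: VFHazardModel | None = None
    target_cumulative_vf: float = 0.5
    trajectory_profile: dict | None = None  # overrides for make_trajectory
    seed: int = 0


@dataclass
class AnimalRecord:
    animal_id: str
    group: str
    vf_minute: float | None
    truth: list[FiducialTable]
    recordings: list[ElectrogramRecording]

    @property
    def minutes(self) -> list[float]:
        return [t.minute for t in self.truth]


@dataclass
class CohortDataset:
    animals: list[AnimalRecord]
    seed: int
    config: SimulationConfig
    trajectories: dict[str, IschemiaTrajectory]
    hazard: VFHazardModel

    def outcomes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": [a.animal_id for a in self.animals],
                "group": [a.group for a in self.animals],
                "vf_minute": [
                    np.nan if a.vf_minute is None else a.vf_minute
                    for a in self.animals
                ],
            }
        )


def _truth_table(
    animal_id: str,
    group: str,
    minute: float,
    trajectory: IschemiaTrajectory,
    leads: list[LeadInfo],
    at_offset: float,
    gain: float,
    rr: float,
    rng: np.random.Generator,
    at_jitter_sd: float,
    apd_jitter_sd: float,
) -> FiducialTable:
    """Ground-truth per-lead fiducials for one animal-minute."""
    i = trajectory.minute_index(minute)
    regions = [lead.region for lead in leads]
    at = (
        np.array([trajectory.baseline_at[r] + gain * trajectory.delta_at[r][i] for r in regions])
        + at_offset
        + rng.normal(0.0, at_jitter_sd, size=len(leads))
    )
    ari = np.maximum(
        np.array([trajectory.baseline_ari[r] + trajectory.delta_apd[r][i] for r in regions])
        + rng.normal(0.0, apd_jitter_sd, size=len(leads)),
        60.0,
    )
    frame = pd.DataFrame(
        {
            "lead_id": [lead.lead_id for lead in leads],
            "wall": [lead.wall for lead in leads],
            "level": [lead.level for lead in leads],
            "zone": [lead.zone for lead in leads],
            "at_ms": at,
            "rt_ms": at + ari,
            "ari_ms": ari,
            "flag": "ok",
            "reason": "",
        }
    )
    return FiducialTable(
        frame=frame,
        rr_ms=rr,
        animal_id=animal_id,
        group=group,
        minute=minute,
    )


def _reference_trace(t: np.ndarray, qrs_time: float, rr: float) -> np.ndarray:
    """Surface-type reference: monophasic beats at qrs_time, qrs_time+RR, ..."""
    ref = np.zeros_like(t)
    beat = qrs_time
    while beat < t[-1] - 50.0:
        ref += ap_waveform(
            t,
            APParams(
                resting_potential=0.0,
                amplitude=1.0,
                upstroke_width=1.5,
                apd=80.0,
                at_true=beat,
                repol_width=25.0,
            ),
        )
        beat += rr
    return ref


def _build_recording(
    truth: FiducialTable,
    trajectory: IschemiaTrajectory,
    cfg: SimulationConfig,
    rr: float,
    rng: np.random.Generator,
    leads: list[LeadInfo],
) -> ElectrogramRecording:
    """Synthesise the waveform recording matching a truth table."""
    duration = cfg.qrs_time_ms + 2.0 * rr + 150.0
    n = int(round(duration * cfg.fs / 1000.0))
    t = np.arange(n) * (1000.0 / cfg.fs)

    i = trajectory.minute_index(truth.minute)
    at_abs = cfg.qrs_time_ms + truth.frame["at_ms"].to_numpy()
    apd = truth.frame["ari_ms"].to_numpy()
    def _ap_matrix(upstroke_width: float, repol_width: float) -> np.ndarray:
        s_u = upstroke_width / _LOG81
        s_r = repol_width / _LOG81
        return cfg.amplitude * (
            expit((t[None, :] - at_abs[:, None]) / s_u)
            - expit((t[None, :] - at_abs[:, None] - apd[:, None]) / s_r)
        ) - 85.0

    # local APs keep sharp edges; the same sources seen as far-field remotes
    # carry spatially blurred edges (see module docstring)
    local = _ap_matrix(cfg.upstroke_width, cfg.repol_width)
    remote = _ap_matrix(cfg.remote_upstroke_width, cfg.remote_repol_width)
    total = remote.sum(axis=0)
    n_leads = len(leads)
    st = np.array(
        [trajectory.st_shift[lead.region][i] for lead in leads]
    )
    phi = (total - remote) / (n_leads - 1) - local + st[:, None]
    if cfg.noise_sd > 0:
        phi = phi + rng.normal(0.0, cfg.noise_sd, size=phi.shape)
    reference = _reference_trace(t, cfg.qrs_time_ms, rr)
    return ElectrogramRecording(
        animal_id=truth.animal_id,
        group=truth.group,
        minute=truth.minute,
        fs=cfg.fs,
        signals=phi,
        leads=leads,
        reference=reference,
    ).validate()


def simulate_animal(
    animal_id: str,
    group: str,
    trajectory: IschemiaTrajectory,
    hazard: VFHazardModel,
    montage: list[LeadInfo] | None = None,
    seed: int | np.random.Generator | None = None,
    config: SimulationConfig | None = None,
) -> AnimalRecord:
    """Simulate one animal: truth tables per minute, optional waveforms, VF draw.

    Per minute the 48-lead truth fiducials are drawn from the region-level
    trajectory with animal- and lead-level variation, the true covariates
    (AT IVS base, maximal AT, DOR) are computed from them, and a VF event is
    drawn from the per-minute hazard.  Recordings stop at the VF minute
    (inclusive — the animal is euthanised immediately after VF).
    """
    cfg = config or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    leads = montage if montage is not None else default_montage(cfg.n_per_region)

    at_offset = rng.normal(0.0, cfg.animal_at_sd)
    gain = float(np.exp(rng.normal(0.0, cfg.animal_gain_sd)))
    rr = float(np.clip(rng.normal(cfg.rr_ms, cfg.rr_between_animal_sd), 350.0, 1200.0))

    truth_tables: list[FiducialTable] = []
    recordings: list[ElectrogramRecording] = []
    vf_minute: float | None = None
    for minute in trajectory.minutes:
        table = _truth_table(
            animal_id, group, float(minute), trajectory, leads,
            at_offset, gain, rr, rng, cfg.at_jitter_sd, cfg.apd_jitter_sd,
        )
        truth_tables.append(table)
        if cfg.signals:
            recordings.append(_build_recording(table, trajectory, cfg, rr, rng, leads))
        if minute >= 1.0:
            ok = table.frame
            ivs_base = ok.loc[
                (ok["wall"] == "IVS") & (ok["level"] == "base"), "at_ms"
            ].mean()
            at_max = ok["at_ms"].max()
            dor = ok["rt_ms"].max() - ok["rt_ms"].min()
            p = hazard.prob(float(ivs_base), float(at_max), float(dor))
            if rng.uniform() < p:
                vf_minute = float(minute)
                break
    return AnimalRecord(animal_id, group, vf_minute, truth_tables, recordings)


def simulate_cohort(
    n_control: int | None = None,
    n_melatonin: int | None = None,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> CohortDataset:
    """Simulate a two-arm cohort; deterministic under ``seed``."""
    cfg = config or SimulationConfig()
    if n_control is not None:
        cfg = replace(cfg, n_control=n_control)
    if n_melatonin is not None:
        cfg = replace(cfg, n_melatonin=n_melatonin)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if cfg.n_control + cfg.n_melatonin == 0:
        raise ParameterError("cohort must contain at least one animal")

    trajectories = {
        "control": make_trajectory(cfg.trajectory_profile, group="control"),
        "melatonin": make_trajectory(cfg.trajectory_profile, group="melatonin"),
    }
    hazard = cfg.hazard or VFHazardModel.calibrated(
        trajectories["control"], target_cumulative=cfg.target_cumulative_vf
    )

    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_control + cfg.n_melatonin)
    animals: list[AnimalRecord] = []
    idx = 0
    for group, count in (("control", cfg.n_control), ("melatonin", cfg.n_melatonin)):
        for k in range(count):
            animals.append(
                simulate_animal(
                    animal_id=f"{'C' if group == 'control' else 'M'}{k + 1:02d}",
                    group=group,
                    trajectory=trajectories[group],
                    hazard=hazard,
                    seed=np.random.default_rng(children[idx]),
                    config=cfg,
                )
            )
            idx += 1
    return CohortDataset(
        animals=animals,
        seed=cfg.seed,
        config=cfg,
        trajectories=trajectories,
        hazard=hazard,
    )
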