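"""In-memory containers: one multichannel recording, one fiducial table.

An :class:`ElectrogramRecording` holds the unipolar intramyocardial signal
matrix (millivolts) for one animal at one occlusion minute together with a
surface-type reference channel used for beat timing.  A
:class:`FiducialTable` holds the per-lead activation time (AT), end of
repolarization time (RT) and activation-repolarization interval
(ARI = RT - AT), all in milliseconds from QRS onset, plus one RR interval
per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, MontageError
from .montage import LeadInfo

#: recording schedule in minutes of occlusion; 0 is the preischemic baseline
OCCLUSION_MINUTES = (0.0, 1.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)

GROUPS = ("control", "melatonin")

#: columns of a fiducial table, one row per lead
FIDUCIAL_COLUMNS = (
    "lead_id",
    "wall",
    "level",
    "zone",
    "at_ms",
    "rt_ms",
    "ari_ms",
    "flag",
    "reason",
)


@dataclass
class ElectrogramRecording:
    """Signal matrix [n_leads x n_samples] plus montage and acquisition metadata."""

    animal_id: str
    group: str
    minute: float
    fs: float
    signals: np.ndarray
    leads: list[LeadInfo]
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)

    @property
    def n_leads(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs

    def validate(self) -> "ElectrogramRecording":
        if self.group not in GROUPS:
            raise FormatError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not np.isscalar(self.fs) or self.fs <= 0:
            raise FormatError(f"fs must be positive, got {self.fs!r}")
        if float(self.minute) not in OCCLUSION_MINUTES:
            raise FormatError(
                f"minute {self.minute!r} is not on the occlusion schedule "
                f"{OCCLUSION_MINUTES}"
            )
        if self.signals.ndim != 2:
            raise FormatError("signals must be a 2-D [n_leads x n_samples] matrix")
        if len(self.leads) != self.signals.shape[0]:
            raise MontageError(
                f"montage declares {len(self.leads)} leads but the signal matrix "
                f"has {self.signals.shape[0]} rows"
            )
        if self.reference.shape != (self.signals.shape[1],):
            raise FormatError("reference length must match the signal matrix")
        if not np.all(np.isfinite(self.signals)):
            raise FormatError("signals contain non-finite values")
        if not np.all(np.isfinite(self.reference)):
            raise FormatError("reference contains non-finite values")
        ids = [lead.lead_id for lead in self.leads]
        if len(set(ids)) != len(ids):
            raise MontageError("duplicate lead ids in montage")
        return self


@dataclass
class FiducialTable:
    """Per-lead fiducials for one recording.

    ``frame`` has one row per lead with columns :data:`FIDUCIAL_COLUMNS`;
    ``flag`` is 'ok' or 'excluded' (with ``reason`` naming the quality rule).
    ``rr_ms`` is NaN when fewer than two beats were available.
    """

    frame: pd.DataFrame
    rr_ms: float
    animal_id: str = ""
    group: str = ""
    minute: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def ok(self) -> pd.DataFrame:
        """Rows that passed quality rules."""
        return self.frame[self.frame["flag"] == "ok"]

    @property
    def n_ok(self) -> int:
        return int((self.frame["flag"] == "ok").sum())

    def validate(self) -> "FiducialTable":
        missing = set(FIDUCIAL_COLUMNS) - set(self.frame.columns)
        if missing:
            raise FormatError(f"fiducial table missing columns {sorted(missing)}")
        ok = self.ok
        if not np.allclose(ok["ari_ms"], ok["rt_ms"] - ok["at_ms"]):
            raise FormatError("ARI != RT - AT on an ok row")
        if not (ok["rt_ms"] > ok["at_ms"]).all():
            raise FormatError("RT <= AT on an ok row")
        if np.isfinite(self.rr_ms) and self.rr_ms <= 0:
            raise FormatError("RR must be positive when defined")
        return self
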