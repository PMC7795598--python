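"""Readers/writers for the ``ischemap-rec v1`` container.

A recording is stored as a directory with two plain-text members:

* ``header.json`` — format tag, animal id, group, occlusion minute, sampling
  rate and the lead table (lead_id, wall, level).
* ``signals.csv`` — one column per channel, one row per sample; the first
  column is the surface reference, the remaining columns are the
  intramyocardial leads in header order.  Values are millivolts.

Headers round-trip bit-exactly; signals round-trip to the precision of the
``%.10g`` text representation (better than 1e-6 mV at physiological
amplitudes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MontageError
from .montage import LeadInfo
from .recording import ElectrogramRecording

FORMAT_TAG = "ischemap-rec v1"

_HEADER_FIELDS = ("format", "animal_id", "group", "minute", "fs", "leads")


def write_recording(rec: ElectrogramRecording, path: str | Path) -> None:
    """Write a validated recording to ``path`` (a directory, created/overwritten)."""
    rec.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "format": FORMAT_TAG,
        "animal_id": rec.animal_id,
        "group": rec.group,
        "minute": rec.minute,
        "fs": rec.fs,
        "leads": [
            {"lead_id": lead.lead_id, "wall": lead.wall, "level": lead.level}
            for lead in rec.leads
        ],
    }
    (path / "header.json").write_text(json.dumps(header, indent=1) + "\n")
    frame = pd.DataFrame(
        np.column_stack([rec.reference, rec.signals.T]),
        columns=["reference"] + [lead.lead_id for lead in rec.leads],
    )
    frame.to_csv(path / "signals.csv", index=False, float_format="%.10g")


def read_recording(path: str | Path) -> ElectrogramRecording:
    """Read and validate an ``ischemap-rec v1`` container."""
    path = Path(path)
    header_path = path / "header.json"
    signals_path = path / "signals.csv"
    if not header_path.exists():
        raise FormatError(f"{header_path} not found")
    if not signals_path.exists():
        raise FormatError(f"{signals_path} not found")
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed header: {exc}") from exc
    for fld in _HEADER_FIELDS:
        if fld not in header:
            raise FormatError(f"missing header field {fld!r}")
    if header["format"] != FORMAT_TAG:
        raise FormatError(
            f"unsupported format {header['format']!r}; expected {FORMAT_TAG!r}"
        )
    leads = []
    for entry in header["leads"]:
        for fld in ("lead_id", "wall", "level"):
            if fld not in entry:
                raise FormatError(f"lead entry missing field {fld!r}")
        leads.append(LeadInfo(entry["lead_id"], entry["wall"], entry["level"]))

    frame = pd.read_csv(signals_path)
    if "reference" not in frame.columns:
        raise FormatError("signals.csv has no 'reference' column")
    signal_cols = [c for c in frame.columns if c != "reference"]
    if len(signal_cols) != len(leads):
        raise MontageError(
            f"header declares {len(leads)} leads but signals.csv has "
            f"{len(signal_cols)} signal columns"
        )
    if signal_cols != [lead.lead_id for lead in leads]:
        raise MontageError("signals.csv column order does not match the lead table")
    rec = ElectrogramRecording(
        animal_id=header["animal_id"],
        group=header["group"],
        minute=float(header["minute"]),
        fs=float(header["fs"]),
        signals=frame[signal_cols].to_numpy().T,
        leads=leads,
        reference=frame["reference"].to_numpy(),
    )
    return rec.validate()
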