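"""Local and global electrophysiological parameters and the occlusion time course.

Local parameters are the mean AT and ARI per region (6 regions: LV/IVS x
apex/middle/base).  Global parameters span all analyzed (LV + IVS) leads:

* DOR     — dispersion of repolarization, max(RT) - min(RT);
* AT_max  — latest activation;
* ARI_max / ARI_min — activation-recovery extrema.

Regional means use quality-passing leads only; a region whose leads all
failed is reported missing (NaN) with a warning, never imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ParameterError
from .montage import REGION_NAMES
from .recording import FiducialTable


def _analyzed_ok(tbl: FiducialTable) -> pd.DataFrame:
    ok = tbl.ok
    return ok[ok["zone"] != "excluded"]


def regional_means(
    tbl: FiducialTable, regions: tuple[str, ...] = REGION_NAMES
) -> pd.DataFrame:
    """Mean AT and ARI per region over ok leads; NaN rows for empty regions."""
    ok = _analyzed_ok(tbl)
    rows = []
    for region in regions:
        wall, level = region.split("_")
        sub = ok[(ok["wall"] == wall) & (ok["level"] == level)]
        if sub.empty:
            warnings.warn(f"region {region}: all leads excluded", stacklevel=2)
            rows.append({"region": region, "at_ms": np.nan, "ari_ms": np.nan, "n": 0})
        else:
            rows.append(
                {
                    "region": region,
                    "at_ms": float(sub["at_ms"].mean()),
                    "ari_ms": float(sub["ari_ms"].mean()),
                    "n": int(len(sub)),
                }
            )
    return pd.DataFrame(rows).set_index("region")


def global_metrics(tbl: FiducialTable) -> dict[str, float]:
    """DOR, AT_max and ARI extrema over all analyzed ok leads."""
    ok = _analyzed_ok(tbl)
    if len(ok) < 2:
        raise ParameterError("global metrics require at least 2 ok leads")
    rt = ok["rt_ms"].to_numpy()
    return {
        "dor": float(rt.max() - rt.min()),
        "at_max": float(ok["at_ms"].max()),
        "ari_max": float(ok["ari_ms"].max()),
        "ari_min": float(ok["ari_ms"].min()),
    }


def build_timecourse(tables: list[FiducialTable]) -> pd.DataFrame:
    """One row per available minute: regional means + global metrics + RR.

    Input tables must be sorted by minute; minutes after a VF event are
    simply absent from the input and hence from the output.
    """
    if not tables:
        raise ParameterError("no fiducial tables supplied")
    minutes = [t.minute for t in tables]
    if any(b <= a for a, b in zip(minutes, minutes[1:])):
        raise ParameterError("fiducial tables must be sorted by strictly increasing minute")
    rows = []
    for tbl in tables:
        ok = _analyzed_ok(tbl)
        if len(ok) < 2:
            raise ParameterError("global metrics require at least 2 ok leads")
        row: dict[str, float] = {"minute": tbl.minute, "rr_ms": tbl.rr_ms}
        grouped = ok.groupby(ok["wall"] + "_" + ok["level"], sort=False)[
            ["at_ms", "ari_ms"]
        ].mean()
        for region in REGION_NAMES:
            if region in grouped.index:
                row[f"at_{region}"] = float(grouped.loc[region, "at_ms"])
                row[f"ari_{region}"] = float(grouped.loc[region, "ari_ms"])
            else:
                warnings.warn(f"region {region}: all leads excluded", stacklevel=2)
                row[f"at_{region}"] = np.nan
                row[f"ari_{region}"] = np.nan
        rt = ok["rt_ms"].to_numpy()
        row["dor"] = float(rt.max() - rt.min())
        row["at_max"] = float(ok["at_ms"].max())
        row["ari_max"] = float(ok["ari_ms"].max())
        row["ari_min"] = float(ok["ari_ms"].min())
        rows.append(row)
    return pd.DataFrame(rows).set_index("minute")


def classify_vf_phase(
    vf_minute: float | None,
    windows: dict[str, tuple[float, float]] | None = None,
) -> str:
    """Classify a VF event minute into '1A', '1B', 'intermediate' or 'none'.

    Window membership is inclusive; minutes falling between the early and
    delayed windows are flagged 'intermediate'.
    """
    windows = windows or {"1A": (1.0, 5.0), "1B": (15.0, 40.0)}
    for name in ("1A", "1B"):
        if name not in windows:
            raise ParameterError(f"phase window {name!r} missing")
        lo, hi = windows[name]
        if lo > hi:
            raise ParameterError(f"phase window {name} is inverted: {windows[name]}")
    if windows["1A"][1] > windows["1B"][0]:
        raise ParameterError("1A window must end before the 1B window starts")
    if vf_minute is None or (isinstance(vf_minute, float) and np.isnan(vf_minute)):
        return "none"
    for name in ("1A", "1B"):
        lo, hi = windows[name]
        if lo <= vf_minute <= hi:
            return name
    return "intermediate"
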