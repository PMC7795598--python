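"""Lead montage: walls, levels and ischemia zones.

The analyzed montage covers the left ventricular (LV) free wall and the
interventricular septum (IVS) at three levels each (apex, middle, base),
six regions in total, eight leads per region by default.  The occluded
vessel (LAD, distal to the first diagonal branch) defines a fixed mapping
from region to perfusion zone:

* ischemic  — LV apex, IVS apex, IVS middle
* border    — LV middle, IVS base
* normal    — LV base

Right-ventricular leads may be present in a recording but are excluded
from analysis by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MontageError

WALLS = ("LV", "IVS", "RV")
LEVELS = ("apex", "middle", "base")

#: the six analyzed (wall, level) regions, in canonical order
REGIONS = (
    ("LV", "apex"),
    ("LV", "middle"),
    ("LV", "base"),
    ("IVS", "apex"),
    ("IVS", "middle"),
    ("IVS", "base"),
)

REGION_NAMES = tuple(f"{w}_{lv}" for w, lv in REGIONS)

_ZONE_MAP = {
    ("LV", "apex"): "ischemic",
    ("IVS", "apex"): "ischemic",
    ("IVS", "middle"): "ischemic",
    ("LV", "middle"): "border",
    ("IVS", "base"): "border",
    ("LV", "base"): "normal",
}


def zone_for(wall: str, level: str) -> str:
    """Perfusion zone for a (wall, level) region; RV leads map to 'excluded'."""
    if wall == "RV":
        return "excluded"
    try:
        return _ZONE_MAP[(wall, level)]
    except KeyError:
        raise MontageError(f"unknown region ({wall!r}, {level!r})") from None


@dataclass(frozen=True)
class LeadInfo:
    """One intramyocardial lead terminal."""

    lead_id: str
    wall: str
    level: str

    def __post_init__(self) -> None:
        if self.wall not in WALLS:
            raise MontageError(f"wall must be one of {WALLS}, got {self.wall!r}")
        if self.level not in LEVELS:
            raise MontageError(f"level must be one of {LEVELS}, got {self.level!r}")

    @property
    def zone(self) -> str:
        return zone_for(self.wall, self.level)

    @property
    def region(self) -> str:
        return f"{self.wall}_{self.level}"


def default_montage(n_per_region: int = 8, include_rv: bool = False) -> list[LeadInfo]:
    """Build the default 48-lead montage (6 regions x `n_per_region` leads).

    With ``include_rv=True`` an extra RV block (3 levels x n_per_region) is
    appended; RV leads carry zone 'excluded' and are ignored by the metrics
    layer.
    """
    if n_per_region < 1:
        raise MontageError("n_per_region must be >= 1")
    leads = [
        LeadInfo(f"{w}_{lv}_{i + 1:02d}", w, lv)
        for w, lv in REGIONS
        for i in range(n_per_region)
    ]
    if include_rv:
        leads += [
            LeadInfo(f"RV_{lv}_{i + 1:02d}", "RV", lv)
            for lv in LEVELS
            for i in range(n_per_region)
        ]
    return leads


@dataclass
class MontageReport:
    """Per-region lead counts and flagged problems; never raises."""

    counts: dict[str, int]
    zones: dict[str, str]
    empty_regions: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    n_rv: int = 0

    @property
    def n_analyzed(self) -> int:
        return sum(self.counts.values())

    def summary(self) -> str:
        lines = [
            f"{r}: {self.counts[r]} leads (zone {self.zones[r]})" for r in REGION_NAMES
        ]
        if self.n_rv:
            lines.append(f"RV (excluded from analysis): {self.n_rv} leads")
        if self.empty_regions:
            lines.append("empty regions: " + ", ".join(self.empty_regions))
        if self.duplicate_ids:
            lines.append("duplicate lead ids: " + ", ".join(self.duplicate_ids))
        return "\n".join(lines)


def validate_montage(leads: list[LeadInfo]) -> MontageReport:
    """Report per-region lead counts, empty regions and duplicated lead ids."""
    if not leads:
        raise MontageError("montage is empty")
    counts = {r: 0 for r in REGION_NAMES}
    n_rv = 0
    seen: set[str] = set()
    dups: list[str] = []
    for lead in leads:
        if lead.lead_id in seen:
            dups.append(lead.lead_id)
        seen.add(lead.lead_id)
        if lead.wall == "RV":
            n_rv += 1
        else:
            counts[lead.region] += 1
    return MontageReport(
        counts=counts,
        zones={r: zone_for(w, lv) for (w, lv), r in zip(REGIONS, REGION_NAMES)},
        empty_regions=[r for r in REGION_NAMES if counts[r] == 0],
        duplicate_ids=sorted(set(dups)),
        n_rv=n_rv,
    )
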