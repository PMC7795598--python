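"""End-to-end study orchestration.

``run_study`` reproduces the analysis shape of the occlusion experiment on
a simulated (or ingested) cohort:

(a) a univariate logistic association table — each of the 14 candidate
    predictors (6 regional ATs, 6 regional ARIs, maximal AT, DOR),
    summarised per animal, against VF incidence;
(b) per-phase (1A early / 1B delayed) VF incidence 2x2 tables and tests,
    with the 1B risk set excluding animals that already fibrillated in 1A;
(c) per-group occlusion time courses of DOR, maximal AT, AT IVS base and
    AT LV apex with per-minute group comparisons;
(d) RR-interval regressions against the arrhythmia-linked parameters;
(e) repeated-measures minute-vs-baseline contrasts (Bonferroni) for the
    combined cohort.

The report is a pure function of (input data, config, seed) and echoes
both for reproducibility.

Predictor summarisation policy: the per-animal predictor value is the mean
over the occlusion minutes (>= 1) available before VF or censoring.  The
source analysis does not state its pooling rule; this choice is documented
as an assumption.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, SeparationError, ConvergenceError
from .fiducials import FiducialConfig, annotate_recording
from .io import read_recording
from .metrics import build_timecourse, classify_vf_phase
from .montage import REGION_NAMES
from .recording import FiducialTable
from .stats import (
    chisq_2x2,
    fisher_2x2,
    fit_logistic_univariate,
    linear_regression,
    rm_contrasts_bonferroni,
    two_sample_t,
)
from .synth import CohortDataset, SimulationConfig, simulate_cohort

PREDICTORS = tuple(
    [f"at_{r}" for r in REGION_NAMES]
    + [f"ari_{r}" for r in REGION_NAMES]
    + ["at_max", "dor"]
)

TIMECOURSE_METRICS = ("dor", "at_max", "at_IVS_base", "at_LV_apex")


@dataclass
class StudyConfig:
    """Configuration of one end-to-end study run."""

    n_control: int = 13
    n_melatonin: int = 12
    seed: int = 7
    fiducials: str = "detected"  # "detected" (annotate waveforms) or "truth"
    noise_sd: float = 0.0
    vf_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"1A": (1.0, 5.0), "1B": (15.0, 40.0)}
    )
    incidence_test: str = "pearson"  # or "fisher"
    input_dir: str | None = None
    simulation: SimulationConfig | None = None
    detector: FiducialConfig | None = None

    def to_dict(self) -> dict:
        return {
            "n_control": self.n_control,
            "n_melatonin": self.n_melatonin,
            "seed": self.seed,
            "fiducials": self.fiducials,
            "noise_sd": self.noise_sd,
            "vf_windows": {k: list(v) for k, v in self.vf_windows.items()},
            "incidence_test": self.incidence_test,
            "input_dir": self.input_dir,
        }


# ---------------------------------------------------------------------------
# cohort -> per-animal tables
# ---------------------------------------------------------------------------

def _animal_tables(
    cohort: CohortDataset, config: StudyConfig
) -> dict[str, list[FiducialTable]]:
    """Fiducial tables per animal, either detected from waveforms or truth."""
    tables: dict[str, list[FiducialTable]] = {}
    if config.fiducials == "truth":
        for animal in cohort.animals:
            tables[animal.animal_id] = animal.truth
        return tables
    if config.fiducials != "detected":
        raise ParameterError(f"unknown fiducials mode {config.fiducials!r}")
    fs_values = {
        rec.fs for animal in cohort.animals for rec in animal.recordings
    }
    if len(fs_values) > 1:
        raise FormatError(f"mixed sampling rates across recordings: {sorted(fs_values)}")
    for animal in cohort.animals:
        tables[animal.animal_id] = [
            annotate_recording(rec, config.detector) for rec in animal.recordings
        ]
    return tables


def ingest_cohort(input_dir: str | Path) -> CohortDataset:
    """Load a cohort from a directory with a ``manifest.json`` written by
    ``ischemap simulate`` (or assembled by hand in the same layout)."""
    from .synth import AnimalRecord  # local import to avoid cycle confusion

    input_dir = Path(input_dir)
    manifest_path = input_dir / "manifest.json"
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path} not found")
    manifest = json.loads(manifest_path.read_text())
    animals = []
    for entry in manifest.get("animals", []):
        if "group" not in entry or entry["group"] is None:
            raise FormatError(
                f"animal {entry.get('animal_id', '?')} has no group label"
            )
        recs = [read_recording(input_dir / p) for p in entry.get("recordings", [])]
        animals.append(
            AnimalRecord(
                animal_id=entry["animal_id"],
                group=entry["group"],
                vf_minute=entry.get("vf_minute"),
                truth=[],
                recordings=recs,
            )
        )
    if not animals:
        raise FormatError("manifest lists no animals")
    cfg = SimulationConfig()
    return CohortDataset(
        animals=animals,
        seed=int(manifest.get("seed", -1)),
        config=cfg,
        trajectories={},
        hazard=None,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# analysis blocks
# ---------------------------------------------------------------------------

def summarize_predictors(timecourse: pd.DataFrame) -> dict[str, float]:
    """Per-animal predictor values: mean over available occlusion minutes (>=1)."""
    occl = timecourse[timecourse.index >= 1.0]
    if occl.empty:
        return {p: float("nan") for p in PREDICTORS}
    return {p: float(occl[p].mean()) for p in PREDICTORS}


def association_table(
    predictors: pd.DataFrame, vf: np.ndarray
) -> list[dict]:
    """Univariate logistic fit of VF on each predictor (Table-style output)."""
    rows = []
    for name in PREDICTORS:
        x = predictors[name].to_numpy()
        keep = np.isfinite(x)
        try:
            res = fit_logistic_univariate(x[keep], vf[keep], name=name)
            rows.append(res.row())
        except (SeparationError, ConvergenceError, ParameterError) as exc:
            rows.append({"predictor": name, "error": str(exc)})
    return rows


def incidence_analysis(
    outcomes: pd.DataFrame,
    windows: dict[str, tuple[float, float]] | None = None,
    test: str = "pearson",
) -> dict:
    """Per-phase 2x2 incidence tables (rows melatonin/control, cols VF/no-VF).

    The risk set of a phase excludes animals that fibrillated before the
    window opens — in particular 1B denominators exclude 1A fibrillators.
    Tests with a zero event margin are skipped with a notice.
    """
    windows = windows or {"1A": (1.0, 5.0), "1B": (15.0, 40.0)}
    classify_vf_phase(None, windows)  # validates window geometry
    out = {}
    vf = outcomes["vf_minute"].to_numpy(dtype=float)
    groups = outcomes["group"].to_numpy()
    for phase in ("1A", "1B"):
        lo, hi = windows[phase]
        at_risk = ~(np.isfinite(vf) & (vf < lo))
        event = np.isfinite(vf) & (vf >= lo) & (vf <= hi)
        table = []
        for grp in ("melatonin", "control"):
            sel = (groups == grp) & at_risk
            n_event = int(np.sum(event & sel))
            table.append([n_event, int(np.sum(sel)) - n_event])
        entry: dict = {
            "window": [lo, hi],
            "table": table,
            "rows": ["melatonin", "control"],
            "columns": ["vf", "no_vf"],
        }
        arr = np.asarray(table)
        if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
            entry["test"] = None
            entry["note"] = "test skipped: zero margin"
        elif test == "fisher":
            entry["test"] = {"method": "fisher", "p": fisher_2x2(table)}
        else:
            stat, df, p = chisq_2x2(table)
            entry["test"] = {
                "method": "pearson_chi2",
                "statistic": stat,
                "df": df,
                "p": p,
            }
        out[phase] = entry
    return out


def _group_timecourses(
    timecourses: dict[str, pd.DataFrame], groups: dict[str, str]
) -> dict:
    """Per-minute group means/SEMs and t-tests for the VF-linked metrics."""
    minutes = sorted(
        {m for tc in timecourses.values() for m in tc.index.tolist()}
    )
    out: dict = {}
    for metric in TIMECOURSE_METRICS:
        rows = []
        for minute in minutes:
            values = {"control": [], "melatonin": []}
            for animal, tc in timecourses.items():
                if minute in tc.index and np.isfinite(tc.loc[minute, metric]):
                    values[groups[animal]].append(float(tc.loc[minute, metric]))
            row: dict = {"minute": minute}
            for grp in ("control", "melatonin"):
                v = np.asarray(values[grp])
                row[f"{grp}_n"] = int(v.size)
                row[f"{grp}_mean"] = float(v.mean()) if v.size else None
                row[f"{grp}_sem"] = (
                    float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
                )
            if len(values["control"]) >= 2 and len(values["melatonin"]) >= 2:
                t, df, p = two_sample_t(values["control"], values["melatonin"])
                row["p_group"] = p
            else:
                row["p_group"] = None
            rows.append(row)
        out[metric] = rows
    return out


def _rr_regressions(timecourses: dict[str, pd.DataFrame]) -> dict:
    """Pooled animal-minute regressions of each metric on the RR interval."""
    pooled = pd.concat(
        [tc.reset_index() for tc in timecourses.values()], ignore_index=True
    )
    out = {}
    for metric in ("at_LV_apex", "at_IVS_base", "dor"):
        sub = pooled[np.isfinite(pooled["rr_ms"]) & np.isfinite(pooled[metric])]
        try:
            res = linear_regression(sub["rr_ms"].to_numpy(), sub[metric].to_numpy())
            out[metric] = {
                "slope": res.slope,
                "ci95": list(res.ci95),
                "p": res.p,
                "n": int(len(sub)),
            }
        except ParameterError as exc:
            out[metric] = {"error": str(exc)}
    return out


def _ischemia_contrasts(timecourses: dict[str, pd.DataFrame]) -> dict:
    """Combined-group repeated-measures contrasts of AT_max and DOR vs baseline."""
    minutes = sorted(
        {m for tc in timecourses.values() for m in tc.index.tolist()}
    )
    out = {}
    for metric in ("at_max", "dor"):
        matrix = np.full((len(timecourses), len(minutes)), np.nan)
        for i, tc in enumerate(timecourses.values()):
            for j, minute in enumerate(minutes):
                if minute in tc.index:
                    matrix[i, j] = tc.loc[minute, metric]
        table = rm_contrasts_bonferroni(matrix, minutes=minutes)
        out[metric] = [
            {
                "minute": float(idx),
                "n": int(row["n"]),
                "p_raw": float(row["p_raw"]),
                "p_adjusted": float(row["p_adjusted"]),
            }
            for idx, row in table.iterrows()
        ]
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


@dataclass
class StudyReport:
    config: dict
    config_hash: str
    outcomes: list[dict]
    associations: list[dict]
    incidence: dict
    group_timecourses: dict
    rr_regressions: dict
    ischemia_contrasts: dict

    def to_dict(self) -> dict:
        return _jsonable(
            {
                "config": self.config,
                "config_hash": self.config_hash,
                "outcomes": self.outcomes,
                "associations": self.associations,
                "incidence": self.incidence,
                "group_timecourses": self.group_timecourses,
                "rr_regressions": self.rr_regressions,
                "ischemia_contrasts": self.ischemia_contrasts,
            }
        )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def association(self, predictor: str) -> dict:
        for row in self.associations:
            if row["predictor"] == predictor:
                return row
        raise KeyError(predictor)


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Simulate (or ingest) a cohort, annotate, aggregate and analyse it."""
    config = config or StudyConfig()
    if config.input_dir is not None:
        cohort = ingest_cohort(config.input_dir)
        if config.fiducials == "truth":
            raise ParameterError("ingested cohorts carry no truth tables")
    else:
        sim = config.simulation or SimulationConfig(
            n_control=config.n_control,
            n_melatonin=config.n_melatonin,
            signals=(config.fiducials == "detected"),
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        cohort = simulate_cohort(config=sim)

    tables = _animal_tables(cohort, config)
    groups = {a.animal_id: a.group for a in cohort.animals}
    vf_minutes = {a.animal_id: a.vf_minute for a in cohort.animals}
    timecourses = {
        animal_id: build_timecourse(tbls) for animal_id, tbls in tables.items()
    }

    predictor_frame = pd.DataFrame(
        {aid: summarize_predictors(tc) for aid, tc in timecourses.items()}
    ).T
    vf_binary = np.array(
        [0.0 if vf_minutes[aid] is None else 1.0 for aid in predictor_frame.index]
    )

    outcomes_df = pd.DataFrame(
        {
            "animal_id": list(groups),
            "group": [groups[a] for a in groups],
            "vf_minute": [
                np.nan if vf_minutes[a] is None else vf_minutes[a] for a in groups
            ],
        }
    )
    outcomes = [
        {
            "animal_id": aid,
            "group": groups[aid],
            "vf_minute": vf_minutes[aid],
            "vf_phase": classify_vf_phase(vf_minutes[aid], config.vf_windows),
        }
        for aid in groups
    ]

    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()[:16]

    return StudyReport(
        config=config_dict,
        config_hash=config_hash,
        outcomes=outcomes,
        associations=association_table(predictor_frame, vf_binary),
        incidence=incidence_analysis(
            outcomes_df, config.vf_windows, config.incidence_test
        ),
        group_timecourses=_group_timecourses(timecourses, groups),
        rr_regressions=_rr_regressions(timecourses),
        ischemia_contrasts=_ischemia_contrasts(timecourses),
    )
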