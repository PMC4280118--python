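"""Plain-text table plumbing: manual blood samples, TAC/IF tables, JSON params."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import FrameSchedule, InputFunction, TimeActivityCurve

SAMPLE_COLUMNS = ["time_min", "whole_blood_kBq_mL", "plasma_kBq_mL", "parent_fraction"]


@dataclass(frozen=True)
class ManualSample:
    """One bedside arterial blood sample.

    time is minutes post-injection; activities are kBq/mL; parent_fraction is
    the un-metabolized fraction of plasma activity, in [0, 1].
    """

    time: float
    whole_blood: float
    plasma: float
    parent_fraction: float

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("sample time must be >= 0")
        if not (0.0 <= self.parent_fraction <= 1.0):
            raise ValueError("parent_fraction must lie in [0, 1]")


def read_samples(path: str | Path) -> list[ManualSample]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    return [ManualSample(r.time_min, r.whole_blood_kBq_mL, r.plasma_kBq_mL,
                         r.parent_fraction)
            for r in df.itertuples()]


def write_samples(samples: list[ManualSample], path: str | Path) -> None:
    pd.DataFrame(
        [(s.time, s.whole_blood, s.plasma, s.parent_fraction) for s in samples],
        columns=SAMPLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_tac(tac: TimeActivityCurve, path: str | Path,
              value_column: str = "activity_kBq_per_mL") -> None:
    pd.DataFrame({"time_s": tac.times, value_column: tac.values}).to_csv(
        path, sep="\t", index=False)


def read_tac(path: str | Path) -> TimeActivityCurve:
    df = pd.read_csv(path, sep="\t")
    value_col = [c for c in df.columns if c != "time_s"][0]
    return TimeActivityCurve(df["time_s"].to_numpy(), df[value_col].to_numpy(),
                             name=Path(path).stem)


def write_frame_tac(schedule: FrameSchedule, values: np.ndarray, path: str | Path
                    ) -> None:
    """Frame-resolved TAC table: t_start_s, t_end_s, activity_kBq_per_mL."""
    pd.DataFrame({"t_start_s": schedule.frame_starts,
                  "t_end_s": schedule.frame_ends,
                  "activity_kBq_per_mL": np.asarray(values, float)}).to_csv(
        path, sep="\t", index=False)


def read_frame_tac(path: str | Path) -> tuple[FrameSchedule, TimeActivityCurve]:
    df = pd.read_csv(path, sep="\t")
    sched = FrameSchedule(df["t_start_s"].to_numpy(), df["t_end_s"].to_numpy())
    return sched, TimeActivityCurve(sched.mid_times,
                                    df["activity_kBq_per_mL"].to_numpy())


def write_region_tacs(schedule: FrameSchedule, tacs: dict[str, np.ndarray],
                      path: str | Path) -> None:
    """Multi-region frame TAC table: schedule columns + one column per region."""
    data = {"t_start_s": schedule.frame_starts, "t_end_s": schedule.frame_ends}
    for label, vals in tacs.items():
        data[label] = np.asarray(vals, float)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_region_tacs(path: str | Path
                     ) -> tuple[FrameSchedule, dict[str, TimeActivityCurve]]:
    df = pd.read_csv(path, sep="\t")
    sched = FrameSchedule(df["t_start_s"].to_numpy(), df["t_end_s"].to_numpy())
    tacs = {c: TimeActivityCurve(sched.mid_times, df[c].to_numpy(), name=c)
            for c in df.columns if c not in ("t_start_s", "t_end_s")}
    return sched, tacs


def write_input_function(inp: InputFunction, path: str | Path) -> None:
    pd.DataFrame({"time_s": inp.times,
                  "parent_plasma_kBq_mL": inp.values}).to_csv(
        path, sep="\t", index=False)
    meta = Path(str(path) + ".json")
    meta.write_text(json.dumps({"provenance": inp.provenance,
                                "calibration": inp.calibration}, indent=1))


def read_input_function(path: str | Path) -> InputFunction:
    df = pd.read_csv(path, sep="\t")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return InputFunction(df["time_s"].to_numpy(),
                         df["parent_plasma_kBq_mL"].to_numpy(),
                         provenance=meta.get("provenance", "ABSS"),
                         calibration=meta.get("calibration", {}))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
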