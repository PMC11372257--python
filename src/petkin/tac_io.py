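"""Time-activity-curve containers, table I/O, and run configuration.

A dynamic PET study is represented as per-region time-activity curves
(TACs) sampled on a shared frame schedule.  Frame boundaries are accepted
in seconds (the convention of scanner exports) and stored internally in
minutes, so that rate constants are in 1/min throughout.

The exchange format is a plain delimited table (CSV or TSV, autodetected)
with columns ``frame_start``, ``frame_end`` (seconds) followed by one
column per region; a leading ``#``-comment line records the activity unit.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

logger = logging.getLogger("petkin")

AORTA = "aorta"
RIGHT_VENTRICLE = "right_ventricle"
BLOOD_LABELS = (AORTA, RIGHT_VENTRICLE)

#: default total-body 90-min protocol with high-temporal-resolution early
#: framing: 30 x 2 s, 12 x 10 s, 7 x 60 s, 16 x 300 s  (= 5400 s)
DEFAULT_FRAMING_SECONDS: tuple[tuple[float, int], ...] = (
    (2.0, 30),
    (10.0, 12),
    (60.0, 7),
    (300.0, 16),
)


class ScheduleError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered frame boundaries, in minutes."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ScheduleError("starts/ends must be equal-length 1-d arrays")
        if np.any(ends <= starts):
            raise ScheduleError("every frame must satisfy end > start")
        if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ScheduleError("frames must be increasing and non-overlapping")
        if np.any(starts[1:] > ends[:-1] + 1e-9):
            logger.warning("frame schedule has gaps between frames")
        if self.duration <= 0:
            raise ScheduleError("schedule duration must be positive")

    @classmethod
    def from_seconds(cls, starts_s: Sequence[float], ends_s: Sequence[float]) -> "FrameSchedule":
        return cls(np.asarray(starts_s, float) / 60.0, np.asarray(ends_s, float) / 60.0)

    @classmethod
    def from_framing(cls, framing: Sequence[tuple[float, int]] = DEFAULT_FRAMING_SECONDS) -> "FrameSchedule":
        """Build from (frame_duration_seconds, count) blocks."""
        durs = np.concatenate([[d] * int(n) for d, n in framing])
        ends = np.cumsum(durs)
        starts = ends - durs
        return cls.from_seconds(starts, ends)

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def duration(self) -> float:
        return float(self.ends[-1] - self.starts[0])

    def truncated(self, t_max_min: float) -> "FrameSchedule":
        """Keep frames ending at or before ``t_max_min`` minutes."""
        keep = self.ends <= t_max_min + 1e-9
        if not np.any(keep):
            raise ScheduleError(f"no frames end before {t_max_min} min")
        return FrameSchedule(self.starts[keep], self.ends[keep])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and self.starts.shape == other.starts.shape
            and np.allclose(self.starts, other.starts)
            and np.allclose(self.ends, other.ends)
        )


def default_schedule() -> FrameSchedule:
    return FrameSchedule.from_framing()


@dataclass
class TimeActivityCurve:
    """Per-frame activity concentration of one region of one scan."""

    region_label: str
    schedule: FrameSchedule
    values: np.ndarray
    unit: str = "SUV"
    aggregation: Literal["mean", "peak"] = "mean"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise SchemaError(
                f"TAC '{self.region_label}': {self.values.size} values for "
                f"{self.schedule.n_frames} frames"
            )
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(f"TAC '{self.region_label}' contains non-finite values")
        if np.any(self.values < 0):
            logger.info("TAC '%s' has negative values (noise)", self.region_label)

    def truncated(self, t_max_min: float) -> "TimeActivityCurve":
        sched = self.schedule.truncated(t_max_min)
        return replace(self, schedule=sched, values=self.values[: sched.n_frames])


@dataclass
class ScanRecord:
    """All TACs of one dynamic scan, incl. the two blood-pool curves."""

    subject_id: str
    scan_id: str
    tacs: dict[str, TimeActivityCurve] = field(default_factory=dict)

    def __post_init__(self):
        missing = [b for b in BLOOD_LABELS if b not in self.tacs]
        if missing:
            raise SchemaError(
                f"scan {self.subject_id}/{self.scan_id} is missing required blood "
                f"region(s) {missing}; needs all of {list(BLOOD_LABELS)}"
            )
        sched = self.schedule
        for tac in self.tacs.values():
            if tac.schedule != sched:
                raise SchemaError("all TACs of a scan must share one frame schedule")

    @property
    def schedule(self) -> FrameSchedule:
        return next(iter(self.tacs.values())).schedule

    @property
    def tissue_labels(self) -> list[str]:
        return sorted(k for k in self.tacs if k not in BLOOD_LABELS)

    def blood(self, which: str = AORTA) -> TimeActivityCurve:
        return self.tacs[which]


# ---------------------------------------------------------------------------
# table I/O

def write_tac_table(scan: ScanRecord, path) -> Path:
    """Write a scan as a delimited table (blood columns first, then regions
    alphabetically); a header comment records units and subject/scan ids."""
    path = Path(path)
    sched = scan.schedule
    unit = next(iter(scan.tacs.values())).unit
    cols = list(BLOOD_LABELS) + scan.tissue_labels
    df = pd.DataFrame(
        {
            "frame_start": np.round(sched.starts * 60.0, 9),
            "frame_end": np.round(sched.ends * 60.0, 9),
        }
    )
    for c in cols:
        df[c] = scan.tacs[c].values
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    buf = io.StringIO()
    buf.write(
        f"# unit={unit} time=seconds subject={scan.subject_id} scan={scan.scan_id}\n"
    )
    df.to_csv(buf, sep=sep, index=False, float_format="%.17g")
    path.write_text(buf.getvalue())
    return path


def read_tac_table(path, schedule: Optional[FrameSchedule] = None) -> ScanRecord:
    """Read a TAC table written by :func:`write_tac_table` (or hand-made in
    the same layout).  ``schedule`` is checked against the file if given."""
    path = Path(path)
    text = path.read_text()
    meta: dict[str, str] = {}
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            for tok in line.lstrip("# ").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        else:
            break
    body = "\n".join(lines[body_start:])
    sep = "\t" if "\t" in lines[body_start] else ","
    try:
        df = pd.read_csv(io.StringIO(body), sep=sep, float_precision="round_trip")
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"cannot parse TAC table {path}: {e}") from e
    for col in ("frame_start", "frame_end"):
        if col not in df.columns:
            raise SchemaError(f"TAC table {path} lacks required column '{col}'")
    bad = df.columns[df.isna().any() | ~df.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna().all()
    )]
    if len(bad):
        rows = df[bad[0]].pipe(lambda c: pd.to_numeric(c, errors="coerce")).isna()
        raise SchemaError(
            f"non-numeric cell(s) in column '{bad[0]}' at row(s) "
            f"{list(df.index[rows])[:5]}"
        )
    file_sched = FrameSchedule.from_seconds(df["frame_start"].values, df["frame_end"].values)
    if schedule is not None and file_sched != schedule:
        raise SchemaError(
            f"frame schedule in {path} ({file_sched.n_frames} frames) does not "
            f"match the expected schedule ({schedule.n_frames} frames)"
        )
    unit = meta.get("unit", "SUV")
    region_cols = [c for c in df.columns if c not in ("frame_start", "frame_end")]
    missing = [b for b in BLOOD_LABELS if b not in region_cols]
    if missing:
        raise SchemaError(
            f"TAC table {path} is missing blood region column(s) {missing}; "
            f"required blood regions are {list(BLOOD_LABELS)}"
        )
    tacs = {
        c: TimeActivityCurve(c, file_sched, df[c].to_numpy(float), unit=unit)
        for c in region_cols
    }
    return ScanRecord(meta.get("subject", "unknown"), meta.get("scan", "scan"), tacs)


# ---------------------------------------------------------------------------
# run configuration

class RunConfig(BaseModel):
    """Validated pipeline configuration with the study's standard defaults."""

    model_config = ConfigDict(extra="forbid")

    t_star_min: float = 30.0            # Logan linearity onset
    suvr_window_min: tuple[float, float] = (60.0, 90.0)
    biexp_window_min: tuple[float, float] = (14.0, 90.0)
    extrap_horizon_min: float = 600.0   # 10 h
    mc_replicates: int = 100
    scan_minutes: float = 90.0
    delay_bound_min: float = 1.0
    seed: int = 20240901                # fixed documented default

    @model_validator(mode="after")
    def _check(self):
        if self.t_star_min >= self.scan_minutes:
            raise ValueError(
                f"t* = {self.t_star_min} min must be before scan end "
                f"({self.scan_minutes} min)"
            )
        for name in ("suvr_window_min", "biexp_window_min"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must be an increasing window, got {(lo, hi)}")
        if self.extrap_horizon_min < self.scan_minutes:
            raise ValueError("extrapolation horizon must reach past the scan end")
        if self.mc_replicates < 2:
            raise ValueError("mc_replicates must be >= 2")
        return self


def load_config(path=None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected with their names."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"config {path} must be a mapping")
    return RunConfig(**raw)
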