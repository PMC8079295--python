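"""Data model and file formats for shuttle-box hypoxia-avoidance trials.

A shuttle-box choice chamber consists of two circular compartments joined by a
short rectangular passage.  Dissolved oxygen (DO, expressed as % air
saturation) is controlled independently per compartment; a PVC tube in each
compartment serves as a shelter.  One fish is tracked per trial, its position
logged once per second together with the DO of both compartments and the water
temperature.

This module defines

* :class:`ArenaGeometry` — chamber dimensions, compartment centers, shelter
  zones, and the point-to-zone assignment used by all occupancy metrics;
* :class:`TrialProtocol` — the stepped DO schedule (normoxic baseline, ramps,
  holds, reoxygenation) and its decomposition into analysis intervals;
* :class:`PositionLog` / :class:`EODRecording` — the per-trial data containers
  with CSV / WAV round-trip I/O;
* YAML config I/O for geometry + protocol.

Coordinate convention: origin at the arena centroid, x-axis along the
compartment–passage–compartment line (left compartment at negative x), y up.
Boundary points shared between the passage rectangle and a compartment circle
are resolved to the passage, which makes side changes well defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .errors import ConfigError, FormatError, GeometryError, ProtocolError

Side = Literal["left", "right"]

LOG_COLUMNS = ["t_s", "x_cm", "y_cm", "dist_cm", "vel_cm_s", "do_left", "do_right", "temp_c"]

# column -> decimals written to CSV (the stated precision of the format)
_LOG_PRECISION = {"t_s": 0, "x_cm": 2, "y_cm": 2, "dist_cm": 3, "vel_cm_s": 3,
                  "do_left": 1, "do_right": 1, "temp_c": 2}


# ---------------------------------------------------------------------------
# Arena geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaGeometry:
    """Shuttle-box floor plan, all lengths in cm.

    Defaults correspond to a commercial two-compartment choice chamber: two
    50 cm circular compartments joined by an 8.5 cm × 14 cm passage, with a
    15 cm PVC tube (inner diameter 2.6 cm) as shelter in each compartment.
    The shelter *zone* is the tube footprint dilated by ``shelter_margin`` on
    every side, since "time in shelter" needs a geometric region rather than
    a physical tube wall.
    """

    compartment_diameter: float = 50.0
    passage_width: float = 8.5     # extent along y
    passage_length: float = 14.0   # extent along x (gap between the circles)
    shelter_length: float = 15.0   # tube length, along x
    shelter_width: float = 2.6     # tube inner diameter
    shelter_margin: float = 1.0    # dilation of the tube footprint

    def __post_init__(self) -> None:
        if self.compartment_diameter <= 0 or self.passage_width <= 0 or self.passage_length <= 0:
            raise GeometryError("arena dimensions must be positive")
        half_diag = math.hypot(self.shelter_length / 2 + self.shelter_margin,
                               self.shelter_width / 2 + self.shelter_margin)
        if half_diag > self.compartment_radius:
            raise GeometryError("shelter zone does not fit inside its compartment")

    @property
    def compartment_radius(self) -> float:
        return self.compartment_diameter / 2.0

    @property
    def compartment_centers(self) -> dict[Side, tuple[float, float]]:
        cx = self.compartment_radius + self.passage_length / 2.0
        return {"left": (-cx, 0.0), "right": (cx, 0.0)}

    @property
    def passage_bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the passage rectangle."""
        hx = self.passage_length / 2.0
        hy = self.passage_width / 2.0
        return (-hx, hx, -hy, hy)

    def shelter_bounds(self, side: Side) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the dilated shelter zone on ``side``."""
        cx, cy = self.compartment_centers[side]
        hx = self.shelter_length / 2.0 + self.shelter_margin
        hy = self.shelter_width / 2.0 + self.shelter_margin
        return (cx - hx, cx + hx, cy - hy, cy + hy)


@dataclass(frozen=True)
class Zone:
    compartment: Literal["left", "right", "passage"]
    in_shelter: bool


def assign_zone(x: float, y: float, geometry: ArenaGeometry) -> Zone:
    """Assign a tracked point to a compartment (or the passage) and a shelter flag.

    Every in-bounds point maps to exactly one of {left, right, passage};
    points on the circle/passage boundary go to the passage.  Raises
    :class:`GeometryError` for points outside the arena footprint.
    """
    comp, shel = assign_zones(np.asarray([x], float), np.asarray([y], float), geometry)
    return Zone(("left", "right", "passage")[comp[0]], bool(shel[0]))


def assign_zones(x: np.ndarray, y: np.ndarray,
                 geometry: ArenaGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized zone assignment.

    Returns ``(compartment, in_shelter)`` where compartment codes are
    0 = left, 1 = right, 2 = passage.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = geometry.compartment_radius
    centers = geometry.compartment_centers
    xmin, xmax, ymin, ymax = geometry.passage_bounds

    in_passage = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
    d_left = np.hypot(x - centers["left"][0], y - centers["left"][1])
    d_right = np.hypot(x - centers["right"][0], y - centers["right"][1])
    in_left = d_left <= r
    in_right = d_right <= r

    # tolerate coordinates rounded onto the wrong side of the wall (0.01 cm grid)
    tol = 0.05
    near_left = d_left <= r + tol
    near_right = d_right <= r + tol
    out = ~(in_passage | near_left | near_right)
    if np.any(out):
        i = int(np.flatnonzero(out)[0])
        raise GeometryError(f"point ({x.flat[i]:.2f}, {y.flat[i]:.2f}) outside arena footprint")

    comp = np.full(x.shape, 2, dtype=np.int8)
    comp[near_left & ~in_passage] = 0
    comp[near_right & ~in_passage] = 1

    in_shelter = np.zeros(x.shape, dtype=bool)
    for side in ("left", "right"):
        sxmin, sxmax, symin, symax = geometry.shelter_bounds(side)  # type: ignore[arg-type]
        in_shelter |= (x >= sxmin) & (x <= sxmax) & (y >= symin) & (y <= symax)
    in_shelter &= comp != 2
    return comp, in_shelter


# ---------------------------------------------------------------------------
# Trial protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One homogeneous piece of the hypoxic-side DO schedule."""
    kind: Literal["baseline", "ramp", "hold", "reoxygenation"]
    start_s: int
    duration_s: int
    do_start: float   # hypoxic-side target at segment start, % air sat
    do_end: float     # hypoxic-side target at segment end

    @property
    def end_s(self) -> int:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class Interval:
    """One analysis bin: the baseline block or a 10-min post-baseline bin."""
    interval_id: str
    kind: Literal["baseline", "ramp", "hold", "reoxygenation"]
    start_s: int
    end_s: int
    nominal_do: float  # hypoxic-side target for the bin; 100 for baseline

    @property
    def duration_s(self) -> int:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class TrialProtocol:
    """Stepped hypoxia schedule for the preferred ("hypoxic") compartment.

    The trial opens with a normoxic baseline in both compartments, then DO on
    the hypoxic side is lowered through ``step_targets`` — each step is a
    linear ramp of ``ramp_min`` minutes followed by a ``hold_min`` hold —
    and finally ramped back up during reoxygenation.  The refuge compartment
    is held at ``refuge_saturation`` (always above ``normoxic_floor``).
    """

    baseline_min: float = 40.0
    step_targets: tuple[float, ...] = (70.0, 50.0, 30.0, 25.0, 20.0, 15.0, 10.0)
    ramp_min: float = 10.0
    hold_min: float = 10.0
    reox_min: float = 20.0
    baseline_saturation: float = 97.0  # both sides during baseline (> 95 = normoxia)
    refuge_saturation: float = 90.0    # normoxic side after baseline
    normoxic_floor: float = 80.0

    def __post_init__(self) -> None:
        if min(self.baseline_min, self.ramp_min, self.hold_min, self.reox_min) <= 0:
            raise ProtocolError("all durations must be positive")
        targets = tuple(float(t) for t in self.step_targets)
        if any(not (0.0 < t <= 100.0) for t in targets):
            raise ProtocolError("step targets must lie in (0, 100] % air saturation")
        if any(b <= a for a, b in zip(targets[1:], targets[:-1])):
            raise ProtocolError(f"step targets must be strictly decreasing, got {targets}")
        if self.refuge_saturation <= self.normoxic_floor:
            raise ProtocolError("refuge saturation must exceed the normoxic floor")

    # -- durations ---------------------------------------------------------

    @property
    def total_min(self) -> float:
        return (self.baseline_min
                + len(self.step_targets) * (self.ramp_min + self.hold_min)
                + self.reox_min)

    @property
    def total_s(self) -> int:
        return int(round(self.total_min * 60))

    # -- schedule ----------------------------------------------------------

    def segments(self) -> list[Segment]:
        """Decompose the hypoxic-side schedule into contiguous segments."""
        segs: list[Segment] = []
        t = 0
        do = self.baseline_saturation
        segs.append(Segment("baseline", t, int(self.baseline_min * 60), do, do))
        t = segs[-1].end_s
        for target in self.step_targets:
            segs.append(Segment("ramp", t, int(self.ramp_min * 60), do, float(target)))
            t = segs[-1].end_s
            do = float(target)
            segs.append(Segment("hold", t, int(self.hold_min * 60), do, do))
            t = segs[-1].end_s
        segs.append(Segment("reoxygenation", t, int(self.reox_min * 60),
                            do, self.baseline_saturation))
        return segs

    def hypoxic_target(self, t_s: np.ndarray | float) -> np.ndarray:
        """Hypoxic-side DO target (% air sat) for every requested second."""
        t = np.atleast_1d(np.asarray(t_s, float))
        out = np.empty_like(t)
        for seg in self.segments():
            m = (t >= seg.start_s) & (t < seg.end_s)
            if seg.duration_s > 0:
                frac = (t[m] - seg.start_s) / seg.duration_s
                out[m] = seg.do_start + frac * (seg.do_end - seg.do_start)
        out[t >= self.total_s] = self.baseline_saturation
        return out

    def schedule(self) -> pd.DataFrame:
        """Per-second target DO for both sides over the whole trial.

        Columns: ``t_s``, ``do_hypoxic``, ``do_normoxic``.
        """
        t = np.arange(self.total_s)
        do_h = self.hypoxic_target(t)
        do_n = np.where(t < self.baseline_min * 60,
                        self.baseline_saturation, self.refuge_saturation)
        return pd.DataFrame({"t_s": t, "do_hypoxic": do_h, "do_normoxic": do_n})

    # -- analysis bins -----------------------------------------------------

    def intervals(self) -> list[Interval]:
        """Baseline block plus one bin per post-baseline schedule segment.

        Ramps and holds each form one bin; the reoxygenation segment is split
        into ``hold_min``-long bins.  Nominal DO is the hold target for hold
        bins and the bin-mean of the linear target for ramp/reoxygenation
        bins; baseline is coded at 100 (normoxia).
        """
        out: list[Interval] = [
            Interval("baseline", "baseline", 0, int(self.baseline_min * 60), 100.0)]
        idx = 1
        for seg in self.segments():
            if seg.kind == "baseline":
                continue
            if seg.kind == "reoxygenation":
                chunk = int(self.hold_min * 60)
                starts = list(range(seg.start_s, seg.end_s, chunk))
            else:
                starts = [seg.start_s]
            for s in starts:
                e = min(s + (int(self.hold_min * 60) if seg.kind == "reoxygenation"
                             else seg.duration_s), seg.end_s)
                if seg.kind == "hold":
                    nominal = seg.do_end
                else:
                    mid = np.arange(s, e) + 0.5
                    nominal = float(np.mean(self.hypoxic_target(mid)))
                out.append(Interval(f"bin{idx:02d}", seg.kind, s, e, nominal))
                idx += 1
        return out


def build_trial_protocol(baseline_min: float,
                         step_targets: Sequence[float],
                         ramp_min: float,
                         hold_min: float,
                         reox_min: float,
                         **kwargs) -> TrialProtocol:
    """Construct and validate a :class:`TrialProtocol`.

    The default trial (40 min baseline, steps 70/50/30/25/20/15/10 %,
    10 min ramps and holds, 20 min reoxygenation) totals 200 min.
    """
    return TrialProtocol(baseline_min=float(baseline_min),
                         step_targets=tuple(float(t) for t in step_targets),
                         ramp_min=float(ramp_min), hold_min=float(hold_min),
                         reox_min=float(reox_min), **kwargs)


def default_protocol() -> TrialProtocol:
    return TrialProtocol()


# ---------------------------------------------------------------------------
# Position logs
# ---------------------------------------------------------------------------

@dataclass
class PositionLog:
    """Per-second tracked state of one fish plus its DO/temperature environment.

    ``frame`` columns: t_s (int seconds from trial start, strictly 1-s
    spaced), x_cm, y_cm, dist_cm (step distance), vel_cm_s, do_left,
    do_right (% air saturation), temp_c.
    """

    fish_id: str
    sbl: float                    # standard body length, cm
    hypoxic_side: Side
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"position log missing columns: {missing}")
        self.frame = self.frame[LOG_COLUMNS].reset_index(drop=True)
        t = self.frame["t_s"].to_numpy()
        if len(t) and not np.all(np.diff(t) == 1):
            bad = int(np.flatnonzero(np.diff(t) != 1)[0]) + 1
            raise FormatError(f"time not strictly increasing at 1 s spacing at row {bad + 1}")
        if (self.frame["dist_cm"] < 0).any():
            raise FormatError("negative step distance")
        dv = (self.frame["vel_cm_s"] - self.frame["dist_cm"]).abs()
        if (dv > 0.05).any():
            raise FormatError("velocity inconsistent with per-second step distance")
        do = self.frame[["do_left", "do_right"]].to_numpy()
        if ((do < 0) | (do > 110)).any():
            raise FormatError("DO outside [0, 110] % air saturation")
        if self.sbl <= 0:
            raise FormatError("standard body length must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def do_hypoxic(self) -> pd.Series:
        return self.frame["do_left" if self.hypoxic_side == "left" else "do_right"]

    @property
    def do_normoxic(self) -> pd.Series:
        return self.frame["do_right" if self.hypoxic_side == "left" else "do_left"]


def write_position_log(log: PositionLog, path: str | Path) -> None:
    """Write a position log as commented-header CSV (UTF-8).

    Metadata lines (``# key=value``) precede the column header; numeric
    columns are rounded to the format's stated precision (x/y to 0.01 cm,
    DO to 0.1 %)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# fish_id={log.fish_id}\n")
        fh.write(f"# sbl_cm={log.sbl:.2f}\n")
        fh.write(f"# hypoxic_side={log.hypoxic_side}\n")
        fh.write(",".join(LOG_COLUMNS) + "\n")
        fmt = ["%d" if _LOG_PRECISION[c] == 0 else f"%.{_LOG_PRECISION[c]}f"
               for c in LOG_COLUMNS]
        arr = log.frame[LOG_COLUMNS].to_numpy()
        np.savetxt(fh, arr, fmt=fmt, delimiter=",")


def read_position_log(path: str | Path) -> PositionLog:
    """Read a position log written by :func:`write_position_log`.

    Raises :class:`FormatError` naming the offending line for missing
    columns, duplicated/non-monotone timestamps, or malformed metadata.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            header_line += 1
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
            else:
                break
    for key in ("fish_id", "sbl_cm", "hypoxic_side"):
        if key not in meta:
            raise FormatError(f"{path}: missing metadata line '# {key}=...'")
    if meta["hypoxic_side"] not in ("left", "right"):
        raise FormatError(f"{path}: hypoxic_side must be left or right")
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} in header line {header_line}")
    t = frame["t_s"].to_numpy()
    steps = np.diff(t)
    if np.any(steps != 1):
        row = int(np.flatnonzero(steps != 1)[0]) + 1
        raise FormatError(
            f"{path}: non-monotone or gapped timestamp at data row {row + 1} "
            f"(t={t[row]} after t={t[row - 1]})")
    try:
        return PositionLog(meta["fish_id"], float(meta["sbl_cm"]),
                           meta["hypoxic_side"], frame)  # type: ignore[arg-type]
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# EOD recordings
# ---------------------------------------------------------------------------

@dataclass
class EODRecording:
    """Single-channel electric-organ-discharge voltage trace.

    ``window_times`` supports decimated synthesis/recording: when not None it
    holds the trial-clock second of each consecutive 1-s block of ``samples``
    (so ``len(samples) == len(window_times) * sample_rate``).  A contiguous
    recording has ``window_times is None`` and starts at ``start_time``.
    """

    fish_id: str
    sample_rate: int
    samples: np.ndarray
    start_time: float = 0.0
    window_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.window_times is not None:
            self.window_times = np.asarray(self.window_times, dtype=np.int64)
            if len(self.samples) != len(self.window_times) * self.sample_rate:
                raise FormatError("samples length inconsistent with window_times")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def write_eod_recording(rec: EODRecording, wav_path: str | Path) -> None:
    """Write as float32 WAV plus a JSON sidecar (<wav>.json) with metadata."""
    wav_path = Path(wav_path)
    wavfile.write(wav_path, rec.sample_rate, rec.samples.astype(np.float32))
    sidecar = {"fish_id": rec.fish_id, "sample_rate": rec.sample_rate,
               "start_time": rec.start_time,
               "window_times": None if rec.window_times is None
               else rec.window_times.tolist()}
    Path(str(wav_path) + ".json").write_text(json.dumps(sidecar), encoding="utf-8")


def read_eod_recording(wav_path: str | Path) -> EODRecording:
    wav_path = Path(wav_path)
    rate, samples = wavfile.read(wav_path)
    sidecar_path = Path(str(wav_path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text(encoding="utf-8"))
    if int(meta["sample_rate"]) != int(rate):
        raise FormatError(f"{wav_path}: sidecar sample_rate disagrees with WAV header")
    wt = meta.get("window_times")
    return EODRecording(meta["fish_id"], int(rate), np.asarray(samples, np.float64),
                        float(meta.get("start_time", 0.0)),
                        None if wt is None else np.asarray(wt, np.int64))


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def save_config(path: str | Path, geometry: ArenaGeometry, protocol: TrialProtocol) -> None:
    """Write arena geometry and trial protocol to one YAML file."""
    doc = {
        "arena": {k: getattr(geometry, k) for k in
                  ("compartment_diameter", "passage_width", "passage_length",
                   "shelter_length", "shelter_width", "shelter_margin")},
        "protocol": {
            "baseline_min": protocol.baseline_min,
            "step_targets": list(protocol.step_targets),
            "ramp_min": protocol.ramp_min,
            "hold_min": protocol.hold_min,
            "reox_min": protocol.reox_min,
            "baseline_saturation": protocol.baseline_saturation,
            "refuge_saturation": protocol.refuge_saturation,
            "normoxic_floor": protocol.normoxic_floor,
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_config(path: str | Path) -> tuple[ArenaGeometry, TrialProtocol]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        geometry = ArenaGeometry(**doc.get("arena", {}))
        proto = dict(doc.get("protocol", {}))
        if "step_targets" in proto:
            proto["step_targets"] = tuple(proto["step_targets"])
        protocol = TrialProtocol(**proto)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return geometry, protocol
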