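"""Interval-level behavioral metrics from shuttle-box position logs.

Each trial is summarized over the normoxic baseline block and every
subsequent 10-min bin: residence in the hypoxic compartment (% of interval
time), time in shelter (%), number of side changes, distance travelled (m)
and median swimming velocity in body lengths per second.  Passage time counts
to neither compartment but stays in the denominator of the percentages, so
hypoxic + normoxic + passage occupancy always totals 100 %.

Swimming speed and distance are deliberately *not* corrected for the
circulating water current of the chamber; they index activity changes
(stationary vs. roaming), not calibrated kinematics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .trial_io import ArenaGeometry, PositionLog, Side, TrialProtocol, assign_zones

_LEFT, _RIGHT, _PASSAGE = 0, 1, 2


@dataclass(frozen=True)
class IntervalSummary:
    """Behavioral metrics for one fish in one analysis bin."""

    fish_id: str
    interval_id: str
    interval_kind: str          # baseline | ramp | hold | reoxygenation
    nominal_do: float           # hypoxic-side target, % air sat (100 at baseline)
    measured_do_mean: float     # mean measured hypoxic-side DO over the bin
    residence_hypoxic: float    # % of interval time
    shelter_time: float         # % of interval time
    side_changes: int
    distance: float             # m
    velocity_median: float      # BL/s


def residence_hypoxic(compartments: np.ndarray, hypoxic_side: Side) -> float:
    """Percent of interval seconds spent in the hypoxic compartment.

    ``compartments`` holds zone codes (0 = left, 1 = right, 2 = passage);
    passage seconds count toward the denominator only.
    """
    comp = np.asarray(compartments)
    if comp.size == 0:
        raise InsufficientDataError("empty interval: residence undefined")
    code = _LEFT if hypoxic_side == "left" else _RIGHT
    return 100.0 * float(np.mean(comp == code))


def shelter_time(in_shelter: np.ndarray) -> float:
    """Percent of interval seconds spent inside either shelter zone."""
    flags = np.asarray(in_shelter, bool)
    if flags.size == 0:
        raise InsufficientDataError("empty interval: shelter time undefined")
    return 100.0 * float(np.mean(flags))


def count_side_changes(compartments: np.ndarray) -> int:
    """Number of left<->right transitions of compartment occupancy.

    Passage dwell between two entries of the *same* compartment does not
    count; passage dwell between different compartments counts once.
    Implemented by dropping passage seconds and counting changes in the
    collapsed left/right sequence.
    """
    comp = np.asarray(compartments)
    sides = comp[comp != _PASSAGE]
    if sides.size < 2:
        return 0
    return int(np.sum(sides[1:] != sides[:-1]))


def distance_and_velocity(step_cm: np.ndarray, vel_cm_s: np.ndarray,
                          sbl: float) -> tuple[float, float]:
    """Total distance (m) and median velocity (body lengths per second)."""
    if sbl <= 0:
        raise ValueError("standard body length must be positive")
    step = np.asarray(step_cm, float)
    vel = np.asarray(vel_cm_s, float)
    return float(np.sum(step) / 100.0), float(np.median(vel) / sbl)


def side_preference(compartments: np.ndarray) -> tuple[Side, float]:
    """Preferred compartment during baseline and its occupancy (% of time).

    Ties are broken toward the left compartment with a warning.
    """
    comp = np.asarray(compartments)
    if comp.size == 0:
        raise InsufficientDataError("empty baseline interval")
    left = 100.0 * float(np.mean(comp == _LEFT))
    right = 100.0 * float(np.mean(comp == _RIGHT))
    if left == right:
        warnings.warn("no side preference (exact tie); reporting left", stacklevel=2)
        return "left", left
    return ("left", left) if left > right else ("right", right)


def bin_intervals(log: PositionLog, protocol: TrialProtocol,
                  geometry: ArenaGeometry) -> list[IntervalSummary]:
    """Summarize one trial log over the protocol's analysis bins.

    Returns one :class:`IntervalSummary` per interval (baseline first).
    Raises :class:`InsufficientDataError` if the log is shorter than the
    protocol, naming the missing bins.
    """
    intervals = protocol.intervals()
    n = len(log)
    missing = [iv.interval_id for iv in intervals if iv.end_s > n]
    if missing:
        raise InsufficientDataError(
            f"log covers {n} s but protocol needs {protocol.total_s} s; "
            f"missing bins: {missing}")

    comp, shel = assign_zones(log.frame["x_cm"].to_numpy(),
                              log.frame["y_cm"].to_numpy(), geometry)
    do_hyp = log.do_hypoxic.to_numpy()
    step = log.frame["dist_cm"].to_numpy()
    vel = log.frame["vel_cm_s"].to_numpy()

    out: list[IntervalSummary] = []
    for iv in intervals:
        sl = slice(iv.start_s, iv.end_s)
        dist_m, vel_med = distance_and_velocity(step[sl], vel[sl], log.sbl)
        out.append(IntervalSummary(
            fish_id=log.fish_id,
            interval_id=iv.interval_id,
            interval_kind=iv.kind,
            nominal_do=iv.nominal_do,
            measured_do_mean=float(np.mean(do_hyp[sl])),
            residence_hypoxic=residence_hypoxic(comp[sl], log.hypoxic_side),
            shelter_time=shelter_time(shel[sl]),
            side_changes=count_side_changes(comp[sl]),
            distance=dist_m,
            velocity_median=vel_med,
        ))
    return out


def summaries_frame(summaries: Iterable[IntervalSummary]) -> pd.DataFrame:
    """Stack interval summaries (possibly across fish) into a tidy DataFrame."""
    return pd.DataFrame([s.__dict__ for s in summaries])


def residence_by_level(summaries: Iterable[IntervalSummary],
                       include_baseline: bool = True) -> pd.DataFrame:
    """Residence-vs-DO dataset for broken-stick threshold estimation.

    One row per fish per *established* air-saturation level (hold bins), with
    the baseline block coded at DO = 100 when ``include_baseline`` is true.
    Columns: ``fish_id``, ``do``, ``residence``.
    """
    rows = []
    for s in summaries:
        if s.interval_kind == "hold" or (include_baseline
                                         and s.interval_kind == "baseline"):
            rows.append({"fish_id": s.fish_id, "do": s.nominal_do,
                         "residence": s.residence_hypoxic})
    if not rows:
        raise InsufficientDataError("no hold/baseline intervals in summaries")
    return pd.DataFrame(rows)
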