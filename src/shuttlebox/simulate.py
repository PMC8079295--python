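"""Synthetic shuttle-box trials: cohorts, trajectories, and EOD traces.

The generator emulates the structure of a hypoxia-avoidance choice experiment
with juvenile wave-type weakly electric fish:

* each fish has a strong baseline preference for one compartment and rests in
  its shelter at normoxia;
* hypoxia is induced on the *preferred* side; once the DO target there falls
  below the fish's individual avoidance threshold θ, a responder shifts to the
  normoxic refuge, upregulates swimming, and only re-enters hypoxia for brief
  excursions (geometric dwell, mean ~20 s);
* a cohort of 16 contains exactly one non-responder (θ = 0);
* the electric organ discharge (EOD) is a continuous quasi-sinusoid whose
  instantaneous frequency follows water temperature with a Q10 law,
  f(t) = f0 · Q10^((T(t) − T0)/10); temperature drifts linearly during a trial
  (default −0.15 °C).

Behavior is a two-state (shelter/roam) per-second Markov chain with
DO-dependent transition probabilities; transits between compartments follow
way-points through the passage at a bounded speed, so trajectories are
continuous paths.  One RNG stream is derived per fish from (seed, fish index),
so cohorts are extensible without reshuffling earlier fish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .trial_io import (ArenaGeometry, EODRecording, PositionLog, Side,
                       TrialProtocol, assign_zones)


@dataclass(frozen=True)
class FishParams:
    """Per-fish simulation parameters.

    Rates are per-second probabilities of the two-state behavior chain:
    ``roam_rate_base``/``roam_rate_hypoxic`` govern leaving the shelter at
    normoxia vs. under avoidance, ``settle_rate`` returning to a shelter,
    ``switch_rate_base`` spontaneous side changes while roaming, and
    ``excursion_rate`` starting a brief foray back into hypoxia while
    avoiding.  ``avoidance_threshold`` θ is the hypoxic-side DO (% air
    saturation) below which a responder starts avoiding; a non-responder has
    ``responder=False`` and θ = 0.
    """

    fish_id: str
    sbl: float                     # standard body length, cm
    body_mass: float               # g
    base_eod_freq: float           # f0, Hz at trial-start temperature
    preferred_side: Side
    avoidance_threshold: float     # θ, % air saturation
    roam_rate_base: float = 0.004
    roam_rate_hypoxic: float = 0.25
    settle_rate: float = 0.08
    switch_rate_base: float = 0.0015
    excursion_rate: float = 0.010
    mean_excursion_s: float = 20.0
    responder: bool = True

    def __post_init__(self) -> None:
        for name in ("roam_rate_base", "roam_rate_hypoxic", "settle_rate",
                     "switch_rate_base", "excursion_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if self.avoidance_threshold < 0:
            raise ConfigError("avoidance threshold must be >= 0")
        if self.sbl <= 0:
            raise ConfigError("sbl must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level study conditions.

    Defaults reproduce the experiment the generator emulates: n = 16 fish,
    base EOD frequencies in [807, 1151] Hz at ~25.7 °C, body lengths in
    [7.6, 10.4] cm, a linear temperature drift of −0.15 °C per trial, and a
    Q10 of 1.55 for EOD frequency.  ``theta_mean``/``theta_sd`` set the
    population distribution of the avoidance threshold θ.
    """

    n_fish: int = 16
    seed: int = 0
    protocol: TrialProtocol = field(default_factory=TrialProtocol)
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    theta_mean: float = 22.0
    theta_sd: float = 2.0
    n_nonresponders: int | None = None   # None -> 1 when n_fish == 16 else 0
    eod_freq_range: tuple[float, float] = (807.0, 1151.0)
    sbl_range: tuple[float, float] = (7.6, 10.4)
    temperature_start: float = 25.65
    temperature_drift: float = -0.15     # ΔT over the whole trial, °C
    q10: float = 1.55
    sample_rate: int = 20000
    eod_noise_sd: float = 0.05
    eod_harmonics: tuple[float, ...] = (1.0, 0.25, 0.08)  # fundamental first
    do_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ConfigError("n_fish must be >= 1")
        if self.q10 <= 0:
            raise ConfigError("q10 must be positive")
        if self.eod_noise_sd < 0 or self.do_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")


def _fish_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    # independent streams per (fish, purpose); stream 0 = params, 1 = trajectory, 2 = EOD
    return np.random.default_rng([seed, index, stream])


def _fish_index(fish_id: str) -> int:
    """Stable small integer from a fish id ('f07' -> 6; otherwise hashed)."""
    tail = fish_id.lstrip("fF")
    if tail.isdigit():
        return int(tail) - 1
    return sum(ord(c) * 31 ** k for k, c in enumerate(fish_id)) % (2**20)


def sample_cohort(config: SimulationConfig) -> list[FishParams]:
    """Draw a reproducible cohort of :class:`FishParams`.

    Preferred sides are balanced to within one fish; with the default
    16-fish cohort exactly one fish is a non-responder (θ = 0).
    """
    n = config.n_fish
    n_nr = config.n_nonresponders
    if n_nr is None:
        n_nr = 1 if n == 16 else 0
    if n_nr > n:
        raise ConfigError("more non-responders than fish")

    head = np.random.default_rng([config.seed, 10**6])
    sides = np.array(["left", "right"] * ((n + 1) // 2))[:n]
    head.shuffle(sides)
    nonresp = head.choice(n, size=n_nr, replace=False)

    cohort: list[FishParams] = []
    for i in range(n):
        rng = _fish_rng(config.seed, i, 0)
        sbl = rng.uniform(*config.sbl_range)
        # mass roughly cubic in length, matched to ~3 g at 8.9 cm
        mass = 3.0 * (sbl / 8.9) ** 3 * rng.uniform(0.85, 1.15)
        f0 = rng.uniform(*config.eod_freq_range)
        theta = float(np.clip(rng.normal(config.theta_mean, config.theta_sd), 5.0, 60.0))
        responder = i not in nonresp
        if not responder:
            theta = 0.0
        cohort.append(FishParams(
            fish_id=f"f{i + 1:02d}", sbl=float(sbl), body_mass=float(mass),
            base_eod_freq=float(f0), preferred_side=str(sides[i]),  # type: ignore[arg-type]
            avoidance_threshold=theta, responder=responder))
    return cohort


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

_TRANSIT_SPEED = 12.0   # cm/s while shuttling between compartments or homing
_ROAM_SPEED = 1.3       # mean roaming speed, cm/s
_ROAM_SPEED_SD = 0.6
_TURN_SD = 0.7          # rad/s heading diffusion while roaming
_SHELTER_JITTER = 0.05  # cm while resting in the shelter
_WALL_MARGIN = 1.5      # cm kept clear of the compartment wall
_DEPTH_SCALE = 20.0     # %sat below theta over which avoidance ramps to full
_ROAM_RETURN = 0.05     # extra per-second return rate to the hypoxic side as avoidance wanes


def _clamp_to_compartment(pos: np.ndarray, side: Side, geom: ArenaGeometry) -> np.ndarray:
    cx, cy = geom.compartment_centers[side]
    r = geom.compartment_radius - _WALL_MARGIN
    d = math.hypot(pos[0] - cx, pos[1] - cy)
    if d > r:
        scale = r / d
        return np.array([cx + (pos[0] - cx) * scale, cy + (pos[1] - cy) * scale])
    return pos


def _shelter_center(side: Side, geom: ArenaGeometry) -> np.ndarray:
    return np.asarray(geom.compartment_centers[side], float)


def simulate_trajectory(fish: FishParams, config: SimulationConfig) -> PositionLog:
    """Simulate one fish's per-second trajectory over the whole trial.

    The fish starts sheltering on its preferred side (which is also the side
    later made hypoxic).  Avoidance is *graded*: its intensity
    ``a = clip((θ − DO) / depth_scale, 0, 1)`` rises from 0 at the threshold
    to 1 once DO is ``depth_scale`` %sat below θ.  With increasing intensity
    the fish leaves its shelter more readily, flees the hypoxic side while
    roaming, settles there less, and re-enters hypoxia only for brief
    excursions (geometric dwell, mean ``mean_excursion_s``).  This yields the
    threshold dynamic the analysis targets: occupancy flat above θ and
    declining roughly linearly below it, with a non-zero excursion floor.

    The logged DO columns are the protocol targets plus measurement noise;
    temperature drifts linearly by ``temperature_drift``.
    """
    rng = _fish_rng(config.seed, _fish_index(fish.fish_id), 1)
    protocol, geom = config.protocol, config.geometry
    sched = protocol.schedule()
    n = len(sched)
    do_h_target = sched["do_hypoxic"].to_numpy()

    hyp_side: Side = fish.preferred_side
    ref_side: Side = "right" if hyp_side == "left" else "left"

    pos = _shelter_center(hyp_side, geom).copy()
    side: Side = hyp_side
    state = "shelter"              # shelter | roam | transit | homing
    waypoints: list[np.ndarray] = []
    transit_target: Side = hyp_side
    heading = rng.uniform(0, 2 * np.pi)

    xs = np.empty(n)
    ys = np.empty(n)
    xs[0], ys[0] = pos

    theta = fish.avoidance_threshold if fish.responder else 0.0

    for t in range(1, n):
        a = min(max((theta - do_h_target[t]) / _DEPTH_SCALE, 0.0), 1.0)

        if state in ("transit", "homing"):
            target = waypoints[0]
            delta = target - pos
            dist = math.hypot(*delta)
            if dist <= _TRANSIT_SPEED:
                pos = target.copy()
                waypoints.pop(0)
                if not waypoints:
                    if state == "transit":
                        side = transit_target
                        state = "roam"
                        heading = rng.uniform(0, 2 * np.pi)
                    else:
                        state = "shelter"
            else:
                pos = pos + delta * (_TRANSIT_SPEED / dist)
        elif state == "shelter":
            leave_p = fish.roam_rate_base + a * (fish.roam_rate_hypoxic
                                                 - fish.roam_rate_base)
            if rng.random() < leave_p:
                state = "roam"
                heading = rng.uniform(0, 2 * np.pi)
            pos = _clamp_to_compartment(pos + rng.normal(0, _SHELTER_JITTER, 2), side, geom)
        else:  # roam
            start_transit_to: Side | None = None
            go_home = False
            if a > 0:
                # symmetric two-state side switching: leaving the hypoxic side
                # accelerates with avoidance intensity (dwell ~ mean_excursion/a),
                # returns decay toward the bare excursion rate, so hypoxic-side
                # occupancy declines smoothly from ~1 toward the excursion floor
                if side == hyp_side:
                    if rng.random() < a / fish.mean_excursion_s:
                        start_transit_to = ref_side
                    elif rng.random() < fish.settle_rate:
                        go_home = True
                else:
                    back_p = fish.excursion_rate + _ROAM_RETURN * (1.0 - a)
                    if rng.random() < back_p:
                        start_transit_to = hyp_side
                    elif rng.random() < fish.settle_rate:
                        go_home = True
            else:
                if rng.random() < fish.switch_rate_base:
                    start_transit_to = ref_side if side == hyp_side else hyp_side
                elif side != fish.preferred_side and rng.random() < 0.1:
                    start_transit_to = fish.preferred_side  # drift home at normoxia
                elif rng.random() < fish.settle_rate:
                    go_home = True
            if start_transit_to is not None:
                # route through the passage: entry/exit on the centerline keep
                # every leg a chord of a convex region (no corner cutting)
                state = "transit"
                transit_target = start_transit_to
                hx = geom.passage_bounds[1]
                entry = np.array([-hx if side == "left" else hx, 0.0])
                exit_ = np.array([hx if start_transit_to == "right" else -hx, 0.0])
                waypoints = [entry, exit_,
                             _shelter_center(start_transit_to, geom)
                             + rng.normal(0, 2.0, 2)]
            elif go_home:
                state = "homing"
                waypoints = [_shelter_center(side, geom) + rng.normal(0, 0.3, 2)]
            else:
                heading += rng.normal(0, _TURN_SD)
                speed = max(rng.normal(_ROAM_SPEED, _ROAM_SPEED_SD), 0.0)
                cand = pos + speed * np.array([math.cos(heading), math.sin(heading)])
                new = _clamp_to_compartment(cand, side, geom)
                if not np.array_equal(new, cand):
                    heading = rng.uniform(0, 2 * np.pi)  # bounced off the wall
                pos = new
        xs[t], ys[t] = pos

    step = np.hypot(np.diff(xs, prepend=xs[0]), np.diff(ys, prepend=ys[0]))
    do_h = np.clip(do_h_target + rng.normal(0, config.do_noise_sd, n), 0, 110)
    do_n = np.clip(sched["do_normoxic"].to_numpy()
                   + rng.normal(0, config.do_noise_sd, n), 0, 110)
    temp = config.temperature_start + config.temperature_drift * np.arange(n) / max(n - 1, 1)

    frame = pd.DataFrame({
        "t_s": np.arange(n),
        "x_cm": np.round(xs, 2), "y_cm": np.round(ys, 2),
        "dist_cm": np.round(step, 3), "vel_cm_s": np.round(step, 3),
        "do_left": np.round(do_h if hyp_side == "left" else do_n, 1),
        "do_right": np.round(do_h if hyp_side == "right" else do_n, 1),
        "temp_c": np.round(temp, 2),
    })
    return PositionLog(fish.fish_id, fish.sbl, hyp_side, frame)


def simulate_cohort_logs(config: SimulationConfig) -> list[PositionLog]:
    """Sample a cohort and simulate one trial log per fish."""
    return [simulate_trajectory(f, config) for f in sample_cohort(config)]


# ---------------------------------------------------------------------------
# EOD synthesis
# ---------------------------------------------------------------------------

def simulate_eod(fish: FishParams, log: PositionLog, config: SimulationConfig,
                 stride: int = 1, phase0: float | None = None) -> EODRecording:
    """Synthesize the EOD voltage trace implied by a trial log.

    The instantaneous frequency follows the Q10 temperature law
    ``f(t) = f0 * q10 ** ((T(t) - T0) / 10)`` with T0 the trial-start
    temperature; the signal is the fundamental plus the configured harmonic
    series plus white Gaussian noise, with phase accumulated sample by sample
    (continuous within the synthesized stretch).

    ``stride=1`` synthesizes the full trial contiguously.  ``stride=k > 1``
    produces one 1-s snippet every k seconds (times recorded in
    ``window_times``), which keeps long-trial fixtures small; phase restarts
    at each snippet.
    """
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    rng = _fish_rng(config.seed, _fish_index(fish.fish_id), 2)
    fs = config.sample_rate
    temp = log.frame["temp_c"].to_numpy()
    t0 = temp[0]
    f_sec = fish.base_eod_freq * config.q10 ** ((temp - t0) / 10.0)

    n_sec = len(f_sec)
    seconds = np.arange(0, n_sec, stride)
    out = np.empty(len(seconds) * fs)
    amps = np.asarray(config.eod_harmonics, float)

    phase = rng.uniform(0, 2 * np.pi) if phase0 is None else float(phase0)
    for j, s in enumerate(seconds):
        # linear frequency interpolation across the window
        f_start = f_sec[s]
        f_end = f_sec[min(s + 1, n_sec - 1)]
        f_inst = f_start + (f_end - f_start) * np.arange(fs) / fs
        ph = phase + 2 * np.pi * np.cumsum(f_inst) / fs
        block = np.zeros(fs)
        for h, a in enumerate(amps, start=1):
            block += a * np.sin(h * ph)
        if config.eod_noise_sd > 0:
            block += rng.normal(0, config.eod_noise_sd, fs)
        out[j * fs:(j + 1) * fs] = block
        if stride == 1:
            phase = ph[-1]
        else:
            phase = rng.uniform(0, 2 * np.pi) if phase0 is None else float(phase0)

    return EODRecording(fish.fish_id, fs, out,
                        start_time=float(log.frame["t_s"].iloc[0]),
                        window_times=None if stride == 1 else seconds)
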