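"""Saltatory mitochondrial transport: a continuous-time run/pause process.

Each mitochondrion alternates processive runs and pauses with exponential
dwell times (run -> pause at ``pause_rate``, pause -> run at
``resume_rate``); at each run start the direction may reverse with
``switch_prob`` and a new speed is drawn. Positions are confined to
[0, axon_length]: a run that reaches a boundary sticks there (a pause)
until its scheduled end. Time is continuous; sampling onto the frame grid
happens only when the movie is rendered or samples are requested.

For recordings of connecting axonal segments, electrical stimulation can
trigger halting: shortly after the train ends each mitochondrion halts
with probability ``halt_prob`` for an exponentially distributed recovery
time, producing a transient drop in ensemble transport that partially
recovers within the recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..datatypes import MitoTrajectory, StimulationProtocol, TransportEvent

__all__ = [
    "MotilityParams",
    "HaltingParams",
    "simulate_mito_transport",
    "stationary_run_fraction",
    "expected_moved_fraction",
]


@dataclass(frozen=True)
class MotilityParams:
    """Run/pause chain parameters.

    Default rates give a mean run of 20 s, mean pause of 30 s, hence a
    stationary moving fraction of 0.4 — an actively transported axonal
    pool of realistic size.
    """

    speed_mean: float = 0.5  # um/s
    speed_sd: float = 0.15
    speed_bounds: tuple[float, float] = (0.05, 2.0)
    antero_bias: float = 0.5  # P(first run is anterograde)
    switch_prob: float = 0.3  # P(direction reversal at a run start)
    pause_rate: float = 0.05  # 1/s, run -> pause
    resume_rate: float = 1.0 / 30.0  # 1/s, pause -> run

    def __post_init__(self) -> None:
        if self.pause_rate < 0 or self.resume_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.antero_bias <= 1 and 0 <= self.switch_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class HaltingParams:
    """Activity-triggered halting for connecting segments.

    A halted mitochondrion stops ``latency`` seconds after the end of the
    stimulus train and resumes after an Exp(``recovery_tau``) interval, so
    the ensemble binned-distance trace dips sharply and climbs back to
    roughly half its baseline by the end of a 300 s recording.
    """

    halt_prob: float = 0.9
    latency: float = 2.0  # s after stimulus offset
    recovery_tau: float = 240.0  # s

    def __post_init__(self) -> None:
        if not (0 <= self.halt_prob <= 1):
            raise ValueError("halt_prob must lie in [0, 1]")
        if self.latency < 0 or self.recovery_tau <= 0:
            raise ValueError("invalid halting timing parameters")


def stationary_run_fraction(motility: MotilityParams) -> float:
    """Stationary probability of the run state, resume/(resume+pause)."""
    kp, kr = motility.pause_rate, motility.resume_rate
    if math.isinf(kp):
        return 0.0
    if kp == 0 and kr == 0:
        return 1.0  # degenerate: whatever state it starts in; we start running
    return kr / (kr + kp)


def expected_moved_fraction(motility: MotilityParams, duration: float) -> float:
    """P(a mitochondrion spends any time running within ``duration``).

    Starting from the stationary distribution, only one started-paused
    path never moves: 1 - pi_pause * exp(-resume_rate * duration).
    """
    pi_run = stationary_run_fraction(motility)
    return 1.0 - (1.0 - pi_run) * math.exp(-motility.resume_rate * duration)


def _draw_speed(rng: np.random.Generator, mp: MotilityParams) -> float:
    lo, hi = mp.speed_bounds
    if mp.speed_sd == 0:
        return min(max(mp.speed_mean, lo), hi)
    v = rng.normal(mp.speed_mean, mp.speed_sd)
    while not (lo <= v <= hi):
        v = rng.normal(mp.speed_mean, mp.speed_sd)
    return v


def _exp_duration(rng: np.random.Generator, rate: float) -> float:
    if rate == 0:
        return math.inf
    if math.isinf(rate):
        return 0.0
    return rng.exponential(1.0 / rate)


def _simulate_one(
    rng: np.random.Generator,
    mito_id: int,
    length: float,
    mp: MotilityParams,
    duration: float,
    frame_times: np.ndarray,
    halt: tuple[float, float] | None,
) -> MitoTrajectory:
    segs: list[tuple[float, float, float, float, str]] = []  # t0, t1, x0, x1, kind
    t = 0.0
    x = rng.uniform(0.0, length)
    direction = 1 if rng.random() < mp.antero_bias else -1
    running = rng.random() < stationary_run_fraction(mp)
    pending_halt = halt  # (t_halt, recovery duration)
    first_run = True

    def new_direction() -> int:
        nonlocal direction, first_run
        if not first_run and rng.random() < mp.switch_prob:
            direction = -direction
        first_run = False
        return direction

    while t < duration - 1e-12:
        if pending_halt is not None and t >= pending_halt[0] - 1e-12:
            t1 = min(t + pending_halt[1], duration)
            if t1 > t:
                segs.append((t, t1, x, x, "pause"))
            t = t1
            pending_halt = None
            running = True
            continue
        if running:
            dwell = _exp_duration(rng, mp.pause_rate)
        else:
            dwell = _exp_duration(rng, mp.resume_rate)
        t1 = min(t + dwell, duration)
        if pending_halt is not None:
            t1 = min(t1, pending_halt[0])
        if t1 <= t:
            running = not running
            continue
        if running:
            v = _draw_speed(rng, mp)
            d = new_direction()
            # runs reflect at the segment boundaries (an organelle leaving
            # the traced stretch is replaced by one entering it)
            tt = t
            while tt < t1 - 1e-12 and v > 0:
                x_hit = length if d > 0 else 0.0
                t_hit = tt + abs(x_hit - x) / v
                if t_hit < t1:
                    if t_hit > tt:
                        segs.append((tt, t_hit, x, x_hit, "run"))
                    x = x_hit
                    tt = t_hit
                    d = -d
                    direction = d
                else:
                    x1 = x + d * v * (t1 - tt)
                    segs.append((tt, t1, x, x1, "run"))
                    x = x1
                    tt = t1
        else:
            segs.append((t, t1, x, x, "pause"))
        t = t1
        running = not running

    # breakpoints for piecewise-linear sampling
    if segs:
        ts = np.array([segs[0][0]] + [s[1] for s in segs])
        xs = np.array([segs[0][2]] + [s[3] for s in segs])
    else:
        ts = np.array([0.0, duration])
        xs = np.array([x, x])
    positions = np.interp(frame_times, ts, xs)

    # merge adjacent same-type segments into events
    events: list[TransportEvent] = []
    for t0, t1, x0, x1, kind in segs:
        if t1 <= t0:
            continue
        etype = (
            "pause"
            if kind == "pause"
            else ("run-antero" if x1 >= x0 else "run-retro")
        )
        if events and events[-1].type == etype:
            prev = events[-1]
            events[-1] = TransportEvent(
                type=etype,
                start=prev.start,
                end=t1,
                displacement=prev.displacement + (x1 - x0),
            )
        else:
            events.append(
                TransportEvent(type=etype, start=t0, end=t1, displacement=x1 - x0)
            )
    if not events:
        events = [
            TransportEvent(type="pause", start=0.0, end=duration, displacement=0.0)
        ]

    return MitoTrajectory(
        id=mito_id, time=frame_times.copy(), position=positions, events=events
    )


def simulate_mito_transport(
    axon_length_um: float = 100.0,
    motility: MotilityParams = MotilityParams(),
    protocol: StimulationProtocol | None = None,
    connecting: bool = False,
    n_mito: int = 20,
    duration: float = 300.0,
    frame_interval: float = 1.0,
    halting: HaltingParams = HaltingParams(),
    seed: int = 0,
) -> list[MitoTrajectory]:
    """Simulate ground-truth trajectories of ``n_mito`` mitochondria.

    With ``connecting=True`` and a stimulation protocol, mitochondria are
    subject to post-stimulus halting; with ``connecting=False`` the state
    process is independent of the stimulus. Returns trajectories sampled
    on the common frame grid with exact event labels.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if n_mito < 0:
        raise ValueError("n_mito must be non-negative")
    if axon_length_um <= 0 or duration <= 0:
        raise ValueError("axon_length_um and duration must be positive")
    rng = np.random.default_rng(seed)
    frame_times = np.arange(0.0, duration + 1e-9, frame_interval)
    trajs = []
    for k in range(n_mito):
        halt = None
        if connecting and protocol is not None and protocol.ap_count() > 0:
            if rng.random() < halting.halt_prob:
                t_halt = protocol.offset + halting.latency
                if t_halt < duration:
                    halt = (t_halt, rng.exponential(halting.recovery_tau))
        trajs.append(
            _simulate_one(
                rng, k, axon_length_um, motility, duration, frame_times, halt
            )
        )
    return trajs
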