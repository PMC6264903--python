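"""Gaze protocols: saccade/fixation training trajectories and test schedules.

Training emulates natural gaze statistics: for each of M head-centred
target locations (one "period"), the eyes make a sequence of P fixations
(300 ms each) at uniformly drawn eye positions, joined by constant-velocity
saccades at 400 deg/s, while the target stays put in head-centred space.
Testing holds the eyes at each of E positions in turn while the target
steps through T head-centred locations, dwelling 330 ms at each; output
rates are recorded at the end of every dwell.

Trajectories are stored as exact piecewise-linear breakpoints (fixations
constant, saccades linear), which linear interpolation reproduces exactly
at any sampling rate; ``sampled()`` returns dense arrays on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolConfig",
    "GazeTrajectory",
    "training_trajectory",
    "testing_schedule",
    "retinal_location",
    "sample_trajectory",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Training/testing protocol parameters (angles in deg, times in ms)."""

    training_locations: tuple[float, ...] = (-63.0, -45.0, -27.0, -9.0, 9.0, 27.0, 45.0, 63.0)
    fixations_per_location: int = 15  # P
    eye_range: tuple[float, float] = (-24.0, 24.0)
    saccade_speed: float = 400.0  # deg/s
    fixation_ms: float = 300.0
    test_eye_positions: tuple[float, ...] = (-18.0, -6.0, 6.0, 18.0)
    test_target_span: tuple[float, float] = (-79.0, 79.0)
    test_target_count: int = 80
    test_dwell_ms: float = 330.0

    @property
    def n_locations(self) -> int:
        return len(self.training_locations)


@dataclass
class GazeTrajectory:
    """Piecewise-linear gaze trajectory.

    ``times`` are segment breakpoints (ms, non-decreasing; duplicated times
    encode the instantaneous eye jump at a period/sweep boundary).  ``eye``
    gives eye position at each breakpoint with linear interpolation in
    between; ``target_h`` and ``labels`` describe segment k spanning
    [times[k], times[k+1]).
    """

    times: np.ndarray
    eye: np.ndarray
    target_h: np.ndarray  # per segment, len(times) - 1
    labels: np.ndarray  # per segment: 'fixation' | 'saccade'
    record_marks: np.ndarray = field(default_factory=lambda: np.empty(0))
    sweep_starts: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def sample(self, t):
        """(eye, target_h) at time(s) t: eye linearly interpolated, target
        piecewise constant.  At a duplicated breakpoint the later segment
        wins (the jump has happened)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("time outside trajectory span")
        k = np.searchsorted(self.times, t, side="right") - 1
        k = np.clip(k, 0, len(self.times) - 2)
        t0, t1 = self.times[k], self.times[k + 1]
        span = t1 - t0
        w = np.where(span > 0, (t - t0) / np.where(span > 0, span, 1.0), 0.0)
        eye = self.eye[k] * (1.0 - w) + self.eye[k + 1] * w
        return eye, self.target_h[k]

    def sampled(self, rate_hz: float = 1000.0):
        """Dense (times, eye, target) arrays at the given sampling rate."""
        ts = np.arange(0.0, self.duration + 1e-9, 1000.0 / rate_hz)
        eye, target = self.sample(ts)
        return ts, eye, target


def retinal_location(target_h, eye):
    """Retinal location r of a target at head-centred location h seen from
    eye position e: h = r + e, hence r = h - e."""
    return np.asarray(target_h) - np.asarray(eye)


def sample_trajectory(traj: GazeTrajectory, t):
    """Functional alias for :meth:`GazeTrajectory.sample`."""
    return traj.sample(t)


def training_trajectory(
    M: int | None = None,
    P: int | None = None,
    locations=None,
    eye_range: tuple[float, float] = (-24.0, 24.0),
    seed: int = 0,
    *,
    config: ProtocolConfig | None = None,
    saccade_speed: float = 400.0,
    fixation_ms: float = 300.0,
) -> GazeTrajectory:
    """One training epoch.

    The M listed head-centred locations are visited in order; each period
    holds the target fixed while the eyes make P fixations at eye positions
    drawn uniformly from ``eye_range`` (continuous), joined by P - 1
    constant-velocity saccades.  Each period starts at a freshly drawn eye
    position (no saccade across the period boundary).
    """
    if config is not None:
        locations = config.training_locations if locations is None else locations
        P = config.fixations_per_location if P is None else P
        eye_range = config.eye_range
        saccade_speed = config.saccade_speed
        fixation_ms = config.fixation_ms
    locations = tuple(locations)
    if M is None:
        M = len(locations)
    if len(locations) == 0:
        raise ValueError("empty training location list")
    if len(locations) != M:
        raise ValueError("M does not match the number of listed locations")

    rng = np.random.default_rng(seed)
    lo, hi = eye_range
    times: list[float] = [0.0]
    eye: list[float] = []
    target: list[float] = []
    labels: list[str] = []
    t = 0.0
    for m, h in enumerate(locations):
        fixes = rng.uniform(lo, hi, size=P)
        eye.append(fixes[0])  # instantaneous jump at the period boundary
        for p in range(P):
            t += fixation_ms
            times.append(t)
            eye.append(fixes[p])
            target.append(h)
            labels.append("fixation")
            if p + 1 < P:
                dur = abs(fixes[p + 1] - fixes[p]) / saccade_speed * 1000.0
                if dur > 0:
                    t += dur
                    times.append(t)
                    eye.append(fixes[p + 1])
                    target.append(h)
                    labels.append("saccade")
        if m + 1 < M:
            # duplicated breakpoint: zero-length segment marking the
            # instantaneous eye jump into the next period (never sampled)
            times.append(t)
            target.append(locations[m + 1])
            labels.append("fixation")
    return GazeTrajectory(
        times=np.asarray(times),
        eye=np.asarray(eye),
        target_h=np.asarray(target),
        labels=np.asarray(labels),
    )


def testing_schedule(
    E_positions=None,
    T_count: int | None = None,
    target_span: tuple[float, float] | None = None,
    dwell: float | None = None,
    *,
    config: ProtocolConfig | None = None,
) -> GazeTrajectory:
    """Deterministic test schedule.

    For each eye position (held fixed for a whole sweep) the target visits
    the T evenly spaced head-centred locations in ascending order for one
    dwell each; a record mark is placed at the end of every dwell, giving
    E x T marks in total.
    """
    if config is not None:
        E_positions = config.test_eye_positions if E_positions is None else E_positions
        T_count = config.test_target_count if T_count is None else T_count
        target_span = config.test_target_span if target_span is None else target_span
        dwell = config.test_dwell_ms if dwell is None else dwell
    E_positions = tuple(E_positions)
    targets = np.linspace(target_span[0], target_span[1], T_count)

    times: list[float] = [0.0]
    eye: list[float] = []
    target: list[float] = []
    labels: list[str] = []
    marks: list[float] = []
    sweeps: list[float] = []
    t = 0.0
    for s, e in enumerate(E_positions):
        sweeps.append(t)
        eye.append(e)
        for h in targets:
            t += dwell
            times.append(t)
            eye.append(e)
            target.append(h)
            labels.append("fixation")
            marks.append(t)
        if s + 1 < len(E_positions):
            times.append(t)  # zero-length jump segment into the next sweep
            target.append(targets[0])
            labels.append("fixation")
    return GazeTrajectory(
        times=np.asarray(times),
        eye=np.asarray(eye),
        target_h=np.asarray(target),
        labels=np.asarray(labels),
        record_marks=np.asarray(marks),
        sweep_starts=np.asarray(sweeps),
    )
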