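"""Prescribed head-motion scenarios.

Each scenario emulates a subject following a dot on a screen viewed at
76 cm, re-orienting the head ("nose pointing at the dot") without
deliberate translation.  Dot displacement maps to head rotation through
the small-angle ratio (``motion.expected_deflection``): a vertical dot
offset produces pitch (theta_x), a horizontal offset yaw (theta_y).

Families and their canonical timings (full 338 s scan):

* ``still`` — no deliberate motion.
* ``stepwise`` — the dot jumps between screen targets (up, down, right,
  left, then the four diagonal targets), one position per 35 s dwell
  starting 20 s into the scan, returning to centre between targets.
  Displacement 2.5 cm (1.9 deg) or 7.5 cm (5.7 deg).
* ``circular`` — the head axis traces a cone of constant deflection
  (2.5 cm radius -> 1.9 deg) at 4 or 6 cycles/min, in three 1-min bouts
  (on/off) starting 10 s into the scan.
* ``pitchwise`` — nodding: pitch dips to the full deflection in 2 s,
  returns over 15 s, rests 35 s (17 s of motion per 52 s cycle),
  magnitudes 1.9 / 3.8 / 5.7 deg.
* ``slow_diagonal`` — a 90 s linear ramp along the +-45 deg diagonal
  (3.5 cm -> 2.6 deg) starting at 120 s, then hold.

Shorter simulated scans scale *all* event times (starts, dwells, ramps,
bout and cycle durations) by ``scan_duration / 338`` so the fraction of
k-space affected by each motion phase is preserved.

The "peak rotation magnitude" of a trace is measured as the Euclidean
norm of the three angle parameters; for the two-axis poses used here it
equals the prescribed deflection exactly (the composed-rotation angle
differs only at third order in the angle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion import (
    MotionScoreParams,
    MotionTrace,
    expected_deflection,
    mean_motion_score,
)

__all__ = [
    "ScenarioSpec",
    "generate_scenario_trace",
    "expected_motion_score",
    "peak_rotation_deg",
    "SCENARIO_NAMES",
]

REFERENCE_SCAN_S = 338.0  # 5:38 min, the full-length acquisition

FAMILIES = ("still", "stepwise", "circular", "pitchwise", "slow_diagonal")

# unit screen-offset directions (vertical, horizontal) for stepwise targets
_STEP_TARGETS = [
    (1.0, 0.0),  # up
    (-1.0, 0.0),  # down
    (0.0, 1.0),  # right
    (0.0, -1.0),  # left
    (np.sqrt(0.5), np.sqrt(0.5)),  # up-right
    (-np.sqrt(0.5), -np.sqrt(0.5)),  # down-left
    (np.sqrt(0.5), -np.sqrt(0.5)),  # up-left
    (-np.sqrt(0.5), np.sqrt(0.5)),  # down-right
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one prescribed-motion experiment."""

    family: str = "still"
    dot_displacement_cm: float = 2.5
    circle_radius_cm: float = 2.5
    diagonal_direction: str = "up"
    eye_screen_distance_cm: float = 76.0
    cycles_per_min: float = 6.0
    start_time_s: float = 20.0  # canonical (full-scan) motion onset
    dwell_s: float = 35.0
    scan_duration_s: float = REFERENCE_SCAN_S

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown scenario family {self.family!r}")
        if self.scan_duration_s <= 0:
            raise ValueError("scan_duration_s must be positive")

    @property
    def time_scale(self) -> float:
        return self.scan_duration_s / REFERENCE_SCAN_S

    @property
    def deflection_deg(self) -> float:
        """Prescribed peak head rotation for this scenario's geometry."""
        if self.family == "still":
            return 0.0
        d = (
            self.circle_radius_cm
            if self.family == "circular"
            else self.dot_displacement_cm
        )
        return expected_deflection(d, self.eye_screen_distance_cm)

    @classmethod
    def named(cls, name: str, scan_duration_s: float = REFERENCE_SCAN_S) -> "ScenarioSpec":
        """Construct one of the study's named scenarios."""
        try:
            kw = dict(SCENARIO_NAMES[name])
        except KeyError:
            raise ValueError(
                f"unknown scenario {name!r}; choose from {sorted(SCENARIO_NAMES)}"
            ) from None
        return cls(scan_duration_s=scan_duration_s, **kw)


SCENARIO_NAMES = {
    "still": dict(family="still"),
    "stepwise-small": dict(family="stepwise", dot_displacement_cm=2.5),
    "stepwise-large": dict(family="stepwise", dot_displacement_cm=7.5),
    "circular-4": dict(family="circular", cycles_per_min=4.0),
    "circular-6": dict(family="circular", cycles_per_min=6.0),
    "pitch-small": dict(family="pitchwise", dot_displacement_cm=2.5),
    "pitch-medium": dict(family="pitchwise", dot_displacement_cm=5.0),
    "pitch-large": dict(family="pitchwise", dot_displacement_cm=7.5),
    "diag-up": dict(family="slow_diagonal", dot_displacement_cm=3.5, diagonal_direction="up"),
    "diag-down": dict(family="slow_diagonal", dot_displacement_cm=3.5, diagonal_direction="down"),
}


def generate_scenario_trace(
    scenario: ScenarioSpec, sample_rate_hz: float = 30.0
) -> MotionTrace:
    """Noise-free prescribed pose trace sampled uniformly over the scan.

    Translations are zero throughout (the instruction is a pure head
    re-orientation); rotations are the (theta_x, theta_y) pair pointing
    the nose at the dot.
    """
    dur = scenario.scan_duration_s
    n = int(np.floor(dur * sample_rate_hz)) + 1
    t = np.arange(n) / sample_rate_hz
    if t[-1] < dur - 1e-9:  # always cover the full scan
        t = np.append(t, dur)
        n += 1
    amp = scenario.deflection_deg
    tx = np.zeros(n)
    ty = np.zeros(n)
    s = scenario.time_scale
    if scenario.family == "still" or amp == 0.0:
        pass
    elif scenario.family == "stepwise":
        tx, ty = _stepwise_angles(t, scenario, amp)
    elif scenario.family == "circular":
        tx, ty = _circular_angles(t, scenario, amp)
    elif scenario.family == "pitchwise":
        tx = _pitchwise_angles(t, scenario, amp)
    elif scenario.family == "slow_diagonal":
        tx, ty = _diagonal_angles(t, scenario, amp)
    poses = np.zeros((n, 6))
    poses[:, 0] = tx
    poses[:, 1] = ty
    return MotionTrace(times=t, poses=poses, reference_time=0.0, sampling_label="prescribed")


def _stepwise_angles(t, scenario, amp):
    s = scenario.time_scale
    start = scenario.start_time_s * s
    dwell = scenario.dwell_s * s
    tx = np.zeros_like(t)
    ty = np.zeros_like(t)
    active = t >= start
    slot = np.floor((t[active] - start) / dwell).astype(int)
    # even slots are targets, odd slots return to centre
    target_idx = (slot // 2) % len(_STEP_TARGETS)
    on_target = slot % 2 == 0
    vert = np.array([_STEP_TARGETS[i][0] for i in target_idx])
    horz = np.array([_STEP_TARGETS[i][1] for i in target_idx])
    tx[active] = np.where(on_target, amp * vert, 0.0)
    ty[active] = np.where(on_target, amp * horz, 0.0)
    return tx, ty


def _circular_angles(t, scenario, amp, ramp_canonical_s=2.0):
    s = scenario.time_scale
    bout_len = 60.0 * s
    starts = np.array([10.0, 130.0, 250.0]) * s
    period = 60.0 / scenario.cycles_per_min * s
    ramp = ramp_canonical_s * s
    tx = np.zeros_like(t)
    ty = np.zeros_like(t)
    for t0 in starts:
        inb = (t >= t0) & (t < t0 + bout_len)
        tt = t[inb] - t0
        env = np.minimum(1.0, np.minimum(tt / ramp, (bout_len - tt) / ramp))
        phase = 2.0 * np.pi * tt / period
        tx[inb] = amp * env * np.sin(phase)
        ty[inb] = amp * env * np.cos(phase)  # cone precession
    return tx, ty


def _pitchwise_angles(t, scenario, amp):
    s = scenario.time_scale
    start = scenario.start_time_s * s
    down, up, rest = 2.0 * s, 15.0 * s, 35.0 * s
    cycle = down + up + rest
    tx = np.zeros_like(t)
    active = t >= start
    tt = np.mod(t[active] - start, cycle)
    vals = np.zeros_like(tt)
    in_down = tt < down
    vals[in_down] = -amp * tt[in_down] / down
    in_up = (tt >= down) & (tt < down + up)
    vals[in_up] = -amp * (1.0 - (tt[in_up] - down) / up)
    tx[active] = vals
    return tx


def _diagonal_angles(t, scenario, amp):
    s = scenario.time_scale
    start = 120.0 * s
    ramp = 90.0 * s
    sign = {"up": 1.0, "down": -1.0}[scenario.diagonal_direction]
    frac = np.clip((t - start) / ramp, 0.0, 1.0)
    comp = amp * np.sqrt(0.5) * frac
    return sign * comp, comp  # (pitch, yaw): up-right or down-right diagonal


def peak_rotation_deg(trace: MotionTrace) -> float:
    """Peak Euclidean norm (degrees) of the angle triple over the trace."""
    return float(np.max(np.linalg.norm(trace.poses[:, :3], axis=1)))


def expected_motion_score(
    scenario: ScenarioSpec,
    params: MotionScoreParams | None = None,
    frame_interval_s: float = 2.41,
) -> float:
    """Mean motion score (mm) of the noise-free prescribed trace sampled
    once per ``frame_interval_s`` (one frame per readout train)."""
    trace = generate_scenario_trace(scenario, sample_rate_hz=1.0 / frame_interval_s)
    if scenario.family == "still":
        return 0.0
    return mean_motion_score(trace, params)
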