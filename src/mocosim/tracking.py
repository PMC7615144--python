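"""Emulated motion-tracking observations.

Two modalities are emulated at the pose level:

* a high-rate (~30 Hz) markerless tracker stream — the true trace
  resampled to the device rate with additive white noise, band-limited
  high-frequency jitter and optional slow drift; downstream processing
  removes the noise with a 1 Hz zero-phase low-pass filter;
* low-resolution fat-only navigator volumes acquired once per TR — the
  scalp fat shell moves rigidly with the head while the neck fat follows
  only a fraction of the head rotation (the non-rigid confound), so
  registration of these volumes reproduces the pitch-estimation bias that
  neck masking removes.

Navigator volumes are rasterised analytically at each transformed pose
(no resampling chain), so registration tests see no interpolation
artefacts from the simulation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .motion import MotionTrace, RigidTransform
from .phantom import FAT_TAGS, PhantomModel

__all__ = [
    "TrackerNoiseModel",
    "emulate_tracker",
    "simulate_navigator_volume",
    "navigator_series",
    "NavigatorSeries",
]


@dataclass(frozen=True)
class TrackerNoiseModel:
    """Noise characteristics of the emulated high-rate pose tracker.

    ``white_sigma_*`` is broadband measurement noise per sample;
    ``jitter_sigma_rot`` adds band-limited (5-10 Hz by default) angular
    jitter such as facial-motion flutter; ``drift_amp_*`` adds a slow
    sinusoidal bias (amplitude, not std) emulating calibration drift.
    """

    sample_rate_hz: float = 30.0
    white_sigma_rot_deg: float = 0.05
    white_sigma_trans_mm: float = 0.05
    jitter_sigma_rot_deg: float = 0.1
    jitter_band_hz: tuple[float, float] = (5.0, 10.0)
    drift_amp_rot_deg: float = 0.0
    drift_amp_trans_mm: float = 0.0
    drift_period_s: float = 120.0

    def __post_init__(self):
        for v in (
            self.white_sigma_rot_deg,
            self.white_sigma_trans_mm,
            self.jitter_sigma_rot_deg,
            self.drift_amp_rot_deg,
            self.drift_amp_trans_mm,
        ):
            if v < 0:
                raise ValueError("noise magnitudes must be >= 0")


def emulate_tracker(
    true_trace: MotionTrace,
    noise: TrackerNoiseModel | None = None,
    seed: int = 0,
) -> MotionTrace:
    """Emulated tracker observation of ``true_trace``.

    The true trace is linearly interpolated to the device sample rate and
    corrupted per the noise model; reproducible from ``seed``.
    """
    noise = noise or TrackerNoiseModel()
    rng = np.random.default_rng(seed)
    duration = float(true_trace.times[-1])
    # ceil so the uniform grid covers the full scan (end pose held)
    n = int(np.ceil(duration * noise.sample_rate_hz - 1e-9)) + 1
    t = np.arange(n) / noise.sample_rate_hz
    poses = true_trace.sample_at(t)
    sig = np.array(
        [noise.white_sigma_rot_deg] * 3 + [noise.white_sigma_trans_mm] * 3
    )
    poses = poses + rng.standard_normal((n, 6)) * sig
    if noise.jitter_sigma_rot_deg > 0 and n > 30:
        lo, hi = noise.jitter_band_hz
        hi = min(hi, 0.49 * noise.sample_rate_hz)
        b, a = butter(2, (lo, hi), btype="band", fs=noise.sample_rate_hz)
        for j in range(3):
            raw = filtfilt(b, a, rng.standard_normal(n))
            rms = np.sqrt(np.mean(raw**2))
            if rms > 0:
                poses[:, j] += raw * (noise.jitter_sigma_rot_deg / rms)
    if noise.drift_amp_rot_deg > 0 or noise.drift_amp_trans_mm > 0:
        phases = rng.uniform(0, 2 * np.pi, 6)
        amps = np.array(
            [noise.drift_amp_rot_deg] * 3 + [noise.drift_amp_trans_mm] * 3
        )
        poses += amps * np.sin(
            2 * np.pi * t[:, None] / noise.drift_period_s + phases
        )
    return MotionTrace(
        times=t,
        poses=poses,
        reference_time=true_trace.reference_time,
        sampling_label="tracker",
    )


# ---------------------------------------------------------------------------
# Navigator volumes
# ---------------------------------------------------------------------------

@dataclass
class NavigatorSeries:
    """Stack of per-TR fat navigator volumes with their pose times."""

    volumes: np.ndarray  # (n_frames, m, m, m)
    times: np.ndarray  # seconds, one per frame
    fov_mm: float
    matrix: int

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, float)
        self.times = np.asarray(self.times, float)
        if self.volumes.shape[0] != len(self.times):
            raise ValueError("one time per navigator volume required")

    def __len__(self) -> int:
        return self.volumes.shape[0]

    def to_nifti(self, path) -> None:
        """Write the series as a 4-D NIfTI (frames along the last axis)
        with a JSON sidecar holding the frame times."""
        import json
        from pathlib import Path

        import nibabel as nib

        voxel = self.fov_mm / self.matrix
        affine = np.diag([voxel, voxel, voxel, 1.0])
        affine[:3, 3] = -(self.matrix // 2) * voxel
        data = np.moveaxis(self.volumes, 0, -1).astype(np.float32)
        nib.save(nib.Nifti1Image(data, affine), str(path))
        Path(str(path) + ".json").write_text(
            json.dumps({"times_s": self.times.tolist(), "fov_mm": self.fov_mm})
        )


def simulate_navigator_volume(
    phantom: PhantomModel,
    pose: RigidTransform,
    matrix: int = 32,
    fov_mm: float | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Low-resolution image of the fat-tagged components only.

    The scalp shell moves by ``pose``; the neck moves by the coupled pose
    (rotation scaled by ``phantom.neck_coupling``).  ``noise_sigma`` adds
    Rician-like magnitude noise (magnitude of complex Gaussian noise
    added to the real image).
    """
    fov = phantom.fov_mm if fov_mm is None else fov_mm
    voxel = fov / matrix
    # keep the rendered edge resolvable on the navigator grid: an edge
    # sharper than ~0.7 voxel aliases and biases sub-voxel registration
    sigma = max(phantom.edge_sigma_mm, 0.7 * voxel)
    vol = phantom.rasterize(matrix, fov, pose=pose, tags=FAT_TAGS, edge_sigma_mm=sigma)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng()
        re = vol + rng.standard_normal(vol.shape) * noise_sigma
        im = rng.standard_normal(vol.shape) * noise_sigma
        vol = np.sqrt(re**2 + im**2)
    return vol


def navigator_series(
    phantom: PhantomModel,
    trace: MotionTrace,
    tr_s: float = 2.41,
    matrix: int = 32,
    fov_mm: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> NavigatorSeries:
    """One navigator volume per TR (or per explicit acquisition time).

    Poses are sampled from ``trace`` at the navigator times (end of each
    readout train by default).
    """
    fov = phantom.fov_mm if fov_mm is None else fov_mm
    if times is None:
        duration = float(trace.times[-1])
        n_tr = max(int(np.floor(duration / tr_s)), 1)
        times = (np.arange(n_tr) + 1) * tr_s
        times = times[times <= duration + 1e-9]
    times = np.asarray(times, float)
    rng = np.random.default_rng(seed)
    vols = np.empty((len(times), matrix, matrix, matrix))
    cache: dict[tuple, np.ndarray] = {}
    for i, t in enumerate(times):
        pose = trace.pose_at(t)
        key = tuple(np.round(pose.params, 9))
        if noise_sigma == 0.0 and key in cache:
            vols[i] = cache[key]
            continue
        vols[i] = simulate_navigator_volume(
            phantom, pose, matrix, fov, noise_sigma=noise_sigma, rng=rng
        )
        if noise_sigma == 0.0:
            cache[key] = vols[i]
    return NavigatorSeries(volumes=vols, times=times, fov_mm=fov, matrix=matrix)
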