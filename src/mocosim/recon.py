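"""Forward k-space simulation and retrospective rigid motion correction.

Forward model
-------------
The acquisition is segmented Cartesian: one readout train per TR, each
train acquiring all (readout, pe2) samples of one pe1 line, with the
head pose constant within a train.  If the head pose at train time tau is
(R, t), the sampled value at Cartesian location k is::

    s(k) = exp(-i 2 pi k . t) * F(R^T k)

where F is the phantom's reference spectrum (closed-form ellipsoid
Fourier transform, so the simulation is exact for any pose; the neck
component is transformed by its non-rigidly coupled pose).

Retrospective correction inverts this per train: each sample is
multiplied by ``exp(+i 2 pi k . t)`` (Fourier shift theorem) and assigned
the effective coordinate ``R^T k`` (Fourier rotation theorem), after
rebasing the motion trace to the centre-of-k-space acquisition time.
Samples acquired at the reference pose therefore map back to their
original grid locations; rotated trains leave the Cartesian grid, and a
type-1 NUFFT (Kaiser-Bessel gridding with 2x oversampling, numerically
computed deapodization, and optional gridded density compensation or CG
least-squares) reconstructs the non-Cartesian set.

k-space coordinates are in cycles/mm with the DC sample at grid index
``N//2`` (FFT-shift convention); reconstructed images are scaled by the
inverse voxel volume so they are directly comparable to the rasterised
phantom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import i0 as bessel_i0

from .motion import MotionTrace, RigidTransform, rebase_trace
from .phantom import PhantomModel

__all__ = [
    "AcquisitionSpec",
    "KSpaceData",
    "NonCartesianSamples",
    "simulate_acquisition",
    "correct_kspace",
    "phase_correct_translations",
    "reconstruct_fft",
    "reconstruct_nufft",
    "nyquist_outside_fraction",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Cartesian MPRAGE-like acquisition geometry and timing.

    Axis roles are fixed to array axes: readout = axis 0 (x), pe1 =
    axis 1 (y, one line per train), pe2 = axis 2 (z, all lines within a
    train).  ``tr_s`` is the per-train repetition interval.
    """

    matrix: int = 64
    fov_mm: float = 200.0
    tr_s: float = 2.41
    pe_ordering: str = "linear"

    def __post_init__(self):
        if self.pe_ordering not in ("linear", "centric"):
            raise ValueError("pe_ordering must be 'linear' or 'centric'")
        if self.matrix < 8:
            raise ValueError("matrix too small")

    @property
    def n_trains(self) -> int:
        return self.matrix

    @property
    def lines_per_train(self) -> int:
        return self.matrix

    @property
    def scan_duration_s(self) -> float:
        return self.n_trains * self.tr_s

    @property
    def voxel_mm(self) -> float:
        return self.fov_mm / self.matrix

    def k_axis(self) -> np.ndarray:
        """k coordinates (cycles/mm) along one axis, DC at index N//2."""
        return (np.arange(self.matrix) - self.matrix // 2) / self.fov_mm

    def train_order(self) -> np.ndarray:
        """pe1 index acquired by each train, in acquisition order."""
        n = self.matrix
        idx = np.arange(n)
        if self.pe_ordering == "linear":
            return idx
        dist = np.abs(idx - n // 2)
        return idx[np.lexsort((idx, dist))]

    def train_times(self) -> np.ndarray:
        """Pose timestamp of each train (train end), acquisition order."""
        return (np.arange(self.n_trains) + 1) * self.tr_s

    @property
    def center_time_s(self) -> float:
        """Acquisition time of the k-space centre (pe1 == N//2 train)."""
        order = self.train_order()
        pos = int(np.where(order == self.matrix // 2)[0][0])
        return float(self.train_times()[pos])

    def to_dict(self) -> dict:
        return dict(
            matrix=self.matrix,
            fov_mm=self.fov_mm,
            tr_s=self.tr_s,
            pe_ordering=self.pe_ordering,
        )


@dataclass
class KSpaceData:
    """Complex Cartesian samples plus per-train acquisition bookkeeping.

    ``samples`` is indexed ``[readout, pe1, pe2]``; ``train_index[j]`` is
    the train (acquisition-order position) that acquired pe1 line ``j``.
    """

    samples: np.ndarray
    train_index: np.ndarray
    train_times: np.ndarray
    spec: AcquisitionSpec

    def __post_init__(self):
        self.samples = np.asarray(self.samples, complex)
        self.train_index = np.asarray(self.train_index, int)
        self.train_times = np.asarray(self.train_times, float)
        if np.any(np.diff(self.train_times) <= 0):
            raise ValueError("train_times must be strictly increasing")
        if len(self.train_index) != self.samples.shape[1]:
            raise ValueError("one train index per pe1 line required")

    def save(self, path) -> None:
        path = Path(path)
        np.savez_compressed(
            path,
            kspace=self.samples,
            train_index=self.train_index,
            train_times=self.train_times,
        )
        header = path.with_suffix(".json")
        header.write_text(json.dumps(self.spec.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "KSpaceData":
        path = Path(path)
        with np.load(path) as z:
            samples = z["kspace"]
            train_index = z["train_index"]
            train_times = z["train_times"]
        header = path.with_suffix(".json")
        spec = AcquisitionSpec(**json.loads(header.read_text()))
        return cls(samples, train_index, train_times, spec)


@dataclass
class NonCartesianSamples:
    """Rotation-corrected k-space samples off the Cartesian grid."""

    coordinates: np.ndarray  # (M, 3) cycles/mm
    values: np.ndarray  # (M,) complex
    spec: AcquisitionSpec

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        self.values = np.asarray(self.values, complex)
        if self.coordinates.shape != (len(self.values), 3):
            raise ValueError("coordinates must be (M, 3) matching values")


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def simulate_acquisition(
    phantom: PhantomModel,
    trace: MotionTrace,
    spec: AcquisitionSpec,
) -> KSpaceData:
    """Motion-corrupted Cartesian k-space of the phantom under ``trace``."""
    times = spec.train_times()
    if trace.times[-1] < times[-1] - 1e-6:
        raise ValueError(
            f"motion trace ends at {trace.times[-1]:.2f} s but the scan "
            f"runs to {times[-1]:.2f} s"
        )
    n = spec.matrix
    kax = spec.k_axis()
    order = spec.train_order()
    samples = np.empty((n, n, n), complex)
    train_index = np.empty(n, int)
    kx = kax[:, None]
    kz = kax[None, :]
    plane = np.empty((n, n, 3))
    plane[..., 0] = np.broadcast_to(kx, (n, n))
    plane[..., 2] = np.broadcast_to(kz, (n, n))
    for pos, pe1 in enumerate(order):
        pose = trace.pose_at(times[pos])
        plane[..., 1] = kax[pe1]
        samples[:, pe1, :] = phantom.analytic_ft(plane, pose=pose)
        train_index[pe1] = pos
    return KSpaceData(samples, train_index, times, spec)


# ---------------------------------------------------------------------------
# Retrospective correction
# ---------------------------------------------------------------------------

def _poses_per_train(data: KSpaceData, trace: MotionTrace) -> list[RigidTransform]:
    if trace.times[-1] < data.train_times[-1] - 1e-6:
        raise ValueError("motion trace does not cover all train times")
    rebased = rebase_trace(trace, data.spec.center_time_s)
    return [rebased.pose_at(t) for t in data.train_times]


def correct_kspace(data: KSpaceData, trace: MotionTrace) -> NonCartesianSamples:
    """Rotation + translation correction of motion-corrupted k-space.

    The trace is rebased internally to the centre-of-k-space time.  Each
    sample is multiplied by ``exp(+i 2 pi k . t)`` and moved to the
    effective coordinate ``R^T k`` of its train's pose.
    """
    spec = data.spec
    n = spec.matrix
    kax = spec.k_axis()
    poses = _poses_per_train(data, trace)
    coords = np.empty((n * n * n, 3))
    values = np.empty(n * n * n, complex)
    plane = np.empty((n, n, 3))
    kx = kax[:, None]
    kz = kax[None, :]
    plane[..., 0] = np.broadcast_to(kx, (n, n))
    plane[..., 2] = np.broadcast_to(kz, (n, n))
    block = n * n
    for pe1 in range(n):
        pose = poses[data.train_index[pe1]]
        plane[..., 1] = kax[pe1]
        flat = plane.reshape(-1, 3)
        phase = np.exp(2j * np.pi * (flat @ pose.translation))
        sl = slice(pe1 * block, (pe1 + 1) * block)
        values[sl] = data.samples[:, pe1, :].reshape(-1) * phase
        coords[sl] = flat @ pose.rotation_matrix()  # row @ R == R^T k
    return NonCartesianSamples(coords, values, spec)


def phase_correct_translations(data: KSpaceData, trace: MotionTrace) -> KSpaceData:
    """Translation-only correction: phase ramps applied in place on the
    Cartesian grid (exact when the motion contains no rotation)."""
    spec = data.spec
    n = spec.matrix
    kax = spec.k_axis()
    poses = _poses_per_train(data, trace)
    out = data.samples.copy()
    kx = kax[:, None]
    kz = kax[None, :]
    for pe1 in range(n):
        t = poses[data.train_index[pe1]].translation
        phase = np.exp(2j * np.pi * (kx * t[0] + kax[pe1] * t[1] + kz * t[2]))
        out[:, pe1, :] *= phase
    return KSpaceData(out, data.train_index.copy(), data.train_times.copy(), spec)


def nyquist_outside_fraction(samples: NonCartesianSamples) -> float:
    """Fraction of corrected coordinates outside the reference Nyquist
    cube (the rotation-induced 'pie-slice' bookkeeping)."""
    lim = samples.spec.matrix / (2.0 * samples.spec.fov_mm) + 1e-12
    outside = np.any(np.abs(samples.coordinates) > lim, axis=1)
    return float(np.mean(outside))


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def reconstruct_fft(data: KSpaceData) -> np.ndarray:
    """Magnitude of the inverse FFT (the uncorrected 'MoCo OFF' image),
    scaled by the inverse voxel volume to match the rasterised phantom."""
    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(data.samples)))
    return np.abs(img) / data.spec.voxel_mm**3


def _kb_beta(width: int, osf: float) -> float:
    # Beatty et al. optimal Kaiser-Bessel shape parameter
    return np.pi * np.sqrt((width / osf) ** 2 * (osf - 0.5) ** 2 - 0.8)


def _kb_kernel(d: np.ndarray, width: int, beta: float) -> np.ndarray:
    x = 2.0 * d / width
    arg = 1.0 - x * x
    out = np.zeros_like(d, float)
    ok = arg > 0
    out[ok] = bessel_i0(beta * np.sqrt(arg[ok])) / bessel_i0(beta)
    return out


def _deapodization_1d(grid_size: int, width: int, beta: float) -> np.ndarray:
    """DFT of the integer-sampled kernel on the oversampled grid (centred);
    dividing by it makes the Cartesian degeneration exact."""
    j = np.arange(grid_size) - grid_size // 2
    kern = _kb_kernel(np.abs(j).astype(float), width, beta)
    k_hat = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(kern))).real
    return k_hat


class _Gridder:
    """Separable Kaiser-Bessel spread/gather between non-uniform k-space
    coordinates and a 2x-oversampled Cartesian grid."""

    def __init__(self, spec: AcquisitionSpec, width: int = 4, osf: float = 2.0):
        self.n = spec.matrix
        self.fov = spec.fov_mm
        self.g = int(round(spec.matrix * osf))
        self.width = width
        self.beta = _kb_beta(width, osf)
        self.osf = osf
        deap = _deapodization_1d(self.g, width, self.beta)
        lo = self.g // 2 - self.n // 2
        self.deap_crop = deap[lo : lo + self.n]

    def _index_weights(self, coords: np.ndarray):
        g = coords * self.fov * self.osf + self.g // 2
        base = np.floor(g - self.width / 2.0).astype(int) + 1
        return g, base

    def spread(self, coords: np.ndarray, values: np.ndarray) -> np.ndarray:
        grid = np.zeros((self.g, self.g, self.g), complex)
        g, base = self._index_weights(coords)
        w = self.width
        kb = [
            _kb_kernel(
                np.abs(base[:, ax, None] + np.arange(w)[None, :] - g[:, ax, None]),
                w,
                self.beta,
            )
            for ax in range(3)
        ]
        idx = [np.mod(base[:, ax, None] + np.arange(w)[None, :], self.g) for ax in range(3)]
        flat = grid.reshape(-1)
        for ix in range(w):
            fx = idx[0][:, ix] * self.g * self.g
            kx = kb[0][:, ix]
            for iy in range(w):
                fxy = fx + idx[1][:, iy] * self.g
                kxy = kx * kb[1][:, iy]
                for iz in range(w):
                    np.add.at(
                        flat,
                        fxy + idx[2][:, iz],
                        values * (kxy * kb[2][:, iz]),
                    )
        return grid

    def gather(self, coords: np.ndarray, grid: np.ndarray) -> np.ndarray:
        g, base = self._index_weights(coords)
        w = self.width
        kb = [
            _kb_kernel(
                np.abs(base[:, ax, None] + np.arange(w)[None, :] - g[:, ax, None]),
                w,
                self.beta,
            )
            for ax in range(3)
        ]
        idx = [np.mod(base[:, ax, None] + np.arange(w)[None, :], self.g) for ax in range(3)]
        flat = grid.reshape(-1)
        out = np.zeros(len(coords), complex)
        for ix in range(w):
            fx = idx[0][:, ix] * self.g * self.g
            kx = kb[0][:, ix]
            for iy in range(w):
                fxy = fx + idx[1][:, iy] * self.g
                kxy = kx * kb[1][:, iy]
                for iz in range(w):
                    out += flat[fxy + idx[2][:, iz]] * (kxy * kb[2][:, iz])
        return out

    def crop(self, vol: np.ndarray) -> np.ndarray:
        lo = self.g // 2 - self.n // 2
        sl = slice(lo, lo + self.n)
        return vol[sl, sl, sl]

    def embed(self, vol: np.ndarray) -> np.ndarray:
        out = np.zeros((self.g, self.g, self.g), complex)
        lo = self.g // 2 - self.n // 2
        sl = slice(lo, lo + self.n)
        out[sl, sl, sl] = vol
        return out

    def deapodize(self, vol: np.ndarray) -> np.ndarray:
        d = self.deap_crop
        return vol / (d[:, None, None] * d[None, :, None] * d[None, None, :])


def _density_weights(gr: _Gridder, coords: np.ndarray) -> np.ndarray:
    ones = np.ones(len(coords), complex)
    dgrid = gr.spread(coords, ones)
    dens = gr.gather(coords, dgrid).real
    w = 1.0 / np.maximum(dens, 1e-12)
    return w / np.mean(w)


def reconstruct_nufft(
    samples: NonCartesianSamples,
    method: str = "adjoint",
    density: str = "gridded",
    kernel_width: int = 4,
    osf: float = 2.0,
    cg_iters: int = 12,
) -> np.ndarray:
    """Magnitude volume from rotation-corrected non-Cartesian samples.

    ``method='adjoint'`` grids the (density-compensated) samples onto the
    oversampled grid, inverse-FFTs, crops and deapodizes; on exactly
    Cartesian coordinates it matches :func:`reconstruct_fft` to machine
    precision.  ``method='cg'`` solves the least-squares inverse problem
    with conjugate gradients on the normal equations (no density
    weighting), which handles strongly non-uniform local density better.
    ``density`` is ``'gridded'`` (single-pass kernel-convolution density
    estimate) or ``'uniform'``.
    """
    if len(samples.values) == 0:
        raise ValueError("empty sample set")
    spec = samples.spec
    gr = _Gridder(spec, kernel_width, osf)
    coords = samples.coordinates
    if method == "adjoint":
        if density == "gridded":
            w = _density_weights(gr, coords)
        elif density == "uniform":
            w = np.ones(len(coords))
        else:
            raise ValueError("density must be 'gridded' or 'uniform'")
        grid = gr.spread(coords, samples.values * w)
        img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid)))
        img = gr.deapodize(gr.crop(img)) * gr.osf**3
        return np.abs(img) / spec.voxel_mm**3
    if method == "cg":
        return _reconstruct_cg(gr, samples, cg_iters)
    raise ValueError("method must be 'adjoint' or 'cg'")


def _reconstruct_cg(gr: _Gridder, samples: NonCartesianSamples, iters: int) -> np.ndarray:
    """CG on the normal equations of the forward NUFFT, in physical units."""
    spec = samples.spec
    vox3 = spec.voxel_mm**3
    coords = samples.coordinates
    gcube = gr.g**3

    def forward(img):
        x = gr.embed(gr.deapodize(img))
        spec_grid = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))
        return gr.gather(coords, spec_grid) * vox3

    def adjoint(y):
        grid = gr.spread(coords, y)
        x = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))) * gcube
        return gr.deapodize(gr.crop(x)) * vox3

    b = adjoint(samples.values)
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    for _ in range(iters):
        ap = adjoint(forward(p))
        alpha = rs / max(np.vdot(p, ap).real, 1e-300)
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        if rs_new < 1e-18 * max(rs, 1e-300):
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return np.abs(x)
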