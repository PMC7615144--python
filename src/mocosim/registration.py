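"""Rigid 6-DOF registration of navigator volume series.

Head pose is estimated by registering each low-resolution fat navigator
volume to the first of the series, minimising the (optionally weighted)
mean-squared intensity difference over a two-level multi-resolution
schedule with Gaussian pre-smoothing and trilinear/spline resampling.
The optimiser is Levenberg-Marquardt on the intensity residuals with
finite-difference derivatives.

A spatial weight mask can exclude the neck, whose non-rigid motion
otherwise biases the pitch (theta_x) estimate: the geometric neck mask
keeps the scalp fat shell (dilated by one voxel) and zeroes the neck
component and everything below an axial cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .motion import MotionTrace, RigidTransform
from .phantom import PhantomModel
from .tracking import NavigatorSeries

__all__ = [
    "WeightMask",
    "RegistrationResult",
    "register_volumes",
    "estimate_trace_from_navigators",
    "build_geometric_neck_mask",
]


@dataclass
class WeightMask:
    """Per-voxel registration weights in [0, 1] on the navigator grid."""

    weights: np.ndarray
    provenance: str = "user"  # none | geometric_neck_mask | user

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if np.min(self.weights) < 0 or np.max(self.weights) > 1:
            raise ValueError("mask weights must lie in [0, 1]")


@dataclass
class RegistrationResult:
    pose: RigidTransform
    cost_final: float
    iterations: int
    converged: bool


def _resample(moving: np.ndarray, pose: RigidTransform, voxel_mm: float, order: int) -> np.ndarray:
    """Sample ``moving`` at reference-grid points mapped by ``pose``:
    output(x) = moving(R x + t), with x in mm about the grid centre."""
    n = moving.shape[0]
    center = n // 2
    r = pose.rotation_matrix()
    # voxel index i -> mm x = (i - c) * v;  input index = (R x + t)/v + c
    matrix = r
    offset = (
        -r @ (np.full(3, center)) + pose.translation / voxel_mm + center
    )
    return ndimage.affine_transform(
        moving, matrix, offset=offset, order=order, mode="constant", cval=0.0,
        prefilter=(order > 1),
    )


def _smooth(vol: np.ndarray, fwhm_voxels: float) -> np.ndarray:
    sigma = fwhm_voxels / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return ndimage.gaussian_filter(vol, sigma)


def _downsample(vol: np.ndarray) -> np.ndarray:
    return ndimage.zoom(_smooth(vol, 2.0), 0.5, order=1, grid_mode=True, mode="grid-constant")


def register_volumes(
    reference: np.ndarray,
    moving: np.ndarray,
    mask: WeightMask | None = None,
    init: RigidTransform | None = None,
    voxel_mm: float = 1.0,
    smooth_fwhm_voxels: float = 1.0,
    order: int = 3,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RegistrationResult:
    """Estimate the rigid pose mapping ``reference`` onto ``moving``.

    Returns the pose ``T`` such that ``moving(x) ~= reference(T^-1 x)``,
    i.e. the head pose of ``moving`` relative to ``reference``.  The cost
    is the (mask-weighted) MSE after resampling ``moving`` back by the
    candidate pose, optimised coarse-to-fine; non-convergence is flagged,
    not raised.
    """
    reference = np.asarray(reference, float)
    moving = np.asarray(moving, float)
    if reference.shape != moving.shape:
        raise ValueError("volumes must share a grid")
    if not (np.all(np.isfinite(reference)) and np.all(np.isfinite(moving))):
        raise ValueError("volumes contain non-finite voxels")
    weights = None if mask is None else mask.weights
    if weights is not None and weights.shape != reference.shape:
        raise ValueError("mask must live on the same grid as the volumes")
    x0 = np.zeros(6) if init is None else init.params.copy()
    # a near-zero warm start collapses the optimiser's initial trust
    # region (it is sized by |x0|); snap to exactly zero instead
    x0[np.abs(x0) < 1e-4] = 0.0
    if np.linalg.norm(x0) < 1e-4:
        x0[:] = 0.0

    # zero-pad so spline boundary handling cannot inject cost
    # discontinuities for objects reaching the field-of-view edge
    pad = 4
    ref_s = np.pad(_smooth(reference, smooth_fwhm_voxels), pad)
    mov_s = np.pad(_smooth(moving, smooth_fwhm_voxels), pad)
    # weights pad with 1 so an all-ones mask is exactly neutral
    w_s = None if weights is None else np.pad(weights, pad, constant_values=1.0)
    levels = [(ref_s, mov_s, w_s, voxel_mm, order)]
    if min(reference.shape) >= 16:
        w_c = None if w_s is None else np.clip(_downsample(w_s), 0.0, 1.0)
        levels.insert(0, (_downsample(ref_s), _downsample(mov_s), w_c, voxel_mm * 2.0, 1))

    nfev = 0
    success = True
    cost = np.inf
    for ref_l, mov_l, w_l, vox_l, order_l in levels:
        sw = None if w_l is None else np.sqrt(np.maximum(w_l, 0.0)).ravel()
        norm = np.sqrt(ref_l.size)

        def residuals(p):
            res = (_resample(mov_l, RigidTransform.from_params(p), vox_l, order_l) - ref_l).ravel()
            if sw is not None:
                res = res * sw
            return res / norm

        def jacobian(p, step=1e-2):
            # forward differences with a fixed absolute step (deg / mm):
            # relative steps degenerate near zero parameters
            f0 = residuals(p)
            cols = []
            for j in range(6):
                pj = p.copy()
                pj[j] += step
                cols.append((residuals(pj) - f0) / step)
            return np.stack(cols, axis=1)

        sol = least_squares(
            residuals,
            x0,
            jac=jacobian,
            method="trf",
            x_scale=1.0,
            xtol=tol,
            ftol=tol,
            max_nfev=max_iter * 7,
        )
        x0 = sol.x
        nfev += sol.nfev
        cost = 2.0 * sol.cost  # least_squares cost = 0.5 * sum(res^2)
        success = success and sol.status > 0
    return RegistrationResult(
        pose=RigidTransform.from_params(x0),
        cost_final=float(cost),
        iterations=int(nfev),
        converged=bool(success),
    )


def estimate_trace_from_navigators(
    series: NavigatorSeries,
    mask: WeightMask | None = None,
    reference_index: int = 0,
) -> MotionTrace:
    """Motion trace from a navigator series: each volume registered to
    the reference volume (the first by default), warm-starting each
    frame from the previous estimate.  Non-convergent frames keep their
    best estimate and are reported through the result's label only.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 navigator volumes")
    voxel = series.fov_mm / series.matrix
    ref = series.volumes[reference_index]
    poses = np.zeros((len(series), 6))
    prev = RigidTransform()
    for i in range(len(series)):
        if i == reference_index:
            prev = RigidTransform()
            continue
        res = register_volumes(ref, series.volumes[i], mask=mask, init=prev, voxel_mm=voxel)
        poses[i] = res.pose.params
        prev = res.pose
    return MotionTrace(
        times=series.times.copy(),
        poses=poses,
        reference_time=float(series.times[reference_index]),
        sampling_label="navigator",
    )


def build_geometric_neck_mask(
    phantom: PhantomModel,
    matrix: int,
    fov_mm: float | None = None,
    axial_cut_mm: float | None = None,
) -> WeightMask:
    """Registration weight mask excluding the non-rigid neck.

    Weight 1 over the scalp fat support dilated by one navigator voxel,
    0 over the neck component and the inferior slab below ``axial_cut_mm``
    (default: one voxel above the top of the neck), with a smooth
    one-voxel transition in between.
    """
    fov = phantom.fov_mm if fov_mm is None else fov_mm
    voxel = fov / matrix
    sigma = max(phantom.edge_sigma_mm, 0.7 * voxel)
    scalp_bin = phantom.support(matrix, fov, tags=("scalp_fat",), edge_sigma_mm=sigma)
    neck_sup = phantom.support(
        matrix, fov, tags=("neck_fat",), edge_sigma_mm=sigma, threshold=0.25
    )
    # exclude the neck support plus a ~6 mm margin covering where the
    # non-rigidly moving neck can appear under poses of interest
    margin_vox = max(1, int(np.ceil(6.0 / voxel)))
    neck_bin = ndimage.binary_dilation(neck_sup, iterations=margin_vox)
    keep = ndimage.binary_dilation(scalp_bin, iterations=1)
    w = ndimage.gaussian_filter(keep.astype(float), 0.5)
    if axial_cut_mm is None:
        # just below the scalp support: the slab removes stray inferior
        # signal without eating into the shell's bottom cap
        scalps = [c for c in phantom.components if c.tissue_tag == "scalp_fat"]
        bottom = min(c.center[2] - c.semi_axes[2] for c in scalps)
        axial_cut_mm = bottom - voxel
    z = (np.arange(matrix) - matrix // 2) * voxel
    w[:, :, z < axial_cut_mm] = 0.0
    w[neck_bin] = 0.0
    return WeightMask(weights=np.clip(w, 0.0, 1.0), provenance="geometric_neck_mask")
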