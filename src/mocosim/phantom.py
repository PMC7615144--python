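"""Analytic ellipsoid head phantom.

The phantom is a sum of (possibly overlapping, signed-intensity)
ellipsoids: a brain with internal contrast features, a thin
high-intensity scalp fat shell, and an inferior neck fat component.  The
scalp moves rigidly with the head; the neck is *non-rigidly coupled* — it
follows only a fraction ``neck_coupling`` of the head rotation (while
translating rigidly), which is the confound that biases unmasked
navigator registration.

Every ellipsoid has a closed-form 3-D Fourier transform, so k-space
simulation evaluates the moving object's spectrum exactly at arbitrary
rotated coordinates; image-space rasterisation uses the matching
Gaussian-smoothed edge profile, keeping image and k-space views of the
phantom consistent.

World coordinates are mm in the scanner frame, with voxel index ``N//2``
at the origin (the FFT DC convention used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .motion import RigidTransform

__all__ = ["Ellipsoid", "PhantomModel", "build_default_phantom", "grid_coords"]

FAT_TAGS = ("scalp_fat", "neck_fat")


@dataclass(frozen=True)
class Ellipsoid:
    """One signed-intensity ellipsoid component.

    ``orientation`` are Euler angles in degrees in the pose convention
    (``Rz @ Ry @ Rx`` about fixed axes); ``intensity`` may be negative,
    which is how hollow structures (the scalp shell) are composed.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity: float = 1.0
    tissue_tag: str = "brain"
    rigid: bool = True

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def rotation(self) -> np.ndarray:
        return RigidTransform(*self.orientation).rotation_matrix()

    def transformed(self, pose: RigidTransform) -> "Ellipsoid":
        """The ellipsoid after the head moves by ``pose`` (center and
        orientation updated; shape unchanged — rigid transport)."""
        r = pose.rotation_matrix()
        new_center = r @ np.asarray(self.center) + pose.translation
        new_rot = r @ self.rotation()
        from scipy.spatial.transform import Rotation

        ang = Rotation.from_matrix(new_rot).as_euler("xyz", degrees=True)
        return replace(self, center=tuple(new_center), orientation=tuple(ang))


@dataclass
class PhantomModel:
    """Ellipsoid head model with a non-rigidly coupled neck component."""

    components: list[Ellipsoid]
    neck_coupling: float = 0.3
    edge_sigma_mm: float = 2.0  # Gaussian edge smoothing, shared by image & k-space
    fov_mm: float = 200.0

    def __post_init__(self):
        if not 0.0 <= self.neck_coupling <= 1.0:
            raise ValueError("neck_coupling must lie in [0, 1]")
        tags = {c.tissue_tag for c in self.components}
        for required in ("brain", "scalp_fat", "neck_fat"):
            if required not in tags:
                raise ValueError(f"phantom must contain a {required} component")
        half = self.fov_mm / 2.0
        for comp in self.components:
            rot = comp.rotation()
            extent = np.sqrt((rot**2) @ (np.asarray(comp.semi_axes) ** 2))
            reach = np.abs(np.asarray(comp.center)) + extent
            if np.any(reach > half):
                raise ValueError(
                    f"component {comp.tissue_tag} at {comp.center} does not fit "
                    f"inside the {self.fov_mm} mm field of view"
                )

    def component_pose(self, comp: Ellipsoid, pose: RigidTransform) -> RigidTransform:
        """Pose actually followed by a component: rigid components follow
        the head pose; the neck follows the rotation scaled by the
        coupling factor (translation follows rigidly)."""
        if comp.rigid:
            return pose
        c = self.neck_coupling
        return RigidTransform(
            c * pose.theta_x,
            c * pose.theta_y,
            c * pose.theta_z,
            pose.t_x,
            pose.t_y,
            pose.t_z,
        )

    def select(self, tags=None) -> list[Ellipsoid]:
        if tags is None:
            return list(self.components)
        return [c for c in self.components if c.tissue_tag in tags]

    # ------------------------------------------------------------------
    # Image-space rasterisation
    # ------------------------------------------------------------------
    def rasterize(
        self,
        matrix: int,
        fov_mm: float | None = None,
        pose: RigidTransform | None = None,
        tags=None,
        edge_sigma_mm: float | None = None,
    ) -> np.ndarray:
        """Sample the phantom on a ``matrix^3`` grid covering ``fov_mm``.

        Each ellipsoid contributes its intensity times a smoothed
        indicator: an erf profile of width ``edge_sigma_mm`` along the
        local surface normal, i.e. the ellipsoid convolved with an
        isotropic Gaussian.  ``pose`` (if given) moves the head; the neck
        follows its coupled pose.
        """
        fov = self.fov_mm if fov_mm is None else fov_mm
        sigma = self.edge_sigma_mm if edge_sigma_mm is None else edge_sigma_mm
        coords = grid_coords(matrix, fov)  # (matrix, 3) axis coords
        xs, ys, zs = np.meshgrid(coords[:, 0], coords[:, 1], coords[:, 2], indexing="ij")
        pts = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)
        vol = np.zeros(pts.shape[0])
        for comp in self.select(tags):
            eff = comp
            if pose is not None:
                eff = comp.transformed(self.component_pose(comp, pose))
            vol += eff.intensity * _soft_ellipsoid(pts, eff, sigma)
        return vol.reshape(matrix, matrix, matrix)

    def support(
        self,
        matrix: int,
        fov_mm: float | None = None,
        tags=None,
        edge_sigma_mm: float | None = None,
        threshold: float = 0.5,
    ) -> np.ndarray:
        """Boolean support of the selected components (their smoothed
        indicator, ignoring intensities, thresholded at ``threshold``).
        Signs are kept so hollow composites (the scalp shell) resolve."""
        fov = self.fov_mm if fov_mm is None else fov_mm
        sigma = self.edge_sigma_mm if edge_sigma_mm is None else edge_sigma_mm
        coords = grid_coords(matrix, fov)
        xs, ys, zs = np.meshgrid(coords[:, 0], coords[:, 1], coords[:, 2], indexing="ij")
        pts = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)
        vol = np.zeros(pts.shape[0])
        for comp in self.select(tags):
            vol += np.sign(comp.intensity) * _soft_ellipsoid(pts, comp, sigma)
        return vol.reshape(matrix, matrix, matrix) >= threshold

    # ------------------------------------------------------------------
    # k-space (closed-form spectrum)
    # ------------------------------------------------------------------
    def analytic_ft(
        self,
        k: np.ndarray,
        pose: RigidTransform | None = None,
        tags=None,
        edge_sigma_mm: float | None = None,
    ) -> np.ndarray:
        """Exact Fourier transform at coordinates ``k`` (..., 3, cycles/mm).

        Uses the closed-form spectrum of a uniform ellipsoid,
        ``rho V 3 (sin u - u cos u)/u^3`` with ``u = 2 pi |A R_e^T k|``,
        modulated by the centre phase and the Gaussian edge factor.
        ``pose`` moves the head (neck coupled as in ``component_pose``).
        """
        sigma = self.edge_sigma_mm if edge_sigma_mm is None else edge_sigma_mm
        kk = np.asarray(k, float)
        flat = kk.reshape(-1, 3)
        out = np.zeros(flat.shape[0], complex)
        k2 = np.einsum("ij,ij->i", flat, flat)
        apod = np.exp(-2.0 * np.pi**2 * sigma**2 * k2)
        for comp in self.select(tags):
            eff = comp
            if pose is not None:
                eff = comp.transformed(self.component_pose(comp, pose))
            out += _ellipsoid_ft(flat, eff)
        return (out * apod).reshape(kk.shape[:-1])


def grid_coords(matrix: int, fov_mm: float) -> np.ndarray:
    """World coordinates (mm) of the grid axes: index ``N//2`` at 0."""
    voxel = fov_mm / matrix
    ax = (np.arange(matrix) - matrix // 2) * voxel
    return np.stack([ax, ax, ax], axis=-1)


def _soft_ellipsoid(pts: np.ndarray, comp: Ellipsoid, sigma: float) -> np.ndarray:
    rot = comp.rotation()
    v = (pts - np.asarray(comp.center)) @ rot  # body-frame offsets
    a = np.asarray(comp.semi_axes)
    w = v / a
    rho = np.sqrt(np.einsum("ij,ij->i", w, w))
    grad = np.linalg.norm(w / a, axis=1) / np.maximum(rho, 1e-30)  # |grad rho|
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, (rho - 1.0) / np.maximum(grad, 1e-30), -np.min(a))
    # signed distance to surface (positive outside); erf edge profile
    return 0.5 * (1.0 - erf(dist / (np.sqrt(2.0) * sigma)))


def _ellipsoid_ft(k: np.ndarray, comp: Ellipsoid) -> np.ndarray:
    rot = comp.rotation()
    a = np.asarray(comp.semi_axes)
    kb = k @ rot  # body-frame k
    u = 2.0 * np.pi * np.linalg.norm(kb * a, axis=1)
    f = np.empty_like(u)
    small = u < 1e-4
    us = u[~small]
    f[~small] = 3.0 * (np.sin(us) - us * np.cos(us)) / us**3
    f[small] = 1.0 - u[small] ** 2 / 10.0
    phase = np.exp(-2j * np.pi * (k @ np.asarray(comp.center)))
    return comp.intensity * comp.volume_mm3 * f * phase


def build_default_phantom(
    matrix_size: int = 64,
    fov_mm: float = 200.0,
    neck_coupling: float = 0.3,
) -> PhantomModel:
    """Deterministic head-like phantom sized for the given field of view.

    The geometry (in mm, scanner frame: x left, y up, z head) comprises a
    brain ellipsoid with six internal contrast features (ventricles,
    deep-gray nuclei, cortical foci) so the quality metrics have edges to
    score, a thin high-intensity scalp fat shell, and an inferior neck fat
    component whose rotation is scaled by ``neck_coupling``.
    """
    if matrix_size < 32:
        raise ValueError("matrix_size must be >= 32 per axis")
    # the scanner origin (the rotation centre of all poses) sits at the
    # cranio-cervical junction — the natural pivot of nodding motion —
    # with the head above it and the small neck fat pad just below
    comps = [
        # scalp shell: outer fat minus inner void
        Ellipsoid((0, 0, 30), (72, 82, 66), intensity=1.0, tissue_tag="scalp_fat"),
        Ellipsoid((0, 0, 30), (66, 76, 60), intensity=-1.0, tissue_tag="scalp_fat"),
        # brain
        Ellipsoid((0, 0, 30), (61, 71, 55), intensity=0.8, tissue_tag="brain"),
        # lateral ventricles (dark)
        Ellipsoid((14, 5, 40), (8, 20, 12), (0, 0, 10), -0.35, "feature"),
        Ellipsoid((-14, 5, 40), (8, 20, 12), (0, 0, -10), -0.35, "feature"),
        # deep-gray nuclei (bright)
        Ellipsoid((24, -5, 32), (9, 11, 13), (0, 0, 0), 0.25, "feature"),
        Ellipsoid((-24, -5, 32), (9, 11, 13), (0, 0, 0), 0.25, "feature"),
        # cortical foci
        Ellipsoid((0, 42, 52), (9, 9, 9), (0, 0, 0), 0.3, "feature"),
        Ellipsoid((6, -46, 28), (10, 12, 10), (0, 0, 0), -0.2, "feature"),
        # neck fat: small, inferior-posterior, clear of the scalp shell,
        # non-rigid
        Ellipsoid((0, -28, -56), (16, 20, 14), (0, 0, 0), 0.18, "neck_fat", rigid=False),
    ]
    model = PhantomModel(comps, neck_coupling=neck_coupling, fov_mm=fov_mm)
    # sanity: everything must also fit at the requested raster size
    _ = matrix_size
    return model
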