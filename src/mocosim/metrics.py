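"""Image-quality metrics and evaluation statistics.

All volumetric scores are means of 2-D per-slice metrics over the 30
central axial slices, after normalising each slice independently to
[0, 1] (and rescaling to [0, 255] for FSIM) — never volumetric filters.

* FSIM (feature similarity index, reference-based, in [0, 1]): combines
  phase-congruency similarity with gradient-magnitude similarity,
  weighted by the maximum phase congruency.  Phase congruency is a
  contrast-invariant, frequency-domain edge-significance measure built
  from multi-scale, multi-orientation log-Gabor filter responses.
* NGS (normalized gradient squared, non-reference): sharpness measure
  ``sum_p (g_p / sum_q g_q)^2`` over the gradient magnitude ``g`` of a
  slice; increases as edges sharpen.
* Background ghost analysis: per-slice foreground masks from the dilated
  convex hull of a simple threshold, and the background power ratio
  (sum of squared background intensities over total).

Statistical helpers (Wilcoxon signed-rank for paired image-quality
comparisons, refused below n = 6; Pearson correlation with a two-sided
t-test) wrap scipy.stats with the conventions fixed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.filters import scharr_h, scharr_v, sobel_h, sobel_v
from skimage.morphology import convex_hull_image, dilation, disk

__all__ = [
    "FsimParams",
    "MetricProtocol",
    "QualityReport",
    "phase_congruency_2d",
    "compute_fsim",
    "compute_ngs",
    "background_mask_2d",
    "background_power",
    "wilcoxon_signed_rank",
    "pearson_correlation",
    "central_slice_indices",
]


@dataclass(frozen=True)
class FsimParams:
    """FSIM constants and log-Gabor phase-congruency settings.

    ``t1`` stabilises the phase-congruency similarity term; ``t2`` the
    gradient term (sized for a 0-255 intensity range).  The log-Gabor
    bank uses ``n_scales`` scales spaced by ``mult`` from
    ``min_wavelength`` pixels, with radial bandwidth ``sigma_onf`` and
    ``n_orientations`` orientations; ``noise_k`` scales the estimated
    noise floor subtracted from the local energy.
    """

    t1: float = 0.85
    t2: float = 160.0
    n_scales: int = 4
    n_orientations: int = 4
    min_wavelength: float = 6.0
    mult: float = 2.0
    sigma_onf: float = 0.55
    noise_k: float = 2.0
    gradient: str = "scharr"

    def __post_init__(self):
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("T1 and T2 must be positive")
        if self.gradient not in ("scharr", "sobel"):
            raise ValueError("gradient must be 'scharr' or 'sobel'")


@dataclass(frozen=True)
class MetricProtocol:
    """Slice-selection and normalisation protocol for volume scoring."""

    n_central_slices: int = 30
    slice_axis: int = 2  # axial (head-foot axis)
    fsim_rescale: float = 255.0


@dataclass
class QualityReport:
    """Per-arm image-quality summary."""

    fsim: float | None = None
    fsim_masked: float | None = None
    ngs: float | None = None
    ngs_masked: float | None = None
    background_power: float | None = None
    mean_motion_score: float | None = None
    per_slice: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "fsim",
                "fsim_masked",
                "ngs",
                "ngs_masked",
                "background_power",
                "mean_motion_score",
            )
        }
        return {k: (None if v is None else float(v)) for k, v in out.items()}


def central_slice_indices(n_slices_total: int, protocol: MetricProtocol) -> np.ndarray:
    n = min(protocol.n_central_slices, n_slices_total)
    lo = (n_slices_total - n) // 2
    return np.arange(lo, lo + n)


def _normalize_slice(sl: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(sl)), float(np.max(sl))
    if hi - lo <= 0:
        return np.zeros_like(sl, float)
    return (sl - lo) / (hi - lo)


def _iter_slices(volume: np.ndarray, protocol: MetricProtocol):
    vol = np.moveaxis(volume, protocol.slice_axis, 0)
    for idx in central_slice_indices(vol.shape[0], protocol):
        yield int(idx), vol[idx]


# ---------------------------------------------------------------------------
# Phase congruency (multi-scale log-Gabor, PC2-style construction)
# ---------------------------------------------------------------------------

def _log_gabor_bank(shape, params: FsimParams):
    rows, cols = shape
    fy = np.fft.fftshift(np.fft.fftfreq(rows))[:, None]
    fx = np.fft.fftshift(np.fft.fftfreq(cols))[None, :]
    radius = np.hypot(fx, fy)
    radius[rows // 2, cols // 2] = 1.0  # avoid log(0) at DC; filter zeroed there
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)  # tame corner frequencies
    radials = []
    for s in range(params.n_scales):
        f0 = 1.0 / (params.min_wavelength * params.mult**s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(params.sigma_onf) ** 2))
        lg *= lowpass
        lg[rows // 2, cols // 2] = 0.0
        radials.append(lg)
    spreads = []
    sigma_theta = np.pi / params.n_orientations / 1.2
    for o in range(params.n_orientations):
        angle = o * np.pi / params.n_orientations
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta**2) / (2.0 * sigma_theta**2)))
    return radials, spreads


def phase_congruency_2d(image: np.ndarray, params: FsimParams | None = None) -> np.ndarray:
    """Per-pixel phase congruency in [0, 1] of a 2-D image.

    Multi-scale, multi-orientation log-Gabor filtering with a
    noise-threshold subtraction; contrast invariant (``PC(a I + b) =
    PC(I)`` for ``a > 0``) because both the local energy and the noise
    floor scale with the image.  A constant image maps to all zeros.
    """
    params = params or FsimParams()
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError("phase_congruency_2d expects a 2-D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if np.ptp(img) == 0:
        return np.zeros_like(img)
    # affine pre-normalisation: makes the contrast invariance of the
    # construction exact despite the fixed numerical epsilons below
    img = (img - np.min(img)) / np.ptp(img)
    eps = 1e-8
    fimg = np.fft.fftshift(np.fft.fft2(img))
    radials, spreads = _log_gabor_bank(img.shape, params)
    pc_num = np.zeros_like(img)
    pc_den = np.zeros_like(img)
    for spread in spreads:
        sum_e = np.zeros_like(img, complex)
        sum_an = np.zeros_like(img)
        max_an = np.zeros_like(img)
        an_scale1 = None
        for s, radial in enumerate(radials):
            resp = np.fft.ifft2(np.fft.ifftshift(fimg * (radial * spread)))
            an = np.abs(resp)
            sum_e += resp
            sum_an += an
            np.maximum(max_an, an, out=max_an)
            if s == 0:
                an_scale1 = an
        energy = np.abs(sum_e)
        # noise floor: Rayleigh-statistics estimate from the smallest scale
        tau = np.median(an_scale1) / np.sqrt(np.log(4.0))
        m = params.mult
        total_tau = tau * (1.0 - (1.0 / m) ** params.n_scales) / (1.0 - 1.0 / m)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        t_o = noise_mean + params.noise_k * noise_sigma
        # frequency-spread sigmoid: true edges excite many scales, ringing
        # and flat regions mostly one — down-weight narrow spectra
        width = (sum_an / (max_an + eps) - 1.0) / (params.n_scales - 1.0)
        weight = 1.0 / (1.0 + np.exp(10.0 * (0.4 - width)))
        pc_num += weight * np.maximum(energy - t_o, 0.0)
        pc_den += sum_an
    return pc_num / (pc_den + eps)


# ---------------------------------------------------------------------------
# FSIM / NGS
# ---------------------------------------------------------------------------

def _gradient_magnitude(img: np.ndarray, kind: str) -> np.ndarray:
    if kind == "scharr":
        return np.hypot(scharr_h(img), scharr_v(img))
    return np.hypot(sobel_h(img), sobel_v(img))


def _fsim_slice(a: np.ndarray, b: np.ndarray, params: FsimParams) -> float:
    pc1 = phase_congruency_2d(a, params)
    pc2 = phase_congruency_2d(b, params)
    g1 = _gradient_magnitude(a, params.gradient)
    g2 = _gradient_magnitude(b, params.gradient)
    t1, t2 = params.t1, params.t2
    s_pc = (2.0 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2.0 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    pc_max = np.maximum(pc1, pc2)
    den = float(np.sum(pc_max))
    if den <= 1e-12:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(np.sum(s_pc * s_g * pc_max) / den)


def compute_fsim(
    test: np.ndarray,
    reference: np.ndarray,
    protocol: MetricProtocol | None = None,
    params: FsimParams | None = None,
    background_masks: dict | None = None,
) -> float:
    """Mean FSIM over the central axial slices.

    Each slice of both volumes is min-max normalised to [0, 1] and
    rescaled to [0, 255] before scoring.  Identical volumes score exactly
    1.  ``background_masks`` (slice index -> boolean foreground mask)
    zeroes the background of both slices before scoring, the protocol
    used to probe background-ghost sensitivity.
    """
    protocol = protocol or MetricProtocol()
    params = params or FsimParams()
    test = np.asarray(test, float)
    reference = np.asarray(reference, float)
    if test.shape != reference.shape:
        raise ValueError("test and reference volumes must share a shape")
    vals = []
    ref_slices = dict(_iter_slices(reference, protocol))
    for idx, sl in _iter_slices(test, protocol):
        a = _normalize_slice(sl) * protocol.fsim_rescale
        b = _normalize_slice(ref_slices[idx]) * protocol.fsim_rescale
        if background_masks is not None:
            fg = background_masks[idx]
            a = a * fg
            b = b * fg
        vals.append(_fsim_slice(a, b, params))
    return float(np.mean(vals))


def compute_ngs(
    test: np.ndarray,
    protocol: MetricProtocol | None = None,
    gradient: str = "scharr",
    background_masks: dict | None = None,
) -> float:
    """Mean normalized-gradient-squared sharpness over central slices.

    Per normalised slice: ``NGS = sum_p (g_p / sum_q g_q)^2``; a constant
    slice contributes 0 by convention.  Scale-invariant per slice by
    construction.
    """
    protocol = protocol or MetricProtocol()
    test = np.asarray(test, float)
    vals = []
    for idx, sl in _iter_slices(test, protocol):
        a = _normalize_slice(sl)
        if background_masks is not None:
            a = a * background_masks[idx]
        g = _gradient_magnitude(a, gradient)
        total = float(np.sum(g))
        vals.append(0.0 if total <= 0 else float(np.sum((g / total) ** 2)))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Background ghost analysis
# ---------------------------------------------------------------------------

def background_mask_2d(
    slice_img: np.ndarray, threshold: float = 0.1, dilation_px: int = 2
) -> np.ndarray:
    """Foreground mask of a slice: dilated convex hull of the
    supra-threshold pixels (``threshold`` is a fraction of the slice
    maximum).  Background is the complement."""
    sl = np.asarray(slice_img, float)
    mx = float(np.max(sl))
    if mx <= 0:
        warnings.warn("empty slice: full-background mask")
        return np.zeros(sl.shape, bool)
    core = sl > threshold * mx
    if not np.any(core):
        warnings.warn("no supra-threshold pixels: full-background mask")
        return np.zeros(sl.shape, bool)
    hull = convex_hull_image(core)
    if dilation_px > 0:
        hull = dilation(hull, disk(dilation_px))
    return hull


def volume_background_masks(
    volume: np.ndarray,
    protocol: MetricProtocol | None = None,
    threshold: float = 0.1,
    dilation_px: int = 2,
) -> dict:
    """Per-central-slice foreground masks (slice index -> bool array)."""
    protocol = protocol or MetricProtocol()
    masks = {}
    for idx, sl in _iter_slices(volume, protocol):
        masks[idx] = background_mask_2d(_normalize_slice(sl), threshold, dilation_px)
    return masks


def background_power(
    volume: np.ndarray,
    masks: dict,
    protocol: MetricProtocol | None = None,
) -> float:
    """Ratio of summed squared background intensity to total, over the
    central slices (masks give the foreground)."""
    protocol = protocol or MetricProtocol()
    bg = 0.0
    total = 0.0
    for idx, sl in _iter_slices(volume, protocol):
        a = _normalize_slice(sl)
        sq = a**2
        total += float(np.sum(sq))
        bg += float(np.sum(sq[~masks[idx]]))
    return 0.0 if total <= 0 else bg / total


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(paired_a, paired_b):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; ties get average ranks; the
    statistic is ``W = min(T+, T-)`` (all-positive differences give
    W = 0).  Exact null for n <= 15 without rank ties, normal
    approximation otherwise.  Refuses fewer than 6 pairs (the study's
    own minimum sample size).
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if len(a) < 6:
        raise ValueError("signed-rank test refused: fewer than 6 pairs")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        raise ValueError("signed-rank test refused: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    t_plus = float(np.sum(ranks[d > 0]))
    t_minus = float(np.sum(ranks[d < 0]))
    w = min(t_plus, t_minus)
    n = len(d)
    if n <= 15:
        # exact null: enumerate all 2^n sign patterns (handles rank ties,
        # which the scipy exact path does not)
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        t_dist = signs @ ranks
        p = 2.0 * min(
            np.mean(t_dist <= t_plus + 1e-12), np.mean(t_dist >= t_plus - 1e-12)
        )
        return w, float(min(p, 1.0))
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="approx")
    return w, float(res.pvalue)


def pearson_correlation(x, y):
    """Sample Pearson r with the two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
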