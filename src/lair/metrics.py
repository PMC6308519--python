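"""Figures of merit for reconstructed images and sinograms.

Global similarity indices (PSNR, UIQI, SSIM, rTV) drive both reporting and
the image-quality-based stopping rule of the iterative solvers.  ROI-based
physics metrics (CNR, SNR, FWHM, HA linearity) evaluate QA phantom scans.

Definitions
-----------
* ``PSNR = 10 log10( max(f1, f2)^2 / MSE )`` where the peak is the joint
  maximum pixel value over both images.
* ``UIQI = 4 mu1 mu2 s12 / ((mu1^2 + mu2^2)(s1^2 + s2^2))`` on global
  statistics; 1.0 iff the (non-constant) images are identical.
* ``SSIM`` uses ``c1 = (0.01 L)^2``, ``c2 = (0.03 L)^2`` with L the dynamic
  range.  The default mode is the conventional 11x11 Gaussian window
  (sigma 1.5), mean-pooled; ``mode="global"`` evaluates the formula once on
  whole-image statistics.
* ``rTV = ||f*||_TV / ||f||_TV`` — the ratio of total-variation norms,
  1.0 when the reconstruction has the reference's edge content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from skimage.metrics import structural_similarity as _sk_ssim

from .tv import tv_norm

__all__ = [
    "mse",
    "psnr",
    "uiqi",
    "ssim",
    "rtv",
    "cnr",
    "snr",
    "fwhm",
    "linearity",
    "ROISpec",
    "ProfileLine",
    "roi_pixels",
    "iq_summary",
]


def _check_shapes(f1: np.ndarray, f2: np.ndarray) -> None:
    if f1.shape != f2.shape:
        raise ValueError(f"shape mismatch: {f1.shape} vs {f2.shape}")


def mse(f1: np.ndarray, f2: np.ndarray) -> float:
    """Mean squared error, pixel by pixel over all N pixels."""
    _check_shapes(f1, f2)
    d = np.asarray(f1, dtype=np.float64) - np.asarray(f2, dtype=np.float64)
    return float(np.mean(d * d))


def psnr(f1: np.ndarray, f2: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; the peak is max over both images.

    Identical images give ``inf`` (a defined sentinel, not an error).
    """
    _check_shapes(f1, f2)
    err = mse(f1, f2)
    if err == 0.0:
        return float("inf")
    peak = float(max(np.max(f1), np.max(f2)))
    return float(10.0 * np.log10(peak * peak / err))


def uiqi(f1: np.ndarray, f2: np.ndarray) -> float:
    """Universal image quality index on global statistics, in [-1, 1].

    When both means are exactly zero the luminance factor degenerates to
    0/0 and the index reduces to its structure-contrast part
    ``2 cov / (var1 + var2)``; if the variances also vanish the index is
    undefined (NaN sentinel).
    """
    _check_shapes(f1, f2)
    a = np.asarray(f1, dtype=np.float64).ravel()
    b = np.asarray(f2, dtype=np.float64).ravel()
    mu1, mu2 = a.mean(), b.mean()
    v1, v2 = a.var(), b.var()
    cov = float(np.mean((a - mu1) * (b - mu2)))
    if mu1 * mu1 + mu2 * mu2 <= 1e-20 * (v1 + v2):
        if v1 + v2 == 0.0:
            return float("nan")
        return float(2.0 * cov / (v1 + v2))
    denom = (mu1 * mu1 + mu2 * mu2) * (v1 + v2)
    if denom == 0.0:
        return float("nan")
    return float(4.0 * mu1 * mu2 * cov / denom)


def ssim(
    f1: np.ndarray,
    f2: np.ndarray,
    dynamic_range: float | None = None,
    mode: str = "windowed",
) -> float:
    """Structural similarity index.

    ``mode="windowed"`` (default) uses an 11x11 Gaussian window with
    sigma 1.5, mean-pooled — the conventional implementation.  In
    ``mode="global"`` the SSIM expression is evaluated once on whole-image
    mean/variance/covariance.
    """
    _check_shapes(f1, f2)
    a = np.asarray(f1, dtype=np.float64)
    b = np.asarray(f2, dtype=np.float64)
    L = dynamic_range
    if L is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        L = float(hi - lo) or 1.0
    if L <= 0:
        raise ValueError("dynamic_range must be > 0")
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    if mode == "global":
        mu1, mu2 = a.mean(), b.mean()
        v1, v2 = a.var(), b.var()
        cov = float(np.mean((a - mu1) * (b - mu2)))
        return float(
            (2 * mu1 * mu2 + c1)
            * (2 * cov + c2)
            / ((mu1 * mu1 + mu2 * mu2 + c1) * (v1 + v2 + c2))
        )
    if mode != "windowed":
        raise ValueError(f"unknown ssim mode {mode!r}")
    return float(
        _sk_ssim(
            a,
            b,
            data_range=L,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
        )
    )


def rtv(f_star: np.ndarray, f_ref: np.ndarray) -> float:
    """Relative total variation ``||f*||_TV / ||f_ref||_TV``.

    Asymmetric by construction; the reference must have nonzero TV.
    """
    denom = tv_norm(f_ref)
    if denom == 0.0:
        raise ValueError("reference image has zero total variation")
    return float(tv_norm(f_star) / denom)


# ---------------------------------------------------------------------------
# ROI-based metrics


@dataclass(frozen=True)
class ROISpec:
    """Axis-aligned rectangular region of interest in physical mm.

    ``center_mm`` is (x, y) relative to the image centre; the default size is
    the conventional 3 x 3 mm^2 analysis box.
    """

    center_mm: tuple[float, float]
    width_mm: float = 3.0
    height_mm: float = 3.0
    role: str = "signal"


def roi_pixels(img: np.ndarray, roi: ROISpec, voxel_mm: float) -> np.ndarray:
    """Extract the ROI as a flat pixel array; errors if out of bounds."""
    n_rows, n_cols = img.shape
    cx, cy = roi.center_mm
    half_w = roi.width_mm / 2.0
    half_h = roi.height_mm / 2.0
    # x -> columns, y -> -rows; origin at the grid centre
    j0 = int(round((cx - half_w) / voxel_mm + n_cols / 2.0))
    j1 = int(round((cx + half_w) / voxel_mm + n_cols / 2.0))
    i0 = int(round(n_rows / 2.0 - (cy + half_h) / voxel_mm))
    i1 = int(round(n_rows / 2.0 - (cy - half_h) / voxel_mm))
    if i0 < 0 or j0 < 0 or i1 > n_rows or j1 > n_cols or i1 <= i0 or j1 <= j0:
        raise ValueError(f"ROI {roi} exceeds image bounds {img.shape}")
    return img[i0:i1, j0:j1].ravel()


def cnr(img: np.ndarray, roi_sig: ROISpec, roi_bg: ROISpec, voxel_mm: float) -> float:
    """Contrast-to-noise ratio ``|mu_sig - mu_bg| / sqrt(s_sig^2 + s_bg^2)``."""
    sig = roi_pixels(img, roi_sig, voxel_mm)
    bg = roi_pixels(img, roi_bg, voxel_mm)
    denom = float(np.sqrt(sig.var() + bg.var()))
    if denom == 0.0:
        return float("inf") if sig.mean() != bg.mean() else 0.0
    return float(abs(sig.mean() - bg.mean()) / denom)


def snr(img: np.ndarray, roi: ROISpec, voxel_mm: float) -> float:
    """Signal-to-noise ratio ``mu_ROI / sigma_ROI`` (+inf for zero sigma)."""
    px = roi_pixels(img, roi, voxel_mm)
    s = float(px.std())
    if s == 0.0:
        return float("inf")
    return float(px.mean() / s)


@dataclass(frozen=True)
class ProfileLine:
    """Straight sampling line through an image, in physical mm."""

    start_mm: tuple[float, float]
    end_mm: tuple[float, float]
    n_samples: int = 200

    def __post_init__(self) -> None:
        dx = self.end_mm[0] - self.start_mm[0]
        dy = self.end_mm[1] - self.start_mm[1]
        if dx == 0 and dy == 0:
            raise ValueError("profile line has zero length")


def sample_profile(img: np.ndarray, line: ProfileLine, voxel_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample image values along the line (bilinear); returns (s_mm, values)."""
    from scipy.ndimage import map_coordinates

    n_rows, n_cols = img.shape
    t = np.linspace(0.0, 1.0, line.n_samples)
    x = line.start_mm[0] + t * (line.end_mm[0] - line.start_mm[0])
    y = line.start_mm[1] + t * (line.end_mm[1] - line.start_mm[1])
    cols = x / voxel_mm + (n_cols - 1) / 2.0
    rows = (n_rows - 1) / 2.0 - y / voxel_mm
    vals = map_coordinates(img.astype(np.float64), [rows, cols], order=1, mode="constant")
    s = t * float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return s, vals


_FWHM_OF_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm(positions: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum of a single-peak profile.

    A Gaussian plus constant baseline is least-squares fitted and the FWHM is
    ``2 sqrt(2 ln 2) * sigma_fit``, in the units of ``positions``.
    """
    x = np.asarray(positions, dtype=np.float64)
    y = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape or x.size < 5:
        raise ValueError("profile must be 1-D with at least 5 samples")

    def model(x, amp, mu, sigma, base):
        return base + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    base0 = float(np.percentile(y, 10))
    amp0 = float(y.max() - base0)
    mu0 = float(x[np.argmax(y)])
    sigma0 = max((x[-1] - x[0]) / 10.0, np.finfo(float).eps)
    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=[amp0, mu0, sigma0, base0], maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological profiles
        raise ValueError(f"Gaussian fit did not converge: {exc}") from exc
    sigma_fit = abs(popt[2])
    if not np.isfinite(sigma_fit) or sigma_fit == 0:
        raise ValueError("Gaussian fit degenerate (sigma = 0)")
    return float(_FWHM_OF_SIGMA * sigma_fit)


def linearity(
    img: np.ndarray,
    inserts: list[tuple[ROISpec, float]],
    voxel_mm: float,
) -> float:
    """Pearson r between insert ROI mean intensities and nominal densities."""
    if len(inserts) < 3:
        raise ValueError("linearity needs at least 3 inserts")
    means = [float(roi_pixels(img, roi, voxel_mm).mean()) for roi, _ in inserts]
    densities = [float(d) for _, d in inserts]
    r, _ = stats.pearsonr(means, densities)
    return float(r)


@dataclass
class IQSummary:
    psnr: float
    uiqi: float
    ssim: float
    rtv: float
    extras: dict = field(default_factory=dict)


def iq_summary(recon: np.ndarray, reference: np.ndarray, ssim_mode: str = "windowed") -> IQSummary:
    """All four similarity indices of a reconstruction against a reference."""
    return IQSummary(
        psnr=psnr(recon, reference),
        uiqi=uiqi(recon, reference),
        ssim=ssim(recon, reference, mode=ssim_mode),
        rtv=rtv(recon, reference),
        extras={"ssim_mode": ssim_mode},
    )
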