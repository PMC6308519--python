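"""Filtered backprojection for parallel and flat-detector fan beams.

This is the 2D central-slice specialisation of the Feldkamp cone-beam
algorithm: cosine pre-weighting of each detector row (fan mode), convolution
with the band-limited ramp kernel, then distance-weighted backprojection.
The fan-beam detector coordinate is rescaled to the isocenter so that the
source-to-detector geometry enters only through the weights.

The discrete Ram-Lak kernel (sample spacing h) is
``g(0) = 1/(4 h^2)``, ``g(n) = -1/(pi^2 n^2 h^2)`` for odd n, 0 for even n;
apodised variants (Shepp-Logan, Hann) multiply its frequency response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ScanGeometry
from .sinogram import Sinogram

__all__ = ["FilterSpec", "ramp_kernel", "ramp_filter_rows", "fbp_reconstruct"]


@dataclass(frozen=True)
class FilterSpec:
    kernel: str = "ramlak"
    cutoff: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.cutoff <= 1.0):
            raise ValueError("cutoff must be in (0, 1]")
        if self.kernel not in ("ramlak", "shepp_logan_filter", "hann"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


def ramp_kernel(n: int, spacing: float) -> np.ndarray:
    """Discrete band-limited ramp kernel values g(-n+1..n-1) wrapped for FFT.

    Returned length is the FFT padding size (next power of two >= 2n), with
    g(0) at index 0 and symmetric lags wrapped around.
    """
    npad = 1 << int(np.ceil(np.log2(max(2 * n, 16))))
    k = np.zeros(npad)
    lags = np.arange(1, n)
    k[0] = 1.0 / (4.0 * spacing * spacing)
    odd = lags[lags % 2 == 1]
    k[odd] = -1.0 / (np.pi * np.pi * odd * odd * spacing * spacing)
    k[npad - odd] = k[odd]
    return k


def _filter_freq_response(n_bins: int, spacing: float, spec: FilterSpec) -> np.ndarray:
    kern = ramp_kernel(n_bins, spacing)
    npad = kern.size
    H = np.fft.rfft(kern).real
    freq = np.fft.rfftfreq(npad)  # cycles/sample, Nyquist at 0.5
    rel = freq / 0.5
    if spec.kernel == "shepp_logan_filter":
        H = H * np.sinc(rel / (2.0 * spec.cutoff))
    elif spec.kernel == "hann":
        H = H * 0.5 * (1.0 + np.cos(np.pi * rel / spec.cutoff))
    H[rel > spec.cutoff] = 0.0
    # note: the truncated kernel's tiny positive DC is kept — it compensates
    # the finite kernel support, and removing it biases reconstructed values
    return H


def ramp_filter_rows(
    rows: np.ndarray, spacing: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Convolve each angular row with the band-limited ramp kernel.

    A unit impulse row returns the kernel itself (zero lag ``1/(4 h^2)``).
    The quadrature factor h is applied by the backprojector, not here.
    """
    rows = np.asarray(rows, dtype=np.float64)
    n_bins = rows.shape[-1]
    H = _filter_freq_response(n_bins, spacing, spec)
    npad = 2 * (H.size - 1)
    padded = np.zeros(rows.shape[:-1] + (npad,))
    padded[..., :n_bins] = rows
    out = np.fft.irfft(np.fft.rfft(padded, axis=-1) * H, axis=-1)
    return out[..., :n_bins]


def fbp_reconstruct(
    sino: Sinogram,
    geom: ScanGeometry,
    grid_n: int,
    voxel_mm: float,
    filter_spec: FilterSpec = FilterSpec(),
) -> np.ndarray:
    """Filtered backprojection onto a grid_n x grid_n image (mm^-1).

    Negative values are retained; clipping is the caller's choice.  For a
    full 360 deg scan every line is measured twice, which the angular
    quadrature weight accounts for.
    """
    if sino.n_bins != geom.det_count:
        raise ValueError(
            f"sinogram bins ({sino.n_bins}) != detector count ({geom.det_count})"
        )
    p = sino.data
    n_det = sino.n_bins
    demag = geom.sod / geom.sid
    if geom.beam == "fan_flat":
        spacing = geom.det_pitch_um * 1e-3 * demag  # detector rescaled to isocenter
        s = (np.arange(n_det) - (n_det - 1) / 2.0) * spacing
        D = geom.sod
        p = p * (D / np.sqrt(D * D + s * s))[None, :]
    else:
        spacing = geom.det_pitch_um * 1e-3 * demag
        s = (np.arange(n_det) - (n_det - 1) / 2.0) * spacing

    q = ramp_filter_rows(p, spacing, filter_spec)

    # pixel centres: columns -> +x, rows -> -y, origin at the grid centre
    ax = (np.arange(grid_n) - (grid_n - 1) / 2.0) * voxel_mm
    X = np.broadcast_to(ax[None, :], (grid_n, grid_n))
    Y = np.broadcast_to(ax[::-1][:, None], (grid_n, grid_n))

    theta = np.deg2rad(sino.angles_deg)
    dtheta = np.deg2rad(sino.angle_step_deg)
    # each line appears twice per full rotation
    weight = dtheta * spacing * (0.5 if sino.coverage_deg >= 360.0 - 1e-9 else 1.0)

    img = np.zeros((grid_n, grid_n))
    s0 = s[0]
    inv_ds = 1.0 / spacing
    for a, th in enumerate(theta):
        cu, su = np.cos(th), np.sin(th)
        pu = X * cu + Y * su
        if geom.beam == "fan_flat":
            pv = -X * su + Y * cu
            denom = geom.sod + pv
            sprime = geom.sod * pu / denom
            U2 = (denom / geom.sod) ** 2
            contrib = np.interp(sprime, s, q[a], left=0.0, right=0.0) / U2
        else:
            contrib = np.interp(pu, s, q[a], left=0.0, right=0.0)
        img += contrib
    return img * weight
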