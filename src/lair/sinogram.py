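"""Sinogram container and the limited-angle manipulation chain.

A fan-beam sinogram repeats after 360 deg, so a full-coverage acquisition
can be extended to 450 deg by copying its first 90 deg of rows.  The
limited-angle (LA) acquisition is then emulated by zeroing the 90-359 deg
band, leaving a known context of [0, 90) + [360, 450) around the missing
region — the layout the context-encoder inpainting model is trained on.
After completion, the duplicated band is folded back onto [0, 90) and the
360 deg sinogram reconstructed as usual.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Sinogram",
    "extend_to_450",
    "apply_la_mask",
    "resize_for_ce",
    "fold_back_360",
    "read_sinogram",
    "write_sinogram",
    "missing_band_rows",
    "ce_region_rows",
]


class SinogramFormatError(ValueError):
    """Raised when a sinogram file lacks required metadata."""


@dataclass
class Sinogram:
    """Angle-major stack of line integrals with its angular-grid metadata.

    ``data`` has shape (n_angles, n_bins); values are dimensionless line
    integrals (mm^-1 times mm).  ``known`` optionally marks, per angle row,
    whether the row was measured (True) or is missing/inpainted (False).
    """

    data: np.ndarray
    angle_step_deg: float
    bin_pitch_um: float
    angle_start_deg: float = 0.0
    known: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2-D (angles x bins)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")
        if self.known is not None:
            self.known = np.asarray(self.known, dtype=bool)
            if self.known.shape != (self.data.shape[0],):
                raise ValueError("known-mask length must equal n_angles")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def coverage_deg(self) -> float:
        return self.n_angles * self.angle_step_deg

    @property
    def angles_deg(self) -> np.ndarray:
        return self.angle_start_deg + np.arange(self.n_angles) * self.angle_step_deg


def _require_coverage(s: Sinogram, coverage: float, what: str) -> None:
    if abs(s.coverage_deg - coverage) > 1e-6:
        raise ValueError(
            f"{what} requires {coverage} deg coverage, got {s.coverage_deg}"
        )


def extend_to_450(s360: Sinogram) -> Sinogram:
    """Append a copy of the first 90 deg of rows: 360 -> 450 deg coverage."""
    _require_coverage(s360, 360.0, "extend_to_450")
    n90 = int(round(90.0 / s360.angle_step_deg))
    if abs(n90 * s360.angle_step_deg - 90.0) > 1e-9:
        raise ValueError("angular step must divide 90 deg to extend")
    data = np.vstack([s360.data, s360.data[:n90]])
    known = None
    if s360.known is not None:
        known = np.concatenate([s360.known, s360.known[:n90]])
    return replace(s360, data=data, known=known)


def missing_band_rows(s450: Sinogram) -> np.ndarray:
    """Row indices whose angle lies in the missing [90, 360) deg band."""
    ang = s450.angles_deg
    return np.nonzero((ang >= 90.0 - 1e-9) & (ang < 360.0 - 1e-9))[0]


def apply_la_mask(s450: Sinogram) -> tuple[Sinogram, np.ndarray]:
    """Zero the [90, 360) band of a 450 deg sinogram; mask marks missing rows.

    Returns the masked sinogram (masked rows exactly 0, known rows bit-exact
    copies) and the boolean per-angle mask (True = missing).  The missing
    flag is carried separately from the data so a measured zero is never
    confused with an absent measurement.
    """
    _require_coverage(s450, 450.0, "apply_la_mask")
    missing = np.zeros(s450.n_angles, dtype=bool)
    missing[missing_band_rows(s450)] = True
    data = s450.data.copy()
    data[missing] = 0.0
    return replace(s450, data=data, known=~missing), missing


def _resize_rows_mask(known_in: np.ndarray, n_out: int) -> np.ndarray:
    """Known-mask after angular resampling: a resampled row is known only if
    every input row it interpolates from is known (conservative)."""
    n_in = known_in.shape[0]
    scale = n_in / n_out
    known_out = np.ones(n_out, dtype=bool)
    for i in range(n_out):
        pos = (i + 0.5) * scale - 0.5
        lo = int(np.floor(pos))
        for j in (lo, lo + 1):
            jj = min(max(j, 0), n_in - 1)
            if not known_in[jj]:
                known_out[i] = False
    return known_out


def resize_for_ce(
    s: Sinogram,
    n_angles: int = 448,
    n_bins: int = 544,
) -> Sinogram:
    """Bilinear resampling to the network input dims (default 544 x 448).

    Metadata is rescaled with the dims: the radial sampling becomes
    ``pitch * n_bins_in / n_bins`` and the angular step
    ``step * n_angles_in / n_angles`` — e.g. 541 bins at 75 um -> 544 bins
    at 74.586 um and 450 angles at 1.00 deg -> 448 at 1.004 deg.
    """
    if n_angles < 1 or n_bins < 1:
        raise ValueError("target dims must be positive")
    for n_in, n_out in ((s.n_angles, n_angles), (s.n_bins, n_bins)):
        if not (0.5 <= n_in / n_out <= 2.0):
            raise ValueError(
                f"resize factor {n_in}/{n_out} outside the supported 2x range"
            )
    downsampling = n_angles < s.n_angles or n_bins < s.n_bins
    data = _sk_resize(
        s.data, (n_angles, n_bins), order=1, mode="edge",
        anti_aliasing=downsampling, preserve_range=True,
    )
    known = None
    if s.known is not None:
        known = _resize_rows_mask(s.known, n_angles)
    return Sinogram(
        data=data,
        angle_step_deg=s.angle_step_deg * s.n_angles / n_angles,
        bin_pitch_um=s.bin_pitch_um * s.n_bins / n_bins,
        angle_start_deg=s.angle_start_deg,
        known=known,
    )


def ce_region_rows(n_angles: int, known: np.ndarray) -> tuple[int, int]:
    """Start row and height of the network's predicted band.

    The height is the number of unknown rows rounded up to a multiple of 16
    (four 2x decoder upsamplings), extended symmetrically into known
    territory and clipped to the sinogram; compositing later overwrites any
    known rows inside the band from the measured input.
    """
    missing = np.nonzero(~known)[0]
    if missing.size == 0:
        raise ValueError("sinogram has no missing rows")
    count = missing.size
    height = int(-(-count // 16) * 16)
    height = min(height, (n_angles // 16) * 16)
    start = int(round(missing[0] - (height - count) / 2))
    start = min(max(start, 0), n_angles - height)
    return start, height


def fold_back_360(s450: Sinogram, mode: str = "mean") -> Sinogram:
    """Reduce a 450 deg sinogram to 360 deg.

    ``mode="mean"`` replaces the [0, 90) rows by the element-wise mean of
    the [0, 90) and [360, 450) bands (exact on consistent data, averages
    completion noise); ``mode="keep-first"`` keeps the [0, 90) band as-is.
    """
    _require_coverage(s450, 450.0, "fold_back_360")
    n90 = int(round(90.0 / s450.angle_step_deg))
    n360 = int(round(360.0 / s450.angle_step_deg))
    data = s450.data[:n360].copy()
    if mode == "mean":
        data[:n90] = 0.5 * (s450.data[:n90] + s450.data[n360 : n360 + n90])
    elif mode != "keep-first":
        raise ValueError(f"unknown fold mode {mode!r}")
    known = None
    if s450.known is not None:
        known = s450.known[:n360].copy()
        if mode == "mean":
            known[:n90] = s450.known[:n90] & s450.known[n360 : n360 + n90]
    return replace(s450, data=data, known=known)


# ---------------------------------------------------------------------------
# HDF5 persistence: /sino float32 (slices x angles x bins), /mask uint8,
# attrs {angle_start, angle_step_deg, coverage_deg, bin_pitch_um}.


def write_sinogram(path: str | Path, sinos: Sinogram | list[Sinogram]) -> None:
    """Write one or a stack of same-shape sinograms losslessly (float32)."""
    stack = [sinos] if isinstance(sinos, Sinogram) else list(sinos)
    first = stack[0]
    data = np.stack([s.data.astype(np.float32) for s in stack])
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sino", data=data, compression="gzip", compression_opts=4)
        ds.attrs["angle_start"] = first.angle_start_deg
        ds.attrs["angle_step_deg"] = first.angle_step_deg
        ds.attrs["coverage_deg"] = first.coverage_deg
        ds.attrs["bin_pitch_um"] = first.bin_pitch_um
        if first.known is not None:
            f.create_dataset(
                "mask", data=np.stack([s.known.astype(np.uint8) for s in stack])
            )


def read_sinogram(path: str | Path) -> list[Sinogram]:
    """Read a sinogram stack written by :func:`write_sinogram`."""
    with h5py.File(path, "r") as f:
        if "sino" not in f:
            raise SinogramFormatError(f"{path}: missing /sino dataset")
        ds = f["sino"]
        for key in ("angle_step_deg", "bin_pitch_um"):
            if key not in ds.attrs:
                raise SinogramFormatError(f"{path}: missing attr {key!r}")
        data = ds[...]
        known = f["mask"][...].astype(bool) if "mask" in f else None
        start = float(ds.attrs.get("angle_start", 0.0))
        step = float(ds.attrs["angle_step_deg"])
        pitch = float(ds.attrs["bin_pitch_um"])
    if data.ndim == 2:
        data = data[None]
        known = known[None] if known is not None else None
    return [
        Sinogram(
            data=data[i].astype(np.float64),
            angle_step_deg=step,
            bin_pitch_um=pitch,
            angle_start_deg=start,
            known=known[i] if known is not None else None,
        )
        for i in range(data.shape[0])
    ]
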