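"""Scan geometry, magnification arithmetic and acquisition protocols.

Conventions used throughout the package
---------------------------------------
* Angles are in degrees, counter-clockwise, with 0 deg along the +x axis of
  the image grid.  The source-detector pair rotates; the object is fixed.
* At view angle 0 the source sits at ``(0, -SOD)`` and the flat detector line
  at ``y = SID - SOD``, with the detector coordinate running along +x.
* Image grids are square, pixel (row 0, col 0) at the top-left, physical
  origin at the grid centre; columns map to +x, rows to -y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ScanGeometry",
    "AcquisitionProtocol",
    "magnification",
    "isocenter_voxel_size",
    "fov_mm",
    "projection_angles",
    "load_config",
    "LA",
    "DSFC",
    "LSFC",
]


class GeometryError(ValueError):
    """Raised for unphysical scan geometries."""


class ProtocolError(ValueError):
    """Raised for inconsistent acquisition protocols."""


@dataclass(frozen=True)
class ScanGeometry:
    """Fan/parallel-beam scan geometry of a rotating-gantry micro-CT.

    Parameters
    ----------
    sod : float
        Source-to-rotation-centre distance in mm.
    sid : float
        Source-to-detector distance in mm (``sid >= sod``).
    det_pitch_um : float
        Detector pixel pitch in micrometres.
    det_count : int
        Number of detector bins in one row.
    beam : {"fan_flat", "parallel"}
        Beam shape. ``fan_flat`` is a point source with a flat equidistant
        detector (flat-panel geometry); ``parallel`` provides the classical
        Radon transform, mainly for closed-form testing.
    """

    sod: float
    sid: float
    det_pitch_um: float
    det_count: int
    beam: str = "fan_flat"

    def __post_init__(self) -> None:
        if self.sod <= 0:
            raise GeometryError(f"sod must be > 0, got {self.sod}")
        if self.sid < self.sod:
            raise GeometryError(f"sid ({self.sid}) must be >= sod ({self.sod})")
        if self.det_pitch_um <= 0:
            raise GeometryError("det_pitch_um must be > 0")
        if self.det_count < 1:
            raise GeometryError("det_count must be >= 1")
        if self.beam not in ("fan_flat", "parallel"):
            raise GeometryError(f"unknown beam type {self.beam!r}")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Angular sampling protocol: step and total coverage in degrees.

    ``LA`` (limited angle) is 1 deg/projection over 90 deg, ``DSFC``
    (densely-sampled full coverage) 1 deg over 360 deg and ``LSFC``
    (loosely-sampled full coverage) 5 deg over 360 deg.
    """

    step_deg: float
    coverage_deg: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.step_deg <= 0:
            raise ProtocolError("step_deg must be > 0")
        if self.coverage_deg <= 0:
            raise ProtocolError("coverage_deg must be > 0")
        ratio = self.coverage_deg / self.step_deg
        if abs(ratio - round(ratio)) > 1e-9:
            raise ProtocolError(
                f"coverage ({self.coverage_deg}) must be an integer multiple "
                f"of step ({self.step_deg})"
            )

    @property
    def n_views(self) -> int:
        return int(round(self.coverage_deg / self.step_deg))


#: The three acquisition protocols compared in the study.
LA = AcquisitionProtocol(step_deg=1.0, coverage_deg=90.0, label="LA")
DSFC = AcquisitionProtocol(step_deg=1.0, coverage_deg=360.0, label="DSFC")
LSFC = AcquisitionProtocol(step_deg=5.0, coverage_deg=360.0, label="LSFC")


def magnification(geom: ScanGeometry) -> float:
    """Geometric magnification SID/SOD of the flat-panel system."""
    return geom.sid / geom.sod


def isocenter_voxel_size(geom: ScanGeometry) -> float:
    """Detector sampling demagnified to the rotation centre, in um.

    This is the natural reconstructed voxel size: ``det_pitch * SOD / SID``.
    """
    return geom.det_pitch_um * geom.sod / geom.sid


def fov_mm(geom: ScanGeometry) -> float:
    """Transaxial field of view at the isocenter in mm."""
    return geom.det_count * isocenter_voxel_size(geom) * 1e-3


def projection_angles(protocol: AcquisitionProtocol) -> np.ndarray:
    """Ordered view angles ``[0, step, 2*step, ...]`` in degrees.

    The last angle is ``coverage - step``; a full-coverage protocol does not
    repeat the 0/360 view.
    """
    n = protocol.n_views
    return np.arange(n, dtype=np.float64) * protocol.step_deg


def load_config(path: str | Path) -> tuple[ScanGeometry, AcquisitionProtocol]:
    """Read geometry + protocol from a YAML/JSON config file.

    Recognised keys: ``sod_mm, sid_mm, det_pitch_um, det_count, beam,
    step_deg, coverage_deg, label``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    geom = ScanGeometry(
        sod=float(cfg["sod_mm"]),
        sid=float(cfg["sid_mm"]),
        det_pitch_um=float(cfg["det_pitch_um"]),
        det_count=int(cfg["det_count"]),
        beam=str(cfg.get("beam", "fan_flat")),
    )
    protocol = AcquisitionProtocol(
        step_deg=float(cfg["step_deg"]),
        coverage_deg=float(cfg["coverage_deg"]),
        label=str(cfg.get("label", "custom")),
    )
    return geom, protocol
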