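"""Monte-Carlo digital phantoms and QA test objects.

Training/testing data for the sinogram-completion model is generated rather
than measured: randomized cylinder phantoms (1-4 discs, radii 10-20 px,
random placement, pose augmentation by rotation/reflection/reversed
rotation), the classic Shepp-Logan head phantom (2D and 3D), and
"digit-like" thick-stroke images standing in for handwritten-digit data.
QA phantoms (wire, contrast-scale, water, hydroxyapatite) mirror the
physical objects used for resolution, CNR/SNR and linearity measurements.

Disc attenuation values are drawn uniform in [0.01, 0.05] mm^-1,
a soft-tissue-like range at micro-CT tube voltages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metrics import ProfileLine, ROISpec

__all__ = [
    "RandomizationConfig",
    "PoseInfo",
    "QAPhantom",
    "random_cylinder_phantom",
    "shepp_logan",
    "digit_like",
    "randomize_pose",
    "qa_phantom",
    "generate_dataset",
    "SinogramDataset",
]

#: water-equivalent linear attenuation (mm^-1) used by the QA phantoms
MU_WATER = 0.02
#: attenuation per unit hydroxyapatite density (mm^-1 per mg/cm^3)
MU_PER_HA_DENSITY = 2.5e-5
#: nominal HA insert densities (mg/cm^3)
HA_DENSITIES = (0.0, 100.0, 200.0, 400.0, 800.0)


@dataclass(frozen=True)
class RandomizationConfig:
    """Monte-Carlo ranges for the cylinder phantom and pose augmentation."""

    n_cyl_range: tuple[int, int] = (1, 4)
    radius_range_px: tuple[int, int] = (10, 20)
    value_range: tuple[float, float] = (0.01, 0.05)
    allow_reflection: bool = True
    allow_reversed_rotation: bool = True
    rotation_max_deg: float = 360.0

    def __post_init__(self) -> None:
        lo, hi = self.n_cyl_range
        if not (1 <= lo <= hi):
            raise ValueError("n_cyl_range must satisfy 1 <= min <= max")
        rlo, rhi = self.radius_range_px
        if rlo <= 0 or rhi < rlo:
            raise ValueError("radius bounds must be positive and ordered")


@dataclass(frozen=True)
class PoseInfo:
    """Pose augmentation applied to one phantom draw."""

    angle_deg: float = 0.0
    reflected: bool = False
    reversed_rotation: bool = False


def _grid_coords(grid_n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates in pixels, origin at the grid centre."""
    ax = np.arange(grid_n) - (grid_n - 1) / 2.0
    return np.meshgrid(ax, ax[::-1])  # X right, Y up


def random_cylinder_phantom(
    cfg: RandomizationConfig, rng: np.random.Generator, grid_n: int = 128
) -> np.ndarray:
    """1-4 filled discs with uniform radii/centres, fully contained in grid."""
    rlo, rhi = cfg.radius_range_px
    if 2 * rhi >= grid_n:
        raise ValueError(
            f"max radius {rhi} px does not fit in a {grid_n} px grid"
        )
    k = int(rng.integers(cfg.n_cyl_range[0], cfg.n_cyl_range[1] + 1))
    X, Y = _grid_coords(grid_n)
    img = np.zeros((grid_n, grid_n))
    half = (grid_n - 1) / 2.0
    for _ in range(k):
        r = float(rng.uniform(rlo, rhi))
        cx = float(rng.uniform(-(half - r), half - r))
        cy = float(rng.uniform(-(half - r), half - r))
        val = float(rng.uniform(*cfg.value_range))
        img[(X - cx) ** 2 + (Y - cy) ** 2 <= r * r] += val
    return img


# (value, a, b, x0, y0, phi_deg) — the classical head-phantom ellipse table;
# values compose to the 0..2 attenuation scale.
_SL_ELLIPSES_2D = [
    (2.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.98, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.01, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.01, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
]

# (value, a, b, c, x0, y0, z0, phi_deg)
_SL_ELLIPSOIDS_3D = [
    (2.00, 0.6900, 0.9200, 0.810, 0.00, 0.0000, 0.00, 0.0),
    (-0.98, 0.6624, 0.8740, 0.780, 0.00, -0.0184, 0.00, 0.0),
    (-0.02, 0.1100, 0.3100, 0.220, 0.22, 0.0000, 0.00, -18.0),
    (-0.02, 0.1600, 0.4100, 0.280, -0.22, 0.0000, 0.00, 18.0),
    (0.01, 0.2100, 0.2500, 0.410, 0.00, 0.3500, -0.15, 0.0),
    (0.01, 0.0460, 0.0460, 0.050, 0.00, 0.1000, 0.25, 0.0),
    (0.01, 0.0460, 0.0460, 0.050, 0.00, -0.1000, 0.25, 0.0),
    (0.01, 0.0460, 0.0230, 0.050, -0.08, -0.6050, 0.00, 0.0),
    (0.01, 0.0230, 0.0230, 0.020, 0.00, -0.6060, 0.00, 0.0),
    (0.01, 0.0230, 0.0460, 0.020, 0.06, -0.6050, 0.00, 0.0),
]


def shepp_logan(grid_n: int, dims: int = 2) -> np.ndarray:
    """Classical Shepp-Logan phantom on the unit square/cube, values in [0, 2]."""
    if grid_n < 16:
        raise ValueError("grid_n must be >= 16")
    if dims == 2:
        ax = (np.arange(grid_n) - (grid_n - 1) / 2.0) / (grid_n / 2.0)
        X, Y = np.meshgrid(ax, ax[::-1])  # row 0 at top (y = +1)
        img = np.zeros((grid_n, grid_n))
        for val, a, b, x0, y0, phi in _SL_ELLIPSES_2D:
            c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
            xr = (X - x0) * c + (Y - y0) * s
            yr = -(X - x0) * s + (Y - y0) * c
            img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += val
        return np.clip(img, 0.0, None)
    if dims == 3:
        ax = (np.arange(grid_n) - (grid_n - 1) / 2.0) / (grid_n / 2.0)
        Z, Y, X = np.meshgrid(ax, ax[::-1], ax, indexing="ij")
        vol = np.zeros((grid_n, grid_n, grid_n))
        for val, a, b, c3, x0, y0, z0, phi in _SL_ELLIPSOIDS_3D:
            c, s = np.cos(np.deg2rad(phi)), np.sin(np.deg2rad(phi))
            xr = (X - x0) * c + (Y - y0) * s
            yr = -(X - x0) * s + (Y - y0) * c
            zr = Z - z0
            vol[(xr / a) ** 2 + (yr / b) ** 2 + (zr / c3) ** 2 <= 1.0] += val
        return np.clip(vol, 0.0, None)
    raise ValueError("dims must be 2 or 3")


def digit_like(
    grid_n: int, rng: np.random.Generator, n_strokes: tuple[int, int] = (2, 4)
) -> np.ndarray:
    """Random thick strokes/blobs emulating handwritten-digit shapes."""
    img = np.zeros((grid_n, grid_n))
    k = int(rng.integers(n_strokes[0], n_strokes[1] + 1))
    margin = grid_n // 6
    val = float(rng.uniform(0.01, 0.05))
    for _ in range(k):
        p = rng.uniform(margin, grid_n - margin, size=(2, 2))
        n_pts = 2 * grid_n
        t = np.linspace(0, 1, n_pts)
        pts = p[0][None, :] * (1 - t[:, None]) + p[1][None, :] * t[:, None]
        rows = np.clip(pts[:, 0].astype(int), 0, grid_n - 1)
        cols = np.clip(pts[:, 1].astype(int), 0, grid_n - 1)
        stroke = np.zeros((grid_n, grid_n), dtype=bool)
        stroke[rows, cols] = True
        width = int(rng.integers(2, max(3, grid_n // 24)))
        stroke = ndimage.binary_dilation(stroke, iterations=width)
        img[stroke] = val
    return img


def randomize_pose(
    img: np.ndarray, cfg: RandomizationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, PoseInfo]:
    """Random rotation (bilinear, zero fill), optional left-right reflection,
    and a reversed-rotation flag consumed by sinogram generation."""
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("pose randomization expects a square 2D image")
    angle = float(rng.uniform(0.0, cfg.rotation_max_deg))
    reflected = bool(cfg.allow_reflection and rng.integers(0, 2))
    reversed_rot = bool(cfg.allow_reversed_rotation and rng.integers(0, 2))
    out = np.fliplr(img) if reflected else img
    if angle != 0.0:
        out = ndimage.rotate(
            out, angle, reshape=False, order=1, mode="constant", cval=0.0
        )
        out = np.clip(out, 0.0, None)
    else:
        out = out.copy()
    return out, PoseInfo(angle, reflected, reversed_rot)


# ---------------------------------------------------------------------------
# QA phantoms


@dataclass
class QAPhantom:
    """Digital QA object with its analysis annotations."""

    kind: str
    image: np.ndarray
    voxel_um: float
    rois: list[ROISpec] = field(default_factory=list)
    inserts: list[tuple[ROISpec, float]] = field(default_factory=list)
    profiles: list[ProfileLine] = field(default_factory=list)

    @property
    def voxel_mm(self) -> float:
        return self.voxel_um * 1e-3


def _five_roi_layout(offset_mm: float, size_mm: float = 3.0) -> list[ROISpec]:
    """Central ROI plus upper/lower/left/right boxes at the given offset."""
    centers = [(0.0, 0.0), (0.0, offset_mm), (0.0, -offset_mm),
               (-offset_mm, 0.0), (offset_mm, 0.0)]
    roles = ["signal", "background", "background", "background", "background"]
    return [
        ROISpec(center_mm=c, width_mm=size_mm, height_mm=size_mm, role=r)
        for c, r in zip(centers, roles)
    ]


def _deposit_subpixel(img: np.ndarray, x_px: float, y_px: float, mass: float) -> None:
    """Bilinear deposit of a point mass at sub-pixel position (x right, y up)."""
    n = img.shape[0]
    col = x_px + (n - 1) / 2.0
    row = (n - 1) / 2.0 - y_px
    i0, j0 = int(np.floor(row)), int(np.floor(col))
    fr, fc = row - i0, col - j0
    for di, wi in ((0, 1 - fr), (1, fr)):
        for dj, wj in ((0, 1 - fc), (1, fc)):
            img[i0 + di, j0 + dj] += mass * wi * wj


def qa_phantom(kind: str, grid_n: int = 128, voxel_um: float = 500.0) -> QAPhantom:
    """Digital wire / contrast-scale / water / hydroxyapatite phantom.

    * ``qa_wire``: two sub-pixel impulses of equal integrated mass, one at
      the centre and one at the periphery, with profile lines across each.
    * ``qa_contrast``: water disc with a dense HA core and the five-ROI
      layout (core = signal, surroundings = background) for CNR.
    * ``qa_water``: uniform water disc with five 3x3 mm^2 ROIs for SNR.
    * ``qa_ha``: water disc with five HA inserts of nominal densities
      0-800 mg/cm^3 and matching ROIs for the linearity check.
    """
    voxel_mm = voxel_um * 1e-3
    fov_mm = grid_n * voxel_mm
    disc_r_mm = 0.40 * fov_mm
    X, Y = _grid_coords(grid_n)
    R2 = (X * voxel_mm) ** 2 + (Y * voxel_mm) ** 2
    img = np.zeros((grid_n, grid_n))

    if kind == "qa_wire":
        peripheral = 0.6 * disc_r_mm
        _deposit_subpixel(img, 0.3, 0.3, 1.0)
        _deposit_subpixel(img, peripheral / voxel_mm + 0.3, 0.3, 1.0)
        half_line = 0.25 * fov_mm
        profiles = [
            ProfileLine((-half_line, 0.0), (half_line, 0.0), n_samples=4 * grid_n),
            ProfileLine(
                (peripheral - half_line, 0.0),
                (peripheral + half_line, 0.0),
                n_samples=4 * grid_n,
            ),
        ]
        return QAPhantom(kind, img, voxel_um, profiles=profiles)

    offset_mm = 0.55 * disc_r_mm
    roi_size = min(3.0, 0.5 * offset_mm)
    if kind == "qa_water":
        img[R2 <= disc_r_mm**2] = MU_WATER
        return QAPhantom(
            kind, img, voxel_um, rois=_five_roi_layout(offset_mm, roi_size)
        )
    if kind == "qa_contrast":
        img[R2 <= disc_r_mm**2] = MU_WATER
        core_r = 0.22 * disc_r_mm
        img[R2 <= core_r**2] = MU_WATER + MU_PER_HA_DENSITY * 800.0
        rois = _five_roi_layout(offset_mm, min(roi_size, 0.9 * core_r))
        return QAPhantom(kind, img, voxel_um, rois=rois)
    if kind == "qa_ha":
        img[R2 <= disc_r_mm**2] = MU_WATER
        insert_r = max(0.12 * disc_r_mm, 0.75 * roi_size)
        layout = _five_roi_layout(offset_mm, roi_size)
        inserts = []
        for roi, dens in zip(layout, HA_DENSITIES):
            cx, cy = roi.center_mm
            mask = (X * voxel_mm - cx) ** 2 + (Y * voxel_mm - cy) ** 2 <= insert_r**2
            img[mask] = MU_WATER + MU_PER_HA_DENSITY * dens
            inserts.append((roi, dens))
        return QAPhantom(kind, img, voxel_um, inserts=inserts)
    raise ValueError(f"unknown QA phantom kind {kind!r}")


# ---------------------------------------------------------------------------
# Paired (complete, limited-angle, mask) dataset generation


@dataclass
class SinogramDataset:
    """Paired complete/LA sinogram set at network dims plus native context.

    ``complete``/``masked`` hold the 450 deg sinograms resampled to the
    network profile (n, angles, bins); ``known`` is the per-angle known
    flag shared by all samples.  ``native_*`` keep the un-resampled chain
    for fold-back and reconstruction; ``phantoms`` are the ground-truth
    images, and ``sample_seeds`` make every sample reproducible.
    """

    complete: np.ndarray
    masked: np.ndarray
    known: np.ndarray
    native_complete: np.ndarray
    native_masked: np.ndarray
    native_known: np.ndarray
    native_step_deg: float
    bin_pitch_um: float
    phantoms: np.ndarray
    poses: list[PoseInfo]
    sample_seeds: list[int]
    voxel_mm: float

    def __len__(self) -> int:
        return self.complete.shape[0]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("complete", data=self.complete.astype(np.float32),
                             compression="gzip")
            f.create_dataset("masked", data=self.masked.astype(np.float32),
                             compression="gzip")
            f.create_dataset("mask", data=(~self.known).astype(np.uint8))
            meta = f.create_group("meta")
            meta.attrs["native_step_deg"] = self.native_step_deg
            meta.attrs["bin_pitch_um"] = self.bin_pitch_um
            meta.attrs["voxel_mm"] = self.voxel_mm
            meta.create_dataset("sample_seeds", data=np.array(self.sample_seeds))


def generate_dataset(
    n_slices: int,
    geom,
    grid_n: int = 96,
    voxel_mm: float = 0.5,
    native_step_deg: float = 2.5,
    ce_angles: int = 112,
    ce_bins: int | None = None,
    kinds: tuple[str, ...] = ("cylinders",),
    cfg: RandomizationConfig | None = None,
    seed: int = 0,
    noise: str | None = None,
    noise_scale: float = 0.0,
) -> SinogramDataset:
    """Generate paired (complete, LA-masked, mask) sinogram triples.

    Each sample draws a randomized phantom, applies pose augmentation
    (reversed rotation negates the angular ordering of the sinogram rows),
    forward-projects over 360 deg, extends to 450 deg, applies the LA mask
    and resamples both versions to the network profile.  Fully reproducible
    from (config, master seed); per-sample seeds are logged.
    """
    from .projector import build_system_matrix
    from .sinogram import Sinogram, apply_la_mask, extend_to_450, resize_for_ce

    cfg = cfg or RandomizationConfig()
    ce_bins = ce_bins or geom.det_count
    angles = np.arange(0.0, 360.0, native_step_deg)
    A = build_system_matrix(geom, angles, grid_n, voxel_mm)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_slices)
    sample_seeds = [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]

    completes, maskeds, nat_completes, nat_maskeds = [], [], [], []
    phantoms, poses = [], []
    known_ce = known_native = None
    for i, child_seed in enumerate(sample_seeds):
        rng = np.random.default_rng(child_seed)
        kind = kinds[i % len(kinds)]
        if kind == "cylinders":
            base = random_cylinder_phantom(cfg, rng, grid_n)
        elif kind == "shepp_logan_2d":
            base = shepp_logan(grid_n, dims=2) * 0.025  # rescale to mm^-1 range
        elif kind == "digit_like":
            base = digit_like(grid_n, rng)
        else:
            raise ValueError(f"unknown phantom kind {kind!r}")
        img, pose = randomize_pose(base, cfg, rng)
        p = A.forward(img)
        if pose.reversed_rotation:
            # reversed gantry rotation: row i holds the view at -i*step.
            # Scanning at negated angles equals scanning the object mirrored
            # about the x-axis, so the reconstruction-frame ground truth is
            # the vertically flipped phantom; store that.
            p = np.roll(p[::-1], 1, axis=0).copy()
            img = img[::-1].copy()
        if noise == "poisson":
            i0 = noise_scale or 1e5
            p = -np.log(
                np.clip(rng.poisson(i0 * np.exp(-p)) / i0, 1e-12, None)
            )
        elif noise == "gaussian":
            p = p + rng.normal(0.0, noise_scale, size=p.shape)
        s360 = Sinogram(p, angle_step_deg=native_step_deg,
                        bin_pitch_um=geom.det_pitch_um)
        s450 = extend_to_450(s360)
        s_la, _ = apply_la_mask(s450)
        c_ce = resize_for_ce(s450, n_angles=ce_angles, n_bins=ce_bins)
        m_ce = resize_for_ce(s_la, n_angles=ce_angles, n_bins=ce_bins)
        completes.append(c_ce.data.astype(np.float32))
        maskeds.append(m_ce.data.astype(np.float32))
        nat_completes.append(s450.data.astype(np.float32))
        nat_maskeds.append(s_la.data.astype(np.float32))
        phantoms.append(img.astype(np.float32))
        poses.append(pose)
        known_ce = m_ce.known
        known_native = s_la.known
    # masked rows of the resampled LA sinogram are forced to exactly zero so
    # the network input carries no interpolation leakage from the band edges
    masked_arr = np.stack(maskeds)
    masked_arr[:, ~known_ce, :] = 0.0
    return SinogramDataset(
        complete=np.stack(completes),
        masked=masked_arr,
        known=known_ce,
        native_complete=np.stack(nat_completes),
        native_masked=np.stack(nat_maskeds),
        native_known=known_native,
        native_step_deg=native_step_deg,
        bin_pitch_um=geom.det_pitch_um,
        phantoms=np.stack(phantoms),
        poses=poses,
        sample_seeds=sample_seeds,
        voxel_mm=voxel_mm,
    )
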