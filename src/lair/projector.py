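"""Sparse system-matrix forward/back projection.

The system matrix ``A`` holds the exact intersection length ``a_ij`` (mm) of
projection ray ``j`` with pixel ``i``, computed by Siddon-style parametric
grid traversal.  Forward projection is the sparse product ``p = A f`` and
backprojection is the matched adjoint ``A^T p``, so the operator pair passes
inner-product (adjointness) tests to machine precision by construction.

Rays are ordered angle-major: row ``a * det_count + k`` is detector bin ``k``
at view ``a``.  Images are flattened row-major (row ``i`` = image row,
matching ``image.ravel()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, prange
from scipy import sparse

from .geometry import ScanGeometry, isocenter_voxel_size

__all__ = ["SystemMatrix", "build_system_matrix", "forward_project", "back_project"]


@njit(cache=True)
def _trace_ray(p0x, p0y, p1x, p1y, n, h, rows, cols, vals):
    """Exact intersection lengths of segment p0->p1 with the n x n grid.

    The grid is centred at the origin with pixel size h; row 0 is the top
    (largest y).  Entries are written into the provided buffers; the count
    is returned.
    """
    xmin = -0.5 * n * h
    ymin = -0.5 * n * h
    xmax = 0.5 * n * h
    ymax = 0.5 * n * h

    dx = p1x - p0x
    dy = p1y - p0y
    length = np.sqrt(dx * dx + dy * dy)
    if length == 0.0:
        return 0

    # clip parameter range to the bounding box
    tmin = 0.0
    tmax = 1.0
    if dx != 0.0:
        tx0 = (xmin - p0x) / dx
        tx1 = (xmax - p0x) / dx
        if tx0 > tx1:
            tx0, tx1 = tx1, tx0
        tmin = max(tmin, tx0)
        tmax = min(tmax, tx1)
    elif p0x <= xmin or p0x >= xmax:
        return 0
    if dy != 0.0:
        ty0 = (ymin - p0y) / dy
        ty1 = (ymax - p0y) / dy
        if ty0 > ty1:
            ty0, ty1 = ty1, ty0
        tmin = max(tmin, ty0)
        tmax = min(tmax, ty1)
    elif p0y <= ymin or p0y >= ymax:
        return 0
    if tmax <= tmin:
        return 0

    # entry point, nudged inside to pick the starting cell robustly
    eps = 1e-12 * n
    t = tmin
    x = p0x + t * dx
    y = p0y + t * dy
    col = int(np.floor((x - xmin) / h + eps * (1.0 if dx >= 0 else -1.0)))
    rowf = int(np.floor((ymax - y) / h + eps * (1.0 if dy <= 0 else -1.0)))
    if col < 0:
        col = 0
    if col > n - 1:
        col = n - 1
    if rowf < 0:
        rowf = 0
    if rowf > n - 1:
        rowf = n - 1

    # parametric step to the next x / y grid line
    if dx > 0.0:
        t_next_x = ((col + 1) * h + xmin - p0x) / dx
        dt_x = h / dx
        step_col = 1
    elif dx < 0.0:
        t_next_x = (col * h + xmin - p0x) / dx
        dt_x = -h / dx
        step_col = -1
    else:
        t_next_x = 1e30
        dt_x = 1e30
        step_col = 0
    if dy < 0.0:  # moving down -> row increases
        t_next_y = (ymax - (rowf + 1) * h - p0y) / dy
        dt_y = -h / dy
        step_row = 1
    elif dy > 0.0:
        t_next_y = (ymax - rowf * h - p0y) / dy
        dt_y = h / dy
        step_row = -1
    else:
        t_next_y = 1e30
        dt_y = 1e30
        step_row = 0

    count = 0
    while t < tmax - eps:
        if t_next_x < t_next_y:
            t_stop = t_next_x
        else:
            t_stop = t_next_y
        if t_stop > tmax:
            t_stop = tmax
        seg = (t_stop - t) * length
        if seg > 0.0 and 0 <= rowf < n and 0 <= col < n:
            rows[count] = rowf
            cols[count] = col
            vals[count] = seg
            count += 1
        if t_next_x < t_next_y:
            t = t_next_x
            t_next_x += dt_x
            col += step_col
        else:
            t = t_next_y
            t_next_y += dt_y
            rowf += step_row
        if col < 0 or col > n - 1 or rowf < 0 or rowf > n - 1:
            break
    return count


@njit(parallel=True, cache=True)
def _trace_all(p0, p1, n, h, capacity):
    n_rays = p0.shape[0]
    out_rows = np.empty((n_rays, capacity), dtype=np.int32)
    out_cols = np.empty((n_rays, capacity), dtype=np.int32)
    out_vals = np.empty((n_rays, capacity), dtype=np.float64)
    counts = np.zeros(n_rays, dtype=np.int64)
    for j in prange(n_rays):
        counts[j] = _trace_ray(
            p0[j, 0], p0[j, 1], p1[j, 0], p1[j, 1], n, h,
            out_rows[j], out_cols[j], out_vals[j],
        )
    return out_rows, out_cols, out_vals, counts


def _ray_endpoints(geom: ScanGeometry, angles_deg: np.ndarray, grid_n: int, voxel_mm: float):
    """Source/detector endpoints (mm) for every (angle, bin) ray."""
    n_det = geom.det_count
    theta = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
    cos_t = np.cos(theta)[:, None]
    sin_t = np.sin(theta)[:, None]
    if geom.beam == "fan_flat":
        s = (np.arange(n_det) - (n_det - 1) / 2.0) * (geom.det_pitch_um * 1e-3)
        s = s[None, :]
        # unrotated: source (0, -sod), bin (s, sid - sod)
        src = np.array([0.0, -geom.sod])
        p0x = cos_t * src[0] - sin_t * src[1] + 0.0 * s
        p0y = sin_t * src[0] + cos_t * src[1] + 0.0 * s
        dy = geom.sid - geom.sod
        p1x = cos_t * s - sin_t * dy
        p1y = sin_t * s + cos_t * dy
    else:  # parallel: bins at isocenter pitch, rays along the rotated +y axis
        pitch_iso = isocenter_voxel_size(geom) * 1e-3
        s = (np.arange(n_det) - (n_det - 1) / 2.0) * pitch_iso
        s = s[None, :]
        half = grid_n * voxel_mm  # spans the grid from either side
        p0x = cos_t * s - sin_t * (-half)
        p0y = sin_t * s + cos_t * (-half)
        p1x = cos_t * s - sin_t * half
        p1y = sin_t * s + cos_t * half
    p0 = np.stack([p0x.ravel(), p0y.ravel()], axis=1)
    p1 = np.stack([p1x.ravel(), p1y.ravel()], axis=1)
    return p0, p1


@dataclass
class SystemMatrix:
    """Sparse ray-pixel intersection-length operator for one scan setup."""

    matrix: sparse.csr_matrix
    geom: ScanGeometry
    angles_deg: np.ndarray
    grid_n: int
    voxel_mm: float

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def forward(self, image: np.ndarray) -> np.ndarray:
        """``p = A f`` -> sinogram of shape (n_angles, det_count)."""
        if image.shape != (self.grid_n, self.grid_n):
            raise ValueError(
                f"image shape {image.shape} != grid {(self.grid_n, self.grid_n)}"
            )
        p = self.matrix @ image.ravel().astype(np.float64)
        return p.reshape(self.n_angles, self.geom.det_count)

    def back(self, sino: np.ndarray) -> np.ndarray:
        """``A^T p`` -> image of shape (grid_n, grid_n)."""
        expected = (self.n_angles, self.geom.det_count)
        if sino.shape != expected:
            raise ValueError(f"sinogram shape {sino.shape} != {expected}")
        f = self.matrix.T @ sino.ravel().astype(np.float64)
        return f.reshape(self.grid_n, self.grid_n)

    def row_sums(self) -> np.ndarray:
        """Chord length of each ray through the grid (mm)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    def col_sums(self) -> np.ndarray:
        """Sensitivity image ``A^T 1`` flattened."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()


_CACHE: dict[tuple, SystemMatrix] = {}


def build_system_matrix(
    geom: ScanGeometry,
    angles_deg: np.ndarray,
    grid_n: int,
    voxel_mm: float,
    cache: bool = True,
) -> SystemMatrix:
    """Construct (or fetch from cache) the system matrix for one setup.

    Building dominates the cost of iterative studies, so matrices are cached
    per (geometry, angle grid, image grid) within a session.
    """
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    key = (
        geom.sod, geom.sid, geom.det_pitch_um, geom.det_count, geom.beam,
        grid_n, voxel_mm, angles_deg.tobytes(),
    )
    if cache and key in _CACHE:
        return _CACHE[key]

    p0, p1 = _ray_endpoints(geom, angles_deg, grid_n, voxel_mm)
    capacity = 2 * grid_n + 4
    rows, cols, vals, counts = _trace_all(p0, p1, grid_n, float(voxel_mm), capacity)
    n_rays = p0.shape[0]
    ray_idx = np.repeat(np.arange(n_rays, dtype=np.int64), counts)
    keep = np.zeros(rows.shape, dtype=bool)
    for j in range(n_rays):  # mask valid entries per ray
        keep[j, : counts[j]] = True
    pixel_idx = (rows[keep].astype(np.int64) * grid_n + cols[keep]).astype(np.int64)
    data = vals[keep]
    A = sparse.csr_matrix(
        (data, (ray_idx, pixel_idx)),
        shape=(n_rays, grid_n * grid_n),
    )
    sm = SystemMatrix(A, geom, angles_deg, grid_n, float(voxel_mm))
    if cache:
        _CACHE[key] = sm
    return sm


def forward_project(image: np.ndarray, A: SystemMatrix) -> np.ndarray:
    """Line integrals ``p = A f`` as an (n_angles, det_count) array."""
    return A.forward(image)


def back_project(sino: np.ndarray, A: SystemMatrix) -> np.ndarray:
    """Adjoint ``A^T p`` as a (grid_n, grid_n) image."""
    return A.back(sino)
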