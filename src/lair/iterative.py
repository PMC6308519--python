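"""TV-constrained iterative reconstruction with image-quality stopping.

Two solvers of the constrained problem

    f* = argmin_f  U(f) + lambda V(f),   s.t. f >= 0,

with U a data-fidelity term for ``p = A f`` and V the (smoothed) total
variation, are provided:

* **EM-TV** — multiplicative MLEM fidelity updates (Poisson likelihood)
  alternated with normalised TV descent steps weighted by ``lambda``.
* **ASD-POCS** — a relaxed SART fidelity pass plus nonnegativity projection,
  alternated with adaptive-steepest-descent TV minimisation whose step is a
  fraction of the POCS update magnitude and shrinks when the TV descent
  overshoots the data-residual ball.

Instead of thresholding the (unknowable) pixel error, iteration stops on
image quality: among iterates whose PSNR against the reference exceeds a
gate ``k`` (35 dB by default), the score ``s = UIQI - rTV`` is tracked and
the argmax-s iterate is returned once ``s`` has not improved for a patience
window.  In simulation the reference is the ground-truth phantom; in a real
LA pipeline it is the FBP reconstruction of the completed sinogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import psnr as _psnr
from .metrics import rtv as _rtv
from .metrics import ssim as _ssim
from .metrics import uiqi as _uiqi
from .projector import SystemMatrix
from .tv import tv_gradient, tv_norm

__all__ = [
    "IRConfig",
    "StoppingConfig",
    "IQReport",
    "em_update",
    "em_tv_reconstruct",
    "asd_pocs_reconstruct",
    "iq_stop_decision",
]


class InconsistentDataError(ValueError):
    """Raised when the model predicts zero counts where data are positive."""


@dataclass
class IRConfig:
    """Hyperparameters of the iterative solvers.

    Defaults follow the common settings of the ASD-POCS literature family;
    none are data-dependent.  ``lam`` is the relaxation weight balancing
    fidelity against TV; ``epsilon_tv`` smooths the TV gradient.
    """

    algorithm: str = "em_tv"
    lam: float = 0.2
    tv_steps: int = 10
    tv_step_size: float = 0.1
    max_iters: int = 50
    epsilon_tv: float = 1e-6
    beta: float = 1.0
    beta_red: float = 0.995
    alpha_frac: float = 0.2
    alpha_red: float = 0.95
    r_max: float = 0.95

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.epsilon_tv <= 0:
            raise ValueError("epsilon_tv must be > 0")


@dataclass
class StoppingConfig:
    """Image-quality stopping rule: PSNR gate plus UIQI - rTV patience."""

    k_psnr: float = 35.0
    patience: int = 3
    use_rtv_distance: bool = False  # score UIQI - |rTV - 1| instead of UIQI - rTV

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class IQReport:
    """Per-iteration quality record of an iterative reconstruction."""

    psnr: list[float] = field(default_factory=list)
    uiqi: list[float] = field(default_factory=list)
    ssim: list[float] = field(default_factory=list)
    rtv: list[float] = field(default_factory=list)
    data_residual: list[float] = field(default_factory=list)
    iterate_min: list[float] = field(default_factory=list)
    stop_iteration: int = 0  # 1-based iteration whose iterate was returned
    reason: str = ""

    def score(self, stop: StoppingConfig) -> np.ndarray:
        """Stopping score s_t per recorded iteration."""
        u = np.asarray(self.uiqi)
        r = np.asarray(self.rtv)
        return u - (np.abs(r - 1.0) if stop.use_rtv_distance else r)

    def n_iterations(self) -> int:
        return len(self.psnr)

    def as_dict(self) -> dict:
        return {
            "psnr": list(self.psnr),
            "uiqi": list(self.uiqi),
            "ssim": list(self.ssim),
            "rtv": list(self.rtv),
            "data_residual": list(self.data_residual),
            "iterate_min": list(self.iterate_min),
            "stop_iteration": self.stop_iteration,
            "reason": self.reason,
        }


def iq_stop_decision(
    report_so_far: IQReport, stop: StoppingConfig
) -> tuple[str, int]:
    """Decide whether to continue iterating, and which iterate is best.

    Returns ``("continue" | "stop", best_iteration)`` with iterations
    numbered from 1.  Only iterates passing the PSNR gate are eligible for
    the argmax of ``s = UIQI - rTV``; iteration stops once ``s`` has not
    improved for ``patience`` consecutive iterations.  If no iterate has
    passed the gate yet, the run continues (to ``max_iters``), and the
    caller reports reason ``"psnr-gate-unmet"`` with the last iterate.
    """
    n = report_so_far.n_iterations()
    if n < 1:
        raise ValueError("no iterations recorded yet")
    eligible = np.asarray(report_so_far.psnr) > stop.k_psnr
    if not eligible.any():
        return "continue", n
    s = report_so_far.score(stop)
    s_masked = np.where(eligible, s, -np.inf)
    best = int(np.argmax(s_masked))  # first maximum
    stale = n - 1 - best
    if stale >= stop.patience:
        return "stop", best + 1
    return "continue", best + 1


def em_update(f: np.ndarray, p: np.ndarray, A: SystemMatrix) -> np.ndarray:
    """One multiplicative MLEM step ``f' = f . A^T(p / Af) / A^T 1``.

    0/0 ratios are taken as 0; nonnegativity is preserved by construction.
    Positive measurements on rays the current estimate cannot produce
    (``Af = 0`` with ``p > 0``) are flagged as inconsistent data.
    """
    proj = A.forward(f)
    tiny = np.finfo(np.float64).tiny
    intersects = A.row_sums().reshape(proj.shape) > 0
    bad = (proj <= tiny) & (p > 0) & intersects
    if bad.any():
        raise InconsistentDataError(
            f"{int(bad.sum())} rays have p > 0 but Af = 0"
        )
    ratio = np.where(proj > tiny, p / np.where(proj > tiny, proj, 1.0), 0.0)
    sens = A.col_sums().reshape(f.shape)
    corr = A.back(ratio)
    out = np.where(sens > 0, f * corr / np.where(sens > 0, sens, 1.0), 0.0)
    return out


def _record_iq(report: IQReport, f, reference, residual, ssim_mode="windowed"):
    report.psnr.append(_psnr(f, reference))
    report.uiqi.append(_uiqi(f, reference))
    report.ssim.append(_ssim(f, reference, mode=ssim_mode))
    ref_tv = tv_norm(reference)
    report.rtv.append(tv_norm(f) / ref_tv if ref_tv > 0 else float("nan"))
    report.data_residual.append(residual)
    report.iterate_min.append(float(np.min(f)))


def _finalize(f_best, f_last, report, stop, diverged=False):
    if diverged:
        report.reason = "diverged"
        report.stop_iteration = report.n_iterations()
        return f_last, report
    eligible = np.asarray(report.psnr) > stop.k_psnr if stop else np.array([])
    if stop is None or not eligible.any():
        report.reason = "psnr-gate-unmet" if stop is not None else "max-iters"
        report.stop_iteration = report.n_iterations()
        return f_last, report
    _, best = iq_stop_decision(report, stop)
    report.stop_iteration = best
    if not report.reason:
        report.reason = "max-iters"
    return f_best if f_best is not None else f_last, report


def _run_outer_loop(step_fn, f0, p, A, cfg, stop, reference, ssim_mode):
    """Shared outer loop: update, record IQ, apply the stopping rule."""
    report = IQReport()
    f = f0
    f_best = None
    best_iter = -1
    worse_streak = 0
    prev_residual = np.inf
    for it in range(1, cfg.max_iters + 1):
        f = step_fn(f, it)
        residual = float(np.linalg.norm(A.forward(f) - p))
        _record_iq(report, f, reference, residual, ssim_mode)
        worse_streak = worse_streak + 1 if residual > prev_residual else 0
        prev_residual = residual
        if worse_streak >= 5:
            return _finalize(f_best, f, report, stop, diverged=True)
        if stop is not None:
            decision, best = iq_stop_decision(report, stop)
            if best - 1 != best_iter and np.asarray(report.psnr)[best - 1] > stop.k_psnr:
                if best == it:
                    f_best = f.copy()
                    best_iter = best - 1
            if decision == "stop":
                report.reason = "iq-early-stop"
                return _finalize(f_best, f, report, stop)
    return _finalize(f_best, f, report, stop)


def em_tv_reconstruct(
    p: np.ndarray,
    A: SystemMatrix,
    cfg: IRConfig | None = None,
    stop: StoppingConfig | None = None,
    reference: np.ndarray | None = None,
    ssim_mode: str = "windowed",
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, IQReport]:
    """EM-TV: MLEM fidelity updates alternated with weighted TV descent.

    The TV stage takes ``tv_steps`` normalised gradient steps whose length is
    ``lam * tv_step_size`` times the magnitude of the EM update, so the
    regularisation strength tracks the fidelity progress.  ``lam = 0``
    reduces to plain MLEM.  ``stop=None`` runs the fixed budget and returns
    the last iterate.
    """
    cfg = cfg or IRConfig(algorithm="em_tv")
    if reference is None and stop is not None:
        raise ValueError("the IQ stopping rule needs a reference image")
    if np.any(p < 0):
        raise ValueError("EM-TV expects nonnegative projection data")
    n = A.grid_n
    if not np.any(p > 0):  # nothing measured -> zero image immediately
        report = IQReport(reason="zero-data", stop_iteration=1)
        f = np.zeros((n, n))
        ref = reference if reference is not None else f
        _record_iq(report, f, ref, 0.0, ssim_mode)
        return f, report
    if init is not None:
        floor = max(float(np.mean(p)) / max(A.row_sums().max(), 1e-12), 1e-8)
        f0 = np.clip(init, 0.01 * floor, None)  # EM needs strictly positive support
    else:
        f0 = np.full(
            (n, n), max(float(np.mean(p)) / max(A.row_sums().max(), 1e-12), 1e-8)
        )
    ref = reference if reference is not None else np.zeros((n, n))

    def step(f, it):
        f_new = em_update(f, p, A)
        if cfg.lam > 0:
            em_mag = float(np.linalg.norm(f_new - f))
            for _ in range(cfg.tv_steps):
                g = tv_gradient(f_new, cfg.epsilon_tv)
                gn = float(np.linalg.norm(g))
                if gn == 0:
                    break
                f_new = f_new - (cfg.lam * cfg.tv_step_size * em_mag / gn) * g
                f_new = np.clip(f_new, 0.0, None)
        return f_new

    return _run_outer_loop(step, f0, p, A, cfg, stop, ref, ssim_mode)


def asd_pocs_reconstruct(
    p: np.ndarray,
    A: SystemMatrix,
    cfg: IRConfig | None = None,
    stop: StoppingConfig | None = None,
    reference: np.ndarray | None = None,
    ssim_mode: str = "windowed",
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, IQReport]:
    """ASD-POCS: relaxed SART + positivity, then adaptive TV descent.

    Per outer iteration the SART relaxation is ``beta`` (decayed by
    ``beta_red``); the TV stage takes ``tv_steps`` steps of length
    ``alpha_frac * ||POCS update||`` along the normalised TV gradient, and
    the step fraction is decayed by ``alpha_red`` whenever the TV stage
    moved farther than ``r_max`` times the POCS update.
    """
    cfg = cfg or IRConfig(algorithm="asd_pocs")
    if reference is None and stop is not None:
        raise ValueError("the IQ stopping rule needs a reference image")
    n = A.grid_n
    row = A.row_sums().reshape(-1, A.geom.det_count)
    col = A.col_sums().reshape(n, n)
    row_inv = np.where(row > 0, 1.0 / np.where(row > 0, row, 1.0), 0.0)
    col_inv = np.where(col > 0, 1.0 / np.where(col > 0, col, 1.0), 0.0)
    state = {"beta": cfg.beta, "alpha": cfg.alpha_frac}
    ref = reference if reference is not None else np.zeros((n, n))

    def step(f, it):
        f0 = f
        resid = p - A.forward(f)
        f = f + state["beta"] * A.back(resid * row_inv) * col_inv
        f = np.clip(f, 0.0, None)
        dp = float(np.linalg.norm(f - f0))
        f_pocs = f
        dtvg = state["alpha"] * dp
        for _ in range(cfg.tv_steps):
            g = tv_gradient(f, cfg.epsilon_tv)
            gn = float(np.linalg.norm(g))
            if gn == 0:
                break
            f = np.clip(f - dtvg * g / gn, 0.0, None)
        dg = float(np.linalg.norm(f - f_pocs))
        if dg > cfg.r_max * dp and dp > 0:
            state["alpha"] *= cfg.alpha_red
        state["beta"] *= cfg.beta_red
        return f

    f0 = np.clip(init, 0.0, None) if init is not None else np.zeros((n, n))
    return _run_outer_loop(step, f0, p, A, cfg, stop, ref, ssim_mode)
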