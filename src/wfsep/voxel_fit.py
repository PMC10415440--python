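"""Voxel-independent VARPRO water-fat fitting.

For fixed nonlinear parameters (field map df, relaxation R2*) the model

    I_n = exp((-R2* + j 2 pi df) TE_n) . [PW + PF c_n],
    c_n = sum_p alpha_p exp(j 2 pi f_p TE_n)

is linear in the complex amplitudes (PW, PF): variable projection solves
them in closed form, leaving a 2-D search over (df, R2*).  The residual
landscape in df is periodic (period ~ 1/dTE), which is the root of the
water-fat swap ambiguity; a multi-start grid over the field-map search
range followed by bounded local refinement selects the global minimum per
voxel.  No spatial regularisation is applied — voxels are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .signal_model import (
    AcquisitionParams,
    EchoSeries,
    FatSpectrum,
    ParameterMaps,
    ValidationError,
    fat_modulation,
)

__all__ = ["FitConfig", "VoxelFit", "varpro_residual", "fit_voxel", "fit_image"]

logger = logging.getLogger(__name__)


class FittingError(RuntimeError):
    """The linear subproblem is degenerate (rank-deficient design)."""


@dataclass(frozen=True)
class FitConfig:
    """Search strategy for the nonlinear (df, R2*) parameters.

    The default field-map range (+/-400 Hz) and R2* bounds ([0, 200] 1/s)
    mirror the normalisation envelope used for network labels.
    """

    fieldmap_search_range_hz: tuple[float, float] = (-400.0, 400.0)
    n_initializations: int = 41
    r2star_bounds_per_s: tuple[float, float] = (0.0, 200.0)
    convergence_tol: float = 1e-14
    max_iterations: int = 100
    n_refine_starts: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.fieldmap_search_range_hz
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValidationError("fieldmap search range must be finite and ordered")
        if self.n_initializations < 1:
            raise ValidationError("n_initializations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValidationError("convergence_tol must be positive")
        rlo, rhi = self.r2star_bounds_per_s
        if not (0 <= rlo < rhi):
            raise ValidationError("r2star bounds must satisfy 0 <= low < high")


@dataclass
class VoxelFit:
    """Single-voxel estimate with the residual norm at the solution."""

    pw: complex
    pf: complex
    r2star_per_s: float
    fieldmap_hz: float
    residual: float
    converged: bool = True


def _project(
    df_hz, r2_per_s, signal: np.ndarray, tes: np.ndarray, cn: np.ndarray
):
    """Closed-form linear least squares for (PW, PF) at fixed (df, R2*).

    Broadcasts over leading dimensions of ``df_hz``/``r2_per_s`` (grid
    scoring) against a single signal vector.  Returns (residual_sq, pw, pf).
    """
    df = np.asarray(df_hz, dtype=float)[..., None]
    r2 = np.asarray(r2_per_s, dtype=float)[..., None]
    phi = np.exp((-r2 + 2j * np.pi * df) * tes)  # (..., n)
    a1 = phi
    a2 = phi * cn
    # normal equations of the 2-column complex design [a1 a2]
    g11 = (np.abs(a1) ** 2).sum(-1)
    g22 = (np.abs(a2) ** 2).sum(-1)
    g12 = (np.conj(a1) * a2).sum(-1)
    b1 = (np.conj(a1) * signal).sum(-1)
    b2 = (np.conj(a2) * signal).sum(-1)
    det = g11 * g22 - np.abs(g12) ** 2
    scale = np.maximum(g11 * g22, 1e-300)
    degenerate = det <= 1e-12 * scale
    det_safe = np.where(degenerate, 1.0, det)
    pw = (g22 * b1 - g12 * b2) / det_safe
    pf = (g11 * b2 - np.conj(g12) * b1) / det_safe
    pw = np.where(degenerate, 0.0, pw)
    pf = np.where(degenerate, 0.0, pf)
    energy = (np.abs(signal) ** 2).sum()
    res_sq = energy - np.real(np.conj(b1) * pw + np.conj(b2) * pf)
    res_sq = np.maximum(res_sq, 0.0)
    return res_sq, pw, pf, degenerate


def varpro_residual(
    candidate_fieldmap_hz: float,
    candidate_r2star_per_s: float,
    signal: np.ndarray,
    acq: AcquisitionParams,
    spectrum: FatSpectrum,
):
    """Residual norm and projected amplitudes at one (df, R2*) candidate.

    Raises :class:`FittingError` when the two model columns are (numerically)
    collinear — e.g. a single-echo or otherwise degenerate TE grid where the
    fat modulation is constant.
    """
    signal = np.asarray(signal, dtype=np.complex128)
    if signal.ndim != 1 or signal.size != acq.n_echoes:
        raise ValidationError("signal length must equal the number of echoes")
    if acq.n_echoes < 3:
        raise ValidationError("at least 3 echoes are required for water-fat fitting")
    tes = acq.echo_times_s
    cn = fat_modulation(tes, spectrum)
    res_sq, pw, pf, degenerate = _project(
        candidate_fieldmap_hz, candidate_r2star_per_s, signal, tes, cn
    )
    if bool(degenerate):
        raise FittingError(
            "rank-deficient water/fat design: fat modulation is constant over the TE grid"
        )
    return float(np.sqrt(res_sq)), complex(pw), complex(pf)


def fit_voxel(
    signal: np.ndarray,
    acq: AcquisitionParams,
    spectrum: FatSpectrum,
    config: FitConfig = FitConfig(),
) -> VoxelFit:
    """Multi-start VARPRO fit of one voxel.

    A coarse (df, R2*) grid scores ``n_initializations`` field-map starts;
    the best few are refined by bounded trust-region least squares on the
    stacked real/imaginary residuals.  Deterministic given the config.
    """
    signal = np.asarray(signal, dtype=np.complex128)
    if acq.n_echoes < 3:
        raise ValidationError("at least 3 echoes are required for water-fat fitting")
    tes = acq.echo_times_s
    cn = fat_modulation(tes, spectrum)

    if np.all(signal == 0):
        return VoxelFit(0.0, 0.0, 0.0, 0.0, 0.0)

    flo, fhi = config.fieldmap_search_range_hz
    rlo, rhi = config.r2star_bounds_per_s
    df_grid = np.linspace(flo, fhi, config.n_initializations)
    r2_grid = np.linspace(rlo, rhi, 5)
    dd, rr = np.meshgrid(df_grid, r2_grid, indexing="ij")
    res_sq, _, _, _ = _project(dd, rr, signal, tes, cn)
    # periodic residual landscape in df: rank starts by distinct local minima
    # of the df profile (minimised over R2*), not by raw grid order, so the
    # refinement explores separate basins instead of one basin three times
    profile = res_sq.min(axis=1)
    best_r2 = res_sq.argmin(axis=1)
    interior = np.arange(1, len(df_grid) - 1)
    is_min = (profile[interior] <= profile[interior - 1]) & (
        profile[interior] <= profile[interior + 1]
    )
    candidates = list(interior[is_min])
    for edge in (0, len(df_grid) - 1):  # edges of the search range count too
        if edge == 0 and profile[0] <= profile[1]:
            candidates.append(0)
        if edge == len(df_grid) - 1 and profile[-1] <= profile[-2]:
            candidates.append(edge)
    if not candidates:
        candidates = [int(profile.argmin())]
    candidates.sort(key=lambda i: profile[i])
    order = [(i, best_r2[i]) for i in candidates]

    def residual_vec(theta):
        phi = np.exp((-theta[1] + 2j * np.pi * theta[0]) * tes)
        a = np.stack([phi, phi * cn], axis=1)
        amps, *_ = np.linalg.lstsq(a, signal, rcond=None)
        r = signal - a @ amps
        return np.concatenate([r.real, r.imag])

    candidates = []
    n_starts = min(config.n_refine_starts, len(order))
    converged = False
    for k in range(n_starts):
        i, j = order[k]
        x0 = np.array([dd[i, j], np.clip(rr[i, j], rlo + 1e-9, rhi - 1e-9)])
        sol = least_squares(
            residual_vec,
            x0,
            bounds=([flo, rlo], [fhi, rhi]),
            xtol=config.convergence_tol,
            ftol=config.convergence_tol,
            gtol=config.convergence_tol,
            max_nfev=config.max_iterations * 4,
        )
        candidates.append((float(np.linalg.norm(sol.fun)), sol.x))
        converged = converged or sol.status > 0
    # the model is exactly periodic in df with period 1/dTE for uniform echo
    # spacing, so a wide search range can hold two equally good minima (the
    # water-fat swap).  Among near-ties, take the solution nearest zero
    # off-resonance — the standard convention absent spatial regularisation.
    best_cost = min(c for c, _ in candidates)
    tol = 1e-6 * float(np.linalg.norm(signal)) + 1e-12
    cost, (df_hat, r2_hat) = min(
        (cand for cand in candidates if cand[0] <= best_cost + tol),
        key=lambda cand: abs(cand[1][0]),
    )
    rs, pw, pf, _ = _project(df_hat, r2_hat, signal, tes, cn)
    if not converged:
        logger.warning("voxel fit did not converge at any start; returning best found")
    return VoxelFit(
        pw=complex(pw),
        pf=complex(pf),
        r2star_per_s=float(r2_hat),
        fieldmap_hz=float(df_hat),
        residual=float(np.sqrt(rs)),
        converged=converged,
    )


def fit_image(
    echoes: EchoSeries,
    spectrum: FatSpectrum,
    config: FitConfig = FitConfig(),
    mask: "np.ndarray | None" = None,
) -> tuple[ParameterMaps, dict]:
    """Voxel-wise fit inside a mask; returns maps and a QC summary.

    The QC dict counts fitted voxels and non-converged voxels (per-voxel
    warnings are aggregated rather than raised).
    """
    if mask is None:
        mask = np.ones(echoes.shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != echoes.shape:
        raise ValidationError("mask shape must match the echo images")
    maps = ParameterMaps.zeros(echoes.shape)
    n_bad = 0
    idx = np.argwhere(mask)
    for r, c in idx:
        fit = fit_voxel(echoes.data[:, r, c], echoes.acquisition, spectrum, config)
        maps.water[r, c] = fit.pw
        maps.fat[r, c] = fit.pf
        maps.r2star_per_s[r, c] = fit.r2star_per_s
        maps.fieldmap_hz[r, c] = fit.fieldmap_hz
        if not fit.converged:
            n_bad += 1
    maps.mask = mask
    qc = {"n_voxels": int(idx.shape[0]), "n_not_converged": int(n_bad)}
    if n_bad:
        logger.warning("%d/%d voxels did not converge", n_bad, idx.shape[0])
    return maps, qc
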