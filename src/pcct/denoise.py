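"""Image-domain noise suppression.

Total-variation denoising is solved with a primal-dual (Chambolle-Pock)
scheme supporting L1 or L2 data fidelity and isotropic or anisotropic TV;
the guided filter implements the local linear model q = a*I + b averaged
over all windows containing each pixel, with truncated border windows.  A
virtual integrating-bin guidance image is built by summing pre-log counts
over all energy bins, reconstructing, and TV-denoising the result.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .geometry import ScanGeometry
from .materials import MaterialSpec, material_attenuation
from .recon import ReconVolume, fbp_slice, log_normalize, sart_slice
from .sinogram import SpectralSinogram


@dataclass
class TVParams:
    lam: float = 1.0
    n_iter: int = 18
    data_term: str = "L1"  # Eq-style L2 fidelity also available
    tv_kind: str = "isotropic"
    tau: float = 1.0 / np.sqrt(8.0)
    sigma: float = 1.0 / np.sqrt(8.0)

    def __post_init__(self) -> None:
        if self.lam < 0 or self.n_iter < 0:
            raise ValueError("lam and n_iter must be nonnegative")
        if self.data_term not in ("L1", "L2"):
            raise ValueError("data_term must be 'L1' or 'L2'")
        if self.tv_kind not in ("isotropic", "anisotropic"):
            raise ValueError("tv_kind must be 'isotropic' or 'anisotropic'")
        # operator norm of the discrete gradient is bounded by sqrt(8)
        if self.tau * self.sigma * 8.0 > 1.0 + 1e-9:
            raise ValueError("step sizes violate the primal-dual convergence bound")


@dataclass
class GFParams:
    radius: int = 5
    eps: float = 1e-8
    n_guide: int = 1000

    def __post_init__(self) -> None:
        if self.radius < 1 or self.eps <= 0 or self.n_guide < 1:
            raise ValueError("invalid guided-filter parameters")


def _grad(u: np.ndarray) -> np.ndarray:
    """Forward differences with Neumann boundary; output (2, H, W)."""
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:, :-1] = u[:, 1:] - u[:, :-1]
    gy[:-1, :] = u[1:, :] - u[:-1, :]
    return np.stack([gx, gy])


def _div(q: np.ndarray) -> np.ndarray:
    """Negative adjoint of _grad (discrete divergence)."""
    qx, qy = q
    dx = np.zeros_like(qx)
    dy = np.zeros_like(qy)
    dx[:, 0] = qx[:, 0]
    dx[:, 1:-1] = qx[:, 1:-1] - qx[:, :-2]
    dx[:, -1] = -qx[:, -2]
    dy[0, :] = qy[0, :]
    dy[1:-1, :] = qy[1:-1, :] - qy[:-2, :]
    dy[-1, :] = -qy[-2, :]
    return dx + dy


def tv_objective(u: np.ndarray, f: np.ndarray, params: TVParams) -> float:
    """data-fidelity(u, f) + lam * TV(u) for the configured variants."""
    g = _grad(u)
    if params.tv_kind == "isotropic":
        tv = np.sqrt((g**2).sum(axis=0)).sum()
    else:
        tv = np.abs(g).sum()
    if params.data_term == "L2":
        fid = ((u - f) ** 2).sum()
    else:
        fid = np.abs(u - f).sum()
    return float(fid + params.lam * tv)


def tv_denoise(f: np.ndarray, params: TVParams) -> np.ndarray:
    """Primal-dual TV denoising with a fixed iteration count.

    The iteration budget is a parameter (default 18) rather than a
    convergence test; lam = 0 returns the input unchanged.
    """
    f = np.asarray(f, dtype=np.float64)
    if not np.all(np.isfinite(f)):
        raise ValueError("input image must be finite")
    if params.lam == 0 or params.n_iter == 0:
        return f.copy()
    u = f.copy()
    u_bar = f.copy()
    q = np.zeros((2,) + f.shape)
    tau, sigma, lam = params.tau, params.sigma, params.lam
    for _ in range(params.n_iter):
        q = q + sigma * _grad(u_bar)
        if params.tv_kind == "isotropic":
            mag = np.sqrt((q**2).sum(axis=0, keepdims=True))
            q = q / np.maximum(1.0, mag / lam)
        else:
            q = np.clip(q, -lam, lam)
        u_old = u
        v = u + tau * _div(q)
        if params.data_term == "L2":
            u = (v + 2.0 * tau * f) / (1.0 + 2.0 * tau)
        else:
            diff = v - f
            u = f + np.sign(diff) * np.maximum(np.abs(diff) - tau, 0.0)
        u_bar = 2.0 * u - u_old
    return u


def _box_sum(x: np.ndarray, radius: int) -> np.ndarray:
    """Sum over the truncated (2r+1)-square window centered at each pixel."""
    c = np.cumsum(x, axis=0)
    c = np.pad(c, ((1, 0), (0, 0)))
    h = x.shape[0]
    hi = np.minimum(np.arange(h) + radius + 1, h)
    lo = np.maximum(np.arange(h) - radius, 0)
    x = c[hi] - c[lo]
    c = np.cumsum(x, axis=1)
    c = np.pad(c, ((0, 0), (1, 0)))
    w = x.shape[1]
    hi = np.minimum(np.arange(w) + radius + 1, w)
    lo = np.maximum(np.arange(w) - radius, 0)
    return c[:, hi] - c[:, lo]


def guided_filter_once(p: np.ndarray, guide: np.ndarray, params: GFParams) -> np.ndarray:
    """One application of the guided filter q = mean(a)*I + mean(b).

    Per window: a_k = cov(I, p) / (var(I) + eps), b_k = mean(p) - a_k*mean(I);
    truncated border windows are normalized by their actual size.
    """
    if p.shape != guide.shape:
        raise ValueError("input and guidance images must share a shape")
    p = np.asarray(p, dtype=np.float64)
    guide = np.asarray(guide, dtype=np.float64)
    r = params.radius
    count = _box_sum(np.ones_like(p), r)
    mean_i = _box_sum(guide, r) / count
    mean_p = _box_sum(p, r) / count
    corr_ii = _box_sum(guide * guide, r) / count
    corr_ip = _box_sum(guide * p, r) / count
    var_i = corr_ii - mean_i**2
    cov_ip = corr_ip - mean_i * mean_p
    a = cov_ip / (var_i + params.eps)
    b = mean_p - a * mean_i
    mean_a = _box_sum(a, r) / count
    mean_b = _box_sum(b, r) / count
    return mean_a * guide + mean_b


def guided_filter(p: np.ndarray, guide: np.ndarray, params: GFParams) -> np.ndarray:
    """Guided filtering applied `n_guide` times with the guidance held fixed."""
    q = np.asarray(p, dtype=np.float64)
    for _ in range(params.n_guide):
        q = guided_filter_once(q, guide, params)
    return q


def build_guidance_image(
    prelog_bins: SpectralSinogram,
    air_scan: np.ndarray | SpectralSinogram,
    geometry: ScanGeometry,
    tv_params: TVParams | None = None,
    reconstructor: str = "fbp",
    output_size: int = 256,
    pixel_size_mm: float | None = None,
    rows: list[int] | None = None,
    sart_iters: int = 200,
) -> np.ndarray:
    """Virtual integrating-bin guidance image, one slice per detector row.

    Pre-log counts are summed over all energy bins (minimizing quantum
    uncertainty), air-corrected with the summed air scan, reconstructed, and
    TV-denoised.  For overlapping-bin data pass the lowest-threshold bin
    alone instead of a sum.
    """
    if prelog_bins.channel_kind != "counts-in-bins":
        raise ValueError("guidance image is built from counts-in-bins data")
    if tv_params is None:
        tv_params = TVParams()
    air = air_scan.data if isinstance(air_scan, SpectralSinogram) else np.asarray(air_scan)
    summed = prelog_bins.data.sum(axis=-1, keepdims=True)
    air_summed = np.broadcast_to(air, prelog_bins.data.shape).sum(axis=-1, keepdims=True)
    virtual = SpectralSinogram(
        data=summed,
        channel_kind="counts-in-bins",
        channel_edges=prelog_bins.channel_edges[[0, -1]],
        angles_deg=prelog_bins.angles_deg,
    )
    line = log_normalize(virtual, air_summed)
    if rows is None:
        rows = list(range(line.data.shape[1]))
    slices = []
    for r in rows:
        sino = line.data[:, r, :, 0]
        if reconstructor == "fbp":
            img = fbp_slice(sino, geometry, "ramp", output_size, pixel_size_mm)
        elif reconstructor == "sart":
            img = sart_slice(
                sino, geometry, n_iter=sart_iters, output_size=output_size,
                pixel_size_mm=pixel_size_mm,
            )
        else:
            raise ValueError(f"unknown reconstructor {reconstructor!r}")
        slices.append(tv_denoise(img, tv_params))
    return np.stack(slices)


def denoise_stack(
    bins: ReconVolume, guidance: np.ndarray, tv: TVParams, gf: GFParams
) -> ReconVolume:
    """Per bin and slice: TV denoising, then guided filtering with the shared
    virtual-integrating-bin guidance image."""
    guidance = np.asarray(guidance)
    if guidance.ndim == 2:
        guidance = guidance[None]
    if guidance.shape[0] != bins.data.shape[1] or guidance.shape[1:] != bins.data.shape[2:]:
        raise ValueError("guidance image is not aligned with the bin images")
    out = np.empty_like(bins.data)
    for b in range(bins.data.shape[0]):
        for s in range(bins.data.shape[1]):
            smoothed = tv_denoise(bins.data[b, s], tv)
            out[b, s] = guided_filter(smoothed, guidance[s], gf)
    return ReconVolume(data=out, voxel_size_mm=bins.voxel_size_mm, bin_edges=bins.bin_edges)


@dataclass
class BasisSet:
    """Basis materials with effective mu (cm^-1) per energy bin."""

    names: list[str]
    matrix: np.ndarray = field(repr=False)  # (n_bins, n_basis)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("basis matrix must have full column rank")


def basis_from_materials(materials: list[MaterialSpec], bin_edges: np.ndarray) -> BasisSet:
    """Evaluate each basis material's mu at the bin-center energies."""
    edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    matrix = np.stack([material_attenuation(m, centers) for m in materials], axis=1)
    return BasisSet(names=[m.name for m in materials], matrix=matrix)


def material_decompose(bins: ReconVolume, basis: BasisSet, nonneg: bool = False) -> np.ndarray:
    """Per-voxel least squares of the bin-wise mu vector onto the basis.

    Returns weight maps shaped (n_basis, slice, y, x); `nonneg` switches to a
    nonnegative solve per voxel.
    """
    n_bins = bins.data.shape[0]
    if n_bins < basis.matrix.shape[1]:
        raise ValueError("need at least as many bins as basis materials")
    vectors = bins.data.reshape(n_bins, -1)
    if nonneg:
        coeffs = np.stack([nnls(basis.matrix, v)[0] for v in vectors.T], axis=1)
    else:
        coeffs, *_ = np.linalg.lstsq(basis.matrix, vectors, rcond=None)
    return coeffs.reshape((basis.matrix.shape[1],) + bins.data.shape[1:])
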