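"""Per-bin tomographic reconstruction: air-corrected log transform, filtered
backprojection and SART, parallel-beam only."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, ScanGeometry
from .projector import _ray_samples
from .sinogram import SpectralSinogram


@dataclass
class ReconVolume:
    """Per-energy-bin image stack [bin, slice, y, x] in cm^-1."""

    data: np.ndarray
    voxel_size_mm: float
    bin_edges: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("ReconVolume data must be 4-D (bin, slice, y, x)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reconstruction contains non-finite values")


def log_normalize(
    counts: SpectralSinogram, air_scan: np.ndarray | SpectralSinogram, floor: float = 0.5
) -> SpectralSinogram:
    """Line integrals p = -ln(max(counts, floor) / air) per pixel and bin.

    `air_scan` may be a full sinogram or any array broadcastable against the
    counts (e.g. one air value per (row, column, bin)).  Zero counts are
    clamped at the configurable positive `floor`.
    """
    air = air_scan.data if isinstance(air_scan, SpectralSinogram) else np.asarray(air_scan)
    if np.any(air <= 0):
        raise ValueError("air scan must be strictly positive")
    if floor <= 0:
        raise ValueError("count floor must be positive")
    p = -np.log(np.maximum(counts.data, floor) / air)
    out = counts.with_data(np.clip(p, 0.0, None))
    return out


def _ramp_filter(size: int, filter_name: str) -> np.ndarray:
    """Fourier-domain ramp (optionally Hann-apodized) from the band-limited
    spatial-domain impulse response."""
    n = np.concatenate(
        [np.arange(1, size / 2 + 1, 2, dtype=int), np.arange(size / 2 - 1, 0, -2, dtype=int)]
    )
    f = np.zeros(size)
    f[0] = 0.25
    f[1::2] = -1.0 / (np.pi * n) ** 2
    fourier = 2.0 * np.real(np.fft.fft(f))
    if filter_name == "hann":
        fourier *= np.fft.fftshift(np.hanning(size + 1)[:-1])
    elif filter_name != "ramp":
        raise ValueError(f"unknown FBP filter {filter_name!r}")
    return fourier


def fbp_slice(
    sino: np.ndarray,
    geometry: ScanGeometry,
    filter_name: str = "ramp",
    output_size: int = 256,
    pixel_size_mm: float | None = None,
) -> np.ndarray:
    """Filtered backprojection of one (n_angles, n_det) line-integral slice.

    Returns a (output_size, output_size) image in cm^-1 (line integrals are
    dimensionless, so the detector spacing converts per-sample attenuation to
    per-cm).
    """
    angles = geometry.angles_deg
    steps = np.diff(angles)
    if steps.size and not np.allclose(steps, steps[0]):
        raise GeometryError("FBP requires uniform angles over 180 degrees")
    if pixel_size_mm is None:
        pixel_size_mm = geometry.det_spacing_mm
    n_det = sino.shape[1]
    size = max(64, int(2 ** np.ceil(np.log2(2 * n_det))))
    fourier = _ramp_filter(size, filter_name)
    padded = np.zeros((sino.shape[0], size))
    padded[:, :n_det] = sino
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * fourier, axis=1))[:, :n_det]

    coords = (np.arange(output_size) + 0.5 - output_size / 2.0) * pixel_size_mm
    xx, yy = np.meshgrid(coords, coords)
    out = np.zeros((output_size, output_size))
    u_axis = np.arange(n_det, dtype=float)
    for a, angle in enumerate(angles):
        theta = np.deg2rad(angle)
        t = xx * np.cos(theta) + yy * np.sin(theta)
        u = t / geometry.det_spacing_mm + n_det / 2.0 - 0.5
        out += np.interp(u, u_axis, filtered[a], left=0.0, right=0.0)
    out *= np.pi / (2.0 * len(angles))
    return out / (geometry.det_spacing_mm / 10.0)


def fbp_parallel(
    line_integrals: SpectralSinogram,
    geometry: ScanGeometry,
    filter_name: str = "ramp",
    output_size: int = 256,
    pixel_size_mm: float | None = None,
    rows: list[int] | None = None,
) -> ReconVolume:
    """Per-bin, per-row FBP of a 4-D line-integral sinogram."""
    data = line_integrals.data
    if rows is None:
        rows = list(range(data.shape[1]))
    n_bins = data.shape[-1]
    stack = np.empty((n_bins, len(rows), output_size, output_size), dtype=np.float32)
    for b in range(n_bins):
        for i, r in enumerate(rows):
            stack[b, i] = fbp_slice(
                data[:, r, :, b], geometry, filter_name, output_size, pixel_size_mm
            )
    edges = line_integrals.channel_edges
    if line_integrals.channel_kind != "counts-in-bins":
        edges = np.concatenate([edges, [edges[-1]]])
    return ReconVolume(
        data=stack,
        voxel_size_mm=pixel_size_mm or geometry.det_spacing_mm,
        bin_edges=edges,
    )


class _SliceOperator:
    """Matched forward/backprojection pair for one in-plane recon grid."""

    def __init__(self, geometry: ScanGeometry, grid_size: int, pixel_size_mm: float):
        self.geometry = geometry
        self.n = grid_size
        self.pixel_mm = pixel_size_mm
        self._views = []
        for angle in geometry.angles_deg:
            corners, n_steps, step_cm = _ray_samples(geometry, grid_size, pixel_size_mm, angle)
            self._views.append((corners, n_steps, step_cm))

    def forward_view(self, image_flat: np.ndarray, view: int) -> np.ndarray:
        corners, n_steps, step_cm = self._views[view]
        acc = np.zeros(self.geometry.n_det * n_steps)
        for idx, weight in corners:
            acc += image_flat[idx] * weight
        return acc.reshape(self.geometry.n_det, n_steps).sum(axis=1) * step_cm

    def back_view(self, proj: np.ndarray, view: int) -> np.ndarray:
        corners, n_steps, step_cm = self._views[view]
        spread = np.repeat(proj, n_steps) * step_cm
        out = np.zeros(self.n * self.n)
        for idx, weight in corners:
            np.add.at(out, idx, spread * weight)
        return out

    def forward(self, image: np.ndarray) -> np.ndarray:
        flat = image.ravel()
        return np.stack([self.forward_view(flat, v) for v in range(self.geometry.n_angles)])


def sart_slice(
    sino: np.ndarray,
    geometry: ScanGeometry,
    n_iter: int = 200,
    relaxation: float = 0.25,
    init: np.ndarray | None = None,
    output_size: int = 256,
    pixel_size_mm: float | None = None,
    return_history: bool = False,
):
    """Simultaneous algebraic reconstruction of one slice.

    Sequential per-view updates with deterministic ordering; relaxation is
    clamped into (0, 2) with a warning if outside.
    """
    if not 0 < relaxation < 2:
        warnings.warn("SART relaxation clamped into (0, 2)", stacklevel=2)
        relaxation = min(max(relaxation, 1e-3), 2 - 1e-3)
    if pixel_size_mm is None:
        pixel_size_mm = geometry.det_spacing_mm
    op = _SliceOperator(geometry, output_size, pixel_size_mm)
    x = np.zeros(output_size * output_size) if init is None else init.ravel().astype(float).copy()
    eps = 1e-12
    rows = [op.forward_view(np.ones_like(x), v) for v in range(geometry.n_angles)]
    cols = [op.back_view(np.ones(geometry.n_det), v) for v in range(geometry.n_angles)]
    history = []
    for _ in range(n_iter):
        for v in range(geometry.n_angles):
            residual = sino[v] - op.forward_view(x, v)
            update = op.back_view(residual / (rows[v] + eps), v)
            x += relaxation * update / (cols[v] + eps)
        if return_history:
            history.append(x.reshape(output_size, output_size).copy())
    image = x.reshape(output_size, output_size)
    return (image, history) if return_history else image


def sart(
    line_integrals: SpectralSinogram,
    geometry: ScanGeometry,
    n_iter: int = 200,
    relaxation: float = 0.25,
    output_size: int = 256,
    pixel_size_mm: float | None = None,
    rows: list[int] | None = None,
) -> ReconVolume:
    """Per-bin, per-row SART of a 4-D line-integral sinogram."""
    data = line_integrals.data
    if rows is None:
        rows = list(range(data.shape[1]))
    n_bins = data.shape[-1]
    stack = np.empty((n_bins, len(rows), output_size, output_size), dtype=np.float32)
    for b in range(n_bins):
        for i, r in enumerate(rows):
            stack[b, i] = sart_slice(
                data[:, r, :, b], geometry, n_iter, relaxation,
                output_size=output_size, pixel_size_mm=pixel_size_mm,
            )
    edges = line_integrals.channel_edges
    if line_integrals.channel_kind != "counts-in-bins":
        edges = np.concatenate([edges, [edges[-1]]])
    return ReconVolume(
        data=stack,
        voxel_size_mm=pixel_size_mm or geometry.det_spacing_mm,
        bin_edges=edges,
    )
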