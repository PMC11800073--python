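"""Quantitative evaluation: RMSE, PSNR, SSIM, noise power spectrum, one-way
ANOVA.  RMSE is the projection-domain figure of merit; PSNR and SSIM are used
on reconstructed images."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity


@dataclass
class MetricReport:
    rmse: float
    psnr: float
    ssim: float
    data_range: float
    per_bin: list[dict] = field(default_factory=list)


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    if data_range <= 0:
        raise ValueError("data range must be positive")
    mse = np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)
    if mse == 0:
        return float("inf")
    return float(20 * np.log10(data_range) - 10 * np.log10(mse))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """SSIM with the standard Gaussian window (sigma 1.5) and K1/K2 constants."""
    return float(
        structural_similarity(
            np.asarray(a, float), np.asarray(b, float),
            data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
    )


def image_metrics(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> MetricReport:
    """RMSE/PSNR/SSIM of `a` against the reference `b`.

    The data range defaults to the reference image's dynamic range and is
    recorded in the report.  For stacks (bin, ...) a per-bin breakdown is
    included and the scalars are means over bins.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        data_range = float(b.max() - b.min())
        if data_range == 0:
            data_range = 1.0
    if a.ndim > 2:
        # stacks: leading axis is the energy bin, images are the last 2 axes
        flat_a = a.reshape((a.shape[0], -1) + a.shape[-2:])
        flat_b = b.reshape((b.shape[0], -1) + b.shape[-2:])
        per_bin = [
            {
                "rmse": rmse(x, y),
                "psnr": psnr(x, y, data_range),
                "ssim": float(np.mean([ssim(xi, yi, data_range) for xi, yi in zip(x, y)])),
            }
            for x, y in zip(flat_a, flat_b)
        ]
        return MetricReport(
            rmse=float(np.mean([m["rmse"] for m in per_bin])),
            psnr=float(np.mean([m["psnr"] for m in per_bin])),
            ssim=float(np.mean([m["ssim"] for m in per_bin])),
            data_range=data_range,
            per_bin=per_bin,
        )
    return MetricReport(
        rmse=rmse(a, b), psnr=psnr(a, b, data_range), ssim=ssim(a, b, data_range),
        data_range=data_range,
    )


def noise_power_spectrum(
    noise: np.ndarray,
    pixel_size_mm: float,
    roi: tuple[slice, slice] | None = None,
    n_radial_bins: int | None = None,
):
    """2-D NPS of a noise (or difference) image plus its radial average.

    The ROI is mean-detrended; NPS = |DFT|^2 * (pixel area) / N_pix, so the
    NPS integrated over frequency equals the ROI noise variance (Parseval).
    Returns (nps_2d, radial_freq_cyc_per_mm, radial_profile).
    """
    img = np.asarray(noise, float)
    if roi is not None:
        img = img[roi]
    img = img - img.mean()
    ny, nx = img.shape
    spectrum = np.fft.fftshift(np.fft.fft2(img))
    nps = (np.abs(spectrum) ** 2) * (pixel_size_mm**2) / (nx * ny)
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_size_mm))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=pixel_size_mm))
    fr = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    nyquist = 0.5 / pixel_size_mm
    # coarse annuli average over many frequency-grid rings per bin
    n_bins = n_radial_bins or max(8, min(nx, ny) // 16)
    edges = np.linspace(0.0, nyquist, n_bins + 1)
    which = np.clip(np.digitize(fr.ravel(), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=nps.ravel(), minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    radial = sums / np.maximum(counts, 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return nps, centers, radial


def anova_one_way(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    Degenerate input (zero variance everywhere with equal means) returns the
    (F=0, p=1) sentinel instead of propagating a 0/0.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 groups with at least 2 values each")
    concat = np.concatenate(arrays)
    if np.ptp(concat) == 0:
        return 0.0, 1.0
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within == 0:
        return float("inf"), 0.0
    f_stat, p_val = stats.f_oneway(*arrays)
    return float(f_stat), float(p_val)
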