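"""Photon-counting detector distortions.

The chain is fixed as: charge splitting (spectral response + pixel
cross-talk) -> Poisson noise -> paralyzable pulse pileup -> threshold
binning.  The spectral response is a parametric four-branch model on the
fine keV grid: free penetration (photon lost), full detection at the
incident energy, partial detection with K-fluorescence escape (recorded at
E_in - E_fluor), and full detection with fluorescence reabsorbed (recorded
at E_in).  Each detected branch is blurred by a Gaussian energy resolution.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.signal import fftconvolve

from .sinogram import SpectralSinogram


class DetectorConfigError(ValueError):
    pass


@dataclass
class ThresholdSet:
    """Sorted pulse-height comparator levels in keV (default 20,30,...,110)."""

    thresholds: np.ndarray = None

    def __post_init__(self) -> None:
        if self.thresholds is None:
            self.thresholds = np.arange(20.0, 111.0, 10.0)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.size < 2:
            raise DetectorConfigError("need at least 2 thresholds")
        if not np.all(np.diff(self.thresholds) > 0):
            raise DetectorConfigError("thresholds must be strictly increasing")


@dataclass
class DetectorModel:
    """Charge-splitting response, cross-talk, dead time and exposure.

    `response[E_rec, E_in]` gives recording probabilities on the fine grid;
    column sums are <= 1 because photons may go undetected.  Default dead
    time gives n*tau ~= 0.05 at 400k counts/pixel/view over a 1 ms exposure.
    """

    energy_grid: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)
    crosstalk_fraction: float = 0.1
    dead_time_s: float = 1.25e-10
    exposure_s: float = 1.0e-3

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n = self.energy_grid.size
        if self.response.shape != (n, n):
            raise DetectorConfigError("response must be square on the energy grid")
        if np.any(self.response < 0) or np.any(self.response.sum(axis=0) > 1 + 1e-9):
            raise DetectorConfigError("response columns must be probabilities summing to <= 1")
        if not 0 <= self.crosstalk_fraction < 1:
            raise DetectorConfigError("crosstalk fraction must be in [0, 1)")
        if self.dead_time_s < 0:
            raise DetectorConfigError("dead time must be nonnegative")


def default_detector_constants() -> dict:
    resource = importlib.resources.files("pcct.data") / "detector_constants.yaml"
    return yaml.safe_load(resource.read_text())


def default_branch_probabilities(energy_grid: np.ndarray, constants: dict | None = None):
    """(p_penetration, p_full, p_fluor_lost, p_fluor_reabsorbed) per E_in.

    Fluorescence branches only open above the Cd K-edge; probabilities sum
    to 1 at every incident energy.
    """
    c = (constants or default_detector_constants())
    bp = c["branch_probabilities"]
    e = np.asarray(energy_grid, dtype=float)
    frac = np.clip((e - bp["penetration_e0_kev"]) / bp["penetration_span_kev"], 0.0, 1.0)
    p_pen = np.clip(bp["penetration_base"] + bp["penetration_gain"] * frac**2, 0.0, 0.95)
    above_edge = e >= c["k_edges"]["cd_kev"]
    p_lost = np.where(above_edge, bp["fluorescence_lost"], 0.0) * (1 - p_pen)
    p_reab = np.where(above_edge, bp["fluorescence_reabsorbed"], 0.0) * (1 - p_pen)
    p_full = 1.0 - p_pen - p_lost - p_reab
    return p_pen, p_full, p_lost, p_reab


def _gaussian_column(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    if sigma <= 0:
        col = np.zeros_like(grid)
        idx = int(np.argmin(np.abs(grid - center)))
        if abs(grid[idx] - center) <= (grid[1] - grid[0]) / 2 + 1e-9:
            col[idx] = 1.0
        return col
    col = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    total = col.sum()
    return col / total if total > 0 else col


def build_charge_splitting_response(
    energy_grid: np.ndarray,
    branch_probabilities=None,
    fluorescence_kev: float | None = None,
    energy_blur_sigma_kev: float | None = None,
) -> np.ndarray:
    """Assemble the four-branch response matrix R[E_rec, E_in].

    Detected mass for incident energy E_in lands at E_in (full detection and
    reabsorption) and at E_in - E_fluor (fluorescence escape), each smeared
    by the energy resolution; column sums equal 1 - P(penetration).
    """
    grid = np.asarray(energy_grid, dtype=float)
    constants = default_detector_constants()
    if branch_probabilities is None:
        branch_probabilities = default_branch_probabilities(grid, constants)
    p_pen, p_full, p_lost, p_reab = (np.broadcast_to(p, grid.shape) for p in branch_probabilities)
    sums = p_pen + p_full + p_lost + p_reab
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise DetectorConfigError("branch probabilities must sum to 1 at every energy")
    if fluorescence_kev is None:
        fl = constants["fluorescence"]
        fluorescence_kev = 0.5 * (fl["cd_k_alpha_kev"] + fl["te_k_alpha_kev"])
    if energy_blur_sigma_kev is None:
        energy_blur_sigma_kev = constants["energy_blur_sigma_kev"]

    n = grid.size
    response = np.zeros((n, n))
    for j, e_in in enumerate(grid):
        col = (p_full[j] + p_reab[j]) * _gaussian_column(grid, e_in, energy_blur_sigma_kev)
        if p_lost[j] > 0:
            shifted = e_in - fluorescence_kev
            if shifted >= grid[0]:
                col = col + p_lost[j] * _gaussian_column(grid, shifted, energy_blur_sigma_kev)
            # escape events falling below the grid floor are unrecorded
        response[:, j] = col
    return response


def default_detector_model(energy_grid: np.ndarray, **overrides) -> DetectorModel:
    response = build_charge_splitting_response(energy_grid)
    return DetectorModel(energy_grid=np.asarray(energy_grid, float), response=response, **overrides)


def apply_charge_splitting(ideal: SpectralSinogram, model: DetectorModel) -> SpectralSinogram:
    """Recorded expected spectrum R @ incident, then 4-neighbor cross-talk.

    A `crosstalk_fraction` share of each pixel's recorded counts is
    redistributed equally to its 4 neighbors in the (row, column) plane;
    shares that would leave the detector stay in place so the global count
    total is conserved.
    """
    if ideal.channel_kind != "fine-keV":
        raise ValueError("charge splitting operates on fine-keV sinograms")
    if ideal.n_channels != model.energy_grid.size:
        raise ValueError("sinogram channel grid does not match the response matrix")
    recorded = np.einsum("ij,arcj->arci", model.response, ideal.data.astype(np.float64))
    f = model.crosstalk_fraction
    if f > 0:
        share = recorded * (f / 4.0)
        out = recorded - 4.0 * share
        for axis, shift in ((1, 1), (1, -1), (2, 1), (2, -1)):
            moved = np.roll(share, shift, axis=axis)
            # undo wrap-around: mass that would leave the edge stays in place
            if axis == 1:
                edge = 0 if shift == 1 else -1
                moved[:, edge] = 0.0
                kept = np.zeros_like(share)
                kept[:, edge] = share[:, edge]
            else:
                edge = 0 if shift == 1 else -1
                moved[:, :, edge] = 0.0
                kept = np.zeros_like(share)
                kept[:, :, edge] = share[:, :, edge]
            out += moved + kept
        recorded = out
    return SpectralSinogram(
        data=recorded,
        channel_kind="fine-keV",
        channel_edges=ideal.channel_edges.copy(),
        angles_deg=ideal.angles_deg,
    )


def add_poisson_noise(expected: SpectralSinogram, seed: int) -> SpectralSinogram:
    """Independent Poisson draw per (pixel, channel); reproducible per seed."""
    if np.any(expected.data < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(expected.data.astype(np.float64)).astype(np.float64)
    return expected.with_data(noisy)


def pileup_event_mc(
    channel_counts: np.ndarray,
    energy_grid: np.ndarray,
    dead_time_s: float,
    exposure_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Event-level paralyzable pileup for a single pixel.

    Arrival times are uniform over the exposure; an event is registered only
    if it follows its predecessor by more than the dead time.  Closer events
    merge into the preceding cluster and contribute their energy with an
    exponential tail weight exp(-dt/tau) measured from the cluster start
    (a bipolar-pulse surrogate).  Returns recorded counts per fine channel.
    """
    counts = np.asarray(channel_counts)
    n_events = int(counts.sum())
    out = np.zeros_like(counts, dtype=np.float64)
    if n_events == 0:
        return out
    energies = np.repeat(energy_grid, counts.astype(np.int64))
    rng.shuffle(energies)
    times = np.sort(rng.uniform(0.0, exposure_s, size=n_events))
    if dead_time_s == 0:
        recorded = energies
    else:
        gaps = np.diff(times, prepend=-np.inf)
        is_first = gaps > dead_time_s
        is_first[0] = True
        cluster = np.cumsum(is_first) - 1
        start_times = times[is_first][cluster]
        weights = np.where(is_first, 1.0, np.exp(-(times - start_times) / dead_time_s))
        recorded = np.zeros(cluster[-1] + 1)
        np.add.at(recorded, cluster, weights * energies)
    step = energy_grid[1] - energy_grid[0]
    idx = np.clip(
        np.round((recorded - energy_grid[0]) / step).astype(np.int64), 0, energy_grid.size - 1
    )
    np.add.at(out, idx, 1.0)
    return out


def _pileup_analytic(data: np.ndarray, tau: float, exposure: float) -> np.ndarray:
    """First-order recorded-rate law applied pixel-wise with a doublet shift.

    Total recorded counts follow m = n*exp(-n*tau); the fraction
    alpha = 1 - exp(-n*tau) of recorded pulses are treated as energy-summed
    doublets whose spectrum is the self-convolution of the pixel's spectral
    density (overflow folded into the top channel).
    """
    shape = data.shape
    flat = data.reshape(-1, shape[-1]).astype(np.float64)
    totals = flat.sum(axis=1)
    rate = totals / exposure
    survival = np.exp(-rate * tau)
    safe_totals = np.where(totals > 0, totals, 1.0)
    pmf = flat / safe_totals[:, None]
    conv = fftconvolve(pmf, pmf, axes=1)[:, : 2 * shape[-1] - 1]
    folded = conv[:, : shape[-1]].copy()
    folded[:, -1] += conv[:, shape[-1]:].sum(axis=1)
    alpha = (1.0 - survival)[:, None]
    shape_rec = (1.0 - alpha) * pmf + alpha * folded
    recorded = shape_rec * (totals * survival)[:, None]
    return np.clip(recorded, 0.0, None).reshape(shape)


def apply_pulse_pileup(
    counts: SpectralSinogram,
    model: DetectorModel,
    mode: str = "analytic",
    seed: int | None = None,
) -> SpectralSinogram:
    """Paralyzable pulse pileup on a fine-keV sinogram.

    ``event_mc`` simulates per-pixel arrival times (exact but slow; intended
    for small studies); ``analytic`` applies the recorded-rate law
    m = n*exp(-n*tau) with a doublet spectrum-shift kernel.
    """
    if counts.channel_kind != "fine-keV":
        raise ValueError("pulse pileup operates on fine-keV sinograms")
    if model.dead_time_s < 0:
        raise ValueError("dead time must be nonnegative")
    if model.dead_time_s == 0:
        return counts.with_data(counts.data.copy())
    if mode == "analytic":
        out = _pileup_analytic(counts.data, model.dead_time_s, model.exposure_s)
    elif mode == "event_mc":
        rng = np.random.default_rng(seed)
        flat = counts.data.reshape(-1, counts.n_channels)
        out = np.stack(
            [
                pileup_event_mc(
                    pix, counts.channel_edges, model.dead_time_s, model.exposure_s, rng
                )
                for pix in flat
            ]
        ).reshape(counts.data.shape)
    else:
        raise ValueError(f"unknown pileup mode {mode!r}")
    return counts.with_data(out)


def counts_in_bins(spectrum: SpectralSinogram, thresholds: ThresholdSet) -> SpectralSinogram:
    """Threshold the recorded spectrum and difference adjacent levels.

    CAT_k = counts with recorded energy >= T_k; bin_j = CAT_j - CAT_{j+1}.
    K thresholds produce K-1 bins whose edges are the thresholds themselves.
    """
    t = thresholds.thresholds
    if spectrum.channel_kind == "fine-keV":
        grid = spectrum.channel_edges
        if t[0] < grid[0] or t[-1] > grid[-1] + (grid[1] - grid[0]):
            raise DetectorConfigError("thresholds outside the channel energy range")
        cat = np.stack(
            [spectrum.data[..., grid >= level].sum(axis=-1) for level in t], axis=-1
        )
    elif spectrum.channel_kind == "counts-above-threshold":
        if spectrum.n_channels != t.size or not np.allclose(spectrum.channel_edges, t):
            raise DetectorConfigError("counts-above-threshold channels do not match thresholds")
        cat = spectrum.data
    else:
        raise ValueError("input must be fine-keV or counts-above-threshold")
    bins = cat[..., :-1] - cat[..., 1:]
    return SpectralSinogram(
        data=np.clip(bins, 0.0, None),
        channel_kind="counts-in-bins",
        channel_edges=t,
        angles_deg=spectrum.angles_deg,
    )
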