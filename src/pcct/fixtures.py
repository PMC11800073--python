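"""End-to-end simulated datasets: paired distorted/ideal spectral sinograms.

The forward chain mirrors the physics order: ideal expected spectral counts
from the projector, charge-splitting response + cross-talk, Poisson noise,
paralyzable pulse pileup, then threshold binning.  The ideal companion is
the noise-free expected counts binned directly.  Processing is per angle to
bound memory at full problem sizes.
"""
from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np

from .detector import (
    DetectorModel,
    ThresholdSet,
    add_poisson_noise,
    apply_charge_splitting,
    apply_pulse_pileup,
    counts_in_bins,
    default_detector_model,
)
from .geometry import ScanGeometry, fixture_geometry
from .phantom import PhantomConfig, SpectralPhantom, generate_phantom
from .projector import material_path_lengths, spectral_line_integrals
from .sinogram import SpectralSinogram
from .spectrum import SourceSpectrum, packaged_spectrum

#: fixture scales: (grid size, n angles, thresholds)
FIXTURE_SCALES = {
    "tiny": (32, 30, np.array([20.0, 50.0, 80.0, 110.0])),
    "small": (64, 60, np.arange(20.0, 111.0, 10.0)),
}


@dataclass
class SimulatedDataset:
    phantom: SpectralPhantom
    geometry: ScanGeometry
    spectrum: SourceSpectrum
    detector: DetectorModel
    thresholds: ThresholdSet
    distorted: SpectralSinogram  # counts-in-bins, with all distortions
    ideal: SpectralSinogram  # counts-in-bins, noise-free expected counts
    air_distorted: np.ndarray  # (rows, cols, bins) expected air counts, distorted chain
    air_ideal: np.ndarray  # (rows, cols, bins) expected air counts, ideal chain
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _angle_seeds(seed: int, n_angles: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n_angles)]


def simulate_paired_sinograms(
    phantom: SpectralPhantom,
    geometry: ScanGeometry,
    spectrum: SourceSpectrum,
    detector: DetectorModel,
    thresholds: ThresholdSet,
    seed: int,
    pileup_mode: str = "analytic",
) -> SimulatedDataset:
    """Run the full forward chain and return aligned distorted/ideal data."""
    geometry.check_covers(phantom.grid_size, phantom.voxel_size_mm)
    paths = material_path_lengths(phantom, geometry)  # (K, A, R, C)
    n_rows = paths.shape[2]
    seeds = _angle_seeds(seed, geometry.n_angles)

    distorted_bins = []
    ideal_bins = []
    for a in range(geometry.n_angles):
        line = spectral_line_integrals(paths[:, a : a + 1], phantom, spectrum.energy_grid)
        lam = spectrum.expected_counts() * np.exp(-line)  # (1, R, C, E)
        fine = SpectralSinogram(
            data=lam, channel_kind="fine-keV", channel_edges=spectrum.energy_grid
        )
        ideal_bins.append(counts_in_bins(fine, thresholds).data[0])
        split = apply_charge_splitting(fine, detector)
        noisy = add_poisson_noise(split, seeds[a])
        piled = apply_pulse_pileup(noisy, detector, mode=pileup_mode, seed=seeds[a])
        distorted_bins.append(counts_in_bins(piled, thresholds).data[0])

    def as_sino(stack):
        return SpectralSinogram(
            data=np.stack(stack).astype(np.float32),
            channel_kind="counts-in-bins",
            channel_edges=thresholds.thresholds,
            angles_deg=geometry.angles_deg,
        )

    # noise-free air calibration scans through both chains
    air_fine = np.broadcast_to(
        spectrum.expected_counts(), (1, n_rows, geometry.n_det, spectrum.n_channels)
    ).copy()
    air_sino = SpectralSinogram(
        data=air_fine, channel_kind="fine-keV", channel_edges=spectrum.energy_grid
    )
    air_ideal = counts_in_bins(air_sino, thresholds).data[0]
    air_split = apply_charge_splitting(air_sino, detector)
    air_piled = apply_pulse_pileup(air_split, detector, mode="analytic")
    air_distorted = counts_in_bins(air_piled, thresholds).data[0]

    return SimulatedDataset(
        phantom=phantom,
        geometry=geometry,
        spectrum=spectrum,
        detector=detector,
        thresholds=thresholds,
        distorted=as_sino(distorted_bins),
        ideal=as_sino(ideal_bins),
        air_distorted=air_distorted,
        air_ideal=air_ideal,
        seed=seed,
    )


def make_fixture(
    scale: str = "tiny",
    seed: int = 0,
    out_dir=None,
    incident_counts: float = 400_000.0,
) -> SimulatedDataset:
    """Scaled paired dataset: 'tiny' (32^3, 30 views, 3 bins) or 'small'
    (64^3, 60 views, 9 bins); deterministic per seed.

    If `out_dir` is given the phantom, sinograms and air scans are written
    there as HDF5.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"unknown fixture scale {scale!r}")
    grid, n_angles, thresholds = FIXTURE_SCALES[scale]
    voxel = 0.11
    config = PhantomConfig(
        grid_size=grid,
        voxel_size_mm=voxel,
        sphere_radius_mm=12.8 * grid / 256.0,
    )
    phantom = generate_phantom(config, seed)
    geometry = fixture_geometry(grid, voxel, n_angles)
    spectrum = packaged_spectrum(incident_counts)
    detector = default_detector_model(spectrum.energy_grid)
    dataset = simulate_paired_sinograms(
        phantom, geometry, spectrum, detector,
        ThresholdSet(thresholds), seed,
    )
    if out_dir is not None:
        from . import fileio

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fileio.write_phantom(phantom, out / "phantom.h5")
        fileio.write_sinogram(dataset.distorted, out / "distorted.h5")
        fileio.write_sinogram(dataset.ideal, out / "ideal.h5")
        fileio.write_volume(dataset.air_distorted, out / "air_distorted.npy")
        fileio.write_volume(dataset.air_ideal, out / "air_ideal.npy")
    return dataset
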