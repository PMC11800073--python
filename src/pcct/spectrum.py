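"""Polychromatic source spectra on a uniform 1 keV grid."""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np


class SpectrumFormatError(ValueError):
    pass


@dataclass
class SourceSpectrum:
    """Relative photon fluence per keV plus the expected photons per pixel per view."""

    energy_grid: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    incident_counts_per_pixel: float = 400_000.0

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.shape != w.shape or e.ndim != 1:
            raise SpectrumFormatError("grid and weights must be matching 1-D arrays")
        if e.size > 1:
            steps = np.diff(e)
            if not np.allclose(steps, steps[0]) or steps[0] <= 0:
                raise SpectrumFormatError("energy grid must be uniform and increasing")
        if np.any(w < 0):
            raise SpectrumFormatError("spectrum weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise SpectrumFormatError("spectrum carries no fluence")
        self.energy_grid = e
        self.weights = w / total

    @property
    def n_channels(self) -> int:
        return self.energy_grid.size

    def expected_counts(self) -> np.ndarray:
        """Unattenuated expected counts per fine channel for one pixel/view."""
        return self.incident_counts_per_pixel * self.weights


def load_spectrum(path_or_text, incident_counts: float = 400_000.0) -> SourceSpectrum:
    """Parse a two-column (keV, relative fluence) text table.

    Weights are normalized to sum to 1; the incident photon budget is stored
    separately.  Normalizing an already normalized table is a no-op.
    """
    try:
        text = path_or_text.read_text()
    except AttributeError:
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            text = str(path_or_text)
    energies, weights = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        energies.append(float(cols[0]))
        weights.append(float(cols[1]))
    if not energies:
        raise SpectrumFormatError("no data rows in spectrum table")
    return SourceSpectrum(
        energy_grid=np.array(energies),
        weights=np.array(weights),
        incident_counts_per_pixel=incident_counts,
    )


def packaged_spectrum(incident_counts: float = 400_000.0) -> SourceSpectrum:
    """The packaged synthetic 120 kVp spectrum (12-120 keV, 1 keV steps)."""
    resource = importlib.resources.files("pcct.data") / "spectrum_120kvp_synthetic.txt"
    return load_spectrum(resource, incident_counts=incident_counts)
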