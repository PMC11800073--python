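"""Spectral sinogram container.

Counts are indexed as (angle, detector row, detector column, energy channel).
`channel_kind` records the channel semantics:

- ``fine-keV``: one channel per fine energy-grid point (channel_edges holds
  the grid centers);
- ``counts-above-threshold``: cumulative counts exceeding each threshold
  (channel_edges holds the thresholds, one per channel);
- ``counts-in-bins``: per-interval counts (channel_edges holds n+1 bin edges).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNEL_KINDS = ("fine-keV", "counts-above-threshold", "counts-in-bins")


@dataclass
class SpectralSinogram:
    data: np.ndarray
    channel_kind: str
    channel_edges: np.ndarray = field(repr=False)
    angles_deg: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_edges = np.asarray(self.channel_edges, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("sinogram data must be 4-D (angle, row, column, channel)")
        if np.any(self.data < 0):
            raise ValueError("sinogram counts must be nonnegative")
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.channel_kind!r}")
        n = self.data.shape[-1]
        expected = n + 1 if self.channel_kind == "counts-in-bins" else n
        if self.channel_edges.size != expected:
            raise ValueError(
                f"channel_edges must have {expected} entries for kind "
                f"{self.channel_kind!r} with {n} channels"
            )

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1]

    def with_data(self, data: np.ndarray) -> "SpectralSinogram":
        return SpectralSinogram(
            data=data,
            channel_kind=self.channel_kind,
            channel_edges=self.channel_edges.copy(),
            angles_deg=None if self.angles_deg is None else self.angles_deg.copy(),
        )
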