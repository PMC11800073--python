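"""Parallel-beam scan geometry."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    pass


@dataclass
class ScanGeometry:
    """Parallel-beam geometry: uniform angles over 180 degrees.

    Detector rows map one-to-one onto phantom z-slices; columns sample the
    in-plane detector axis at `det_spacing_mm`.
    """

    n_angles: int = 180
    n_det: int = 367
    det_spacing_mm: float = 0.11
    n_rows: int = 256
    mode: str = "parallel"

    angles_deg: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode != "parallel":
            raise GeometryError("only parallel-beam geometry is supported")
        if self.angles_deg is None:
            self.angles_deg = np.arange(self.n_angles) * (180.0 / self.n_angles)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.angles_deg.size != self.n_angles:
            raise GeometryError("angles_deg length must equal n_angles")

    @property
    def detector_width_mm(self) -> float:
        return self.n_det * self.det_spacing_mm

    def det_coords_mm(self) -> np.ndarray:
        """Detector column center coordinates (mm), centered on the axis."""
        return (np.arange(self.n_det) + 0.5 - self.n_det / 2.0) * self.det_spacing_mm

    def check_covers(self, grid_size: int, voxel_size_mm: float) -> None:
        diagonal = np.sqrt(2.0) * grid_size * voxel_size_mm
        if self.detector_width_mm < diagonal:
            raise GeometryError(
                f"detector width {self.detector_width_mm:.2f} mm does not cover "
                f"the phantom diagonal {diagonal:.2f} mm"
            )


def fixture_geometry(grid_size: int, voxel_size_mm: float, n_angles: int) -> ScanGeometry:
    """Default margin rule: detector columns = next multiple of 16 covering the diagonal."""
    needed = int(np.ceil(np.sqrt(2.0) * grid_size))
    n_det = 16 * int(np.ceil(needed / 16))
    return ScanGeometry(
        n_angles=n_angles, n_det=n_det, det_spacing_mm=voxel_size_mm, n_rows=grid_size
    )
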