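"""Random multi-material ellipsoid phantoms.

A phantom is a cube of voxels holding a per-voxel weight vector over an
ordered material list.  Ellipsoids of distinct tissues are placed fully
inside a containment sphere; where ellipsoids overlap the voxel becomes an
equal-volume mixture of the involved materials, gaps inside the sphere are
water, and everything outside the sphere is air.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .materials import TISSUE_POOL, MaterialSpec, default_materials, material_attenuation


class ConfigurationError(ValueError):
    """Raised for phantom/geometry configurations that cannot be realized."""


@dataclass
class PhantomConfig:
    grid_size: int = 256
    voxel_size_mm: float = 0.11
    n_ellipsoids: int = 5
    sphere_radius_mm: float = 12.8
    material_pool: tuple[str, ...] = TISSUE_POOL
    # semiaxes sampled uniformly in [semiaxis_min, semiaxis_max] * sphere radius
    semiaxis_min: float = 0.1
    semiaxis_max: float = 0.5


@dataclass
class SpectralPhantom:
    """Voxelized material-mixture volume.

    mixture_volume has shape (n_materials, n, n, n); weights sum to 1 in every
    voxel.  material_list fixes the channel order.
    """

    mixture_volume: np.ndarray
    voxel_size_mm: float
    material_list: list[MaterialSpec]
    containment_sphere_radius_mm: float = field(default=0.0)

    @property
    def grid_size(self) -> int:
        return self.mixture_volume.shape[1]

    def material_index(self, name: str) -> int:
        for i, m in enumerate(self.material_list):
            if m.name == name:
                return i
        raise KeyError(name)

    def check_invariants(self) -> None:
        totals = self.mixture_volume.sum(axis=0)
        if not np.allclose(totals, 1.0, atol=1e-6):
            raise ValueError("per-voxel material weights must sum to 1")


def _voxel_centers_mm(n: int, voxel_mm: float) -> np.ndarray:
    return (np.arange(n) + 0.5 - n / 2.0) * voxel_mm


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=rng).as_matrix()


def generate_phantom(config: PhantomConfig, seed: int) -> SpectralPhantom:
    """Generate a random ellipsoid phantom; bit-reproducible for a fixed seed.

    Ellipsoid centers are sampled uniformly in a sphere of radius
    (R - max semiaxis) so every ellipsoid is fully contained; semiaxes are
    uniform in [semiaxis_min, semiaxis_max] * R and orientations uniform over
    rotations.
    """
    n = config.grid_size
    if n < 8:
        raise ConfigurationError("grid size must be at least 8")
    if config.n_ellipsoids < 0:
        raise ConfigurationError("n_ellipsoids must be nonnegative")
    radius = config.sphere_radius_mm
    half_edge = n * config.voxel_size_mm / 2.0
    if radius > half_edge:
        raise ConfigurationError(
            f"containment sphere radius {radius} mm exceeds half cube edge {half_edge} mm"
        )

    rng = np.random.default_rng(seed)
    replace = config.n_ellipsoids > len(config.material_pool)
    chosen = [
        str(name)
        for name in rng.choice(
            np.array(config.material_pool), size=config.n_ellipsoids, replace=replace
        )
    ]
    materials = default_materials(["water", "air"] + chosen)

    coords = _voxel_centers_mm(n, config.voxel_size_mm)
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)  # (n, n, n, 3)
    sphere = xx**2 + yy**2 + zz**2 <= radius**2

    masks = []
    for _ in range(config.n_ellipsoids):
        for _attempt in range(1000):
            semi = rng.uniform(config.semiaxis_min * radius, config.semiaxis_max * radius, size=3)
            max_c = radius - semi.max()
            # uniform direction * cube-root radius for uniformity in the ball
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center = direction * max_c * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)
            if np.linalg.norm(center) + semi.max() <= radius:
                break
        else:  # pragma: no cover - sampling construction guarantees containment
            raise ConfigurationError("could not place ellipsoid inside the sphere")
        rot = _random_rotation(rng)
        local = (pts - center) @ rot  # rotate into ellipsoid frame
        masks.append(((local / semi) ** 2).sum(axis=-1) <= 1.0)

    mixture = np.zeros((2 + config.n_ellipsoids, n, n, n), dtype=np.float32)
    if masks:
        stack = np.stack(masks)  # (n_ell, n, n, n)
        count = stack.sum(axis=0)
        occupied = count > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(occupied, 1.0 / np.maximum(count, 1), 0.0)
        for k, mask in enumerate(stack):
            mixture[2 + k][mask] = share[mask]
    else:
        occupied = np.zeros((n, n, n), dtype=bool)
    mixture[0][sphere & ~occupied] = 1.0  # water fills the gaps
    mixture[1][~sphere] = 1.0  # air outside the sphere

    phantom = SpectralPhantom(
        mixture_volume=mixture,
        voxel_size_mm=config.voxel_size_mm,
        material_list=materials,
        containment_sphere_radius_mm=radius,
    )
    phantom.check_invariants()
    return phantom


def phantom_to_mu_volume(phantom: SpectralPhantom, energy_kev: float) -> np.ndarray:
    """Scalar volume of linear attenuation (cm^-1) at one energy.

    mu_voxel = sum_k weight_k * mu_k(E); weights must already be normalized.
    """
    totals = phantom.mixture_volume.sum(axis=0)
    if not np.allclose(totals, 1.0, atol=1e-5):
        raise ValueError("phantom weight vectors are not normalized")
    mu = np.zeros(phantom.mixture_volume.shape[1:], dtype=np.float64)
    for weights, material in zip(phantom.mixture_volume, phantom.material_list):
        mu += weights.astype(np.float64) * material_attenuation(material, float(energy_kev))
    return mu
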