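"""Material specifications and energy-dependent attenuation.

A :class:`MaterialSpec` couples a density with a tabulated mass-attenuation
curve mu/rho(E).  Linear attenuation is obtained by log-log interpolation of
the table and multiplication by density; no extrapolation outside the
tabulated range is permitted.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

#: tissue pool from which phantom ellipsoids draw their materials
TISSUE_POOL = (
    "soft_tissue",
    "adipose",
    "brain_gray_matter",
    "brain_white_matter",
    "blood",
    "cortical_bone",
)


@dataclass(frozen=True)
class MaterialSpec:
    """A named material with density (g/cm^3) and a mu/rho table (cm^2/g)."""

    name: str
    density: float
    energy_grid: np.ndarray = field(repr=False)
    mass_attenuation: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, dtype=float)
        m = np.asarray(self.mass_attenuation, dtype=float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("energy grid and mu/rho curve must be matching 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(m < 0):
            raise ValueError("mass attenuation must be nonnegative")
        object.__setattr__(self, "energy_grid", e)
        object.__setattr__(self, "mass_attenuation", m)

    def linear_attenuation(self, energies_kev) -> np.ndarray:
        """Linear attenuation mu(E) in cm^-1 at the requested energies.

        Interpolates mu/rho log-log between table knots; energies outside the
        tabulated range raise rather than extrapolate.
        """
        return material_attenuation(self, energies_kev)


def material_attenuation(material: MaterialSpec, energies_kev) -> np.ndarray:
    """mu(E) = density * mu/rho(E) with log-log interpolation of the table."""
    e = np.atleast_1d(np.asarray(energies_kev, dtype=float))
    grid, mu_rho = material.energy_grid, material.mass_attenuation
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise ValueError(
            f"energy outside tabulated range [{grid[0]}, {grid[-1]}] keV for {material.name}"
        )
    log_mu = np.interp(np.log(e), np.log(grid), np.log(mu_rho))
    out = material.density * np.exp(log_mu)
    return out if np.ndim(energies_kev) else float(out[0])


def _read_table(text: str) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict = {}
    energies, values = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        cols = line.split()
        energies.append(float(cols[0]))
        values.append(float(cols[1]))
    return np.array(energies), np.array(values), meta


def load_material_table(path_or_text, name: str, density: float | None = None) -> MaterialSpec:
    """Load a two-column (keV, cm^2/g) text table into a MaterialSpec.

    `density` overrides any `density_g_cm3` recorded in the table header.
    """
    try:
        text = path_or_text.read_text()
    except AttributeError:
        with open(path_or_text) as fh:
            text = fh.read()
    energy, mu_rho, meta = _read_table(text)
    if density is None:
        if "density_g_cm3" not in meta:
            raise ValueError(f"no density given or recorded in table for {name}")
        density = float(meta["density_g_cm3"])
    return MaterialSpec(name=name, density=density, energy_grid=energy, mass_attenuation=mu_rho)


def packaged_material(name: str) -> MaterialSpec:
    """Load one of the packaged synthetic material tables by name."""
    resource = importlib.resources.files("pcct.data") / f"matten_{name}_synthetic.txt"
    return load_material_table(resource, name=name)


def default_materials(names=None) -> list[MaterialSpec]:
    """Load the packaged materials (all eight by default, in a fixed order)."""
    if names is None:
        names = ("water", "air") + TISSUE_POOL
    return [packaged_material(n) for n in names]
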